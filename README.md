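# timema-ecoevo

Eco-evolutionary analysis of camouflage maladaptation and arthropod
community structure in a mapped chaparral network of host plants, built
around the stick insect *Timema cristinae*.

## The scientific problem

*Timema cristinae* carries heritable colour-pattern morphs: **striped**
individuals are well camouflaged on *Adenostoma fasciculatum* and
conspicuous on *Ceanothus spinosus*; **unstriped** individuals are the
reverse; rare **melanic** individuals show no differential crypsis. Bird
predation selects for local camouflage, while gene flow across the
host-plant mosaic continually reintroduces the wrong morph. The
**maladaptation** of a local population is the realized frequency of its
poorly camouflaged morph (melanics excluded):

    m = n_unstriped / (n_striped + n_unstriped)   on Adenostoma
    m = n_striped  / (n_striped + n_unstriped)    on Ceanothus

This package implements the full observational-survey analysis that asks
how maladaptation covaries with stick-insect abundance, with the
abundance, species richness and body-size structure of the cohabiting
arthropod community, and with host-plant foliar chemistry — plus a
synthetic-data generator that emulates the survey so every stage can be
verified by parameter recovery.

## The statistics at its core

* **Connectivity** (expected immigrant supply) of patch *i* under an
  exponential dispersal kernel with mean movement distance 1/α (2 m):

      C_i = Σ_{j≠i} N_j · (α²/2π) · exp(−α d_ij)

  weighted by *Timema* or by arthropod abundances.
* **Length–mass allometry**: per-morphospecies quadratic OLS
  (mass = c₀ + c₁L + c₂L²) fitted to a weighed subset spanning the length
  range (15 individuals for common morphospecies), used to predict wet
  mass for everyone else.
* **Mass–abundance slope (MAS)**: the range of ln biomass across *all*
  plants is split into 20 equal bins; per plant, OLS of ln(abundance) on
  bin rank over the non-empty bins. Re-centring rank on bin *c* makes the
  intercept the predicted ln abundance at *c*; regressing each of the 20
  intercepts on maladaptation locates which body-size classes respond
  (the intercept scan).
* **Model suites**: quasi-Poisson GLMs (Poisson mean, Pearson-dispersion
  inflated SEs, t tests on residual df) for *Timema* abundance, ≥5 mm
  arthropod abundance and richness; OLS for MAS and foliar C:N. Backward
  selection at α = 0.10 with marginality, host-specific simple effects
  via alternate dummy contrasts with mean-centred covariates, and partial
  adjusted r² (adjusted-R² drop on term deletion, computed on √counts).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
network drawn under the survey's conditions (146 plants, half per host,
70 × 50 m):

```sh
python analysis/01_simulate_network.py --seed 1
python analysis/02_derive_predictors.py
python analysis/03_fit_allometry.py
python analysis/04_mass_abundance.py
python analysis/05_model_suites.py
python analysis/06_recovery.py --replicates 50
```

With `--seed 1` the first five steps print:

```
network: 146 plants (73 Adenostoma, 73 Ceanothus)
Timema: 425 total — striped 242, unstriped 156, melanic 27 (6.4%)
arthropods collected (>=2 mm): 3170 in 147 morphospecies

mean maladaptation: 0.103 on Adenostoma, 0.369 on Ceanothus (gap +0.266)
>=5 mm arthropods per plant: mean 7.5, richness mean 6.9

147 morphospecies fitted -> results/allometry_fits.csv
median relative error of predicted mass at mid-range length: 1.65% over 128 quadratic fits

MAS defined for 146/146 plants; mean slope -0.049 (negative = small bodies dominate)

timema_abundance       maladaptation removed (pre-removal p = 0.159)
arthropod_abundance    maladaptation b = +0.844, p = 0.0006
richness               maladaptation b = +0.752, p = 0.0015
mas                    maladaptation b = +0.058, p = 0.0833
cn                     maladaptation b = -10.864, p = 0.0000
```

Reading the output: maladaptation does not predict *Timema* abundance on
this draw, but plants with more poorly camouflaged *Timema* hold **more**
arthropods (the coefficient is on the log link: b = +0.84 means a fully
maladapted plant holds e^0.84 ≈ 2.3× the arthropods of a fully camouflaged
one, all else equal), more ≥5 mm morphospecies, and more nitrogen-rich
foliage (lower C:N). These are the generator's seeded effects being
recovered through the complete pipeline — morph tallies, allometry,
binning, backward selection and all.

The same pipeline runs on any data in the documented CSV formats through
the CLI:

```sh
ecoevo simulate --seed 42 --out data/
ecoevo run-suite --plants data/plants.csv --arthropods data/arthropods.csv \
                 --timema data/timema.csv --out results/
ecoevo report --results results/
```

## Layout

```
src/timema_ecoevo/   the library (io, predictors, allometry,
                     mass_abundance, glm, suites, simulate, recovery,
                     pipeline, cli)
analysis/            numbered narrative drivers (simulate → recover)
tests/               pytest suite, including end-to-end acceptance checks
docs/methods.md      modelling assumptions, parameter choices, limitations
```
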