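"""Synthetic plant-arthropod network generator.

Emulates the survey's study conditions — a 70 x 50 m chaparral network of
146 host plants, half *Adenostoma fasciculatum* (A) and half *Ceanothus
spinosus* (C) — with every effect size controllable, so each pipeline
stage and the full model suite can be verified by parameter recovery
without any field data.

Generative model
----------------
* Plants are placed uniformly in the extent; volumes are lognormal per
  host (C bushes larger on average, as in the field network).
* Latent camouflage maladaptation is a logistic-transformed Gaussian
  random field with exponential spatial covariance (gene flow makes
  neighbouring populations alike) plus a host-mean offset; the default
  offsets put mean maladaptation on C about 26 percentage points above A,
  the asymmetry an Adenostoma-dominated surrounding landscape produces.
* *Timema* counts are Poisson with log-mean in ln volume and connectivity;
  connectivity is computed in two passes (latent abundance -> kernel ->
  counts) to avoid circular simultaneity.  Morph tallies are binomial
  given the latent field, with a ~7% melanic fraction.  Maladaptation —
  by definition the realized morph frequency of the censused local
  population — is then computed from the tallies, and it (not the latent
  field) is what drives the ecological effects below, since predators
  respond to the morphs actually present.
* Non-*Timema* arthropod counts are gamma-mixed Poisson with quasi-Poisson
  dispersion ``overdispersion`` (variance = phi * mean), log-mean in ln
  volume, realized maladaptation and arthropod connectivity.
* Individuals get morphospecies from a lognormal relative-abundance
  profile; body lengths are lognormal per morphospecies, truncated at the
  2 mm collection floor, with a host-A mean shift of
  ``beta_malad_mas_hostA * m`` on the ln scale (the seeded size-spectrum
  tilt).  True wet masses follow per-morphospecies quadratic allometries
  with 5% Gaussian noise; only the 15-per-morphospecies weighing subset
  carries a measured mass in the output, as in the field protocol.
* Foliar %C is host-independent noise around 48%; %N has a host base
  (C. spinosus fixes nitrogen, so higher %N) plus ``beta_malad_cn * m``.

``truth.json`` records every seeded parameter and the latent per-plant
fields, so recovery experiments can compare estimates against truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import select_weighing_indices
from .predictors import ConnectivityParams, connectivity

__all__ = ["SimConfig", "SimulatedNetwork", "generate_network"]

COLLECTION_FLOOR_MM = 2.0
MAX_LOG_MEAN = 20.0  # guard against infeasible configs


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the field-network conditions."""

    n_plants: int = 146  # half per host
    extent: tuple[float, float] = (70.0, 50.0)  # metres
    # lognormal(mu of ln m^3, sigma) per host; C bushes larger
    volume_lognormal_a: tuple[float, float] = (-0.2, 0.8)
    volume_lognormal_c: tuple[float, float] = (0.5, 0.8)
    alpha: float = 0.5  # dispersal kernel, mean movement 2 m
    # maladaptation field, logit scale; means and spread reproduce the field
    # network's broad mosaic (mean ~0.25 on A vs ~0.51 on C, i.e. about 26
    # percentage points higher on Ceanothus, with wide between-plant scatter)
    malad_range_m: float = 10.0
    malad_sd: float = 1.5
    malad_mean_logit_a: float = -2.1
    malad_mean_logit_c: float = 0.0
    melanic_fraction: float = 0.07
    # Timema count model (Poisson, log link)
    beta0_timema: float = 0.7
    beta_volume_timema: float = 0.5
    beta_conn_timema: float = 2.0
    # arthropod count model (gamma-Poisson, log link)
    beta0_arth: float = 2.3
    beta_volume: float = 0.5
    beta_malad_abund: float = 0.5
    beta_conn: float = 1.0
    overdispersion: float = 2.0  # quasi-Poisson phi; 1 = Poisson
    # community composition and body sizes
    n_morphospecies: int = 149
    ln_length_mu_mean: float = math.log(4.0)  # mm
    ln_length_mu_sd: float = 0.45
    ln_length_sigma: float = 0.35
    beta_malad_mas_hostA: float = 0.3  # ln-length shift per unit maladaptation, host A
    # allometry (mass mg = c0 + c1 L + c2 L^2), ranges of per-species draws
    allometry_c0: tuple[float, float] = (0.1, 0.5)
    allometry_c1: tuple[float, float] = (0.01, 0.05)
    allometry_c2: tuple[float, float] = (0.02, 0.06)
    mass_noise_cv: float = 0.05
    # foliar chemistry (percent by mass)
    pct_carbon_mean: float = 48.0
    pct_carbon_sd: float = 1.5
    pct_nitrogen_base_a: float = 1.5
    pct_nitrogen_base_c: float = 2.4
    pct_nitrogen_sd: float = 0.25
    beta_malad_cn: float = 0.4  # %N added per unit maladaptation
    seed: int = 0

    def __post_init__(self):
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if not 0 <= self.melanic_fraction <= 1:
            raise ValueError("melanic_fraction must lie in [0, 1]")
        for name in ("malad_sd", "ln_length_sigma", "mass_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedNetwork:
    plants: pd.DataFrame
    timema: pd.DataFrame
    arthropods: pd.DataFrame
    truth: dict

    def to_inputs(self):
        """The three tables as validated domain objects, bypassing CSV I/O."""
        from .io import ArthropodIndividual, MorphCounts, PlantPatch

        plants = [
            PlantPatch(
                plant_id=r.plant_id,
                host=r.host,
                x=r.x,
                y=r.y,
                length_m=r.length_m,
                width_m=r.width_m,
                height_m=r.height_m,
                size_year=int(r.size_year),
                pct_carbon=r.pct_carbon,
                pct_nitrogen=r.pct_nitrogen,
            )
            for r in self.plants.itertuples()
        ]
        arthropods = [
            ArthropodIndividual(
                plant_id=r.plant_id,
                morphospecies_id=r.morphospecies_id,
                length_mm=r.length_mm,
                wet_mass_mg=None if pd.isna(r.wet_mass_mg) else float(r.wet_mass_mg),
                mass_source="predicted" if pd.isna(r.wet_mass_mg) else "measured",
            )
            for r in self.arthropods.itertuples()
        ]
        timema = [
            MorphCounts(
                plant_id=r.plant_id,
                n_striped=int(r.n_striped),
                n_unstriped=int(r.n_unstriped),
                n_melanic=int(r.n_melanic),
            )
            for r in self.timema.itertuples()
        ]
        return plants, arthropods, timema

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.plants.to_csv(out / "plants.csv", index=False)
        self.timema.to_csv(out / "timema.csv", index=False)
        self.arthropods.to_csv(out / "arthropods.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def _gaussian_random_field(
    xy: np.ndarray, range_m: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean GRF with exponential covariance sd^2 * exp(-d / range)."""
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    cov = sd**2 * np.exp(-d / range_m)
    cov[np.diag_indices_from(cov)] += 1e-9  # jitter for Cholesky
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(len(xy))


def _check_feasible(log_mean: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(log_mean)) or log_mean.max() > MAX_LOG_MEAN:
        raise ValueError(f"infeasible config: {what} log-mean exceeds {MAX_LOG_MEAN}")


def generate_network(cfg: SimConfig) -> SimulatedNetwork:
    """Draw one complete synthetic survey; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plants
    n_a = n // 2
    hosts = np.array(["A"] * n_a + ["C"] * (n - n_a))
    xy = np.column_stack(
        [rng.uniform(0, cfg.extent[0], n), rng.uniform(0, cfg.extent[1], n)]
    )
    mu_v = np.where(hosts == "A", cfg.volume_lognormal_a[0], cfg.volume_lognormal_c[0])
    sd_v = np.where(hosts == "A", cfg.volume_lognormal_a[1], cfg.volume_lognormal_c[1])
    ln_volume = rng.normal(mu_v, sd_v)
    volume = np.exp(ln_volume)
    # split volume into plausible L x W x H around a cube root
    s = np.cbrt(volume)
    aspect = np.exp(rng.normal(0, 0.15, (n, 2)))
    length = s * aspect[:, 0]
    width = s * aspect[:, 1]
    height = volume / (length * width)

    # latent maladaptation propensity field (spatial structure from gene flow)
    host_mean = np.where(hosts == "A", cfg.malad_mean_logit_a, cfg.malad_mean_logit_c)
    logit_m = host_mean + _gaussian_random_field(xy, cfg.malad_range_m, cfg.malad_sd, rng)
    malad_field = 1.0 / (1.0 + np.exp(-logit_m))

    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    params = ConnectivityParams(alpha=cfg.alpha)

    # Timema: two-pass (latent abundance -> connectivity -> counts)
    log_mu_latent = cfg.beta0_timema + cfg.beta_volume_timema * ln_volume
    _check_feasible(log_mu_latent, "latent Timema")
    latent_t = np.exp(log_mu_latent)
    conn_t = connectivity(latent_t, d, params)
    log_mu_t = cfg.beta0_timema + cfg.beta_volume_timema * ln_volume + cfg.beta_conn_timema * conn_t
    _check_feasible(log_mu_t, "Timema")
    timema_count = rng.poisson(np.exp(log_mu_t))
    n_melanic = rng.binomial(timema_count, cfg.melanic_fraction)
    non_mel = timema_count - n_melanic
    n_bad = rng.binomial(non_mel, malad_field)  # poorly camouflaged morph
    n_striped = np.where(hosts == "A", non_mel - n_bad, n_bad)
    n_unstriped = np.where(hosts == "A", n_bad, non_mel - n_bad)

    # maladaptation is the *realized* morph frequency of the censused local
    # population — predators respond to the frequency actually present; the
    # latent field only shapes where morphs occur.  Plants without striped or
    # unstriped Timema have no defined frequency; the field value stands in
    # (those plants cannot enter maladaptation models downstream anyway).
    with np.errstate(invalid="ignore"):
        malad = np.where(non_mel > 0, n_bad / np.maximum(non_mel, 1), malad_field)

    # arthropods: gamma-mixed Poisson with quasi dispersion phi
    latent_a = np.exp(cfg.beta0_arth + cfg.beta_volume * ln_volume)
    conn_a = connectivity(latent_a, d, params)
    log_mu_a = (
        cfg.beta0_arth
        + cfg.beta_volume * ln_volume
        + cfg.beta_malad_abund * malad
        + cfg.beta_conn * conn_a
    )
    _check_feasible(log_mu_a, "arthropod")
    mu_a = np.exp(log_mu_a)
    if cfg.overdispersion > 1:
        shape = mu_a / (cfg.overdispersion - 1)
        lam = rng.gamma(shape, cfg.overdispersion - 1)
    else:
        lam = mu_a
    arth_count = rng.poisson(lam)

    # morphospecies pool: lognormal relative abundances, lognormal sizes
    ms_weights = rng.lognormal(0.0, 1.2, cfg.n_morphospecies)
    ms_weights /= ms_weights.sum()
    ms_mu = rng.normal(cfg.ln_length_mu_mean, cfg.ln_length_mu_sd, cfg.n_morphospecies)
    ms_c0 = rng.uniform(*cfg.allometry_c0, cfg.n_morphospecies)
    ms_c1 = rng.uniform(*cfg.allometry_c1, cfg.n_morphospecies)
    ms_c2 = rng.uniform(*cfg.allometry_c2, cfg.n_morphospecies)

    plant_ids = [f"{i + 1:03d}" for i in range(n)]
    rows_pid, rows_ms, rows_len, rows_true_mass = [], [], [], []
    floor_ln = math.log(COLLECTION_FLOOR_MM)
    for i in range(n):
        k = int(arth_count[i])
        if k == 0:
            continue
        ms = rng.choice(cfg.n_morphospecies, size=k, p=ms_weights)
        shift = cfg.beta_malad_mas_hostA * malad[i] if hosts[i] == "A" else 0.0
        mu_ln = ms_mu[ms] + shift
        ln_len = rng.normal(mu_ln, cfg.ln_length_sigma)
        # truncate at the collection floor by redrawing
        for _ in range(100):
            small = ln_len < floor_ln
            if not small.any():
                break
            ln_len[small] = rng.normal(mu_ln[small], cfg.ln_length_sigma)
        ln_len = np.maximum(ln_len, floor_ln)
        lengths = np.exp(ln_len)
        true_mass = ms_c0[ms] + ms_c1[ms] * lengths + ms_c2[ms] * lengths**2
        true_mass = true_mass * np.exp(
            rng.normal(0, cfg.mass_noise_cv, k) - cfg.mass_noise_cv**2 / 2
        )
        rows_pid.extend([plant_ids[i]] * k)
        rows_ms.extend(f"ms{m + 1:03d}" for m in ms)
        rows_len.extend(np.round(lengths, 3))
        rows_true_mass.extend(true_mass)

    arthropods = pd.DataFrame(
        {
            "plant_id": rows_pid,
            "morphospecies_id": rows_ms,
            "length_mm": rows_len,
            "wet_mass_mg": np.round(rows_true_mass, 4),
        }
    )
    # emulate the weighing protocol: mass recorded only for the 15-rule subset
    if len(arthropods):
        keep_mass = np.zeros(len(arthropods), dtype=bool)
        for _, idx in arthropods.groupby("morphospecies_id").groups.items():
            pos = np.asarray(idx)
            picks = select_weighing_indices(
                arthropods.loc[pos, "length_mm"].to_numpy(), seed=cfg.seed
            )
            keep_mass[pos[picks]] = True
        arthropods.loc[~keep_mass, "wet_mass_mg"] = np.nan

    pct_c = rng.normal(cfg.pct_carbon_mean, cfg.pct_carbon_sd, n)
    n_base = np.where(hosts == "A", cfg.pct_nitrogen_base_a, cfg.pct_nitrogen_base_c)
    pct_n = np.clip(
        n_base + cfg.beta_malad_cn * malad + rng.normal(0, cfg.pct_nitrogen_sd, n),
        0.3,
        None,
    )

    plants = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "host": hosts,
            "x": np.round(xy[:, 0], 2),
            "y": np.round(xy[:, 1], 2),
            "length_m": np.round(length, 3),
            "width_m": np.round(width, 3),
            "height_m": np.round(height, 3),
            "size_year": 2013,
            "pct_carbon": np.round(pct_c, 2),
            "pct_nitrogen": np.round(pct_n, 2),
        }
    )
    timema = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "n_striped": n_striped,
            "n_unstriped": n_unstriped,
            "n_melanic": n_melanic,
        }
    )
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()
        },
        "latent": {
            "maladaptation": [float(v) for v in malad],
            "maladaptation_field": [float(v) for v in malad_field],
            "conn_timema": [float(v) for v in conn_t],
            "conn_arthropod": [float(v) for v in conn_a],
            "ln_volume": [float(v) for v in ln_volume],
            "timema_mean": [float(v) for v in np.exp(log_mu_t)],
            "arthropod_mean": [float(v) for v in mu_a],
        },
        "allometry": {
            f"ms{i + 1:03d}": [float(ms_c0[i]), float(ms_c1[i]), float(ms_c2[i])]
            for i in range(cfg.n_morphospecies)
        },
    }
    return SimulatedNetwork(plants=plants, timema=timema, arthropods=arthropods, truth=truth)
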