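"""End-to-end pipeline: raw survey tables -> per-plant summary -> model suites.

``derive_summary`` computes every per-plant variable the model suites
consume: maladaptation (optionally passed through a predation-intensity
transform), *Timema*- and arthropod-weighted connectivity, ln plant
volume (with 2013-from-2014 imputation when a calibration table is
supplied), foliar C:N, the >=5 mm community metrics, and the per-plant
mass-abundance slope from predicted biomasses.

``run_all`` drives the whole analysis and writes the derived tables, the
five suite coefficient tables with removal traces, the intercept scan,
and a machine-readable JSON summary keyed like
``"arthropod_abundance.maladaptation.b"``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry as allo
from . import mass_abundance as mas
from . import predictors as pred
from .glm import ModelResult, is_interaction
from .io import (
    ArthropodIndividual,
    CommunitySummary,
    MorphCounts,
    PlantPatch,
    read_arthropods,
    read_plants,
    read_timema,
    summaries_to_frame,
    write_summary,
)
from .suites import run_model_suite

__all__ = ["PipelineConfig", "derive_summary", "DerivedData", "run_all"]

log = logging.getLogger("timema_ecoevo")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable analysis parameters, all defaulting to the survey protocol."""

    threshold_mm: float = 5.0  # size floor for abundance / richness
    alpha: float = 0.5  # dispersal kernel, 1/alpha = 2 m
    predation_k: float = 0.0  # 0 = raw morph frequency
    n_bins: int = 20
    alpha_retain: float = 0.10
    melanic_in_abundance: bool = True
    mas_threshold_mm: float | None = None  # None = all collected (>=2 mm floor)
    mas_host_filter: str | None = "A"  # intercept scan restricted to this host
    seed: int = 0


@dataclass
class DerivedData:
    """Everything computed between raw tables and the model suites."""

    summary: pd.DataFrame
    summaries: list[CommunitySummary]
    allometry_fits: dict[str, allo.AllometryFit]
    bin_scheme: mas.BinScheme | None
    mas_fits: list[mas.MassAbundanceFit]
    masses: pd.DataFrame  # per individual: plant_id, morphospecies_id, mass_mg, source


def _predicted_masses(
    arthropods: list[ArthropodIndividual],
) -> tuple[pd.DataFrame, dict[str, allo.AllometryFit]]:
    """Fit per-morphospecies allometries on weighed individuals, predict the rest."""
    by_ms: dict[str, list[ArthropodIndividual]] = {}
    for a in arthropods:
        by_ms.setdefault(a.morphospecies_id, []).append(a)
    fits: dict[str, allo.AllometryFit] = {}
    rows = []
    for ms_id, inds in by_ms.items():
        weighed = [(i.length_mm, i.wet_mass_mg) for i in inds if i.wet_mass_mg is not None]
        fit = allo.fit_length_mass(weighed, ms_id) if weighed else None
        fits[ms_id] = fit
        for i in inds:
            if i.wet_mass_mg is not None:
                mass, source = i.wet_mass_mg, "measured"
            elif fit is not None:
                mass, source = allo.predict_mass(fit, i.length_mm).mass_mg, "predicted"
            else:
                mass, source = np.nan, "unpredictable"  # no weighed conspecifics
            rows.append(
                {
                    "plant_id": i.plant_id,
                    "morphospecies_id": ms_id,
                    "length_mm": i.length_mm,
                    "mass_mg": mass,
                    "source": source,
                }
            )
    return pd.DataFrame(rows), fits


def derive_summary(
    plants: list[PlantPatch],
    arthropods: list[ArthropodIndividual],
    timema: list[MorphCounts],
    config: PipelineConfig = PipelineConfig(),
    volume_calibration: pd.DataFrame | None = None,
) -> DerivedData:
    """Compute the per-plant summary table from the three validated tables.

    ``volume_calibration``, when given, holds columns ``v2013``, ``v2014``,
    ``host`` for plants measured in both years; its least-squares fit is
    applied to plants whose ``size_year`` is 2014.
    """
    by_plant_t = {t.plant_id: t for t in timema}
    by_plant_a: dict[str, list[ArthropodIndividual]] = {p.plant_id: [] for p in plants}
    for a in arthropods:
        by_plant_a.setdefault(a.plant_id, []).append(a)

    # volumes (optionally imputing 2013 size from a 2014 measurement)
    impute = None
    min_2013 = None
    if volume_calibration is not None:
        impute = pred.fit_volume_imputation(
            volume_calibration["v2013"], volume_calibration["v2014"], volume_calibration["host"]
        )
        min_2013 = float(volume_calibration["v2013"].min())
    volumes: dict[str, float | None] = {}
    for p in plants:
        v, _ = pred.plant_volume(p)
        if v is not None and p.size_year == 2014 and impute is not None:
            v = pred.impute_volume_2013(v, p.host, impute, min_observed_2013=min_2013)
        volumes[p.plant_id] = v

    # connectivity from observed abundances
    distances = pred.pairwise_distances(plants)
    metrics = {
        p.plant_id: pred.community_metrics(
            by_plant_a[p.plant_id],
            by_plant_t.get(p.plant_id),
            threshold_mm=config.threshold_mm,
            melanic_in_abundance=config.melanic_in_abundance,
        )
        for p in plants
    }
    t_ab = np.array([metrics[p.plant_id]["timema_abundance"] for p in plants], dtype=float)
    a_ab = np.array(
        [metrics[p.plant_id]["arthropod_abundance_ge5"] for p in plants], dtype=float
    )
    kernel = pred.ConnectivityParams(alpha=config.alpha)
    conn_t = pred.connectivity(t_ab, distances, kernel)
    conn_a = pred.connectivity(a_ab, distances, kernel)

    # biomass spectrum: predicted masses, global bins, per-plant slope
    masses, fits = _predicted_masses(arthropods)
    scheme = None
    mas_fits: list[mas.MassAbundanceFit] = []
    mas_slope: dict[str, float | None] = {p.plant_id: None for p in plants}
    usable = masses.dropna(subset=["mass_mg"]) if len(masses) else masses
    if config.mas_threshold_mm is not None and len(usable):
        usable = usable[usable["length_mm"] >= config.mas_threshold_mm]
    if len(usable) >= 2 and usable["mass_mg"].nunique() > 1:
        ln_mass = np.log(usable["mass_mg"].to_numpy())
        scheme = mas.make_bins(ln_mass, n_bins=config.n_bins)
        for p in plants:
            sel = usable["plant_id"] == p.plant_id
            counts = mas.bin_abundances(np.log(usable.loc[sel, "mass_mg"]), scheme)
            fit = mas.mass_abundance_fit(p.plant_id, counts, n_bins=config.n_bins)
            mas_fits.append(fit)
            mas_slope[p.plant_id] = fit.slope

    transform = pred.PredationTransform(shape_k=config.predation_k)
    summaries = []
    for i, p in enumerate(plants):
        counts = by_plant_t.get(p.plant_id, MorphCounts(plant_id=p.plant_id))
        m = pred.maladaptation(counts, p.host)
        if m is not None and config.predation_k > 0:
            m = pred.predation_intensity(m, transform)
        v = volumes[p.plant_id]
        cn = (
            pred.cn_ratio(p.pct_carbon, p.pct_nitrogen)
            if p.pct_carbon is not None and p.pct_nitrogen is not None
            else None
        )
        summaries.append(
            CommunitySummary(
                plant_id=p.plant_id,
                host=p.host,
                maladaptation=m,
                conn_timema=float(conn_t[i]),
                conn_arthropod=float(conn_a[i]),
                ln_volume=float(np.log(v)) if v is not None and v > 0 else None,
                cn_ratio=cn,
                mas_slope=mas_slope[p.plant_id],
                **metrics[p.plant_id],
            )
        )
    frame = summaries_to_frame(summaries)
    return DerivedData(
        summary=frame,
        summaries=summaries,
        allometry_fits=fits,
        bin_scheme=scheme,
        mas_fits=mas_fits,
        masses=masses,
    )


def _results_json(results: dict[str, ModelResult]) -> dict:
    out: dict[str, float | int] = {}
    for name, res in results.items():
        out[f"{name}.n"] = res.n_used
        out[f"{name}.dispersion"] = res.dispersion
        for term in res.retained_terms:
            key = term.replace(":", "_x_")
            out[f"{name}.{key}.b"] = res.coef(term)
            out[f"{name}.{key}.t"] = float(res.coefficients.loc[term, "t"])
            out[f"{name}.{key}.p"] = res.pvalue(term)
        for rec in res.removal_trace:
            key = rec["term"].replace(":", "_x_")
            out[f"{name}.{key}.removed.t"] = rec["t"]
            out[f"{name}.{key}.removed.p"] = rec["p"]
        for focal, table in res.simple_effects.items():
            for host in table.index:
                out[f"{name}.{focal}.host_{host}.b"] = float(table.loc[host, "estimate"])
                out[f"{name}.{focal}.host_{host}.p"] = float(table.loc[host, "p"])
        for term, r2 in res.partial_r2.items():
            out[f"{name}.{term.replace(':', '_x_')}.partial_r2"] = r2
    return out


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(
    plants_path: str | Path,
    arthropods_path: str | Path,
    timema_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Full analysis from CSV inputs; writes the results directory, returns the JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    cfg_digest = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    log.info("timema-ecoevo %s config sha256=%s", __version__, cfg_digest)
    for p in (plants_path, arthropods_path, timema_path):
        log.info("input %s sha256=%s", p, _file_hash(Path(p)))

    plants = read_plants(plants_path)
    arthropods = read_arthropods(arthropods_path)
    timema = read_timema(timema_path)
    derived = derive_summary(plants, arthropods, timema, config)
    write_summary(derived.summaries, out / "summary.csv")

    if derived.allometry_fits:
        pd.DataFrame(
            [
                {
                    "morphospecies_id": ms,
                    "c0": f.coef0,
                    "c1": f.coef1,
                    "c2": f.coef2,
                    "n_weighed": f.n_weighed,
                    "length_min_mm": f.length_range[0],
                    "length_max_mm": f.length_range[1],
                    "residual_sd": f.residual_sd,
                }
                for ms, f in derived.allometry_fits.items()
                if f is not None
            ]
        ).to_csv(out / "allometry_fits.csv", index=False)

    results = run_model_suite(derived.summary, alpha_retain=config.alpha_retain)
    for name, res in results.items():
        res.coefficients.to_csv(out / f"suite_{name}_coefficients.csv")
        if res.removal_trace:
            pd.DataFrame(res.removal_trace).to_csv(out / f"suite_{name}_trace.csv", index=False)

    # intercept scan (size-spectrum profile at maladaptation extremes)
    scan = None
    if derived.mas_fits:
        frame = derived.summary.set_index("plant_id")
        host_ok = (
            frame["host"] == config.mas_host_filter
            if config.mas_host_filter
            else pd.Series(True, index=frame.index)
        )
        fits = [f for f in derived.mas_fits if host_ok.get(f.plant_id, False)]
        malad = [frame.loc[f.plant_id, "maladaptation"] for f in fits]
        try:
            scan = mas.intercept_maladaptation_scan(fits, malad)
            scan.to_csv(out / "mas_intercept_scan.csv", index=False)
            mas.plot_intercept_profiles(scan, out / "mas_profile.png")
        except ValueError as e:
            log.warning("intercept scan skipped: %s", e)

    summary_json = _results_json(results)
    if scan is not None:
        sig = scan[scan["significant"]]["bin"].tolist()
        summary_json["mas_scan.significant_bins"] = sig
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2, sort_keys=True))
    return summary_json
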