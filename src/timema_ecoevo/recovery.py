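"""Parameter-recovery experiments over simulated replicates.

Each replicate draws a fresh synthetic network from a :class:`SimConfig`,
runs the full pipeline (derived predictors, allometry, mass-abundance,
model suites with backward selection), and records — for every focal
(suite, term) pair — whether the term was retained, its estimate, and its
95% confidence interval.  The report aggregates retention frequency,
sign-recovery rate among retained replicates, bias, RMSE and CI coverage
against the seeded truth.

Truth mapping: the generator's ``beta_malad_abund``, ``beta_conn``,
``beta_volume`` are on the same log scale as the quasi-Poisson
coefficients, so bias/RMSE/coverage are meaningful; the maladaptation
effects on C:N and MAS act through %N and the individual size
distribution respectively, so only their *sign* is compared there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .glm import average_effect, is_interaction
from .pipeline import PipelineConfig, derive_summary
from .simulate import SimConfig, generate_network
from .suites import run_model_suite

__all__ = ["FocalTerm", "default_focal_terms", "run_replicate", "recovery_experiment"]


@dataclass(frozen=True)
class FocalTerm:
    suite: str
    term: str
    truth: float | None  # comparable-scale truth, or None
    truth_sign: int  # expected sign of the retained coefficient (0 = null)


def default_focal_terms(cfg: SimConfig) -> list[FocalTerm]:
    """The seeded effects worth tracking under a given generator config."""

    def sign(x: float) -> int:
        return 0 if x == 0 else (1 if x > 0 else -1)

    return [
        FocalTerm("arthropod_abundance", "maladaptation", cfg.beta_malad_abund,
                  sign(cfg.beta_malad_abund)),
        FocalTerm("arthropod_abundance", "ln_volume", cfg.beta_volume, sign(cfg.beta_volume)),
        FocalTerm("arthropod_abundance", "conn_arthropod", cfg.beta_conn, sign(cfg.beta_conn)),
        FocalTerm("timema_abundance", "ln_volume", cfg.beta_volume_timema,
                  sign(cfg.beta_volume_timema)),
        FocalTerm("timema_abundance", "conn_timema", cfg.beta_conn_timema,
                  sign(cfg.beta_conn_timema)),
        # %N rises with maladaptation, so C:N falls: sign flips, scale differs
        FocalTerm("cn", "maladaptation", None, -sign(cfg.beta_malad_cn)),
        # ln-length shift on host A tilts the spectrum toward large bodies
        FocalTerm("mas", "maladaptation", None, sign(cfg.beta_malad_mas_hostA)),
    ]


def run_replicate(
    cfg: SimConfig,
    pipeline_config: PipelineConfig | None = None,
    suites: list[str] | None = None,
):
    """One end-to-end pass: simulate -> derive -> model suites."""
    net = generate_network(cfg)
    plants, arthropods, timema = net.to_inputs()
    pc = pipeline_config or PipelineConfig(alpha=cfg.alpha, seed=cfg.seed)
    derived = derive_summary(plants, arthropods, timema, pc)
    results = run_model_suite(derived.summary, alpha_retain=pc.alpha_retain, suites=suites)
    return net, derived, results


def recovery_experiment(
    cfg: SimConfig,
    n_replicates: int,
    seed: int = 0,
    focal: list[FocalTerm] | None = None,
    suites: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate recovery statistics over ``n_replicates`` fresh networks.

    Returns one row per focal term with columns: retained (frequency in the
    final model), detected (retained and significant at the suite threshold,
    judged at-the-average when moderators are retained), detected_with_sign,
    sign_match (rate among retained), mean_estimate, bias, rmse, coverage
    (95% CI covers truth, among retained; NaN where truth is not on the
    coefficient scale).
    """
    focal = focal if focal is not None else default_focal_terms(cfg)
    if suites is None:
        suites = sorted({f.suite for f in focal})
    records: dict[FocalTerm, list[dict]] = {f: [] for f in focal}
    for rep in range(n_replicates):
        rep_seed = (seed + 1_000_003 * rep) % (2**31 - 1)
        _, derived, results = run_replicate(replace(cfg, seed=rep_seed), suites=suites)
        for f in focal:
            res = results[f.suite]
            rec: dict = {"retained": f.term in res.retained_terms, "detected": False}
            if rec["retained"]:
                # evaluate at the average of any retained moderators so the
                # recorded effect is comparable across selection paths; a term
                # kept only by marginality (protecting a chance interaction)
                # does not count as a detected effect unless significant there
                if any(is_interaction(t) and f.term in t.split(":")
                       for t in res.retained_terms):
                    ae = average_effect(res, f.term, derived.summary)
                    est, se, p = ae["estimate"], ae["se"], ae["p"]
                else:
                    est = res.coef(f.term)
                    se = float(res.coefficients.loc[f.term, "se"])
                    p = res.pvalue(f.term)
                df = float(res.coefficients.loc[f.term, "df"])
                half = stats.t.ppf(0.975, df) * se
                rec.update(
                    estimate=est, lo=est - half, hi=est + half,
                    detected=p <= res.spec.alpha_retain,
                )
            records[f].append(rec)

    rows = []
    for f, recs in records.items():
        retained = [r for r in recs if r["retained"]]
        est = np.array([r["estimate"] for r in retained])
        row = {
            "suite": f.suite,
            "term": f.term,
            "truth": f.truth,
            "truth_sign": f.truth_sign,
            "n_replicates": n_replicates,
            "retained": len(retained) / n_replicates,
            "detected": sum(r["detected"] for r in recs) / n_replicates,
            "detected_with_sign": (
                sum(r["detected"] and np.sign(r["estimate"]) == f.truth_sign for r in recs)
                / n_replicates
                if f.truth_sign
                else np.nan
            ),
            "sign_match": (
                float(np.mean(np.sign(est) == f.truth_sign)) if len(est) and f.truth_sign
                else np.nan
            ),
            "mean_estimate": float(est.mean()) if len(est) else np.nan,
            "bias": float(est.mean() - f.truth) if len(est) and f.truth is not None else np.nan,
            "rmse": (
                float(np.sqrt(np.mean((est - f.truth) ** 2)))
                if len(est) and f.truth is not None
                else np.nan
            ),
            "coverage": (
                float(np.mean([r["lo"] <= f.truth <= r["hi"] for r in retained]))
                if len(retained) and f.truth is not None
                else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
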