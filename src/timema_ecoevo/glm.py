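"""Quasi-Poisson / OLS engine with backward selection.

Count responses are modelled as generalized linear models with Poisson
error and quasi-likelihood estimation: the point estimates are Poisson
maximum likelihood (log link), the dispersion is estimated as Pearson
chi-square / (n - p), standard errors are inflated by its square root,
and inference uses t tests on the residual degrees of freedom.
Continuous responses use ordinary least squares.

Model terms are single-column: continuous covariates enter as-is, the
host-plant species as a 0/1 dummy (A = 0, C = 1 by default), and
interactions as products.  Backward selection removes, one step at a
time, the least-significant *eligible* term with p above the retention
threshold (0.10 by default).  Marginality is respected — a main effect is
eligible only once no interaction containing it remains — and an optional
joint-removal rule drops a designated main effect together with its
interaction (used for the maladaptation-by-*Timema*-abundance pair, whose
main effect is only in the model to support the interaction).  The
pre-removal t and p of every removed term are recorded in a trace.

Effect sizes are summarised by partial adjusted r-square: the drop in
adjusted R-square when one term is deleted from an OLS fit on the
(square-root transformed, for counts) response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelResult",
    "build_design",
    "fit_glm",
    "backward_select",
    "simple_effects",
    "average_effect",
    "partial_r2",
]

HOST_COLUMN = "host"


def interaction_parents(term: str) -> list[str]:
    """Split an 'a:b' interaction term into its parent main effects."""
    return term.split(":")


def is_interaction(term: str) -> bool:
    return ":" in term


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model suite.

    ``terms`` are main effects (data columns; ``host`` is the species
    factor), ``interactions`` are ``"a:b"`` strings whose parents must be
    in ``terms``.  ``inclusion_filter`` selects the plants entering the
    suite.  ``joint_removal`` maps an interaction to a main effect that is
    removed together with it when the interaction falls out.
    """

    response: str
    family: str  # "quasipoisson" | "gaussian"
    terms: tuple[str, ...]
    interactions: tuple[str, ...] = ()
    inclusion_filter: Callable[[pd.DataFrame], pd.Series] | None = None
    alpha_retain: float = 0.10
    joint_removal: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.family not in ("quasipoisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        for inter in self.interactions:
            for p in interaction_parents(inter):
                if p not in self.terms:
                    raise ValueError(f"interaction {inter} parent {p} not in terms")


@dataclass
class ModelResult:
    """A fitted suite: final coefficients, dispersion, trace, add-ons."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index term; estimate, se, t, p, df
    dispersion: float  # Pearson chi2 / df (1.0 for gaussian-scale reporting)
    removal_trace: list[dict]  # term, estimate, t, p, step (pre-removal stats)
    retained_terms: list[str]
    n_used: int
    simple_effects: dict[str, pd.DataFrame] = field(default_factory=dict)
    partial_r2: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])

    def pre_removal(self, term: str) -> dict | None:
        """The paper-style report for a dropped term: its last t and p before removal."""
        for rec in self.removal_trace:
            if rec["term"] == term:
                return rec
        return None


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str],
    host_reference: str = "A",
    center: bool = False,
    host_coding: str = "dummy",
) -> pd.DataFrame:
    """Model matrix with intercept for the given terms.

    ``host`` becomes an indicator of the non-reference species under
    ``host_coding="dummy"``, or a centred ±0.5 contrast under
    ``"effect"``; with ``center=True`` continuous main effects are
    mean-centred (interactions are products of the possibly centred
    parents), which makes lower-order coefficients at-the-average
    contrasts.
    """

    def host_col() -> np.ndarray:
        is_c = (data[HOST_COLUMN] == "C").to_numpy(dtype=float)
        if host_coding == "effect":
            return is_c - 0.5
        return is_c if host_reference == "A" else 1.0 - is_c

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    main: dict[str, np.ndarray] = {}
    for term in terms:
        if is_interaction(term):
            continue
        if term == HOST_COLUMN:
            main[term] = host_col()
        else:
            v = data[term].to_numpy(dtype=float)
            main[term] = v - v.mean() if center else v
    # interactions may need parents even when a parent main effect was removed
    for term in terms:
        if not is_interaction(term):
            continue
        prod = np.ones(len(data))
        for p in interaction_parents(term):
            if p in main:
                prod = prod * main[p]
            elif p == HOST_COLUMN:
                prod = prod * host_col()
            else:
                v = data[p].to_numpy(dtype=float)
                prod = prod * (v - v.mean() if center else v)
        main[term] = prod
    cols.update(main)
    return pd.DataFrame(cols, index=data.index)


class RankDeficientError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns (beyond the intercept) that add no rank to the design."""
    arr = X.to_numpy()
    aliased = []
    rank = 0
    kept: list[int] = []
    for j in range(arr.shape[1]):
        r = np.linalg.matrix_rank(arr[:, kept + [j]])
        if r > rank:
            rank = r
            kept.append(j)
        else:
            aliased.append(X.columns[j])
    return [c for c in aliased if c != "Intercept"]


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the first column whose removal restores full column rank parity
        for col in X.columns[::-1]:
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                raise RankDeficientError(f"design is rank deficient; term {col} is aliased")
        raise RankDeficientError("design is rank deficient")


def fit_glm(y: Sequence[float] | np.ndarray, X: pd.DataFrame, family: str):
    """Fit one model; returns a statsmodels results object.

    quasipoisson: Poisson log-link IRLS, SEs scaled by the Pearson
    dispersion, t inference on n - p df.  gaussian: OLS.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values in model frame; filter rows first")
    _check_rank(X)
    if family == "quasipoisson":
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(maxiter=100, tol=1e-10, scale="X2", use_t=True)
        if not res.converged:
            raise ConvergenceError(
                f"IRLS did not converge in 100 iterations; deviance trace "
                f"{res.fit_history['deviance'][-3:]}"
            )
        return res
    if family == "gaussian":
        return sm.OLS(y, X).fit()
    raise ValueError(f"unknown family {family!r}")


def _coef_table(res, dispersion: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "df": res.df_resid,
        }
    )


def _dispersion(res, family: str) -> float:
    if family == "quasipoisson":
        return float(res.scale)  # Pearson chi2 / df_resid
    return float(res.mse_resid)


def backward_select(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """Backward elimination at ``spec.alpha_retain`` with marginality.

    Rows failing the inclusion filter or with missing values in the used
    columns are dropped (listwise) before fitting.  At each step the
    least-significant eligible term with p above the threshold is removed
    (ties: interactions first, then the alphabetically later name); its
    pre-removal estimate, t and p go to the trace.
    """
    frame = data
    if spec.inclusion_filter is not None:
        frame = frame[spec.inclusion_filter(frame)]
    warnings = []
    current = list(spec.terms) + list(spec.interactions)
    # a predictor column that is absent or entirely missing cannot be used at
    # all; drop the term (and its interactions) rather than deleting every row
    for term in [t for t in spec.terms if t != HOST_COLUMN]:
        if term not in frame.columns or frame[term].isna().all():
            dead = [term] + [
                i for i in current if is_interaction(i) and term in interaction_parents(i)
            ]
            current = [t for t in current if t not in dead]
            warnings.append(f"term {term} unavailable (no data); dropped with {dead[1:]}")
    used_cols = {spec.response} | {t for t in current if not is_interaction(t)}
    frame = frame.dropna(subset=[c for c in used_cols if c in frame.columns])
    if len(frame) < 10:
        warnings.append(f"only {len(frame)} plants after filtering")

    # prune terms that are unidentifiable on this subset (e.g. a host contrast
    # when every filtered plant is one species) before selection starts
    while current:
        X = build_design(frame, current)
        aliased = _aliased_columns(X)
        if not aliased:
            break
        victim = max(aliased, key=lambda t: (is_interaction(t), t))
        dead = [victim] + (
            [i for i in current if is_interaction(i) and victim in interaction_parents(i)]
            if not is_interaction(victim)
            else []
        )
        current = [t for t in current if t not in dead]
        warnings.append(f"term {victim} aliased on this subset; dropped {dead}")

    trace: list[dict] = []
    step = 0
    while True:
        X = build_design(frame, current)
        res = fit_glm(frame[spec.response], X, spec.family)
        table = _coef_table(res, _dispersion(res, spec.family))
        in_interactions = [t for t in current if is_interaction(t)]
        eligible = [
            t
            for t in current
            if is_interaction(t)
            or not any(t in interaction_parents(i) for i in in_interactions)
        ]
        candidates = [t for t in eligible if table.loc[t, "p"] > spec.alpha_retain]
        if not candidates:
            break
        # ties broken deterministically: interactions first, then later name
        worst_p = max(table.loc[t, "p"] for t in candidates)
        tied = [t for t in candidates if table.loc[t, "p"] == worst_p]
        victim = max(tied, key=lambda t: (is_interaction(t), t))
        step += 1
        removed = [victim]
        if victim in spec.joint_removal:
            partner = spec.joint_removal[victim]
            if partner in current:
                removed.append(partner)
        for term in removed:
            trace.append(
                {
                    "term": term,
                    "estimate": float(table.loc[term, "estimate"]),
                    "t": float(table.loc[term, "t"]),
                    "p": float(table.loc[term, "p"]),
                    "step": step,
                }
            )
            current.remove(term)
        if not current:
            warnings.append("all terms removed; intercept-only model")
            break

    X = build_design(frame, current)
    res = fit_glm(frame[spec.response], X, spec.family)
    return ModelResult(
        spec=spec,
        coefficients=_coef_table(res, _dispersion(res, spec.family)),
        dispersion=_dispersion(res, spec.family),
        removal_trace=trace,
        retained_terms=current,
        n_used=len(frame),
        warnings=warnings,
    )


def simple_effects(
    result: ModelResult, focal_term: str, data: pd.DataFrame
) -> pd.DataFrame:
    """Per-host estimates of ``focal_term`` when its host interaction is retained.

    Refits the final model twice with alternate dummy contrasts for host
    (A = 0/C = 1, then C = 0/A = 1) and all continuous covariates
    mean-centred; under each coding the focal main effect is its simple
    effect on the reference host.
    """
    inter = f"{focal_term}:{HOST_COLUMN}"
    if inter not in result.retained_terms:
        raise ValueError(
            f"simple effects undefined: interaction {inter} not in the final model"
        )
    spec = result.spec
    frame = data
    if spec.inclusion_filter is not None:
        frame = frame[spec.inclusion_filter(frame)]
    used = [c for c in {spec.response, *[t for t in spec.terms if not is_interaction(t)]}
            if c in frame.columns]
    frame = frame.dropna(subset=used)
    rows = []
    for ref in ("A", "C"):
        X = build_design(frame, result.retained_terms, host_reference=ref, center=True)
        res = fit_glm(frame[spec.response], X, spec.family)
        rows.append(
            {
                "host": ref,
                "estimate": float(res.params[focal_term]),
                "se": float(res.bse[focal_term]),
                "t": float(res.tvalues[focal_term]),
                "p": float(res.pvalues[focal_term]),
            }
        )
    return pd.DataFrame(rows).set_index("host")


def average_effect(result: ModelResult, focal_term: str, data: pd.DataFrame) -> dict:
    """The focal term's effect evaluated at the average of its moderators.

    Refits the final model with continuous covariates mean-centred and
    host effect-coded (±0.5), so the focal main coefficient is the
    across-host, at-the-average conditional effect even when interactions
    involving the focal term were retained.  Identical to the raw
    coefficient when no such interaction is present.
    """
    spec = result.spec
    frame = data
    if spec.inclusion_filter is not None:
        frame = frame[spec.inclusion_filter(frame)]
    used = [t for t in result.retained_terms if not is_interaction(t)]
    frame = frame.dropna(subset=[c for c in {spec.response, *used} if c in frame.columns])
    X = build_design(frame, result.retained_terms, center=True, host_coding="effect")
    res = fit_glm(frame[spec.response], X, spec.family)
    return {
        "estimate": float(res.params[focal_term]),
        "se": float(res.bse[focal_term]),
        "t": float(res.tvalues[focal_term]),
        "p": float(res.pvalues[focal_term]),
    }


def partial_r2(
    terms: Sequence[str],
    response: Sequence[float] | np.ndarray,
    data: pd.DataFrame,
    sqrt_transform: bool = True,
    joint_sets: dict[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Adjusted-R² drop per term of an OLS fit on (sqrt-transformed) response.

    For count responses the OLS runs on sqrt(y) (variance-stabilising);
    each term's partial adjusted r² is adj R²(full) − adj R²(full − term).
    ``joint_sets`` names groups of terms dropped together (e.g. a term and
    its interactions).  Values can be slightly negative; not clamped.
    """
    y = np.sqrt(np.asarray(response, dtype=float)) if sqrt_transform else np.asarray(
        response, dtype=float
    )
    def adj_r2(term_list):
        X = build_design(data, term_list)
        return float(sm.OLS(y, X).fit().rsquared_adj)

    full = adj_r2(list(terms))
    out: dict[str, float] = {}
    for term in terms:
        # dropping a main effect also drops interactions that contain it
        drop = {term} | {
            t for t in terms if is_interaction(t) and term in interaction_parents(t)
        }
        out[term] = full - adj_r2([t for t in terms if t not in drop])
    for name, group in (joint_sets or {}).items():
        drop = set(group)
        out[name] = full - adj_r2([t for t in terms if t not in drop])
    return out
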