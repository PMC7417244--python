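"""The five statistical model suites over the per-plant summary table.

Responses and their engines mirror the survey's analysis protocol:

1. ``timema_abundance`` — quasi-Poisson; plants with at least five
   *Timema* (fewer induce a spurious quadratic maladaptation-abundance
   artefact because tiny samples take extreme morph frequencies).
   Predictors: maladaptation, host species, ln plant volume, foliar C:N,
   *Timema*-weighted connectivity, and every two-way host interaction.
2. ``arthropod_abundance`` — quasi-Poisson on the >=5 mm non-*Timema*
   count; plants with at least one *Timema*; predictors as above but with
   arthropod-weighted connectivity plus *Timema* abundance and its
   interaction with maladaptation (when that interaction is dropped the
   *Timema*-abundance main effect leaves with it).
3. ``richness`` — as 2, on >=5 mm morphospecies richness.
4. ``mas`` — OLS on the per-plant mass-abundance slope; predictors as 2
   plus arthropod abundance and its host interaction.
5. ``cn`` — OLS on foliar C:N; predictors as 4 minus C:N itself.

Every suite runs backward selection at alpha = 0.10, then computes simple
effects for each retained host interaction (alternate dummy contrasts,
continuous covariates mean-centred) and partial adjusted r-square for all
final terms when maladaptation is retained (on sqrt counts for the
quasi-Poisson suites).
"""

from __future__ import annotations

import pandas as pd

from .glm import HOST_COLUMN, ModelResult, ModelSpec, backward_select, is_interaction, \
    interaction_parents, partial_r2, simple_effects

__all__ = ["suite_specs", "run_suite", "run_model_suite", "MIN_TIMEMA_FOR_TIMEMA_MODEL"]

MIN_TIMEMA_FOR_TIMEMA_MODEL = 5
MIN_TIMEMA_FOR_ARTHROPOD_MODELS = 1


def _host_interactions(terms: list[str]) -> tuple[str, ...]:
    return tuple(f"{t}:{HOST_COLUMN}" for t in terms if t != HOST_COLUMN)


def suite_specs(alpha_retain: float = 0.10) -> dict[str, ModelSpec]:
    """The five declarative suite definitions, keyed by suite name."""
    timema_terms = ["maladaptation", HOST_COLUMN, "ln_volume", "cn_ratio", "conn_timema"]
    arth_terms = [
        "maladaptation", HOST_COLUMN, "ln_volume", "cn_ratio", "conn_arthropod",
        "timema_abundance",
    ]
    arth_inter = _host_interactions(arth_terms[:5]) + ("maladaptation:timema_abundance",)
    joint = {"maladaptation:timema_abundance": "timema_abundance"}
    mas_terms = arth_terms + ["arthropod_abundance_ge5"]
    mas_inter = arth_inter + ("arthropod_abundance_ge5:host",)
    cn_terms = [
        "maladaptation", HOST_COLUMN, "ln_volume", "conn_arthropod",
        "timema_abundance", "arthropod_abundance_ge5",
    ]
    cn_inter = _host_interactions(
        ["maladaptation", "ln_volume", "conn_arthropod", "arthropod_abundance_ge5"]
    ) + ("maladaptation:timema_abundance",)
    return {
        "timema_abundance": ModelSpec(
            name="timema_abundance",
            response="timema_abundance",
            family="quasipoisson",
            terms=tuple(timema_terms),
            interactions=_host_interactions(timema_terms[:1] + timema_terms[2:]),
            inclusion_filter=lambda d: d["timema_abundance"] >= MIN_TIMEMA_FOR_TIMEMA_MODEL,
            alpha_retain=alpha_retain,
        ),
        "arthropod_abundance": ModelSpec(
            name="arthropod_abundance",
            response="arthropod_abundance_ge5",
            family="quasipoisson",
            terms=tuple(arth_terms),
            interactions=arth_inter,
            inclusion_filter=lambda d: d["timema_abundance"] >= MIN_TIMEMA_FOR_ARTHROPOD_MODELS,
            alpha_retain=alpha_retain,
            joint_removal=joint,
        ),
        "richness": ModelSpec(
            name="richness",
            response="richness_ge5",
            family="quasipoisson",
            terms=tuple(arth_terms),
            interactions=arth_inter,
            inclusion_filter=lambda d: d["timema_abundance"] >= MIN_TIMEMA_FOR_ARTHROPOD_MODELS,
            alpha_retain=alpha_retain,
            joint_removal=joint,
        ),
        "mas": ModelSpec(
            name="mas",
            response="mas_slope",
            family="gaussian",
            terms=tuple(mas_terms),
            interactions=mas_inter,
            inclusion_filter=lambda d: d["timema_abundance"] >= MIN_TIMEMA_FOR_ARTHROPOD_MODELS,
            alpha_retain=alpha_retain,
            joint_removal=joint,
        ),
        "cn": ModelSpec(
            name="cn",
            response="cn_ratio",
            family="gaussian",
            terms=tuple(cn_terms),
            interactions=cn_inter,
            inclusion_filter=lambda d: d["timema_abundance"] >= MIN_TIMEMA_FOR_ARTHROPOD_MODELS,
            alpha_retain=alpha_retain,
            joint_removal=joint,
        ),
    }


def run_suite(spec: ModelSpec, summary: pd.DataFrame) -> ModelResult:
    """Backward-select one suite and attach simple effects and partial r²."""
    result = backward_select(spec, summary)
    for term in list(result.retained_terms):
        if is_interaction(term) and HOST_COLUMN in interaction_parents(term):
            focal = [p for p in interaction_parents(term) if p != HOST_COLUMN][0]
            try:
                result.simple_effects[focal] = simple_effects(result, focal, summary)
            except ValueError:
                pass
    if "maladaptation" in result.retained_terms:
        frame = summary
        if spec.inclusion_filter is not None:
            frame = frame[spec.inclusion_filter(frame)]
        used = [t for t in result.retained_terms if not is_interaction(t)]
        frame = frame.dropna(subset=[c for c in {spec.response, *used} if c in frame.columns])
        result.partial_r2 = partial_r2(
            result.retained_terms,
            frame[spec.response],
            frame,
            sqrt_transform=spec.family == "quasipoisson",
        )
    return result


def run_model_suite(
    summary: pd.DataFrame, alpha_retain: float = 0.10, suites: list[str] | None = None
) -> dict[str, ModelResult]:
    """Run all (or the named subset of) suites on a per-plant summary table."""
    specs = suite_specs(alpha_retain)
    names = suites if suites is not None else list(specs)
    return {name: run_suite(specs[name], summary) for name in names}
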