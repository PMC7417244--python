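"""Quasi-Poisson engine, backward selection, simple effects, partial r²."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from timema_ecoevo.glm import (
    ModelSpec,
    RankDeficientError,
    backward_select,
    build_design,
    fit_glm,
    partial_r2,
    simple_effects,
)


def quasipoisson_frame(rng, n=200, b_x=0.5, b_noise=0.0, phi=1.0):
    """Counts with log-mean 1 + b_x * x (+ b_noise * z), quasi dispersion phi."""
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    host = np.where(rng.random(n) < 0.5, "A", "C")
    mu = np.exp(1.0 + b_x * x + b_noise * z)
    if phi > 1:
        lam = rng.gamma(mu / (phi - 1), phi - 1)
    else:
        lam = mu
    y = rng.poisson(lam)
    return pd.DataFrame({"y": y, "x": x, "z": z, "host": host})


class TestFitGlm:
    def test_intercept_only_poisson_is_log_mean(self):
        y = np.array([2.0, 4.0, 6.0])
        X = pd.DataFrame({"Intercept": np.ones(3)})
        res = fit_glm(y, X, "quasipoisson")
        assert res.params["Intercept"] == pytest.approx(np.log(4.0), abs=1e-10)

    def test_quasi_estimates_equal_poisson_ml(self, rng):
        data = quasipoisson_frame(rng, phi=2.5)
        X = build_design(data, ["x", "host"])
        quasi = fit_glm(data["y"], X, "quasipoisson")
        # independent route: discrete-model Newton MLE
        ml = sm.Poisson(data["y"], X).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(quasi.params, ml.params, atol=1e-8)

    def test_dispersion_inflates_se_not_estimates(self, rng):
        data = quasipoisson_frame(rng, phi=3.0)
        X = build_design(data, ["x"])
        quasi = fit_glm(data["y"], X, "quasipoisson")
        plain = sm.GLM(data["y"], X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(quasi.params, plain.params, rtol=1e-10)
        assert quasi.bse["x"] > 1.3 * plain.bse["x"]
        # Pearson dispersion recovered near truth
        assert 2.0 < quasi.scale < 4.5

    def test_slope_recovered_within_three_se(self, rng):
        data = quasipoisson_frame(rng, n=500, b_x=0.5)
        X = build_design(data, ["x"])
        res = fit_glm(data["y"], X, "quasipoisson")
        assert abs(res.params["x"] - 0.5) < 3 * res.bse["x"]

    def test_rank_deficiency_names_aliased_term(self, rng):
        data = quasipoisson_frame(rng, n=50)
        data["x_copy"] = data["x"]
        X = build_design(data, ["x", "x_copy"])
        with pytest.raises(RankDeficientError, match="x_copy"):
            fit_glm(data["y"], X, "quasipoisson")

    def test_missing_values_rejected(self, rng):
        data = quasipoisson_frame(rng, n=20)
        data.loc[0, "x"] = np.nan
        X = build_design(data, ["x"])
        with pytest.raises(ValueError, match="missing"):
            fit_glm(data["y"], X, "quasipoisson")


class TestBackwardSelect:
    def test_all_significant_nothing_removed(self, rng):
        data = quasipoisson_frame(rng, n=400, b_x=0.8)
        data["y2"] = rng.poisson(np.exp(1 + 0.8 * data["x"] + 0.6 * (data["host"] == "C")))
        spec = ModelSpec(response="y2", family="quasipoisson", terms=("x", "host"))
        res = backward_select(spec, data)
        assert res.removal_trace == [] and set(res.retained_terms) == {"x", "host"}

    def test_noise_term_removed_first_with_trace(self, rng):
        data = quasipoisson_frame(rng, n=400, b_x=0.8, b_noise=0.0)
        spec = ModelSpec(response="y", family="quasipoisson", terms=("x", "z"))
        res = backward_select(spec, data)
        assert "z" not in res.retained_terms and "x" in res.retained_terms
        rec = res.pre_removal("z")
        assert rec is not None and rec["p"] > 0.10 and "t" in rec

    def test_marginality_protects_main_effects(self, rng):
        # interaction strongly significant, main effect of x null
        n = 600
        x = rng.normal(0, 1, n)
        host = np.where(rng.random(n) < 0.5, "A", "C")
        mu = np.exp(1.0 + 0.8 * x * (host == "C"))
        data = pd.DataFrame({"y": rng.poisson(mu), "x": x, "host": host})
        spec = ModelSpec(
            response="y", family="quasipoisson", terms=("x", "host"),
            interactions=("x:host",),
        )
        res = backward_select(spec, data)
        assert "x:host" in res.retained_terms
        assert "x" in res.retained_terms  # protected by marginality

    def test_retained_nonprotected_terms_all_below_threshold(self, rng):
        data = quasipoisson_frame(rng, n=300, b_x=0.4)
        spec = ModelSpec(
            response="y", family="quasipoisson", terms=("x", "z", "host"),
            interactions=("x:host", "z:host"),
        )
        res = backward_select(spec, data)
        inters = [t for t in res.retained_terms if ":" in t]
        for term in res.retained_terms:
            protected = any(term in i.split(":") for i in inters)
            if not protected:
                assert res.pvalue(term) <= 0.10
        # trace + retained reconstructs the initial term set
        assert set(res.retained_terms) | {r["term"] for r in res.removal_trace} == set(
            spec.terms
        ) | set(spec.interactions)

    def test_joint_removal_rule_fires(self, rng):
        # maladaptation x timema-abundance interaction is noise: both the
        # interaction and the timema-abundance main effect must leave together
        n = 400
        malad = rng.uniform(0, 1, n)
        timema = rng.poisson(5, n).astype(float)
        host = np.where(rng.random(n) < 0.5, "A", "C")
        mu = np.exp(1.0 + 0.8 * malad)
        data = pd.DataFrame(
            {
                "y": rng.poisson(mu),
                "maladaptation": malad,
                "timema_abundance": timema,
                "host": host,
            }
        )
        spec = ModelSpec(
            response="y",
            family="quasipoisson",
            terms=("maladaptation", "timema_abundance", "host"),
            interactions=("maladaptation:timema_abundance",),
            joint_removal={"maladaptation:timema_abundance": "timema_abundance"},
        )
        res = backward_select(spec, data)
        removed = {r["term"]: r["step"] for r in res.removal_trace}
        assert "maladaptation:timema_abundance" in removed
        assert "timema_abundance" in removed
        assert removed["timema_abundance"] == removed["maladaptation:timema_abundance"]
        assert "maladaptation" in res.retained_terms

    def test_empty_model_flagged(self, rng):
        n = 200
        data = pd.DataFrame({"y": rng.poisson(3.0, n), "z": rng.normal(0, 1, n)})
        spec = ModelSpec(response="y", family="quasipoisson", terms=("z",))
        res = backward_select(spec, data)
        assert res.retained_terms == []
        assert any("intercept-only" in w for w in res.warnings)


class TestSimpleEffects:
    def _frame(self, rng, effect_a, effect_c, n=800):
        x = rng.normal(0, 1, n)
        host = np.where(np.arange(n) % 2 == 0, "A", "C")
        mu = np.exp(1.0 + np.where(host == "A", effect_a, effect_c) * x)
        return pd.DataFrame({"y": rng.poisson(mu), "x": x, "host": host})

    def test_zero_interaction_gives_equal_estimates(self, rng):
        data = self._frame(rng, 0.5, 0.5)
        spec = ModelSpec(
            response="y", family="quasipoisson", terms=("x", "host"),
            interactions=("x:host",), alpha_retain=1.1,  # keep everything
        )
        res = backward_select(spec, data)
        se = simple_effects(res, "x", data)
        # both codings estimate x on the reference host; truth equal on both
        assert se.loc["A", "estimate"] == pytest.approx(se.loc["C", "estimate"], abs=0.15)

    def test_per_host_effects_recovered(self, rng):
        data = self._frame(rng, 0.0, 1.0)
        spec = ModelSpec(
            response="y", family="quasipoisson", terms=("x", "host"),
            interactions=("x:host",),
        )
        res = backward_select(spec, data)
        se = simple_effects(res, "x", data)
        assert abs(se.loc["A", "estimate"] - 0.0) < 3 * se.loc["A", "se"]
        assert abs(se.loc["C", "estimate"] - 1.0) < 3 * se.loc["C", "se"]

    def test_coding_identity_links_the_two_fits(self, rng):
        # effect(C) = effect(A) + interaction coefficient under A-reference coding
        data = self._frame(rng, 0.3, 0.9)
        spec = ModelSpec(
            response="y", family="quasipoisson", terms=("x", "host"),
            interactions=("x:host",), alpha_retain=1.1,
        )
        res = backward_select(spec, data)
        se = simple_effects(res, "x", data)
        X = build_design(data, res.retained_terms, host_reference="A", center=True)
        ref = fit_glm(data["y"], X, "quasipoisson")
        assert se.loc["C", "estimate"] == pytest.approx(
            ref.params["x"] + ref.params["x:host"], rel=1e-8
        )

    def test_absent_interaction_is_an_error(self, rng):
        data = self._frame(rng, 0.5, 0.5)
        spec = ModelSpec(response="y", family="quasipoisson", terms=("x", "host"))
        res = backward_select(spec, data)
        with pytest.raises(ValueError, match="interaction"):
            simple_effects(res, "x", data)


class TestPartialR2:
    def test_orthogonal_equal_contributions(self, rng):
        n = 4000
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        y = a + b + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"a": a, "b": b})
        r2 = partial_r2(["a", "b"], y, data, sqrt_transform=False)
        assert r2["a"] == pytest.approx(r2["b"], abs=0.02)

    def test_uncorrelated_term_near_zero_not_clamped(self, rng):
        n = 500
        a = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        y = a + rng.normal(0, 0.3, n)
        r2 = partial_r2(["a", "z"], y, pd.DataFrame({"a": a, "z": z}), sqrt_transform=False)
        assert abs(r2["z"]) < 0.02  # may be slightly negative

    def test_single_term_model_equals_adjusted_r2(self, rng):
        n = 300
        a = rng.normal(0, 1, n)
        y = 2 * a + rng.normal(0, 1, n)
        data = pd.DataFrame({"a": a})
        r2 = partial_r2(["a"], y, data, sqrt_transform=False)
        full = sm.OLS(y, sm.add_constant(a)).fit().rsquared_adj
        # intercept-only adjusted R^2 is 0 by construction
        assert r2["a"] == pytest.approx(full, abs=1e-10)

    def test_joint_sets_reported(self, rng):
        n = 300
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        y = a + b + rng.normal(0, 1, n)
        r2 = partial_r2(
            ["a", "b"], y, pd.DataFrame({"a": a, "b": b}), sqrt_transform=False,
            joint_sets={"both": ["a", "b"]},
        )
        assert r2["both"] >= max(r2["a"], r2["b"])
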