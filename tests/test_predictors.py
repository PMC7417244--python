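"""Maladaptation, connectivity, volume, chemistry and community metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timema_ecoevo.io import MorphCounts, PlantPatch
from timema_ecoevo.predictors import (
    ConnectivityParams,
    PredationTransform,
    cn_ratio,
    community_metrics,
    connectivity,
    fit_volume_imputation,
    impute_volume_2013,
    maladaptation,
    pairwise_distances,
    plant_volume,
    predation_intensity,
    VolumeImputationParams,
)
from tests.conftest import make_individuals


class TestMaladaptation:
    def test_all_striped_on_adenostoma_is_perfectly_adapted(self):
        counts = MorphCounts("p", n_striped=10)
        assert maladaptation(counts, "A") == 0.0

    def test_melanics_excluded_from_ratio(self, mixed_morphs):
        assert maladaptation(mixed_morphs, "A") == pytest.approx(0.7)
        assert maladaptation(mixed_morphs, "C") == pytest.approx(0.3)

    def test_undefined_when_no_striped_or_unstriped(self):
        assert maladaptation(MorphCounts("p", n_melanic=5), "A") is None

    @given(
        striped=st.integers(0, 50),
        unstriped=st.integers(0, 50),
        melanic=st.integers(0, 50),
    )
    def test_host_complementarity(self, striped, unstriped, melanic):
        counts = MorphCounts("p", striped, unstriped, melanic)
        m_a = maladaptation(counts, "A")
        m_c = maladaptation(counts, "C")
        if striped + unstriped == 0:
            assert m_a is None and m_c is None
        else:
            assert m_a + m_c == pytest.approx(1.0)


class TestPredationIntensity:
    def test_linear_limit_is_identity(self):
        assert predation_intensity(0.5, PredationTransform(0.0)) == 0.5

    @pytest.mark.parametrize("k", [0.0, 1.0, 4.0, 8.0])
    def test_fixed_points(self, k):
        t = PredationTransform(k)
        assert predation_intensity(0.0, t) == pytest.approx(0.0)
        assert predation_intensity(1.0, t) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # (1 - e^-2) / (1 - e^-4)
        expected = (1 - math.exp(-2)) / (1 - math.exp(-4))
        assert predation_intensity(0.5, PredationTransform(4.0)) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(0.8808, abs=5e-5)

    @given(k=st.floats(0.0, 20.0), m=st.floats(0.0, 1.0))
    def test_monotone_and_bounded(self, k, m):
        t = PredationTransform(k)
        p = predation_intensity(m, t)
        assert 0.0 <= p <= 1.0
        eps = 0.01
        if m + eps <= 1:
            assert predation_intensity(m + eps, t) >= p

    def test_converges_to_identity_as_k_vanishes(self):
        t = PredationTransform(1e-8)
        for m in (0.1, 0.5, 0.9):
            assert predation_intensity(m, t) == pytest.approx(m, abs=1e-8)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            predation_intensity(1.2, PredationTransform(1.0))


class TestDistancesAndConnectivity:
    def test_three_four_five(self, square_plants):
        d = pairwise_distances(square_plants[:2])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0 and d[1, 0] == d[0, 1]

    def test_single_plant_zero_matrix(self, square_plants):
        d = pairwise_distances(square_plants[:1])
        assert d.shape == (1, 1) and d[0, 0] == 0.0

    def test_matches_brute_force_loop(self, rng):
        xy = rng.uniform(0, 70, size=(10, 2))
        plants = [PlantPatch(f"p{i}", "A", x, y) for i, (x, y) in enumerate(xy)]
        d = pairwise_distances(plants)
        for i in range(10):
            for j in range(10):
                expected = math.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
                assert d[i, j] == pytest.approx(expected, rel=1e-12)

    def test_single_isolated_plant_has_zero_connectivity(self):
        c = connectivity([5.0], np.zeros((1, 1)))
        assert c[0] == 0.0

    def test_hand_evaluated_two_patch_kernel(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        c = connectivity([10.0, 10.0], d, ConnectivityParams(alpha=0.5))
        expected = 10 * (0.25 / (2 * math.pi)) * math.exp(-1.0)
        assert c[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.14639, abs=5e-5)

    def test_linearity_in_abundances(self, rng):
        xy = rng.uniform(0, 50, size=(8, 2))
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        n = rng.poisson(5, 8).astype(float)
        c1 = connectivity(n, d)
        c2 = connectivity(2 * n, d)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_additive_in_sources(self, rng):
        xy = rng.uniform(0, 50, size=(6, 2))
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        a = rng.poisson(3, 6).astype(float)
        b = rng.poisson(4, 6).astype(float)
        np.testing.assert_allclose(
            connectivity(a + b, d), connectivity(a, d) + connectivity(b, d), rtol=1e-12
        )

    def test_decreasing_in_any_distance(self):
        d = np.array([[0.0, 2.0, 5.0], [2.0, 0.0, 3.0], [5.0, 3.0, 0.0]])
        c_near = connectivity([1.0, 1.0, 1.0], d)
        d2 = d.copy()
        d2[0, 1] = d2[1, 0] = 4.0
        c_far = connectivity([1.0, 1.0, 1.0], d2)
        assert c_far[0] < c_near[0] and c_far[1] < c_near[1]
        assert c_far[2] == c_near[2]

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            connectivity([1.0, 2.0], np.zeros((3, 3)))

    def test_missing_coordinate_names_plant(self):
        plants = [PlantPatch("good", "A", 0, 0), PlantPatch("bad", "A", None, 1)]
        with pytest.raises(ValueError, match="bad"):
            pairwise_distances(plants)


class TestVolume:
    def test_rectangular_solid(self, square_plants):
        v, lnv = plant_volume(square_plants[0])  # 2 x 2 x 1
        assert v == pytest.approx(4.0) and lnv == pytest.approx(math.log(4))

    def test_unit_cube_ln_zero(self):
        v, lnv = plant_volume(PlantPatch("p", "A", 0, 0, 1.0, 1.0, 1.0))
        assert lnv == 0.0

    def test_dimension_order_invariant(self):
        a = plant_volume(PlantPatch("p", "A", 0, 0, 0.5, 2.0, 4.0))[0]
        b = plant_volume(PlantPatch("p", "A", 0, 0, 4.0, 0.5, 2.0))[0]
        assert a == pytest.approx(b) == pytest.approx(4.0)

    def test_missing_dimension_gives_missing_volume(self):
        v, lnv = plant_volume(PlantPatch("p", "A", 0, 0, 2.0, None, 1.0))
        assert v is None and lnv is None


class TestVolumeImputation:
    def test_identity_parameters(self):
        params = VolumeImputationParams(0.0, 1.0, 0.0)
        assert impute_volume_2013(3.0, "A", params) == 3.0

    def test_exact_linear_data_recovered(self):
        v2014 = np.array([1.0, 2.0, 4.0, 8.0, 1.5, 3.0, 5.0, 7.0])
        host = ["A"] * 4 + ["C"] * 4
        v2013 = 0.3 + 0.88 * v2014 + np.where(np.array(host) == "C", 0.2, 0.0)
        params = fit_volume_imputation(v2013, v2014, host)
        assert params.intercept == pytest.approx(0.3, abs=1e-10)
        assert params.slope_v2014 == pytest.approx(0.88, abs=1e-10)
        assert params.species_offset == pytest.approx(0.2, abs=1e-10)

    def test_negative_prediction_clamped_to_smallest_observed(self):
        params = VolumeImputationParams(-5.0, 0.5, 0.0)
        assert impute_volume_2013(1.0, "A", params, min_observed_2013=0.2) == 0.2


class TestCommunityMetrics:
    def test_five_mm_threshold_inclusive(self):
        inds = make_individuals("p1", [4.9, 5.0, 6.2])
        m = community_metrics(inds, None)
        assert m["arthropod_abundance_ge5"] == 2 and m["richness_ge5"] == 1

    def test_empty_individuals(self, mixed_morphs):
        m = community_metrics([], mixed_morphs)
        assert m == {"timema_abundance": 12, "arthropod_abundance_ge5": 0, "richness_ge5": 0}

    def test_melanics_toggle(self, mixed_morphs):
        with_mel = community_metrics([], mixed_morphs, melanic_in_abundance=True)
        without = community_metrics([], mixed_morphs, melanic_in_abundance=False)
        assert with_mel["timema_abundance"] == 12 and without["timema_abundance"] == 10

    def test_richness_counts_morphospecies(self):
        inds = make_individuals("p1", [7.0, 7.0, 7.0], morphospecies=["a", "b", "c"])
        m = community_metrics(inds, None)
        assert m["arthropod_abundance_ge5"] == 3 and m["richness_ge5"] == 3

    @settings(deadline=None, max_examples=25)
    @given(perm_seed=st.integers(0, 1000))
    def test_row_order_invariance(self, perm_seed):
        lengths = [2.0, 5.0, 5.5, 8.0, 3.0, 12.0]
        species = ["a", "a", "b", "b", "c", "c"]
        inds = make_individuals("p1", lengths, morphospecies=species)
        shuffled = list(np.random.default_rng(perm_seed).permutation(inds))
        assert community_metrics(inds, None) == community_metrics(shuffled, None)


class TestCnRatio:
    def test_simple_ratio(self):
        assert cn_ratio(48.0, 2.0) == 24.0

    def test_identity_and_scale_invariance(self):
        assert cn_ratio(48.0, 48.0) == 1.0
        assert cn_ratio(20.0, 2.0) == cn_ratio(40.0, 4.0)

    def test_zero_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            cn_ratio(48.0, 0.0)
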