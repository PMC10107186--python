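import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from nichemix.delta_niche import MCMCSettings
from nichemix.mixing_model import (
    DietPosterior,
    MixingProblem,
    c_index,
    fit_mixing,
    ilr,
    ilr_basis,
    ilr_inv,
    mixing_region_probability,
    mixture_moments,
    posterior_compare,
)
from tests.conftest import make_source


class TestILR:
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8).map(
            lambda v: np.array(v) / np.sum(v)
        )
    )
    def test_round_trip(self, p):
        assert np.allclose(ilr_inv(ilr(p)), p, atol=1e-10)

    def test_basis_orthonormal(self):
        for k in (2, 4, 6):
            V = ilr_basis(k)
            assert np.allclose(V.T @ V, np.eye(k - 1), atol=1e-12)
            assert np.allclose(V.sum(axis=0), 0.0, atol=1e-12)

    def test_uniform_composition_maps_to_origin(self):
        assert np.allclose(ilr(np.full(6, 1 / 6)), 0.0, atol=1e-12)


class TestMixtureMoments:
    def test_single_source(self, zero_tef):
        s = make_source(1, (-16.0, 12.0, 17.0), (0.5, 0.4, 0.3))
        m, v = mixture_moments(np.array([1.0]), [s], zero_tef, "d13C")
        assert m == -16.0
        assert v == pytest.approx(0.25)

    def test_tef_shifts_mean_and_adds_variance(self):
        from nichemix.tables_io import IsotopeTriple, TEFScenario

        tef = TEFScenario("t", IsotopeTriple(4.4, 0.9, 0.0), IsotopeTriple(1.0, 0.7, 0.5))
        s = make_source(1, (-16.0, 12.0, 17.0), (0.5, 0.4, 0.3))
        m, v = mixture_moments(np.array([1.0]), [s], tef, "d13C")
        assert m == pytest.approx(-11.6)
        assert v == pytest.approx(0.25 + 1.0)

    def test_two_source_hand_arithmetic(self, zero_tef):
        s1 = make_source(1, (-10, 0, 0), (1, 1, 1), conc=0.8)
        s2 = make_source(2, (-20, 0, 0), (1, 1, 1), conc=0.2)
        m, _ = mixture_moments(np.array([0.5, 0.5]), [s1, s2], zero_tef, "d13C")
        assert m == pytest.approx(-12.0)

    def test_equal_concentrations_reduce_to_linear_mixture(self, zero_tef, rng):
        sources = [
            make_source(i, rng.normal(-16, 2, 3), rng.uniform(0.2, 1, 3), conc=0.37)
            for i in range(1, 5)
        ]
        p = rng.dirichlet(np.ones(4))
        for axis_i, axis in enumerate(("d13C", "d15N", "d34S")):
            m, _ = mixture_moments(p, sources, zero_tef, axis)
            linear = sum(
                p[k] * sources[k].iso_mean.as_array()[axis_i] for k in range(4)
            )
            assert m == pytest.approx(linear, rel=1e-12)

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3).map(lambda v: np.array(v) / np.sum(v)))
    def test_mean_inside_source_range(self, p):
        from nichemix.tables_io import IsotopeTriple, TEFScenario

        tef = TEFScenario("z", IsotopeTriple(0, 0, 0), IsotopeTriple(0, 0, 0))
        sources = [
            make_source(1, (-30, 8, 14), (1, 1, 1), conc=0.6),
            make_source(2, (-16, 13, 17), (1, 1, 1), conc=0.4),
            make_source(3, (-22, 11, 7), (1, 1, 1), conc=0.5),
        ]
        m, _ = mixture_moments(p, sources, tef, "d13C")
        assert -30.0 - 1e-9 <= m <= -16.0 + 1e-9


class TestFitMixing:
    def test_retained_draw_count_and_simplex(self, zero_tef):
        s1 = make_source(1, (-10, 0, 0), (1, 1, 1))
        s2 = make_source(2, (-20, 0, 0), (1, 1, 1))
        prob = MixingProblem((s1, s2), zero_tef, {"a": np.array([[-14.0, 0, 0]] * 3)})
        settings = MCMCSettings(3000, 1000, 4, 2)
        post, _ = fit_mixing(prob, settings, seed=1)
        for dp in post.values():
            assert dp.draws.shape[0] == settings.retained
            assert np.all(dp.draws >= 0)
            assert np.allclose(dp.draws.sum(axis=1), 1.0, atol=1e-9)

    def test_prior_predictive_is_uniform_on_simplex(self, zero_tef):
        """With no consumer data the population posterior is the Dirichlet(1) prior."""
        sources = tuple(
            make_source(i, (-16.0 - i, 12.0, 17.0), (1, 1, 1)) for i in range(1, 4)
        )
        prob = MixingProblem(sources, zero_tef, {})
        post, _ = fit_mixing(prob, MCMCSettings(12000, 2000, 5, 2), seed=2)
        assert post["population"].mean == pytest.approx(np.full(3, 1 / 3), abs=0.03)

    def test_two_endpoint_inversion(self, zero_tef):
        """Consumer at the 30/70 point between two sources on one informative axis."""
        s1 = make_source(1, (0, 0, 0), (0.1, 0.1, 0.1))
        s2 = make_source(2, (-10, 0, 0), (0.1, 0.1, 0.1))
        prob = MixingProblem((s1, s2), zero_tef, {"a": np.array([[-7.0, 0, 0]] * 5)})
        post, _ = fit_mixing(prob, MCMCSettings(12000, 6000, 6, 2), seed=3)
        assert post["a"].mean[0] == pytest.approx(0.30, abs=0.03)

    def test_individual_recovery_for_identifiable_dominant_source(self):
        """When the dominant source is isotopically distinct, individual
        posterior means rank individuals by their true use of it."""
        from scipy.stats import spearmanr

        from nichemix import synthetic_data as syn
        from nichemix.delta_niche import MCMCSettings

        cfg = syn.SimulationConfig(
            seed=31,
            population_diet=np.array([0.03, 0.07, 0.15, 0.15, 0.20, 0.40]),
            individual_sd_ilr=0.6,
        )
        ds = syn.simulate_dataset(cfg)
        y = {}
        for rec in ds.consumers:
            y.setdefault(rec.individual_id, []).append(rec.iso.as_array())
        prob = MixingProblem(
            tuple(ds.sources),
            syn.tef_scenarios()["TEF_C"],
            {k: np.array(v) for k, v in y.items()},
        )
        post, _ = fit_mixing(prob, MCMCSettings(16000, 8000, 8, 2), seed=5)
        k = 5  # estuary teleost: well separated on every axis
        inds = sorted(ds.truth.individual_diets)
        truth = [ds.truth.individual_diets[i][k] for i in inds]
        est = [post[i].mean[k] for i in inds]
        assert spearmanr(truth, est).statistic > 0.8

    def test_reproducible_given_seed(self, zero_tef):
        s1 = make_source(1, (-10, 0, 0), (1, 1, 1))
        s2 = make_source(2, (-20, 0, 0), (1, 1, 1))
        prob = MixingProblem((s1, s2), zero_tef, {"a": np.array([[-14.0, 0, 0]] * 3)})
        p1, _ = fit_mixing(prob, MCMCSettings(2000, 500, 5, 1), seed=9)
        p2, _ = fit_mixing(prob, MCMCSettings(2000, 500, 5, 1), seed=9)
        assert np.array_equal(p1["a"].draws, p2["a"].draws)


class TestMixingRegion:
    def test_deep_interior_probability_one(self, zero_tef):
        sources = [
            make_source(1, (-10, 10, 10), (0.1, 0.1, 0.1)),
            make_source(2, (-20, 10, 10), (0.1, 0.1, 0.1)),
            make_source(3, (-15, 20, 10), (0.1, 0.1, 0.1)),
            make_source(4, (-15, 13, 20), (0.1, 0.1, 0.1)),
        ]
        centroid = np.mean([s.iso_mean.as_array() for s in sources], axis=0)
        p = mixing_region_probability(centroid, sources, zero_tef, n_iter=300, seed=1)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_far_exterior_probability_zero(self, zero_tef):
        sources = [
            make_source(1, (-10, 10, 10), (1, 1, 1)),
            make_source(2, (-20, 10, 10), (1, 1, 1)),
            make_source(3, (-15, 20, 10), (1, 1, 1)),
            make_source(4, (-15, 13, 20), (1, 1, 1)),
        ]
        p = mixing_region_probability(
            np.array([-65.0, 10.0, 10.0]), sources, zero_tef, n_iter=300, seed=2
        )
        assert p == 0.0

    def test_two_source_matches_normal_cdf_oracle(self, zero_tef):
        """1-D segment: P(min < x < max) has a closed form from normal CDFs."""
        m1, s1v = -10.0, 1.5
        m2, s2v = -20.0, 2.0
        x = -13.0
        s1 = make_source(1, (m1, 5, 5), (s1v, 0, 0))
        s2 = make_source(2, (m2, 5, 5), (s2v, 0, 0))
        phi1 = norm.cdf(x, m1, s1v)
        phi2 = norm.cdf(x, m2, s2v)
        expect = phi1 * (1 - phi2) + phi2 * (1 - phi1)
        est = mixing_region_probability(
            np.array([x, 5.0, 5.0]), [s1, s2], zero_tef, n_iter=3000, seed=3, tol=1e-9
        )
        assert est == pytest.approx(expect, abs=0.02)


class TestPosteriorCompare:
    def test_identical_draws_are_ties_at_half(self):
        d = np.random.default_rng(0).dirichlet(np.ones(3), 100)
        a = DietPosterior("a", d, ("x", "y", "z"))
        b = DietPosterior("b", d.copy(), ("x", "y", "z"))
        for row in posterior_compare(a, b):
            assert row["p_ind_below_pop"] == 0.5
            assert row["flag"] == "none"

    def test_disjoint_supports_flagged(self, rng):
        lo = rng.uniform(0.0, 0.4, 500)
        hi = rng.uniform(0.6, 1.0, 500)
        a = DietPosterior("a", np.column_stack([lo, 1 - lo]), ("x", "y"))
        b = DietPosterior("b", np.column_stack([hi, 1 - hi]), ("x", "y"))
        rows = posterior_compare(a, b)
        assert rows[0]["p_ind_below_pop"] == 1.0
        assert rows[0]["flag"] == "significant_low"
        assert rows[1]["flag"] == "significant_high"

    def test_enumerated_strict_less_fraction(self):
        a1 = np.array([0.1, 0.2, 0.1, 0.3, 0.1, 0.2, 0.1, 0.6, 0.7, 0.8])
        b1 = np.array([0.2, 0.3, 0.2, 0.4, 0.2, 0.3, 0.2, 0.5, 0.6, 0.7])
        a = DietPosterior("a", np.column_stack([a1, 1 - a1]), ("x", "y"))
        b = DietPosterior("b", np.column_stack([b1, 1 - b1]), ("x", "y"))
        rows = posterior_compare(a, b)
        assert rows[0]["p_ind_below_pop"] == pytest.approx(0.7)
        assert rows[0]["flag"] == "none"

    def test_draw_count_mismatch_errors(self):
        a = DietPosterior("a", np.full((10, 2), 0.5))
        b = DietPosterior("b", np.full((11, 2), 0.5))
        with pytest.raises(ValueError):
            posterior_compare(a, b)


class TestCIndex:
    def test_identical_is_one(self, rng):
        d = rng.dirichlet(np.ones(4), 50)
        assert c_index(d, d.copy()) == pytest.approx(1.0)

    def test_orthogonal_one_hots_are_zero(self):
        a = np.tile([1.0, 0.0], (20, 1))
        b = np.tile([0.0, 1.0], (20, 1))
        assert c_index(a, b) == 0.0

    def test_single_pair_hand_value(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.5, 0.5]])
        assert c_index(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_permutation_equivariance(self, rng):
        a = rng.dirichlet(np.ones(5), 200)
        b = rng.dirichlet(np.ones(5), 200)
        perm = rng.permutation(5)
        assert c_index(a, b) == pytest.approx(c_index(a[:, perm], b[:, perm]))
        rows = posterior_compare(
            DietPosterior("a", a), DietPosterior("b", b)
        )
        rows_p = posterior_compare(
            DietPosterior("a", a[:, perm]), DietPosterior("b", b[:, perm])
        )
        assert [rows[perm[k]]["p_ind_below_pop"] for k in range(5)] == [
            r["p_ind_below_pop"] for r in rows_p
        ]
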