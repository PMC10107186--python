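from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from nichemix.niche_compare import (
    bh_adjust,
    beta_glm,
    pairwise_permanova,
    permanova_pair,
    select_model,
    squeeze_unit_interval,
)


def beta_loglik(params, y, X):
    """Independent beta-regression log-likelihood (logit mean, log precision)."""
    k = X.shape[1]
    eta = X @ params[:k]
    mu = 1 / (1 + np.exp(-eta))
    phi = np.exp(params[k])
    a, b = mu * phi, (1 - mu) * phi
    return np.sum(
        gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log(1 - y)
    )


class TestBetaGLM:
    y8 = np.array([0.22, 0.35, 0.41, 0.52, 0.48, 0.63, 0.71, 0.82])
    X8 = np.column_stack([np.ones(8), np.array([0, 0, 0, 0, 1, 1, 1, 1.0])])

    def test_matches_numerical_ml_oracle(self):
        """Fit equals an independent multi-start Nelder-Mead ML optimiser."""
        fit = beta_glm(self.y8, self.X8)
        best = -np.inf
        for start in ([0.0, 0.0, 1.0], [0.5, -0.5, 2.0], [-1.0, 1.0, 0.0]):
            res = minimize(
                lambda p: -beta_loglik(p, self.y8, self.X8),
                start,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            best = max(best, -res.fun)
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_intercept_only_symmetric_data(self):
        y = np.array([0.3, 0.7, 0.4, 0.6, 0.45, 0.55, 0.35, 0.65])
        fit = beta_glm(y, np.ones((8, 1)))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)

    def test_k_counts_precision(self):
        fit = beta_glm(self.y8, self.X8)
        assert fit.k == 3
        n, k = fit.n, fit.k
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_nested_model_loglik_monotone(self):
        full = beta_glm(self.y8, self.X8)
        null = beta_glm(self.y8, np.ones((8, 1)))
        assert full.loglik >= null.loglik - 1e-9

    def test_boundary_squeeze(self):
        y = np.array([0.0, 0.5, 1.0, 0.25])
        out = squeeze_unit_interval(y)
        assert np.all((out > 0) & (out < 1))
        assert out[1] == pytest.approx((0.5 * 3 + 0.5) / 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            squeeze_unit_interval(np.array([-0.1, 0.5]))


class TestSelectModel:
    @staticmethod
    def _cov(n, rng):
        return pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], n),
                "size_class": rng.choice(["small", "large"], n),
            }
        )

    def test_size_effect_detected(self, rng):
        wins = 0
        reps = 15
        for _ in range(reps):
            cov = self._cov(40, rng)
            eta = -0.3 + 1.0 * (cov["size_class"] == "small").to_numpy()
            mu = 1 / (1 + np.exp(-eta))
            y = rng.beta(mu * 40, (1 - mu) * 40)
            table = select_model(y, cov)
            if table["model"].iloc[0] == "size":
                wins += 1
        assert wins / reps >= 0.8

    def test_pure_noise_prefers_null(self, rng):
        wins = 0
        reps = 15
        for _ in range(reps):
            cov = self._cov(40, rng)
            y = rng.beta(10, 10, 40)
            if select_model(y, cov)["model"].iloc[0] == "null":
                wins += 1
        assert wins / reps >= 0.5

    def test_table_sorted_with_delta(self, rng):
        cov = self._cov(30, rng)
        y = rng.beta(8, 6, 30)
        t = select_model(y, cov)
        assert list(t["aicc"]) == sorted(t["aicc"])
        assert t["delta_aicc"].iloc[0] == 0.0


class TestPermanova:
    def test_exhaustive_enumeration_three_vs_three(self):
        """Permutation p matches the exhaustive label-assignment distribution."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (3, 3))
        b = rng.normal(1.2, 1, (3, 3))
        f_obs, p_perm = permanova_pair(a, b, n_perm=9999, seed=11)

        X = np.vstack([a, b])
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        sqd = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)

        def pseudo_f(labels):
            labels = np.asarray(labels)
            N = 6
            ss_tot = sqd[np.triu_indices(N, 1)].sum() / N
            ss_w = 0.0
            for gval in (0, 1):
                idx = np.flatnonzero(labels == gval)
                sub = sqd[np.ix_(idx, idx)]
                ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return (ss_tot - ss_w) / (ss_w / 4)

        fs = []
        for combo in combinations(range(6), 3):
            lab = np.ones(6, dtype=int)
            lab[list(combo)] = 0
            fs.append(pseudo_f(lab))
        p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        assert f_obs == pytest.approx(pseudo_f([0, 0, 0, 1, 1, 1]), rel=1e-9)
        assert p_perm == pytest.approx(p_exact, abs=0.02)

    def test_identical_distributions_type_one_error(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(0, 1, (6, 3))
            b = rng.normal(0, 1, (6, 3))
            _, p = permanova_pair(a, b, n_perm=199, seed=int(rng.integers(2**31)))
            if p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.11

    def test_total_separation_gives_minimal_p(self, rng):
        a = rng.normal(0, 1, (8, 3))
        b = rng.normal(30, 1, (8, 3))
        _, p = permanova_pair(a, b, n_perm=999, seed=3)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_affine_rescaling_invariance(self, rng):
        a = rng.normal(0, 1, (6, 3))
        b = rng.normal(0.8, 1, (6, 3))
        f1, p1 = permanova_pair(a, b, n_perm=499, seed=7)
        f2, p2 = permanova_pair(a * 10 + 5, b * 10 + 5, n_perm=499, seed=7)
        assert f1 == pytest.approx(f2, rel=1e-9)
        assert p1 == p2

    def test_matches_skbio_pseudo_f(self, rng):
        """Cross-check the statistic against an independent implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        a = rng.normal(0, 1, (5, 3))
        b = rng.normal(1, 1, (5, 3))
        f_obs, _ = permanova_pair(a, b, n_perm=99, seed=1)
        X = np.vstack([a, b])
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        res = sk_permanova(
            DistanceMatrix(d), ["a"] * 5 + ["b"] * 5, permutations=99
        )
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-9)

    def test_pairwise_skips_singletons_and_adjusts(self, rng):
        data = {
            "x": rng.normal(0, 1, (4, 3)),
            "y": rng.normal(2, 1, (4, 3)),
            "z": rng.normal(0, 1, (1, 3)),  # singleton: pairs skipped
        }
        results = pairwise_permanova(data, n_perm=199, seed=0)
        assert [r.pair for r in results] == [("x", "y")]
        assert results[0].p_adjusted >= results[0].p_perm


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.17]) == pytest.approx([0.17])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_order_preserving_monotone(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
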