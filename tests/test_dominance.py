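"""Dominance decomposition: closed forms, brute-force oracle, Monte-Carlo
aggregation, spurious-null calibration, and determinism."""

import itertools

import numpy as np
import pytest

import sensetraits as st
from sensetraits.dominance import DAConfig, general_dominance_weights, subset_r2


def brute_force_weights(corr):
    """Independent oracle: literally average incremental R² over all
    subsets per size, fitting each subset by linear solve."""
    p = corr.shape[0] - 1

    def r2(S):
        if not S:
            return 0.0
        S = sorted(S)
        A = corr[np.ix_(S, S)]
        b = corr[S, -1]
        return float(b @ np.linalg.solve(A, b))

    weights = []
    for j in range(p):
        others = [k for k in range(p) if k != j]
        size_means = []
        for k in range(p):
            incs = [
                r2(set(S) | {j}) - r2(set(S)) for S in itertools.combinations(others, k)
            ]
            size_means.append(np.mean(incs))
        weights.append(np.mean(size_means))
    return np.array(weights)


def random_corr(p, seed, n=60):
    rng = np.random.default_rng(seed)
    return np.corrcoef(rng.standard_normal((n, p + 1)), rowvar=False)


def exact_corr_data(corr, n, seed=0):
    """Simulate n×(p+1) data whose sample correlation matrix equals
    ``corr`` exactly (orthonormalized noise pushed through a Cholesky)."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, corr.shape[0]))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    return Q @ np.linalg.cholesky(corr).T


class TestSubsetR2:
    def test_single_predictor_square(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert subset_r2(corr, [0]) == pytest.approx(0.36)
        assert subset_r2(corr, []) == 0.0

    def test_orthogonal_additivity(self):
        corr = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1.0]])
        assert subset_r2(corr, [0, 1]) == pytest.approx(0.5)

    def test_matches_regression_on_exact_corr_data(self):
        corr = random_corr(4, seed=1)
        data = exact_corr_data(corr, n=40, seed=2)
        X, y = data[:, :-1], data[:, -1]
        for subset in ([0], [1, 3], [0, 1, 2, 3]):
            coef, *_ = np.linalg.lstsq(X[:, subset], y, rcond=None)
            fitted = X[:, subset] @ coef
            r2_fit = 1 - ((y - fitted) ** 2).sum() / (y**2).sum()
            assert subset_r2(corr, subset) == pytest.approx(r2_fit, abs=1e-10)

    def test_singular_submatrix_warns_and_returns(self):
        corr = np.ones((3, 3))
        corr[:2, 2] = corr[2, :2] = 0.5
        with pytest.warns(UserWarning, match="singular"):
            val = subset_r2(corr, [0, 1])
        assert np.isfinite(val)


class TestGeneralDominanceWeights:
    def test_orthogonal_closed_form(self):
        corr = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1.0]])
        assert general_dominance_weights(corr) == pytest.approx([0.25, 0.25])

    def test_single_predictor_is_full_r2(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert general_dominance_weights(corr) == pytest.approx([0.36])

    def test_matches_brute_force(self):
        for seed in range(5):
            corr = random_corr(5, seed)
            w = general_dominance_weights(corr)
            assert np.allclose(w, brute_force_weights(corr), atol=1e-12)
            assert w.sum() == pytest.approx(subset_r2(corr, range(5)), abs=1e-12)

    def test_complete_dominance_implies_general(self):
        # orthogonal predictors: every incremental R² of A exceeds B's
        corr = np.eye(4)
        corr[0, 3] = corr[3, 0] = 0.6
        corr[1, 3] = corr[3, 1] = 0.3
        corr[2, 3] = corr[3, 2] = 0.1
        w = general_dominance_weights(corr)
        assert w[0] > w[1] > w[2]

    def test_scale_guard(self):
        with pytest.raises(ValueError, match="enumeration guard"):
            general_dominance_weights(np.eye(23))


class TestMonteCarloDominance:
    def test_noiseless_single_dominant_predictor(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        y = 2.0 * X[:, 0]  # exact linear function of predictor 1
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=200, seed=4))
        assert res.rank_mean[0] == pytest.approx(1.0)
        assert res.sig_percent[0] == 100.0

    def test_planted_ordering_and_r2(self):
        rng = np.random.default_rng(5)
        n = 252
        X = rng.standard_normal((n, 3))
        y = 0.5 * X[:, 0] + 0.3 * X[:, 1] + rng.standard_normal(n) * np.sqrt(1 - 0.34)
        res = st.run_mc_dominance(X, y, DAConfig(seed=6))
        w = res.weight_mean
        assert w[0] > w[1] > w[2]
        assert res.r2_ci[0] < w.sum() + res.spurious_weights.mean() < res.r2_ci[1] + 0.05

    def test_per_run_conservation(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 4))
        y = X[:, 0] + rng.standard_normal(80)
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=300, seed=8))
        err = np.abs(res.per_run_weights.sum(1) + res.spurious_weights - res.per_run_r2)
        assert err.max() < 1e-10

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.standard_normal(60)
        a = st.run_mc_dominance(X, y, DAConfig(n_runs=100, seed=10))
        b = st.run_mc_dominance(X, y, DAConfig(n_runs=100, seed=10))
        assert np.array_equal(a.per_run_weights, b.per_run_weights)
        assert np.array_equal(a.spurious_weights, b.spurious_weights)

    def test_parametric_resampling_runs(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 3))
        y = 0.5 * X[:, 0] + rng.standard_normal(100)
        res = st.run_mc_dominance(
            X, y, DAConfig(n_runs=100, resampling="parametric", seed=12)
        )
        assert res.weight_mean[0] == res.weight_mean.max()

    def test_constant_column_redrawn(self):
        rng = np.random.default_rng(13)
        X = np.column_stack([rng.standard_normal(12), np.r_[1, np.zeros(11)]])
        y = X[:, 0] + 0.1 * rng.standard_normal(12)
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=50, seed=14))
        assert res.redraw_counts.sum() > 0  # resamples drop the lone positive often
        assert np.isfinite(res.per_run_weights).all()


class TestSpuriousCriterion:
    def test_trivial_bounds(self):
        w = np.zeros((100, 2))
        s = np.abs(np.random.default_rng(1).standard_normal(100)) + 0.01
        sig = st.significance_proportions(w, s)
        assert sig == pytest.approx([0.0, 0.0])
        w2 = np.full((100, 1), s.max() + 1)
        assert st.significance_proportions(w2, s)[0] == 100.0

    def test_exchangeable_predictor_sits_at_alpha(self):
        """A predictor drawn fresh each run like the spurious one is
        flagged in ≈(1−ci)·100% of runs."""
        rng = np.random.default_rng(2)
        n_runs = 4000
        w = rng.chisquare(1, size=(n_runs, 1))
        s = rng.chisquare(1, size=n_runs)
        sig = st.significance_proportions(w, s, ci_level=0.95)[0]
        se = 100 * np.sqrt(0.05 * 0.95 / n_runs)
        assert abs(sig - 5.0) < 3 * se

    def test_pairwise_identical_columns_zero(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((100, 1))
        X = np.column_stack([X, X])  # duplicated predictor
        y = X[:, 0] + rng.standard_normal(100)
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=100, seed=16))
        m = res.pairwise_percent.to_numpy()
        assert m[0, 1] == 0.0 and np.all(np.diag(m) == 0)

    def test_pairwise_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((120, 3))
        y = 0.4 * X[:, 0] + rng.standard_normal(120)
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=150, seed=18))
        m = res.pairwise_percent.to_numpy()
        assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)

    def test_pairwise_strong_vs_null_exceeds_80(self):
        rng = np.random.default_rng(19)
        n = 252
        X = rng.standard_normal((n, 2))
        y = 0.6 * X[:, 0] + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        res = st.run_mc_dominance(X, y, DAConfig(seed=20))
        assert res.pairwise_percent.iloc[0, 1] > 80.0


def test_weight_ordering_recovery_across_cohorts():
    """Across cohorts with distinct planted orderings, mean weights
    reproduce the planted |effect| ordering (effects ≥0.15 apart)."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(700 + seed)
        order = rng.permutation(3)
        betas = np.array([0.5, 0.3, 0.1])[np.argsort(order)]
        X = rng.standard_normal((252, 3))
        y = X @ betas + rng.standard_normal(252) * 0.8
        res = st.run_mc_dominance(X, y, DAConfig(n_runs=300, seed=seed))
        hits += np.array_equal(np.argsort(-res.weight_mean), np.argsort(-betas))
    assert hits >= 18
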