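"""General dominance analysis with a Monte-Carlo spurious-predictor null.

A predictor's *general dominance weight* is its incremental R² from
joining a subset of the other predictors, averaged over all subsets of
each size and then over sizes; the weights decompose the full-model R²
exactly.  Sampling error is handled by recomputing the weights over
bootstrap resamples of the respondents, each run augmented with a
freshly drawn standard-normal *spurious* predictor that embodies pure
noise.  The 95th percentile of the pooled spurious-weight distribution
is the noise floor q: a predictor counts as "significantly different
from zero" in a run when its weight exceeds q, and two predictors differ
significantly in a run when |w_A − w_B| > q.  Reported per predictor:
mean weight with percentile CI, significance proportion (Sig, in %),
mean rank with CI, plus the full-model R² and the pairwise
percentage-of-runs-different matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MAX_PREDICTORS = 20


@dataclass(frozen=True)
class DAConfig:
    n_runs: int = 1000
    ci_level: float = 0.95
    spurious: bool = True
    resampling: str = "bootstrap"  # or "parametric"
    seed: int = 0
    max_redraws: int = 10

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be ≥ 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.resampling not in ("bootstrap", "parametric"):
            raise ValueError("resampling must be 'bootstrap' or 'parametric'")


@dataclass
class DAResult:
    predictor_names: list[str]
    weight_mean: np.ndarray
    weight_ci: np.ndarray  # (p, 2)
    sig_percent: np.ndarray
    rank_mean: np.ndarray
    rank_ci: np.ndarray  # (p, 2)
    r2_mean: float
    r2_ci: tuple[float, float]
    pairwise_percent: pd.DataFrame
    per_run_weights: np.ndarray  # (n_runs, p)
    spurious_weights: np.ndarray  # (n_runs,)
    per_run_r2: np.ndarray
    redraw_counts: np.ndarray
    config: DAConfig

    def to_frame(self) -> pd.DataFrame:
        """Per-predictor summary table (weight M [CI], Sig %, rank M [CI])."""
        return pd.DataFrame(
            {
                "predictor": self.predictor_names,
                "weight_mean": self.weight_mean,
                "weight_ci_low": self.weight_ci[:, 0],
                "weight_ci_high": self.weight_ci[:, 1],
                "sig_percent": self.sig_percent,
                "rank_mean": self.rank_mean,
                "rank_ci_low": self.rank_ci[:, 0],
                "rank_ci_high": self.rank_ci[:, 1],
            }
        )


def subset_r2(corr: np.ndarray, subset) -> float:
    """Squared multiple correlation of the outcome on a predictor subset.

    ``corr`` is the (p+1)×(p+1) correlation matrix with the outcome in
    the LAST row/column; R² = r_Sᵀ R_SS⁻¹ r_S, 0 for the empty subset.
    A singular R_SS falls back to the pseudoinverse with a warning.
    """
    corr = np.asarray(corr, dtype=float)
    idx = np.asarray(sorted(subset), dtype=int)
    if idx.size == 0:
        return 0.0
    A = corr[np.ix_(idx, idx)]
    b = corr[idx, -1]
    try:
        coef = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular predictor correlation submatrix; using pseudoinverse")
        coef = np.linalg.pinv(A) @ b
    return float(b @ coef)


def _size_coefficients(p: int) -> np.ndarray:
    """Weight of one size-k increment in the dominance average: each size
    contributes equally (1/p), split evenly over its C(p−1, k) subsets."""
    return np.array([1.0 / (p * comb(p - 1, k)) for k in range(p)])


def _all_subset_r2(corr_stack: np.ndarray) -> np.ndarray:
    """R² of every predictor subset for a stack of correlation matrices.

    ``corr_stack`` is (runs, p+1, p+1) with the outcome last; returns
    (2^p, runs).  Batched solves keep the all-subsets enumeration cheap
    across bootstrap runs.
    """
    runs, q, _ = corr_stack.shape
    p = q - 1
    r2 = np.zeros((1 << p, runs))
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        A = corr_stack[:, idx][:, :, idx]
        b = corr_stack[:, idx, -1]
        try:
            coef = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            coef = np.empty_like(b)
            for r in range(runs):
                try:
                    coef[r] = np.linalg.solve(A[r], b[r])
                except np.linalg.LinAlgError:
                    coef[r] = np.linalg.pinv(A[r]) @ b[r]
        r2[mask] = np.einsum("rk,rk->r", b, coef)
    return r2


def _weights_from_r2(r2: np.ndarray, p: int) -> np.ndarray:
    """General dominance weights from the all-subsets R² table.

    ``r2`` is (2^p, runs); returns (runs, p).
    """
    coefs = _size_coefficients(p)
    runs = r2.shape[1]
    w = np.zeros((runs, p))
    sizes = np.array([bin(m).count("1") for m in range(1 << p)])
    for j in range(p):
        bit = 1 << j
        masks = np.array([m for m in range(1 << p) if not m & bit])
        inc = r2[masks | bit] - r2[masks]
        w[:, j] = (coefs[sizes[masks]][:, None] * inc).sum(axis=0)
    return w


def general_dominance_weights(corr: np.ndarray, p: int | None = None) -> np.ndarray:
    """Dominance weights from one correlation matrix (outcome last).

    weight_j = mean over subset sizes k of the average incremental R²
    from adding j to size-k subsets excluding j; Σ weights equals the
    full-model R².  Enumeration is exponential, so p is capped at 20.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0] - 1 if p is None else p
    if p < 1:
        raise ValueError("need at least one predictor")
    if p > MAX_PREDICTORS:
        raise ValueError(f"p = {p} exceeds the 2^p enumeration guard ({MAX_PREDICTORS})")
    r2 = _all_subset_r2(corr[None, :, :])
    return _weights_from_r2(r2, p)[0]


def significance_proportions(
    per_run_weights: np.ndarray, spurious_weights: np.ndarray, ci_level: float = 0.95
) -> np.ndarray:
    """Sig_j = % of runs where weight_j exceeds the spurious noise floor.

    The noise floor q is the ``ci_level`` quantile of the pooled
    spurious-predictor weights across all runs.
    """
    w = np.asarray(per_run_weights, dtype=float)
    s = np.asarray(spurious_weights, dtype=float)
    if w.shape[0] != s.shape[0]:
        raise ValueError("run dimensions differ")
    q = np.quantile(s, ci_level)
    return 100.0 * (w > q).mean(axis=0)


def pairwise_difference_matrix(
    per_run_weights: np.ndarray,
    spurious_weights: np.ndarray,
    ci_level: float = 0.95,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """% of runs in which each pair of predictors differs by more than
    the spurious noise floor; symmetric with zero diagonal."""
    w = np.asarray(per_run_weights, dtype=float)
    if w.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    q = np.quantile(np.asarray(spurious_weights, dtype=float), ci_level)
    diff = np.abs(w[:, :, None] - w[:, None, :])
    m = 100.0 * (diff > q).mean(axis=0)
    np.fill_diagonal(m, 0.0)
    names = names or [f"x{j}" for j in range(w.shape[1])]
    return pd.DataFrame(m, index=names, columns=names)


def run_mc_dominance(X, y, config: DAConfig | None = None) -> DAResult:
    """Monte-Carlo dominance analysis.

    Each run resamples the n respondents with replacement (paired rows),
    appends a freshly drawn standard-normal spurious predictor, and
    computes general dominance weights from that run's own correlation
    matrix (scale-free, so no re-standardization is needed).  Runs whose
    resample leaves a constant column are redrawn, up to
    ``config.max_redraws`` times each.
    """
    config = config or DAConfig()
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    )
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if p < 1:
        raise ValueError("need at least one predictor")
    if n <= p + 2:
        raise ValueError("need n > p + 2")
    rng = np.random.default_rng(config.seed)
    data = np.column_stack([Xa, ya])

    if config.resampling == "parametric":
        # draw synthetic respondents from a Gaussian with the sample moments
        mu = data.mean(axis=0)
        cov = np.cov(data, rowvar=False)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        draws = rng.standard_normal((config.n_runs, n, p + 1)) @ L.T + mu
    else:
        idx = rng.integers(0, n, size=(config.n_runs, n))
        draws = data[idx]

    spur = rng.standard_normal((config.n_runs, n))
    redraws = np.zeros(config.n_runs, dtype=int)
    for b in range(config.n_runs):
        tries = 0
        while draws[b, :, :p].std(axis=0).min() == 0 or draws[b, :, p].std() == 0:
            tries += 1
            if tries > config.max_redraws:
                raise RuntimeError(f"run {b}: constant column persisted after redraws")
            if config.resampling == "parametric":
                draws[b] = rng.standard_normal((n, p + 1)) @ L.T + mu
            else:
                draws[b] = data[rng.integers(0, n, size=n)]
            spur[b] = rng.standard_normal(n)
        redraws[b] = tries

    # assemble [X, spurious, y] per run and the per-run correlation matrices
    if config.spurious:
        stacked = np.concatenate(
            [draws[:, :, :p], spur[:, :, None], draws[:, :, p:]], axis=2
        )
    else:
        stacked = draws
    centered = stacked - stacked.mean(axis=1, keepdims=True)
    cov = np.einsum("rni,rnj->rij", centered, centered)
    sd = np.sqrt(np.einsum("rii->ri", cov))
    corr = cov / (sd[:, :, None] * sd[:, None, :])

    q_pred = p + 1 if config.spurious else p  # real predictors (+ spurious)
    r2 = _all_subset_r2(corr)
    w_all = _weights_from_r2(r2, q_pred)
    w = w_all[:, :p]
    per_run_r2 = r2[(1 << q_pred) - 1]

    lo, hi = (1 - config.ci_level) / 2, 1 - (1 - config.ci_level) / 2
    ranks = rankdata(-w, axis=1, method="average")
    if config.spurious:
        spurious_w = w_all[:, p]
        sig = significance_proportions(w, spurious_w, config.ci_level)
        pairwise = (
            pairwise_difference_matrix(w, spurious_w, config.ci_level, names)
            if p >= 2
            else pd.DataFrame(np.zeros((1, 1)), index=names, columns=names)
        )
    else:
        spurious_w = np.full(config.n_runs, np.nan)
        sig = np.full(p, np.nan)
        pairwise = pd.DataFrame(np.full((p, p), np.nan), index=names, columns=names)
    return DAResult(
        predictor_names=names,
        weight_mean=w.mean(axis=0),
        weight_ci=np.quantile(w, [lo, hi], axis=0).T,
        sig_percent=sig,
        rank_mean=ranks.mean(axis=0),
        rank_ci=np.quantile(ranks, [lo, hi], axis=0).T,
        r2_mean=float(per_run_r2.mean()),
        r2_ci=(float(np.quantile(per_run_r2, lo)), float(np.quantile(per_run_r2, hi))),
        pairwise_percent=pairwise,
        per_run_weights=w,
        spurious_weights=spurious_w,
        per_run_r2=per_run_r2,
        redraw_counts=redraws,
        config=config,
    )
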