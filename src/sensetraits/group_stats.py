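"""Replication-stage descriptive statistics.

Group differences on the sensory scales between two groups (e.g.
autistic vs non-autistic respondents) via Mann–Whitney U, and bivariate
Spearman correlations of every sensory scale with the trait total.
Medians are reported alongside SDs, the pairing the source tables use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import SENSORY_SUBSCALES

#: rows of the comparison table, in reporting order
COMPARISON_SCALES = ("sensory_total",) + SENSORY_SUBSCALES


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney test; returns (U, p) with U = min(U₁, U₂).

    Midranks handle ties.  The p-value uses exact enumeration when
    n₁·n₂ ≤ 400 and the data are tie-free, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman ρ (Pearson on midranks) with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n ≥ 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector has no rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def normality_check(x) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p for 3 ≤ n ≤ 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk supported for 3 ≤ n ≤ 5000")
    if np.unique(x).size < 2:
        raise ValueError("constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def comparison_table(scores: pd.DataFrame, group_flag) -> pd.DataFrame:
    """One row per sensory scale (total + 7 subscales).

    Per row: per-group median and SD (ddof=1), Mann–Whitney U and p
    across groups, and Spearman ρ and p versus the trait total over all
    respondents.  ``group_flag`` is binary, 1 marking the comparison
    group.
    """
    flag = np.asarray(group_flag).astype(bool)
    if flag.size != len(scores):
        raise ValueError("group_flag length mismatch")
    if not flag.any() or flag.all():
        raise ValueError("both groups must be nonempty")
    trait_total = scores["trait_total"].to_numpy(dtype=float)
    rows = []
    for scale in COMPARISON_SCALES:
        v = scores[scale].to_numpy(dtype=float)
        g0, g1 = v[~flag], v[flag]
        u, p_u = mann_whitney(g0, g1)
        rho, p_rho = spearman(v, trait_total)
        rows.append(
            dict(
                scale=scale,
                median_group0=float(np.median(g0)),
                sd_group0=float(np.std(g0, ddof=1)),
                median_group1=float(np.median(g1)),
                sd_group1=float(np.std(g1, ddof=1)),
                U=u,
                p_mannwhitney=p_u,
                spearman_rho=rho,
                p_spearman=p_rho,
            )
        )
    return pd.DataFrame(rows)
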