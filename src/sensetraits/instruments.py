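"""Scoring of the two Likert instruments.

The trait instrument (BAPQ-like) has three 12-item subscales — aloof,
pragmatic, rigid — rated 1..6; subscale and total scores are plain item
sums.  The sensory instrument (GSQ-like) has seven 6-item modality
subscales — visual, auditory, tactile, olfactory, gustatory,
proprioceptive, vestibular — rated 1..5, each item tagged as probing
hyper- or hypo-sensitivity.  Two sensory items (an auditory
repeated-music item and a gustatory same-foods item) overlap
conceptually with the rigid trait construct and are dropped before any
modality→trait modelling, leaving 40 scorable sensory items with
five-item auditory and gustatory subscales.

An *instrument key* is a :class:`pandas.DataFrame` with one row per item
and columns ``item_id, instrument, subscale, tag, levels,
attention_check, correct_answer, overlap_rigid, removed, reversed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TRAIT_SUBSCALES = ("aloof", "pragmatic", "rigid")
SENSORY_SUBSCALES = (
    "visual",
    "auditory",
    "tactile",
    "olfactory",
    "gustatory",
    "proprioceptive",
    "vestibular",
)

KEY_COLUMNS = [
    "item_id",
    "instrument",
    "subscale",
    "tag",
    "levels",
    "attention_check",
    "correct_answer",
    "overlap_rigid",
    "removed",
    "reversed",
]


@dataclass
class ItemResponseTable:
    """Respondents × items integer Likert matrix plus its item key.

    ``responses`` has a ``pid`` column followed by one integer column per
    item; ``key`` is the instrument key describing those items.
    """

    responses: pd.DataFrame
    key: pd.DataFrame

    def __post_init__(self) -> None:
        if "pid" not in self.responses.columns:
            raise ValueError("responses must contain a 'pid' column")

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    def copy(self) -> "ItemResponseTable":
        return ItemResponseTable(self.responses.copy(), self.key.copy())


def synthetic_key(n_attention_checks: int = 4) -> pd.DataFrame:
    """Build the item key for the synthetic instruments.

    Sensory hyper/hypo tags alternate within each subscale; the auditory
    subscale starts on ``hypo`` so that after removing the two
    rigid-overlap items (``gsq_auditory_6``, ``gsq_gustatory_6``) the
    pooled tag counts are exactly 20 hyper / 20 hypo.  Attention checks
    ask for the middle alternative of a 5-point scale.
    """
    rows = []
    for sub in SENSORY_SUBSCALES:
        start = ("hypo", "hyper") if sub == "auditory" else ("hyper", "hypo")
        for i in range(1, 7):
            rows.append(
                dict(
                    item_id=f"gsq_{sub}_{i}",
                    instrument="sensory",
                    subscale=sub,
                    tag=start[(i - 1) % 2],
                    levels=5,
                    attention_check=False,
                    correct_answer=np.nan,
                    overlap_rigid=(sub, i) in (("auditory", 6), ("gustatory", 6)),
                    removed=False,
                    reversed=False,
                )
            )
    for sub in TRAIT_SUBSCALES:
        for i in range(1, 13):
            rows.append(
                dict(
                    item_id=f"bapq_{sub}_{i}",
                    instrument="trait",
                    subscale=sub,
                    tag="",
                    levels=6,
                    attention_check=False,
                    correct_answer=np.nan,
                    overlap_rigid=False,
                    removed=False,
                    reversed=False,
                )
            )
    for i in range(1, n_attention_checks + 1):
        rows.append(
            dict(
                item_id=f"check_{i}",
                instrument="check",
                subscale="attention",
                tag="",
                levels=5,
                attention_check=True,
                correct_answer=3.0,
                overlap_rigid=False,
                removed=False,
                reversed=False,
            )
        )
    return pd.DataFrame(rows, columns=KEY_COLUMNS)


def drop_overlap_items(key: pd.DataFrame) -> pd.DataFrame:
    """Mark the two rigid-overlap sensory items as removed.

    Idempotent.  Raises if either designated item (the auditory
    repeated-music item or the gustatory same-foods item) is absent.
    """
    out = key.copy()
    mask = out["overlap_rigid"].astype(bool)
    subs = set(out.loc[mask, "subscale"])
    if not {"auditory", "gustatory"} <= subs:
        missing = {"auditory", "gustatory"} - subs
        raise ValueError(
            f"designated overlap item(s) missing for subscale(s): {sorted(missing)}"
        )
    out.loc[mask, "removed"] = True
    return out


def _scorable(key: pd.DataFrame, instrument: str) -> pd.DataFrame:
    return key[(key["instrument"] == instrument) & (~key["removed"].astype(bool))]


def score_subscales(responses: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Sum item responses into subscale, total, and hyper/hypo scores.

    Returns one row per respondent with columns ``pid``, the three trait
    subscales, ``trait_total``, the seven sensory subscales,
    ``sensory_total``, ``hyper`` and ``hypo``.  Removed items never
    contribute.  Out-of-range or missing item codes raise, naming the
    offending respondent and item.
    """
    scored = key[~key["removed"].astype(bool) & (key["instrument"] != "check")]
    missing = [i for i in scored["item_id"] if i not in responses.columns]
    if missing:
        raise ValueError(f"missing item column(s): {missing[:5]}")

    pid = responses["pid"].to_numpy()
    values = {}
    for _, row in scored.iterrows():
        col = responses[row["item_id"]].to_numpy()
        if not np.issubdtype(col.dtype, np.integer):
            if np.any(col != np.floor(col)):
                bad = int(np.argmax(col != np.floor(col)))
                raise ValueError(
                    f"non-integer code for respondent {pid[bad]!r}, item {row['item_id']}"
                )
            col = col.astype(np.int64)
        out_of_range = (col < 1) | (col > row["levels"])
        if out_of_range.any():
            bad = int(np.argmax(out_of_range))
            raise ValueError(
                f"out-of-range code {col[bad]} for respondent {pid[bad]!r}, "
                f"item {row['item_id']} (levels={row['levels']})"
            )
        if row["reversed"]:
            col = row["levels"] + 1 - col
        values[row["item_id"]] = col

    out = pd.DataFrame({"pid": pid})
    trait_key = _scorable(key, "trait")
    for sub in TRAIT_SUBSCALES:
        items = trait_key.loc[trait_key["subscale"] == sub, "item_id"]
        out[sub] = np.sum([values[i] for i in items], axis=0)
    out["trait_total"] = out[list(TRAIT_SUBSCALES)].sum(axis=1)

    sens_key = _scorable(key, "sensory")
    for sub in SENSORY_SUBSCALES:
        items = sens_key.loc[sens_key["subscale"] == sub, "item_id"]
        out[sub] = np.sum([values[i] for i in items], axis=0)
    out["sensory_total"] = out[list(SENSORY_SUBSCALES)].sum(axis=1)
    for tag in ("hyper", "hypo"):
        items = sens_key.loc[sens_key["tag"] == tag, "item_id"]
        out[tag] = np.sum([values[i] for i in items], axis=0) if len(items) else 0
    return out


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's α = k/(k−1) · (1 − Σ var(item) / var(sum)).

    Population (divide-by-n) variances are used throughout; α is
    invariant to the shared convention.  Requires ≥2 items, ≥3
    respondents, and a non-degenerate total score.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 item columns")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    k = m.shape[1]
    total_var = m.sum(axis=1).var()
    if total_var == 0:
        raise ValueError("zero variance of the total score")
    item_var = m.var(axis=0).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def reliability_report(responses: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Cronbach's α per subscale and instrument total (removed items excluded)."""
    rows = []
    for instrument, subs in (("trait", TRAIT_SUBSCALES), ("sensory", SENSORY_SUBSCALES)):
        scored = _scorable(key, instrument)
        all_items = list(scored["item_id"])
        rows.append(
            dict(
                scale=f"{instrument}_total",
                n_items=len(all_items),
                alpha=cronbach_alpha(responses[all_items]),
            )
        )
        for sub in subs:
            items = list(scored.loc[scored["subscale"] == sub, "item_id"])
            rows.append(
                dict(scale=sub, n_items=len(items), alpha=cronbach_alpha(responses[items]))
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExclusionRule:
    """One screening rule; ``kind`` is 'attention' or 'flag'.

    'attention' removes respondents answering any attention-check item
    with other than its stored correct alternative; 'flag' removes
    respondents with a 1 in the named binary covariate column.
    """

    reason: str
    kind: str
    column: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("attention", "flag"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "flag" and not self.column:
            raise ValueError("flag rule needs a covariate column name")


def attention_failures(table: ItemResponseTable) -> pd.Series:
    """Boolean per-respondent Series: failed at least one attention check."""
    checks = table.key[table.key["attention_check"].astype(bool)]
    failed = np.zeros(table.n_respondents, dtype=bool)
    for _, row in checks.iterrows():
        failed |= table.responses[row["item_id"]].to_numpy() != int(row["correct_answer"])
    return pd.Series(failed, index=table.responses.index)


def apply_exclusions(
    table: ItemResponseTable,
    covariates: pd.DataFrame,
    rules: Sequence[ExclusionRule],
) -> tuple[ItemResponseTable, pd.DataFrame, pd.DataFrame]:
    """Screen respondents; first matching rule (in declared order) wins.

    Returns the filtered response table, filtered covariates, and an
    exclusion log with one (pid, reason) row per removed respondent.
    """
    reasons = pd.Series([None] * table.n_respondents, index=table.responses.index, dtype=object)
    cov = covariates.set_index(covariates.index)
    for rule in rules:
        if rule.kind == "attention":
            match = attention_failures(table)
        else:
            match = pd.Series(
                cov[rule.column].to_numpy().astype(bool), index=table.responses.index
            )
        fresh = match & reasons.isna()
        reasons[fresh] = rule.reason
    removed = reasons.notna()
    log = pd.DataFrame(
        {"pid": table.responses.loc[removed, "pid"].to_numpy(), "reason": reasons[removed].to_numpy()}
    )
    filtered = ItemResponseTable(
        table.responses.loc[~removed].reset_index(drop=True), table.key.copy()
    )
    cov_out = covariates.loc[~removed.to_numpy()].reset_index(drop=True)
    return filtered, cov_out, log
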