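"""End-to-end study replica.

For each cohort (synthetic or loaded from CSV): screen respondents,
score both instruments (after dropping the two rigid-overlap sensory
items), then for each of the three trait outcomes run SSVS twice on the
modality + covariate design, check two-run MIP stability, select
predictors above the inclusion threshold, intersect selections across
cohorts, and run Monte-Carlo dominance analysis per cohort on that
cohort's own selection.  All randomness derives from one master seed via
a documented splitting rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dominance import DAConfig, DAResult, run_mc_dominance
from .group_stats import comparison_table
from .instruments import (
    KEY_COLUMNS,
    SENSORY_SUBSCALES,
    TRAIT_SUBSCALES,
    ExclusionRule,
    ItemResponseTable,
    apply_exclusions,
    drop_overlap_items,
    reliability_report,
    score_subscales,
)
from .ssvs import SSVSConfig, intersect_selections, run_ssvs, stability_check
from .synthetic import SimConfig, generate_dataset

DEFAULT_OUTCOMES = list(TRAIT_SUBSCALES)
DEFAULT_COVARIATES = ["age", "adhd", "dcd", "anxiety", "mood", "gender_man", "gender_nonbinary"]


def derive_seed(master_seed: int, *labels) -> int:
    """Deterministic sub-stream seed: SHA-256 of master seed + labels,
    folded into [0, 2^31)."""
    msg = ":".join([str(master_seed), *map(str, labels)]).encode()
    return int.from_bytes(hashlib.sha256(msg).digest()[:4], "big") % (2**31)


@dataclass
class CohortSource:
    """Either a synthetic generating config or a pair of CSV paths."""

    label: str
    sim: SimConfig | None = None
    responses_csv: str | None = None
    covariates_csv: str | None = None
    key_csv: str | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.responses_csv is None):
            raise ValueError("provide exactly one of sim config or CSV paths")
        if self.sim is None and self.covariates_csv is None:
            raise ValueError("CSV cohorts need a covariates table")


@dataclass
class StudyConfig:
    cohorts: list[CohortSource] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    exclusion_rules: list[ExclusionRule] = field(
        default_factory=lambda: [ExclusionRule("attention_check", "attention")]
    )
    ssvs: SSVSConfig = field(default_factory=SSVSConfig)
    dominance: DAConfig = field(default_factory=DAConfig)
    mip_threshold: float = 0.5
    stability_min: float = 0.99
    group_column: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.outcomes) - set(TRAIT_SUBSCALES)
        if unknown:
            raise ValueError(f"unknown outcome(s) {sorted(unknown)}")
        if not self.cohorts:
            raise ValueError("need at least one cohort")


@dataclass
class OutcomeAnalysis:
    cohort: str
    outcome: str
    mips: pd.Series
    mips_run2: pd.Series
    stability_r: float
    stable: bool
    selection: list[str]


@dataclass
class ReportBundle:
    scores: dict[str, pd.DataFrame]
    exclusion_logs: dict[str, pd.DataFrame]
    reliability: dict[str, pd.DataFrame]
    comparison: dict[str, pd.DataFrame]
    ssvs: dict[tuple[str, str], OutcomeAnalysis]
    intersection: dict[str, list[str]]
    dominance: dict[tuple[str, str], DAResult | None]
    dominance_notes: dict[tuple[str, str], str]
    manifest: dict[str, Any]


def _resolve_cohort(
    src: CohortSource, master_seed: int
) -> tuple[ItemResponseTable, pd.DataFrame]:
    if src.sim is not None:
        sim = replace(src.sim, seed=derive_seed(master_seed, "simulate", src.label))
        table, covariates, _truth = generate_dataset(sim)
        return table, covariates
    key = read_key_csv(src.key_csv) if src.key_csv else None
    table = read_responses_csv(src.responses_csv, key=key)
    covariates = pd.read_csv(src.covariates_csv)
    if "pid" not in covariates.columns:
        raise ValueError(f"{src.covariates_csv}: missing 'pid' column")
    return table, covariates


def _design(
    scores: pd.DataFrame, covariates: pd.DataFrame, covariate_names: list[str]
) -> pd.DataFrame:
    cols = {sub: scores[sub].to_numpy(dtype=float) for sub in SENSORY_SUBSCALES}
    cov = covariates.set_index("pid").loc[scores["pid"]]
    for name in covariate_names:
        if name not in cov.columns:
            raise ValueError(f"covariate {name!r} not in covariate table")
        cols[name] = cov[name].to_numpy(dtype=float)
    return pd.DataFrame(cols)


def _standardize_frame(X: pd.DataFrame, y: np.ndarray):
    from .ssvs import standardize_design

    Xs, ys, params = standardize_design(X, y)
    return pd.DataFrame(Xs, columns=X.columns), ys, params


def run_study(config: StudyConfig) -> ReportBundle:
    """Run the full multi-cohort analysis; see the module docstring."""
    bundle = ReportBundle({}, {}, {}, {}, {}, {}, {}, {}, {})
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "master_seed": config.seed,
        "seeds": {},
        "stability": {},
        "warnings": [],
    }
    selections: dict[str, dict[str, list[str]]] = {o: {} for o in config.outcomes}
    designs: dict[str, pd.DataFrame] = {}

    for src in config.cohorts:
        label = src.label
        try:
            table, covariates = _resolve_cohort(src, config.seed)
            table = ItemResponseTable(table.responses, drop_overlap_items(table.key))
            table, covariates, log = apply_exclusions(table, covariates, config.exclusion_rules)
            scores = score_subscales(table.responses, table.key)
        except Exception as exc:
            raise RuntimeError(f"[cohort {label}] screening/scoring failed: {exc}") from exc
        bundle.scores[label] = scores
        bundle.exclusion_logs[label] = log
        bundle.reliability[label] = reliability_report(table.responses, table.key)
        if src.sim is not None:
            manifest["seeds"][f"simulate/{label}"] = derive_seed(config.seed, "simulate", label)

        if config.group_column is not None:
            flag = covariates[config.group_column].to_numpy()
            bundle.comparison[label] = comparison_table(scores, flag)

        for nb_col in ("gender_nonbinary",):
            if nb_col in covariates.columns and covariates[nb_col].sum() < 5:
                manifest["warnings"].append(
                    f"[cohort {label}] fewer than 5 positives in {nb_col}"
                )

        X = _design(scores, covariates, config.covariates)
        designs[label] = X
        for outcome in config.outcomes:
            key2 = (label, outcome)
            y = scores[outcome].to_numpy(dtype=float)
            try:
                Xs, ys, _ = _standardize_frame(X, y)
                s1 = derive_seed(config.seed, "ssvs", label, outcome, 1)
                s2 = derive_seed(config.seed, "ssvs", label, outcome, 2)
                r1 = run_ssvs(Xs, ys, replace(config.ssvs, seed=s1))
                r2 = run_ssvs(Xs, ys, replace(config.ssvs, seed=s2))
                r = stability_check(r1, r2)
            except Exception as exc:
                raise RuntimeError(f"[cohort {label} / {outcome}] SSVS failed: {exc}") from exc
            manifest["seeds"][f"ssvs/{label}/{outcome}"] = [s1, s2]
            manifest["stability"][f"{label}/{outcome}"] = r
            stable = r >= config.stability_min
            mean_mips = (r1.mips + r2.mips) / 2
            selection = (
                list(mean_mips[mean_mips > config.mip_threshold].sort_values(ascending=False).index)
                if stable
                else []
            )
            bundle.ssvs[key2] = OutcomeAnalysis(
                cohort=label,
                outcome=outcome,
                mips=r1.mips,
                mips_run2=r2.mips,
                stability_r=r,
                stable=stable,
                selection=selection,
            )
            selections[outcome][label] = selection
            if not stable:
                manifest["warnings"].append(
                    f"[cohort {label} / {outcome}] FAILED stability: r = {r:.4f} "
                    f"< {config.stability_min}"
                )

    for outcome in config.outcomes:
        per_cohort = [selections[outcome][s.label] for s in config.cohorts]
        bundle.intersection[outcome] = intersect_selections(*per_cohort)

    for src in config.cohorts:
        label = src.label
        scores = bundle.scores[label]
        for outcome in config.outcomes:
            key2 = (label, outcome)
            analysis = bundle.ssvs[key2]
            if not analysis.stable:
                bundle.dominance[key2] = None
                bundle.dominance_notes[key2] = "skipped: SSVS stability check failed"
                continue
            if not analysis.selection:
                bundle.dominance[key2] = None
                bundle.dominance_notes[key2] = "no predictors selected"
                continue
            da_seed = derive_seed(config.seed, "dominance", label, outcome)
            manifest["seeds"][f"dominance/{label}/{outcome}"] = da_seed
            X = designs[label]
            try:
                res = run_mc_dominance(
                    X[analysis.selection],
                    scores[outcome].to_numpy(dtype=float),
                    replace(config.dominance, seed=da_seed),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"[cohort {label} / {outcome}] dominance analysis failed: {exc}"
                ) from exc
            bundle.dominance[key2] = res
            bundle.dominance_notes[key2] = "ok"

    bundle.manifest = manifest
    return bundle


# ---------------------------------------------------------------- I/O


def read_responses_csv(path: str | Path, key: pd.DataFrame | None = None) -> ItemResponseTable:
    """Read an item-response CSV (``pid`` column + integer item columns).

    With a key, unknown item columns raise; non-integer codes raise
    naming the offending row.
    """
    from .instruments import synthetic_key

    df = pd.read_csv(path)
    if "pid" not in df.columns:
        raise ValueError(f"{path}: missing 'pid' column")
    key = key if key is not None else synthetic_key()
    known = set(key["item_id"])
    for col in df.columns:
        if col == "pid":
            continue
        if col not in known:
            raise ValueError(f"{path}: unknown item column {col!r}")
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            numeric = pd.to_numeric(vals, errors="coerce")
            bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
            if bad.any():
                row = int(bad.idxmax()) + 2  # header is line 1
                raise ValueError(f"{path}: non-integer code in column {col!r}, line {row}")
            df[col] = numeric.astype(np.int64)
    return ItemResponseTable(df, key.copy())


def read_key_csv(path: str | Path) -> pd.DataFrame:
    key = pd.read_csv(path)
    missing = set(KEY_COLUMNS) - set(key.columns)
    if missing:
        raise ValueError(f"{path}: key missing columns {sorted(missing)}")
    return key


def write_cohort(
    table: ItemResponseTable, covariates: pd.DataFrame, out_dir: str | Path, truth=None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.responses.to_csv(out / "responses.csv", index=False)
    table.key.to_csv(out / "key.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())


def write_report(bundle: ReportBundle, out_dir: str | Path, plots: bool = False) -> Path:
    """Write the report bundle: per-outcome MIP and DA CSVs, pairwise
    matrices, exclusion logs, reliabilities, and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, df in bundle.scores.items():
        df.to_csv(out / f"{label}_scores.csv", index=False)
    for label, df in bundle.exclusion_logs.items():
        df.to_csv(out / f"{label}_exclusions.csv", index=False)
    for label, df in bundle.reliability.items():
        df.to_csv(out / f"{label}_reliability.csv", index=False)
    for label, df in bundle.comparison.items():
        df.to_csv(out / f"{label}_comparison.csv", index=False)
    for (label, outcome), analysis in bundle.ssvs.items():
        df = pd.DataFrame(
            {
                "predictor": analysis.mips.index,
                "mip_run1": analysis.mips.to_numpy(),
                "mip_run2": analysis.mips_run2.to_numpy(),
            }
        )
        df.to_csv(out / f"{label}_{outcome}_mips.csv", index=False)
        if plots:
            from .plots import mip_barplot

            mip_barplot(analysis.mips, out / f"{label}_{outcome}_mips.png")
    for (label, outcome), res in bundle.dominance.items():
        stem = f"{label}_{outcome}_dominance"
        if res is None:
            (out / f"{stem}.SKIPPED").write_text(bundle.dominance_notes[(label, outcome)] + "\n")
            continue
        res.to_frame().to_csv(out / f"{stem}.csv", index=False)
        res.pairwise_percent.to_csv(out / f"{stem}_pairwise.csv")
        if plots:
            from .plots import pairwise_heatmap

            pairwise_heatmap(res.pairwise_percent, out / f"{stem}_pairwise.png")
    manifest = dict(bundle.manifest)
    manifest["intersection"] = bundle.intersection
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
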