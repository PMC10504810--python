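"""Seeded synthetic questionnaire cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: seven correlated latent sensory-modality constructs, three
quantitative-trait latents that are linear functions of the standardized
predictors (modalities plus covariates) with Gaussian noise, Likert item
responses produced by a one-factor-per-subscale graded model
(item = loading·latent + √(1−loading²)·unique noise, thresholded at
equally spaced normal quantiles), demographic covariates, attention-check
items, and seeded attention failures.  Everything is reproducible
bit-for-bit from the :class:`SimConfig` seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instruments import (
    SENSORY_SUBSCALES,
    TRAIT_SUBSCALES,
    ItemResponseTable,
    synthetic_key,
)

GENDER_LEVELS = ("woman", "man", "nonbinary", "other")
#: default gender mix and covariate moments of the clinically enriched cohort
DEFAULT_GENDER_PROBS = (0.575, 0.361, 0.052, 0.012)
DEFAULT_FLAGS = {"adhd": 0.064, "dcd": 0.079, "anxiety": 0.384, "mood": 0.306}


@dataclass(frozen=True)
class CovariateSpec:
    """Demographics of the simulated cohort.

    ``flag_prevalence`` maps binary diagnosis-flag names to prevalences;
    gender is a 4-level categorical dummy-coded against the woman
    reference, with 'other' never dummy-coded.
    """

    age_mean: float = 34.1
    age_sd: float = 11.6
    gender_probs: tuple[float, ...] = DEFAULT_GENDER_PROBS
    flag_prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FLAGS))

    def __post_init__(self) -> None:
        if len(self.gender_probs) != len(GENDER_LEVELS):
            raise ValueError("gender_probs must have 4 entries")
        if abs(sum(self.gender_probs) - 1.0) > 1e-9:
            raise ValueError("gender_probs must sum to 1")
        for name, p in self.flag_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")


def predictor_names(spec: CovariateSpec | None = None) -> list[str]:
    """Canonical predictor order: 7 modalities, age, flags, 2 gender dummies."""
    spec = spec or CovariateSpec()
    return (
        list(SENSORY_SUBSCALES)
        + ["age"]
        + list(spec.flag_prevalence)
        + ["gender_man", "gender_nonbinary"]
    )


def _default_factor_corr() -> np.ndarray:
    r = np.full((7, 7), 0.4)
    np.fill_diagonal(r, 1.0)
    return r


def _default_trait_coefs(names: list[str]) -> np.ndarray:
    """Moderate planted effects with the auditory modality dominant for
    every trait, echoing the qualitative pattern the analysis targets."""
    b = np.zeros((3, len(names)))
    idx = {n: i for i, n in enumerate(names)}
    b[0, idx["auditory"]] = 0.35
    b[0, idx["tactile"]] = 0.15
    b[0, idx["anxiety"]] = 0.10
    b[1, idx["auditory"]] = 0.30
    b[1, idx["proprioceptive"]] = 0.15
    b[1, idx["adhd"]] = 0.10
    b[2, idx["auditory"]] = 0.30
    b[2, idx["vestibular"]] = 0.15
    b[2, idx["anxiety"]] = 0.10
    return b


@dataclass
class SimConfig:
    """Generating model for one synthetic cohort.

    ``trait_coefs`` is a 3×K matrix of standardized coefficients from the
    K predictors (in :func:`predictor_names` order) to the three trait
    latents.  ``loading_sensory``/``loading_trait`` are the common item
    loadings; defaults put 6-item sensory α near 0.69 and 12-item trait α
    near 0.91, the moderate/high reliabilities typical of these
    instruments.
    """

    n_respondents: int = 252
    factor_corr: np.ndarray = field(default_factory=_default_factor_corr)
    trait_coefs: np.ndarray | None = None
    noise_sd: float = 0.85
    items_per_subscale: int = 6
    items_per_trait_subscale: int = 12
    likert_levels_sensory: int = 5
    likert_levels_trait: int = 6
    loading_sensory: float = 0.55
    loading_trait: float = 0.7
    attention_fail_rate: float = 0.035
    n_attention_checks: int = 4
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        if self.factor_corr.shape != (7, 7):
            raise ValueError("factor_corr must be 7×7")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        try:
            np.linalg.cholesky(self.factor_corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("factor_corr is not positive-definite") from exc
        names = predictor_names(self.covariate_spec)
        if self.trait_coefs is None:
            self.trait_coefs = _default_trait_coefs(names)
        self.trait_coefs = np.asarray(self.trait_coefs, dtype=float)
        if self.trait_coefs.shape != (3, len(names)):
            raise ValueError(
                f"trait_coefs must be 3×{len(names)} for predictors {names}, "
                f"got {self.trait_coefs.shape}"
            )
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if not 0.0 <= self.attention_fail_rate <= 1.0:
            raise ValueError("attention_fail_rate outside [0, 1]")
        for lv in (self.likert_levels_sensory, self.likert_levels_trait):
            if lv < 2:
                raise ValueError("likert_levels must be ≥ 2")
        for ld in (self.loading_sensory, self.loading_trait):
            if not 0.0 <= ld <= 1.0:
                raise ValueError("loadings must lie in [0, 1]")

    @property
    def predictors(self) -> list[str]:
        return predictor_names(self.covariate_spec)


@dataclass
class SyntheticTruth:
    """Everything needed to check recovery: realized latents, generating
    coefficients, thresholds, and the seed."""

    seed: int
    predictor_names: list[str]
    trait_coefs: np.ndarray
    factor_corr: np.ndarray
    noise_sd: float
    modality_latents: np.ndarray
    trait_latents: np.ndarray
    predictors_standardized: np.ndarray
    thresholds_sensory: np.ndarray
    thresholds_trait: np.ndarray
    failed_attention_pids: list[str]

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "predictor_names": self.predictor_names,
            "trait_coefs": self.trait_coefs.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "noise_sd": self.noise_sd,
            "thresholds_sensory": self.thresholds_sensory.tolist(),
            "thresholds_trait": self.thresholds_trait.tolist(),
            "failed_attention_pids": list(self.failed_attention_pids),
        }
        return json.dumps(d, indent=2)


def equal_quantile_thresholds(levels: int) -> np.ndarray:
    """Standard-normal cuts giving `levels` equally probable categories."""
    return norm.ppf(np.arange(1, levels) / levels)


def latent_to_likert(latent_value, thresholds) -> np.ndarray | int:
    """Discretize latent values into 1-based categories.

    Category = 1 + number of thresholds strictly below the latent value;
    thresholds must be strictly increasing.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be a strictly increasing 1-D vector")
    cats = np.searchsorted(t, np.asarray(latent_value, dtype=float), side="left") + 1
    if np.isscalar(latent_value):
        return int(cats)
    return cats


def generate_dataset(
    config: SimConfig,
) -> tuple[ItemResponseTable, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort from the generating model.

    Returns the item-response table (with its instrument key), the
    covariate table, and the truth object.  Identical configs produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    spec = config.covariate_spec
    names = config.predictors

    # modality latents: zero-mean MVN with the target correlation matrix
    L = np.linalg.cholesky(config.factor_corr)
    Z = rng.standard_normal((n, 7)) @ L.T

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    gender_idx = rng.choice(len(GENDER_LEVELS), size=n, p=spec.gender_probs)
    gender = np.array(GENDER_LEVELS)[gender_idx]
    flags = {
        name: (rng.random(n) < p).astype(np.int64)
        for name, p in spec.flag_prevalence.items()
    }
    man = (gender == "man").astype(np.int64)
    nonbinary = (gender == "nonbinary").astype(np.int64)

    # standardized predictor matrix using the theoretical moments of the
    # generating distributions (so trait_coefs are true standardized betas)
    def _std_binary(x, p):
        s = np.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
        return (x - p) / s

    cols = [Z[:, i] for i in range(7)]
    cols.append((age - spec.age_mean) / spec.age_sd)
    for name, p in spec.flag_prevalence.items():
        cols.append(_std_binary(flags[name], p))
    p_man, p_nb = spec.gender_probs[1], spec.gender_probs[2]
    cols.append(_std_binary(man, p_man))
    cols.append(_std_binary(nonbinary, p_nb))
    P = np.column_stack(cols)

    T = P @ config.trait_coefs.T + config.noise_sd * rng.standard_normal((n, 3))

    key = synthetic_key(config.n_attention_checks)
    th_s = equal_quantile_thresholds(config.likert_levels_sensory)
    th_t = equal_quantile_thresholds(config.likert_levels_trait)

    data = {"pid": [f"p{i:04d}" for i in range(n)]}
    lam = config.loading_sensory
    for m, sub in enumerate(SENSORY_SUBSCALES):
        for i in range(1, config.items_per_subscale + 1):
            u = lam * Z[:, m] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            data[f"gsq_{sub}_{i}"] = latent_to_likert(u, th_s)

    # item loadings apply to the standardized trait latent
    Tz = (T - T.mean(axis=0)) / T.std(axis=0)
    lam = config.loading_trait
    for m, sub in enumerate(TRAIT_SUBSCALES):
        for i in range(1, config.items_per_trait_subscale + 1):
            u = lam * Tz[:, m] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            data[f"bapq_{sub}_{i}"] = latent_to_likert(u, th_t)

    for i in range(1, config.n_attention_checks + 1):
        data[f"check_{i}"] = np.full(n, 3, dtype=np.int64)

    responses = pd.DataFrame(data)
    table = ItemResponseTable(responses, key)
    table = plant_attention_failures(
        table, config.attention_fail_rate, seed=int(rng.integers(2**31))
    )
    failed = table.responses["pid"][_failed_mask(table)].tolist()

    covariates = pd.DataFrame(
        {
            "pid": responses["pid"],
            "age": age,
            "gender": gender,
            "gender_man": man,
            "gender_nonbinary": nonbinary,
            **flags,
        }
    )

    truth = SyntheticTruth(
        seed=config.seed,
        predictor_names=names,
        trait_coefs=config.trait_coefs.copy(),
        factor_corr=config.factor_corr.copy(),
        noise_sd=config.noise_sd,
        modality_latents=Z,
        trait_latents=T,
        predictors_standardized=P,
        thresholds_sensory=th_s,
        thresholds_trait=th_t,
        failed_attention_pids=failed,
    )
    return table, covariates, truth


def _failed_mask(table: ItemResponseTable) -> np.ndarray:
    checks = table.key[table.key["attention_check"].astype(bool)]
    failed = np.zeros(table.n_respondents, dtype=bool)
    for _, row in checks.iterrows():
        failed |= table.responses[row["item_id"]].to_numpy() != int(row["correct_answer"])
    return failed


def plant_attention_failures(
    table: ItemResponseTable, rate: float, seed: int
) -> ItemResponseTable:
    """Make a seeded random subset of respondents fail ≥1 attention check.

    Each respondent independently fails with probability ``rate``; a
    failing respondent answers one randomly chosen check with a wrong
    alternative, everyone else answers every check correctly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    checks = table.key[table.key["attention_check"].astype(bool)]
    if checks.empty:
        raise ValueError("table has no attention-check items")
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = out.n_respondents
    # reset everyone to the correct alternative first
    for _, row in checks.iterrows():
        out.responses[row["item_id"]] = np.full(n, int(row["correct_answer"]), dtype=np.int64)
    fails = rng.random(n) < rate
    which = rng.integers(0, len(checks), n)
    for k, (_, row) in enumerate(checks.iterrows()):
        sel = fails & (which == k)
        correct = int(row["correct_answer"])
        wrong = correct + 1 if correct < int(row["levels"]) else correct - 1
        col = out.responses[row["item_id"]].to_numpy()
        col[sel] = wrong
        out.responses[row["item_id"]] = col
    return out
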