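"""Build config objects from YAML/JSON dictionaries (CLI plumbing)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dominance import DAConfig
from .instruments import ExclusionRule
from .pipeline import CohortSource, StudyConfig
from .ssvs import SSVSConfig
from .synthetic import CovariateSpec, SimConfig


def load_config_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "covariate_spec" in d:
        cs = dict(d["covariate_spec"])
        if "gender_probs" in cs:
            cs["gender_probs"] = tuple(cs["gender_probs"])
        d["covariate_spec"] = CovariateSpec(**cs)
    for key in ("factor_corr", "trait_coefs"):
        if key in d and d[key] is not None:
            d[key] = np.asarray(d[key], dtype=float)
    return SimConfig(**d)


def study_config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    cohorts = []
    for c in d.get("cohorts", []):
        c = dict(c)
        if "sim" in c and c["sim"] is not None:
            c["sim"] = sim_config_from_dict(c["sim"])
        cohorts.append(CohortSource(**c))
    d["cohorts"] = cohorts
    if "exclusion_rules" in d:
        d["exclusion_rules"] = [ExclusionRule(**r) for r in d["exclusion_rules"]]
    if "ssvs" in d:
        d["ssvs"] = SSVSConfig(**d["ssvs"])
    if "dominance" in d:
        d["dominance"] = DAConfig(**d["dominance"])
    return StudyConfig(**d)
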