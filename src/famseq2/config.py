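"""YAML/JSON study configuration loading.

One structured file drives all stages.  Top-level keys map onto
:class:`famseq2.evaluate.StudyConfig`; the nested ``pheno`` mapping onto
:class:`famseq2.simulate.PhenoModelConfig`.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .evaluate import StudyConfig
from .simulate import PhenoModelConfig


def load_study_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    ) or {}
    pheno_data = data.pop("pheno", {})
    _check_keys(data, StudyConfig, "study config")
    _check_keys(pheno_data, PhenoModelConfig, "pheno config")
    cfg = StudyConfig(**data, pheno=PhenoModelConfig(**pheno_data))
    for name in ("k_list", "thresholds"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    return cfg


def _check_keys(data: dict, cls, label: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)} - {"pheno"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {label} keys: {sorted(unknown)}")
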