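"""Run configuration: defaults mirror the published search settings
(10/20 ppm tolerances, q < 0.01, DE FDR < 0.01 with |log2FC| >= 1,
ORA FDR < 0.05, NMF ranks 2-10 with 30 survey / 500 final runs,
basis-contribution 0.8, 1000 permutations, crosstalk threshold 0.3)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    fdr_threshold: float = 0.01
    de_fdr_threshold: float = 0.01
    de_log2fc_threshold: float = 1.0
    ora_fdr_threshold: float = 0.05
    nmf_k_min: int = 2
    nmf_k_max: int = 10
    nmf_survey_runs: int = 30
    nmf_final_runs: int = 500
    representative_threshold: float = 0.8
    n_permutations: int = 1000
    crosstalk_threshold: float = 0.3
    crosstalk_min_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "precursor_tol_ppm", "fragment_tol_ppm", "fdr_threshold",
            "de_fdr_threshold", "de_log2fc_threshold", "ora_fdr_threshold",
            "representative_threshold", "crosstalk_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.nmf_k_min < 2 or self.nmf_k_max < self.nmf_k_min:
            raise ValueError("invalid NMF rank range")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config, merging over defaults.

    Unknown keys are rejected with the offending key named.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)
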