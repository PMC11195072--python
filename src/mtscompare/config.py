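"""Pipeline configuration: YAML in, validated settings out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_data import DEFAULT_FD_THRESHOLD_MM
from .features import FEATURE_NAMES
from .spis import SPI_NAMES


@dataclass
class PipelineConfig:
    """All module-level settings for an end-to-end run."""

    tr_seconds: float = 2.0
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
    seed: int = 0
    features: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    spis: list[str] = field(default_factory=lambda: list(SPI_NAMES))
    cv_folds: int = 10
    cv_repeats: int = 10
    nulls_n: int = 1000
    nulls_seed: int | None = None
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.nulls_seed is None:
            # every seed explicit after loading
            self.nulls_seed = self.seed + 1
        unknown = set(self.spis) - set(SPI_NAMES)
        if unknown:
            raise ValueError(f"unknown SPIs in config: {sorted(unknown)}")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in config: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config with keys tr_seconds, fd_threshold_mm, seed,
    features, spis, cv{folds,repeats}, nulls{n,seed}, fdr_alpha."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cv = raw.pop("cv", {})
    nulls = raw.pop("nulls", {})
    return PipelineConfig(
        cv_folds=cv.get("folds", 10),
        cv_repeats=cv.get("repeats", 10),
        nulls_n=nulls.get("n", 1000),
        nulls_seed=nulls.get("seed"),
        **raw,
    )
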