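"""Design-matrix families built from the feature and coupling tensors.

Five representation kinds are compared:

- ``region``     — one region's 25 dynamical features (N x F);
- ``feature``    — one feature's brain-wide map (N x R);
- ``uni_combo``  — every feature of every region (N x R*F);
- ``fc``         — one SPI's coupling values over all pairs (N x P);
- ``fc_combo``   — coupling values plus all local features (N x (P + R*F)).

Each builder is a pure column projection/concatenation of the tensors, so
missing cells propagate unchanged; imputation happens inside the
cross-validation harness, per training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTensor
from .spis import SPITensor

KINDS = {"region", "feature", "uni_combo", "fc", "fc_combo", "covariate"}


@dataclass
class DesignMatrix:
    """A named N x d participant-by-variable matrix with provenance."""

    X: np.ndarray
    column_names: list[str]
    kind: str
    unit_id: str
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_region(features: FeatureTensor, region: str) -> DesignMatrix:
    """All univariate features for one region: N x F."""
    if region not in features.region_labels:
        raise KeyError(f"unknown region {region!r}")
    j = features.region_labels.index(region)
    return DesignMatrix(
        X=features.values[:, j, :].copy(),
        column_names=[f"region:{region}|feature:{f}" for f in features.feature_names],
        kind="region",
        unit_id=region,
        participant_ids=list(features.participant_ids),
    )


def build_feature(features: FeatureTensor, feature: str) -> DesignMatrix:
    """One feature across all regions: N x R."""
    if feature not in features.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = features.feature_names.index(feature)
    return DesignMatrix(
        X=features.values[:, :, j].copy(),
        column_names=[f"feature:{feature}|region:{r}" for r in features.region_labels],
        kind="feature",
        unit_id=feature,
        participant_ids=list(features.participant_ids),
    )


def build_uni_combo(features: FeatureTensor) -> DesignMatrix:
    """Every feature of every region, region-major column order: N x R*F."""
    n, r, f = features.values.shape
    names = [
        f"region:{reg}|feature:{feat}"
        for reg in features.region_labels
        for feat in features.feature_names
    ]
    return DesignMatrix(
        X=features.values.reshape(n, r * f).copy(),
        column_names=names,
        kind="uni_combo",
        unit_id="",
        participant_ids=list(features.participant_ids),
    )


def build_fc(spis: SPITensor, spi: str) -> DesignMatrix:
    """One SPI's coupling values over its pair index: N x P."""
    if spi not in spis.values:
        raise KeyError(f"unknown SPI {spi!r}")
    idx = spis.pair_index[spi]
    names = [
        f"spi:{spi}|pair:{spis.region_labels[a]}->{spis.region_labels[b]}"
        for a, b in idx.pairs
    ]
    return DesignMatrix(
        X=spis.values[spi].copy(),
        column_names=names,
        kind="fc",
        unit_id=spi,
        participant_ids=list(spis.participant_ids),
    )


def build_fc_combo(
    spis: SPITensor, spi: str, features: FeatureTensor
) -> DesignMatrix:
    """One SPI's coupling block followed by the full region-feature block."""
    fc = build_fc(spis, spi)
    uni = build_uni_combo(features)
    if fc.participant_ids != uni.participant_ids:
        raise ValueError("tensors cover different participants")
    return DesignMatrix(
        X=np.hstack([fc.X, uni.X]),
        column_names=fc.column_names + uni.column_names,
        kind="fc_combo",
        unit_id=spi,
        participant_ids=fc.participant_ids,
    )


def build_covariates(
    meta: pd.DataFrame,
    participant_ids: list[str],
    columns: tuple[str, ...] = ("age", "sex"),
) -> DesignMatrix:
    """Demographic baseline matrix (age in years, sex as 0=male/1=female)."""
    allowed = {"age", "sex"}
    bad = set(columns) - allowed
    if bad:
        raise ValueError(f"unsupported covariates: {sorted(bad)}")
    x = meta.loc[participant_ids, list(columns)].to_numpy(dtype=float)
    return DesignMatrix(
        X=x,
        column_names=[f"covariate:{c}" for c in columns],
        kind="covariate",
        unit_id="+".join(columns),
        participant_ids=list(participant_ids),
    )


def concat_design(a: DesignMatrix, b: DesignMatrix, kind: str | None = None) -> DesignMatrix:
    """Column-wise concatenation preserving provenance."""
    if a.participant_ids != b.participant_ids:
        raise ValueError("row alignment mismatch")
    return DesignMatrix(
        X=np.hstack([a.X, b.X]),
        column_names=a.column_names + b.column_names,
        kind=kind or a.kind,
        unit_id=a.unit_id,
        participant_ids=a.participant_ids,
    )
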