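"""Data model, I/O and quality control for labeled multivariate time-series datasets.

A dataset is ``N`` participants x ``R`` regions x ``T`` timepoints of a
regional signal (e.g. parcellated BOLD), together with a participant
metadata table (diagnosis, age, sex, site, optional head-motion summary).
Quality control removes participants whose signal is identically zero and
participants with excessive head motion, summarized by mean framewise
displacement (FD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Power et al. convention: rotations (radians) are converted to arc length
#: on a sphere of this radius before being summed into FD.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Default mean-FD exclusion threshold (the "lenient" motion criterion).
DEFAULT_FD_THRESHOLD_MM = 0.55

#: A region time series is "constant zero" when its largest magnitude is
#: below this; guards against float noise masquerading as signal.
CONSTANT_ZERO_TOL = 1e-12

MANIFEST_COLUMNS = [
    "participant_id",
    "diagnosis",
    "age",
    "sex",
    "site",
    "mean_fd",
    "timeseries_path",
]


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`."""

    excluded_constant: list[str] = field(default_factory=list)
    excluded_motion: list[str] = field(default_factory=list)
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_constant) + len(self.excluded_motion)


@dataclass
class TimeSeriesDataset:
    """Labeled multivariate time-series dataset.

    Parameters
    ----------
    data
        Array of shape ``(N, R, T)``.
    region_labels
        ``R`` unique region names; column order is authoritative for every
        downstream representation.
    participant_ids
        ``N`` unique participant identifiers, in manifest order.
    tr_seconds
        Sampling interval in seconds.
    meta
        Metadata table indexed by participant id. Recognised columns:
        ``diagnosis`` (two levels), ``age``, ``sex`` (0=male, 1=female),
        ``site``, ``mean_fd`` (mm, optional). Optional per-participant
        6 x T motion traces live in :attr:`motion`.
    motion
        Optional mapping participant id -> (6, T) array of realignment
        parameters: three translations (mm) then three rotations (radians).
    """

    data: np.ndarray
    region_labels: list[str]
    participant_ids: list[str]
    tr_seconds: float
    meta: pd.DataFrame
    motion: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be N x R x T, got shape {self.data.shape}")
        n, r, t = self.data.shape
        if min(n, r, t) < 1:
            raise ValueError("N, R and T must all be >= 1")
        if len(self.region_labels) != r:
            raise ValueError("region_labels length does not match data")
        if len(set(self.region_labels)) != r:
            raise ValueError("region labels must be unique")
        if len(self.participant_ids) != n:
            raise ValueError("participant_ids length does not match data")
        if len(set(self.participant_ids)) != n:
            raise ValueError("participant ids must be unique")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        missing = [p for p in self.participant_ids if p not in self.meta.index]
        if missing:
            raise ValueError(f"meta missing participants: {missing}")
        if "diagnosis" in self.meta.columns:
            levels = self.meta.loc[self.participant_ids, "diagnosis"].unique()
            if len(levels) > 2:
                raise ValueError(
                    f"diagnosis must have at most two levels, got {sorted(levels)}"
                )

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def labels(self, positive: str | None = None) -> np.ndarray:
        """Binary label vector (1 = case) aligned to participant order.

        ``positive`` names the case level explicitly; by default the
        lexicographically larger of the two diagnosis levels that is not
        literally ``"control"`` is treated as the case.
        """
        diag = self.meta.loc[self.participant_ids, "diagnosis"].to_numpy()
        levels = sorted(set(diag))
        if positive is None:
            non_control = [lv for lv in levels if str(lv).lower() != "control"]
            positive = non_control[-1] if non_control else levels[-1]
        return (diag == positive).astype(int)

    def subset(self, participant_ids: list[str]) -> "TimeSeriesDataset":
        idx = [self.participant_ids.index(p) for p in participant_ids]
        return TimeSeriesDataset(
            data=self.data[idx],
            region_labels=list(self.region_labels),
            participant_ids=list(participant_ids),
            tr_seconds=self.tr_seconds,
            meta=self.meta.loc[participant_ids].copy(),
            motion={p: self.motion[p] for p in participant_ids if p in self.motion},
        )


def compute_framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement from six realignment parameters.

    ``motion`` is (6, T): rows 0-2 translations in mm, rows 3-5 rotations in
    radians. FD[t] is the sum of absolute backward differences of the
    translations plus ``head_radius_mm`` times the summed absolute rotation
    differences; FD[0] = 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError(f"motion must be 6 x T, got shape {motion.shape}")
    if motion.shape[1] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion traces contain non-finite values")
    d = np.abs(np.diff(motion, axis=1))
    fd = d[:3].sum(axis=0) + head_radius_mm * d[3:].sum(axis=0)
    return np.concatenate([[0.0], fd])


def apply_qc(
    dataset: TimeSeriesDataset,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
) -> tuple[TimeSeriesDataset, QCReport]:
    """Exclude constant-zero participants, then high-motion participants.

    A participant is constant-zero when every region trace has maximum
    magnitude below ``1e-12``. The motion criterion uses ``mean_fd`` from
    the metadata if present, otherwise derives it from raw motion traces;
    a participant with neither is retained with a warning.
    """
    report = QCReport(fd_threshold_mm=fd_threshold_mm)
    keep: list[str] = []
    for i, pid in enumerate(dataset.participant_ids):
        if np.max(np.abs(dataset.data[i])) < CONSTANT_ZERO_TOL:
            report.excluded_constant.append(pid)
            continue
        mean_fd = np.nan
        if "mean_fd" in dataset.meta.columns:
            mean_fd = dataset.meta.at[pid, "mean_fd"]
        if not np.isfinite(mean_fd) and pid in dataset.motion:
            mean_fd = compute_framewise_displacement(
                dataset.motion[pid], head_radius_mm
            ).mean()
        if np.isfinite(mean_fd):
            if mean_fd < 0:
                raise ValueError(f"negative mean_fd for {pid}")
            if mean_fd > fd_threshold_mm:
                report.excluded_motion.append(pid)
                continue
        else:
            logger.warning(
                "participant %s has neither mean_fd nor motion traces; "
                "motion criterion skipped",
                pid,
            )
        keep.append(pid)
    if not keep:
        raise ValueError("QC excluded every participant")
    kept = dataset.subset(keep)
    if "diagnosis" in dataset.meta.columns:
        before = set(dataset.meta.loc[dataset.participant_ids, "diagnosis"])
        after = set(kept.meta["diagnosis"])
        if len(before) == 2 and len(after) < 2:
            raise ValueError("QC excluded an entire diagnosis class")
    return kept, report


def _read_timeseries_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}") from exc
    return values, [str(c) for c in df.columns]


def _read_timeseries_h5(path: Path, pid: str) -> tuple[np.ndarray, list[str]]:
    with h5py.File(path, "r") as f:
        grp = f[pid] if pid in f else f
        bold = np.asarray(grp["bold"], dtype=float)  # T x R
        regions = [
            r.decode() if isinstance(r, bytes) else str(r)
            for r in grp["bold"].attrs["regions"]
        ]
    return bold, regions


def load_dataset(manifest_path: str | Path, tr_seconds: float) -> TimeSeriesDataset:
    """Load a dataset from a participant manifest.

    The manifest is a CSV with columns
    ``participant_id,diagnosis,age,sex,site,mean_fd,timeseries_path``.
    Each referenced file is either a wide CSV/TSV (rows = timepoints,
    columns = region labels with a header row) or an HDF5 file with a
    ``bold`` dataset (T x R) carrying a ``regions`` attribute. Region
    columns are aligned by header name across participants; the first
    participant's column order is authoritative. Fails atomically: no
    partial dataset is returned on malformed input.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"participant_id", "diagnosis", "timeseries_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")
    pids = [str(p) for p in manifest["participant_id"]]
    if len(set(pids)) != len(pids):
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        raise ValueError(f"duplicate participant ids in manifest: {dupes}")

    blocks: list[np.ndarray] = []
    region_order: list[str] | None = None
    t_expected: int | None = None
    for pid, rel in zip(pids, manifest["timeseries_path"]):
        path = Path(rel)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise FileNotFoundError(f"time series for participant {pid}: {path}")
        if path.suffix.lower() in {".h5", ".hdf5"}:
            values, regions = _read_timeseries_h5(path, pid)
        else:
            values, regions = _read_timeseries_csv(path)
        if region_order is None:
            region_order = regions
        else:
            if set(regions) != set(region_order):
                raise ValueError(
                    f"participant {pid}: region columns {regions} do not match "
                    f"manifest-leading order {region_order}"
                )
            values = values[:, [regions.index(r) for r in region_order]]
        if t_expected is None:
            t_expected = values.shape[0]
        elif values.shape[0] != t_expected:
            raise ValueError(
                f"participant {pid}: {values.shape[0]} timepoints, "
                f"expected {t_expected}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"participant {pid}: non-finite values in time series")
        blocks.append(values.T)  # R x T

    meta = manifest.copy()
    meta["participant_id"] = pids
    meta = meta.set_index("participant_id")
    if "mean_fd" not in meta.columns:
        meta["mean_fd"] = np.nan
    return TimeSeriesDataset(
        data=np.stack(blocks),
        region_labels=list(region_order or []),
        participant_ids=pids,
        tr_seconds=tr_seconds,
        meta=meta,
    )


def write_dataset(dataset: TimeSeriesDataset, out_dir: str | Path) -> Path:
    """Write a dataset as a manifest plus per-participant wide CSVs.

    Returns the manifest path. The written layout round-trips through
    :func:`load_dataset` bit-for-bit (full float precision is preserved).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    rows = []
    for i, pid in enumerate(dataset.participant_ids):
        rel = f"timeseries/{pid}.csv"
        df = pd.DataFrame(dataset.data[i].T, columns=dataset.region_labels)
        df.to_csv(ts_dir / f"{pid}.csv", index=False, float_format="%.17g")
        meta_row = dataset.meta.loc[pid]
        rows.append(
            {
                "participant_id": pid,
                "diagnosis": meta_row.get("diagnosis", ""),
                "age": meta_row.get("age", np.nan),
                "sex": meta_row.get("sex", np.nan),
                "site": meta_row.get("site", ""),
                "mean_fd": meta_row.get("mean_fd", np.nan),
                "timeseries_path": rel,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path
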