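"""Synthetic case-control multivariate time-series generator.

Participants are simulated as stable VAR(1) processes,
x_t = A x_{t-1} + eps_t with eps ~ N(0, diag(noise_sd^2)), a linear
stochastic model that is a reasonable first approximation to parcellated
resting-state dynamics. Group differences are planted by modifying the
case group's parameters: a region's self-coupling (autocorrelation), its
innovation SD or mean offset, or the coupling between a region pair.
Defaults mirror a typical resting-state acquisition: T = 150 samples at
TR = 2 s. The stationary covariance of the generator is available in
closed form (a discrete Lyapunov equation), giving exact ground truth for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core_data import TimeSeriesDataset

BURN_IN = 200


@dataclass
class Effect:
    """A planted case-group difference.

    target: a region index, a (i, j) pair, or "global".
    parameter: one of {"ar_coef", "noise_sd", "mean_offset", "coupling"}.
    delta: additive change applied in the case group.
    """

    target: int | tuple[int, int] | str
    parameter: str
    delta: float

    def __post_init__(self) -> None:
        allowed = {"ar_coef", "noise_sd", "mean_offset", "coupling"}
        if self.parameter not in allowed:
            raise ValueError(f"parameter must be one of {sorted(allowed)}")
        if self.parameter == "coupling" and not isinstance(self.target, tuple):
            raise ValueError("coupling effects need a (i, j) pair target")


@dataclass
class SyntheticSpec:
    """Complete description of a synthetic case-control dataset."""

    n_case: int = 30
    n_control: int = 30
    n_regions: int = 8
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    ar_coef: float = 0.3
    A: np.ndarray | None = None
    noise_sd: np.ndarray | float = 1.0
    effects: list[Effect] = field(default_factory=list)
    mean_offset: float = 0.0
    include_motion: bool = False
    n_sites: int = 1
    seed: int = 0

    def coefficient_matrix(self, group: str) -> np.ndarray:
        a = (
            np.asarray(self.A, dtype=float).copy()
            if self.A is not None
            else self.ar_coef * np.eye(self.n_regions)
        )
        if a.shape != (self.n_regions, self.n_regions):
            raise ValueError("A must be R x R")
        if group == "case":
            for e in self.effects:
                if e.parameter == "ar_coef":
                    a[e.target, e.target] += e.delta
                elif e.parameter == "coupling":
                    i, j = e.target
                    a[i, j] += e.delta
                    a[j, i] += e.delta
        rho = np.max(np.abs(np.linalg.eigvals(a)))
        if rho >= 1:
            raise ValueError(f"unstable dynamics for {group}: spectral radius {rho:.3f}")
        return a

    def noise_vector(self, group: str) -> np.ndarray:
        q = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_regions,)
        ).copy()
        if group == "case":
            for e in self.effects:
                if e.parameter == "noise_sd":
                    if e.target == "global":
                        q += e.delta
                    else:
                        q[e.target] += e.delta
        if np.any(q <= 0):
            raise ValueError("noise SDs must stay positive")
        return q

    def mean_vector(self, group: str) -> np.ndarray:
        mu = np.full(self.n_regions, self.mean_offset, dtype=float)
        if group == "case":
            for e in self.effects:
                if e.parameter == "mean_offset":
                    if e.target == "global":
                        mu += e.delta
                    else:
                        mu[e.target] += e.delta
        return mu


def expected_stationary_covariance(
    A: np.ndarray, noise_sd: np.ndarray | float
) -> np.ndarray:
    """Stationary covariance of x_t = A x_{t-1} + eps_t: solves
    Sigma = A Sigma A' + Q with Q = diag(noise_sd^2)."""
    A = np.asarray(A, dtype=float)
    q = np.broadcast_to(np.asarray(noise_sd, dtype=float), (A.shape[0],))
    return linalg.solve_discrete_lyapunov(A, np.diag(q**2))


def _simulate_var(
    a: np.ndarray, noise_sd: np.ndarray, mu: np.ndarray, t: int, rng
) -> np.ndarray:
    r = a.shape[0]
    eps = rng.normal(0.0, noise_sd[:, None], size=(r, t + BURN_IN))
    x = np.zeros((r, t + BURN_IN))
    for step in range(1, t + BURN_IN):
        x[:, step] = a @ x[:, step - 1] + eps[:, step]
    return x[:, BURN_IN:] + mu[:, None]


def _random_walk_motion(t: int, rng) -> np.ndarray:
    """6 x T realignment traces: translations (mm) and rotations (rad)
    as small random walks."""
    steps = np.concatenate(
        [rng.normal(0, 0.02, size=(3, t)), rng.normal(0, 0.0004, size=(3, t))]
    )
    return np.cumsum(steps, axis=1)


def generate_dataset(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Simulate the dataset described by ``spec``; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    groups = ["control"] * spec.n_control + ["case"] * spec.n_case
    params = {
        g: (spec.coefficient_matrix(g), spec.noise_vector(g), spec.mean_vector(g))
        for g in ("control", "case")
    }
    data = np.empty((len(groups), spec.n_regions, spec.n_timepoints))
    motion: dict[str, np.ndarray] = {}
    rows = []
    for i, group in enumerate(groups):
        pid = f"sub-{i + 1:04d}"
        a, q, mu = params[group]
        data[i] = _simulate_var(a, q, mu, spec.n_timepoints, rng)
        mean_fd = np.nan
        if spec.include_motion:
            motion[pid] = _random_walk_motion(spec.n_timepoints, rng)
        rows.append(
            {
                "participant_id": pid,
                "diagnosis": group,
                "age": float(np.clip(rng.normal(30.0, 8.0), 18, 65)),
                "sex": int(rng.integers(0, 2)),
                "site": f"site{1 + i % spec.n_sites}",
                "mean_fd": mean_fd,
            }
        )
    meta = pd.DataFrame(rows).set_index("participant_id")
    if spec.include_motion:
        from .core_data import compute_framewise_displacement

        for pid in motion:
            meta.loc[pid, "mean_fd"] = float(
                compute_framewise_displacement(motion[pid]).mean()
            )
    return TimeSeriesDataset(
        data=data,
        region_labels=[f"region_{j + 1}" for j in range(spec.n_regions)],
        participant_ids=list(meta.index),
        tr_seconds=spec.tr_seconds,
        meta=meta,
        motion=motion,
    )
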