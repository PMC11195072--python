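"""Statistics of pairwise interactions (SPIs) between region time series.

Fourteen scalar coupling statistics spanning correlation, elastic
alignment, spectral synchronization, information flow and causal
inference. Directed SPIs are evaluated on every ordered region pair
(P = R(R-1)); undirected SPIs on unique pairs only (P = R(R-1)/2),
matching the upper triangle of a symmetric coupling matrix.

Information-theoretic SPIs (transfer entropy, directed information,
phi-star) use Gaussian/linear estimators with history length 1, which
admit closed-form oracles; spectral statistics share the Welch settings
of the univariate spectral features. All SPIs are computed on z-scored
series, so the Pearson statistic equals the empirical covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize
from scipy import signal as sps

from .features import WELCH_SEGMENT, zscore_series

logger = logging.getLogger(__name__)

SPI_NAMES = [
    "PSI_frequency",
    "ANM",
    "DI",
    "transfer_entropy",
    "phi_star",
    "spectral_GC",
    "PLI",
    "PSI_time_frequency",
    "barycenter_DTW",
    "DTW",
    "power_envelope_corr",
    "coherence_magnitude",
    "cointegration",
    "pearson",
]

#: Direction-sensitive SPIs are evaluated on all ordered pairs; the phase
#: slope index is antisymmetric rather than asymmetric but is stored the
#: same way.
DIRECTED_SPIS = {
    "ANM",
    "DI",
    "transfer_entropy",
    "spectral_GC",
    "PSI_frequency",
    "PSI_time_frequency",
    "cointegration",
}

N_SPIS = len(SPI_NAMES)  # 14


@dataclass
class PairIndex:
    """Ordered list of (i, j) region-index pairs for one SPI."""

    pairs: list[tuple[int, int]]
    directed: bool

    def __len__(self) -> int:
        return len(self.pairs)


def make_pair_index(n_regions: int, directed: bool) -> PairIndex:
    """Row-major pair enumeration: all ordered pairs i != j when directed,
    upper-triangle pairs i < j otherwise."""
    if directed:
        pairs = [
            (i, j) for i in range(n_regions) for j in range(n_regions) if i != j
        ]
    else:
        pairs = [
            (i, j) for i in range(n_regions) for j in range(i + 1, n_regions)
        ]
    return PairIndex(pairs=pairs, directed=directed)


@dataclass
class SPITensor:
    """Per-SPI N x P coupling matrices with their pair indices."""

    values: dict[str, np.ndarray]
    pair_index: dict[str, PairIndex]
    spi_names: list[str]
    region_labels: list[str]
    participant_ids: list[str]


# ---------------------------------------------------------------------------
# correlation and alignment


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input to pearson")
    return float(np.corrcoef(x, y)[0, 1])


@njit(cache=True)
def _dtw_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, m = x.size, y.size
    d = np.full((n + 1, m + 1), np.inf)
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(x[i - 1] - y[j - 1])
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = cost + best
    return d


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Unconstrained dynamic-time-warping distance with |.| local cost."""
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    return float(_dtw_matrix(x, y)[x.size, y.size])


def _dtw_path(x: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    d = _dtw_matrix(
        np.ascontiguousarray(x, dtype=float), np.ascontiguousarray(y, dtype=float)
    )
    i, j = x.size, y.size
    path = []
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        steps = [
            (d[i - 1, j - 1], i - 1, j - 1),
            (d[i - 1, j], i - 1, j),
            (d[i, j - 1], i, j - 1),
        ]
        _, i, j = min(steps, key=lambda s: s[0])
    path.reverse()
    return path


def dba_barycenter(
    series: list[np.ndarray], n_iter: int = 10
) -> np.ndarray:
    """DTW barycenter averaging: elementwise-mean init, fixed iterations."""
    stack = np.vstack([np.asarray(s, dtype=float) for s in series])
    center = stack.mean(axis=0)
    for _ in range(n_iter):
        sums = np.zeros_like(center)
        counts = np.zeros_like(center)
        for s in stack:
            for ci, si in _dtw_path(center, s):
                sums[ci] += s[si]
                counts[ci] += 1
        mask = counts > 0
        center = np.where(mask, sums / np.maximum(counts, 1), center)
    return center


def barycenter_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum value of the DTW-barycenter-average of the pair."""
    return float(dba_barycenter([x, y]).max())


# ---------------------------------------------------------------------------
# spectral statistics


def _welch_coherency(
    x: np.ndarray, y: np.ndarray, tr_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Complex coherency C_xy(f) = S_xy / sqrt(S_xx S_yy) from Welch."""
    fs = 1.0 / tr_seconds
    nperseg = min(x.size, WELCH_SEGMENT)
    noverlap = nperseg // 2
    kw = dict(fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
              detrend="constant")
    f, pxy = sps.csd(x, y, **kw)
    _, pxx = sps.welch(x, **kw)
    _, pyy = sps.welch(y, **kw)
    denom = np.sqrt(pxx * pyy)
    denom[denom == 0] = np.nan
    return f, pxy / denom


def coherence_magnitude(x: np.ndarray, y: np.ndarray, tr_seconds: float) -> float:
    """Mean magnitude of the complex coherency over the full band."""
    _, c = _welch_coherency(x, y, tr_seconds)
    return float(np.nanmean(np.abs(c)))


def psi_frequency(x: np.ndarray, y: np.ndarray, tr_seconds: float) -> float:
    """Phase slope index over the full band: Im(sum_f conj(C(f)) C(f+df)).

    Antisymmetric: psi(x, y) = -psi(y, x). A positive value indicates
    a consistent phase lead of x over y across frequencies.
    """
    _, c = _welch_coherency(x, y, tr_seconds)
    c = c[np.isfinite(c)]
    if c.size < 2:
        raise ValueError("degenerate spectrum for PSI")
    return float(np.imag(np.sum(np.conj(c[:-1]) * c[1:])))


def psi_time_frequency(
    x: np.ndarray, y: np.ndarray, tr_seconds: float, n_windows: int = 4
) -> float:
    """PSI averaged over equal-length time windows."""
    t = x.size
    w = t // n_windows
    if w < 16:
        raise ValueError("series too short for windowed PSI")
    vals = [
        psi_frequency(x[k * w : (k + 1) * w], y[k * w : (k + 1) * w], tr_seconds)
        for k in range(n_windows)
    ]
    return float(np.mean(vals))


def pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index from analytic-signal instantaneous phases.

    |<sign(sin(phi_x - phi_y))>|: blind to zero-lag (0 or pi) phase
    coupling, near 1 for a consistent nonzero phase lag.
    """
    phix = np.angle(sps.hilbert(x))
    phiy = np.angle(sps.hilbert(y))
    return float(np.abs(np.mean(np.sign(np.sin(phix - phiy)))))


def power_envelope_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of analytic-signal amplitude envelopes."""
    ex = np.abs(sps.hilbert(x))
    ey = np.abs(sps.hilbert(y))
    return pearson(ex, ey)


# ---------------------------------------------------------------------------
# information-theoretic statistics (Gaussian estimators, history 1)


def _resid_var(target: np.ndarray, predictors: np.ndarray) -> float:
    """Residual variance of OLS with intercept (MLE normalization)."""
    a = np.column_stack([np.ones(target.size), predictors])
    resid = target - a @ np.linalg.lstsq(a, target, rcond=None)[0]
    return float(np.mean(resid**2))


def transfer_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian transfer entropy TE(x -> y), history 1, delay 1, in nats.

    Half the log ratio of the residual variance of y_t given its own past
    to the residual variance given both pasts; equals the Granger
    ln-variance-ratio divided by two.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    yt, yp, xp = y[1:], y[:-1], x[:-1]
    v_restricted = _resid_var(yt, yp[:, None])
    v_full = _resid_var(yt, np.column_stack([yp, xp]))
    if v_full <= 0:
        raise ValueError("near-singular covariance in TE")
    return 0.5 * float(np.log(v_restricted / v_full))


def directed_information(x: np.ndarray, y: np.ndarray) -> float:
    """TE(x -> y) plus the instantaneous Gaussian MI of the innovations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    te = transfer_entropy(x, y)
    past = np.column_stack([x[:-1], y[:-1]])
    a = np.column_stack([np.ones(past.shape[0]), past])
    rx = x[1:] - a @ np.linalg.lstsq(a, x[1:], rcond=None)[0]
    ry = y[1:] - a @ np.linalg.lstsq(a, y[1:], rcond=None)[0]
    rho = np.corrcoef(rx, ry)[0, 1]
    rho = float(np.clip(rho, -0.999999, 0.999999))
    return te - 0.5 * float(np.log(1 - rho**2))


def _lagged_covariances(x: np.ndarray, y: np.ndarray):
    """Covariance blocks of (past, present) for the bivariate system."""
    past = np.column_stack([x[:-1], y[:-1]])
    pres = np.column_stack([x[1:], y[1:]])
    joint = np.cov(np.column_stack([past, pres]).T, ddof=1)
    return joint[:2, :2], joint[:2, 2:], joint[2:, 2:]


def phi_star(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian integrated-information proxy (mismatched-decoding form).

    Phi* quantifies the lag-1 predictive information lost when the
    bivariate system is replaced by two disconnected parts, each allowed
    only its own past. The mismatched-decoding information I*(beta) is
    maximized over the scalar decoding temperature beta and subtracted
    from the full predictive information; the result is symmetric in the
    two parts and nonnegative up to estimation error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    sx, sxy, sy = _lagged_covariances(x, y)
    syx = sxy.T
    sx_inv = np.linalg.inv(sx)
    cond = sy - syx @ sx_inv @ sxy
    sign_full, logdet_cond = np.linalg.slogdet(cond)
    sign_y, logdet_y = np.linalg.slogdet(sy)
    if sign_full <= 0 or sign_y <= 0:
        raise ValueError("near-singular covariance in phi_star")
    info_full = 0.5 * (logdet_y - logdet_cond)

    # disconnected model: each present coordinate regressed on its own past
    a_d = np.diag([sxy[0, 0] / sx[0, 0], sxy[1, 1] / sx[1, 1]])
    s_d = np.diag(
        [
            sy[0, 0] - sxy[0, 0] ** 2 / sx[0, 0],
            sy[1, 1] - sxy[1, 1] ** 2 / sx[1, 1],
        ]
    )
    s_d_inv = np.linalg.inv(s_d)
    r = sy - a_d @ sxy - syx @ a_d.T + a_d @ sx @ a_d.T
    tr_y = np.trace(s_d_inv @ sy)
    tr_r = np.trace(s_d_inv @ r)

    def neg_istar(beta: float) -> float:
        p = sx_inv + beta * a_d.T @ s_d_inv @ a_d
        sign_p, logdet_p = np.linalg.slogdet(sx @ p)
        if sign_p <= 0:
            return np.inf
        m = s_d_inv @ a_d @ np.linalg.inv(p) @ a_d.T @ s_d_inv
        istar = (
            0.5 * logdet_p
            + 0.5 * beta * (tr_y - tr_r)
            - 0.5 * beta**2 * np.trace(m @ sy)
        )
        return -istar

    res = optimize.minimize_scalar(neg_istar, bounds=(0.0, 10.0), method="bounded")
    return float(info_full + res.fun)  # info_full - max I*(beta)


# ---------------------------------------------------------------------------
# causal statistics


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical distance correlation between two scalar samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def centered(v):
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    a, b = centered(x), centered(y)
    dcov2 = (a * b).mean()
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def additive_noise_model(x: np.ndarray, y: np.ndarray) -> float:
    """Additive-noise-model score for x -> y.

    Kernel-ridge regression (RBF, median-heuristic bandwidth) of y on x,
    then the distance correlation between x and the residuals: a small
    value means the residuals are independent of the cause, consistent
    with the directed model y = f(x) + noise.
    """
    from sklearn.kernel_ridge import KernelRidge

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    pair_d = np.abs(x[:, None] - x[None, :])
    med = np.median(pair_d[pair_d > 0])
    gamma = 1.0 / (2 * med**2) if med > 0 else 1.0
    model = KernelRidge(kernel="rbf", alpha=1e-2, gamma=gamma)
    model.fit(x[:, None], y)
    resid = y - model.predict(x[:, None])
    return distance_correlation(x, resid)


def _fit_var(data: np.ndarray, max_order: int = 10, order: int | None = None):
    """VAR fit returning (coefs [p,2,2], noise covariance, order)."""
    from statsmodels.tsa.api import VAR

    model = VAR(data)
    if order is None:
        sel = model.select_order(maxlags=min(max_order, data.shape[0] // 5))
        order = max(1, sel.bic)
    fit = model.fit(order, trend="c")
    return fit.coefs, fit.sigma_u, order


def spectral_granger(
    x: np.ndarray,
    y: np.ndarray,
    order: int | None = None,
    n_freqs: int = 128,
    return_spectrum: bool = False,
):
    """Geweke frequency-domain Granger causality x -> y, band average.

    A VAR (order chosen by BIC up to 10 unless given) is factorized into
    its transfer function H and innovation covariance; at each frequency
    the causal contribution of x to the spectral power of y gives
    f(lambda) = ln(S_yy / (S_yy - sigma_{x|y} |H_yx|^2)). The scalar
    statistic is the mean over a uniform grid on [0, pi); by the Geweke
    identity this approximates the time-domain ln variance ratio.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    data = np.column_stack([x, y])
    coefs, sigma, order = _fit_var(data, order=order)
    lam = np.arange(n_freqs) * np.pi / n_freqs
    # conditional innovation variance of the source given the target noise
    sig_cond = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
    f_vals = np.empty(n_freqs)
    eye = np.eye(2)
    for k, w in enumerate(lam):
        a = eye.astype(complex).copy()
        for p in range(coefs.shape[0]):
            a -= coefs[p] * np.exp(-1j * w * (p + 1))
        h = np.linalg.inv(a)
        s = h @ sigma @ h.conj().T
        s_yy = s[1, 1].real
        intrinsic = s_yy - sig_cond * np.abs(h[1, 0]) ** 2
        f_vals[k] = np.log(s_yy / intrinsic) if intrinsic > 0 else np.nan
    stat = float(np.nanmean(f_vals))
    if return_spectrum:
        return stat, lam, f_vals
    return stat


def cointegration_stat(x: np.ndarray, y: np.ndarray) -> float:
    """ADF statistic of the residuals of OLS y on x (Engle-Granger step 2).

    Strongly negative when a linear combination of the two series is
    stationary although the series themselves may not be.
    """
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples")
    a = np.column_stack([np.ones(x.size), x])
    resid = y - a @ np.linalg.lstsq(a, y, rcond=None)[0]
    return float(adfuller(resid, regression="c", autolag="AIC")[0])


# ---------------------------------------------------------------------------
# registry and tensor computation


def _spi_func(name: str):
    table = {
        "pearson": lambda x, y, tr: pearson(x, y),
        "DTW": lambda x, y, tr: dtw_distance(x, y),
        "barycenter_DTW": lambda x, y, tr: barycenter_statistic(x, y),
        "coherence_magnitude": coherence_magnitude,
        "PSI_frequency": psi_frequency,
        "PSI_time_frequency": psi_time_frequency,
        "PLI": lambda x, y, tr: pli(x, y),
        "power_envelope_corr": lambda x, y, tr: power_envelope_corr(x, y),
        "DI": lambda x, y, tr: directed_information(x, y),
        "transfer_entropy": lambda x, y, tr: transfer_entropy(x, y),
        "phi_star": lambda x, y, tr: phi_star(x, y),
        "ANM": lambda x, y, tr: additive_noise_model(x, y),
        "spectral_GC": lambda x, y, tr: spectral_granger(x, y),
        "cointegration": lambda x, y, tr: cointegration_stat(x, y),
    }
    return table[name]


def compute_spi_tensor(dataset, spi_names: list[str] | None = None) -> SPITensor:
    """Evaluate each requested SPI on every region pair of every participant.

    Series are z-scored once per participant-region. Per-pair failures are
    logged and stored as NaN; they never abort the tensor.
    """
    names = list(spi_names) if spi_names is not None else list(SPI_NAMES)
    unknown = set(names) - set(SPI_NAMES)
    if unknown:
        raise ValueError(f"unknown SPIs: {sorted(unknown)}")
    n, r, t = dataset.data.shape
    zdata = np.empty((n, r, t))
    for i in range(n):
        for j in range(r):
            try:
                zdata[i, j] = zscore_series(dataset.data[i, j])
            except ValueError:
                zdata[i, j] = np.nan
    values: dict[str, np.ndarray] = {}
    pair_index: dict[str, PairIndex] = {}
    for name in names:
        idx = make_pair_index(r, name in DIRECTED_SPIS)
        func = _spi_func(name)
        mat = np.full((n, len(idx)), np.nan)
        for i in range(n):
            for p, (a, b) in enumerate(idx.pairs):
                xa, xb = zdata[i, a], zdata[i, b]
                if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(xb))):
                    continue
                try:
                    mat[i, p] = func(xa, xb, dataset.tr_seconds)
                except Exception as exc:  # per-pair failures are not fatal
                    logger.debug(
                        "SPI %s failed for participant %s pair (%d,%d): %s",
                        name, dataset.participant_ids[i], a, b, exc,
                    )
        values[name] = mat
        pair_index[name] = idx
    return SPITensor(
        values=values,
        pair_index=pair_index,
        spi_names=names,
        region_labels=list(dataset.region_labels),
        participant_ids=list(dataset.participant_ids),
    )


def write_spi_tensor_h5(tensor: SPITensor, path) -> None:
    """Persist an SPI tensor: one HDF5 group per SPI with its pair index."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["region_labels"] = tensor.region_labels
        f.attrs["participant_ids"] = tensor.participant_ids
        for name in tensor.spi_names:
            grp = f.create_group(name)
            grp.create_dataset("values", data=tensor.values[name])
            grp.create_dataset(
                "pairs", data=np.array(tensor.pair_index[name].pairs, dtype=int)
            )
            grp.attrs["directed"] = tensor.pair_index[name].directed


def read_spi_tensor_h5(path) -> SPITensor:
    """Inverse of :func:`write_spi_tensor_h5`."""
    import h5py

    with h5py.File(path, "r") as f:
        region_labels = [str(r) for r in f.attrs["region_labels"]]
        participant_ids = [str(p) for p in f.attrs["participant_ids"]]
        values, pair_index, names = {}, {}, []
        for name in f:
            names.append(name)
            values[name] = np.asarray(f[name]["values"])
            pair_index[name] = PairIndex(
                pairs=[tuple(p) for p in np.asarray(f[name]["pairs"])],
                directed=bool(f[name].attrs["directed"]),
            )
    return SPITensor(
        values=values,
        pair_index=pair_index,
        spi_names=names,
        region_labels=region_labels,
        participant_ids=participant_ids,
    )


def spi_tensor_to_frame(tensor: SPITensor):
    """Tidy long view: participant_id, region_from, region_to, spi, value."""
    import pandas as pd

    rows = []
    for name in tensor.spi_names:
        idx = tensor.pair_index[name]
        mat = tensor.values[name]
        for i, pid in enumerate(tensor.participant_ids):
            for p, (a, b) in enumerate(idx.pairs):
                rows.append(
                    (
                        pid,
                        tensor.region_labels[a],
                        tensor.region_labels[b],
                        name,
                        mat[i, p],
                    )
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "region_from", "region_to", "spi", "value"]
    )
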