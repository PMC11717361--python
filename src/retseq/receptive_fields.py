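"""Spatio-temporal receptive-field estimation, decomposition, and fitting.

RFs are estimated by triggered averaging of the dense-noise stimulus:
either spike-triggered (MEA path) or *gradient*-triggered, where the weights
are the positive-clipped temporal derivative of the detrended calcium trace.
The 3D kernel F(x, y, tau) is computed on a grid upsampled to 10x the
stimulus rate over lags of about -0.20 to 1.38 s, where positive lag means
stimulus *preceding* the response (a small acausal margin is kept as a
sanity check). F is decomposed into a spatial map Fs and temporal kernel Ft
by rank-1 SVD, scored by the separability index

    QI_RF = 1 - Var[F - Ft x Fs] / Var[F]

and the spatial map is summarized by a constrained 2D
difference-of-Gaussians fit (center and surround share mean and covariance
up to one scalar), yielding polarity, a surround index, and the 2-sigma
center-ellipse area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from .preprocess import Trace
from .stimulus import DenseNoiseStimulus

__all__ = [
    "ReceptiveField3D",
    "RFDecomposition",
    "DoGFit",
    "DoGResult",
    "clipped_gradient",
    "estimate_rf",
    "estimate_rf_spikes",
    "decompose_rf",
    "fit_dog",
    "temporal_fwhm",
    "null_rf_threshold",
]


@dataclass(frozen=True)
class ReceptiveField3D:
    """3D triggered-average kernel F(x, y, tau)."""

    F: np.ndarray               # (rows, cols, n_lags)
    lags_s: np.ndarray          # strictly increasing; positive = past
    source: str                 # "calcium-gradient" or "spike"
    check_um: float = 40.0

    def __post_init__(self):
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("RF contains non-finite values")


@dataclass
class RFDecomposition:
    """Rank-1 decomposition of an RF with quality and scaling conventions.

    max|Ft| = 1 and max|Fs| = max|F|; the sign is fixed so the product
    Ft*Fs matches the sign of F at its dominant element.
    """

    Fs: np.ndarray
    Ft: np.ndarray
    lags_s: np.ndarray
    qi_rf: float
    check_um: float = 40.0


@dataclass(frozen=True)
class DoGFit:
    """Parameters of the tied center/surround difference-of-Gaussians."""

    amplitude: float
    center_xy: tuple[float, float]      # (col, row) in checks
    sigma_x: float
    sigma_y: float
    angle_rad: float
    surround_scale: float               # amplitude ratio surround/center
    surround_sigma_ratio: float         # covariance scale (>1)
    cost: float


@dataclass
class DoGResult:
    """DoG fit of a spatial RF plus derived polarity/surround/size metrics."""

    fit: DoGFit
    polarity: int                       # +1 On, -1 Off
    surround_index: float               # in [-1, 0]
    center_area_um2: float              # 2-sigma ellipse area
    sigma_major_um: float
    sigma_minor_um: float
    low_quality: bool = False
    converged: bool = True


def clipped_gradient(trace: Trace, fs: float | None = None) -> Trace:
    """Positive-clipped forward-difference derivative of a detrended trace.

    Length T-1, left-aligned: sample i is max(0, (r[i+1]-r[i]) * fs).
    """
    fs = fs or trace.fs
    if len(trace.samples) < 2:
        raise ValueError("trace too short to differentiate")
    grad = np.diff(trace.samples) * fs
    return Trace(samples=np.maximum(0.0, grad), fs=fs, t0=trace.t0)


def _weights_on_grid(weights: Trace, t_grid: np.ndarray) -> np.ndarray:
    w = np.interp(t_grid, weights.times, weights.samples, left=0.0, right=0.0)
    return w


def estimate_rf(weights: Trace, stimulus: DenseNoiseStimulus,
                lag_range_s: tuple[float, float] = (-0.20, 1.38),
                upsample: int = 10, smooth: bool = True,
                source: str = "calcium-gradient") -> ReceptiveField3D:
    """Weighted triggered-average RF on an upsampled lag grid.

        F(x, y, tau) = sum_t w(t) * S(x, y, t - tau)

    Stimulus frames are held (zero-order) on a grid of ``upsample`` times the
    stimulus rate; the weight trace is linearly interpolated onto it. With
    ``smooth`` each lag slice is blurred with a 5x5-pixel, 1-pixel-sd
    Gaussian window.
    """
    if np.all(weights.samples == 0):
        raise ValueError("weights are identically zero")
    fs_up = stimulus.rate * upsample
    n_up = int(round(stimulus.duration_s * fs_up))
    t_grid = np.arange(n_up) / fs_up
    frame_idx = np.minimum((t_grid * stimulus.rate).astype(int),
                           stimulus.n_frames - 1)
    S = stimulus.frames.astype(float) - 0.5   # zero-mean contrast
    S_flat = S.reshape(-1, stimulus.n_frames)[:, frame_idx]
    w = _weights_on_grid(weights, t_grid)

    lag_lo = int(round(lag_range_s[0] * fs_up))
    lag_hi = int(round(lag_range_s[1] * fs_up))
    lags = np.arange(lag_lo, lag_hi + 1)
    F = np.empty((stimulus.rows, stimulus.cols, len(lags)))
    for j, lag in enumerate(lags):
        # response at t pairs with stimulus at t - lag
        if lag >= 0:
            sl_w, sl_s = slice(lag, n_up), slice(0, n_up - lag)
        else:
            sl_w, sl_s = slice(0, n_up + lag), slice(-lag, n_up)
        F[:, :, j] = (S_flat[:, sl_s] @ w[sl_w]).reshape(
            stimulus.rows, stimulus.cols)
    if smooth:
        for j in range(F.shape[2]):
            F[:, :, j] = gaussian_filter(F[:, :, j], sigma=1.0, radius=2)
    return ReceptiveField3D(F=F, lags_s=lags / fs_up, source=source,
                            check_um=stimulus.check_um)


def estimate_rf_spikes(spike_times: np.ndarray, stimulus: DenseNoiseStimulus,
                       n_lags: int = 40, smooth: bool = False
                       ) -> ReceptiveField3D:
    """Classic spike-triggered average over ``n_lags`` samples at native rate."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise ValueError("no spikes")
    counts, _ = np.histogram(
        spike_times, bins=stimulus.n_frames,
        range=(0.0, stimulus.duration_s))
    weights = Trace(samples=counts.astype(float), fs=stimulus.rate)
    return estimate_rf(weights, stimulus, upsample=1,
                       lag_range_s=(0.0, (n_lags - 1) / stimulus.rate),
                       smooth=smooth, source="spike")


def decompose_rf(rf: ReceptiveField3D) -> RFDecomposition:
    """Rank-1 SVD decomposition with the package's scaling conventions."""
    rows, cols, n_lags = rf.F.shape
    M = rf.F.reshape(rows * cols, n_lags)
    if np.all(M == 0):
        raise ValueError("all-zero RF cannot be decomposed")
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    fs_raw = u[:, 0] * s[0]
    ft_raw = vt[0]
    rank1 = np.outer(fs_raw, ft_raw)
    qi_rf = 1.0 - float(np.var(M - rank1) / np.var(M))
    # the SVD product reconstructs F's sign; the joint (-Fs, -Ft) ambiguity
    # is resolved so Fs carries the polarity of F at the dominant lag
    i_max = int(np.argmax(np.abs(fs_raw)))
    j_dom = int(np.argmax(np.abs(ft_raw)))
    if np.sign(fs_raw[i_max]) != np.sign(M[i_max, j_dom]) and M[i_max, j_dom] != 0:
        fs_raw, ft_raw = -fs_raw, -ft_raw
    # rescale: max|Ft| = 1, max|Fs| = max|F|
    ft = ft_raw / np.max(np.abs(ft_raw))
    fs_map = fs_raw / np.max(np.abs(fs_raw)) * np.max(np.abs(rf.F))
    return RFDecomposition(Fs=fs_map.reshape(rows, cols), Ft=ft,
                           lags_s=rf.lags_s.copy(), qi_rf=qi_rf,
                           check_um=rf.check_um)


def _dog_model(params: np.ndarray, xx: np.ndarray, yy: np.ndarray
               ) -> np.ndarray:
    amp, x0, y0, sx, sy, th, s_amp, c_ratio = params
    dx, dy = xx - x0, yy - y0
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    q = (u / sx) ** 2 + (v / sy) ** 2
    return amp * (np.exp(-0.5 * q) - s_amp * np.exp(-0.5 * q / c_ratio))


def fit_dog(Fs: np.ndarray, check_um: float = 40.0, n_restarts: int = 5,
            seed: int = 0, xtol: float = 1e-8) -> DoGResult:
    """Constrained least-squares DoG fit of a spatial RF map.

    Center and surround Gaussians share mean and covariance up to the scalar
    ``surround_sigma_ratio``; the surround amplitude is a fraction
    ``surround_scale`` of the center's. Initialization comes from image
    moments of |Fs|, with random restarts. Polarity is the sign of the
    fitted model at its mean; the surround index and the 2-sigma
    center-ellipse area are computed in polarity-rectified space.
    """
    Fs = np.asarray(Fs, dtype=float)
    rows, cols = Fs.shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    absF = np.abs(Fs)
    peak = float(absF.max())
    mad = float(np.median(np.abs(absF - np.median(absF)))) or 1e-12
    low_quality = peak < 3.0 * (np.median(absF) + 3 * mad)

    i_pk, j_pk = np.unravel_index(np.argmax(absF), Fs.shape)
    amp0 = Fs[i_pk, j_pk]
    w = absF / absF.sum()
    x_m = float((w * xx).sum())
    y_m = float((w * yy).sum())
    sx0 = max(0.5, np.sqrt(float((w * (xx - x_m) ** 2).sum())))
    sy0 = max(0.5, np.sqrt(float((w * (yy - y_m) ** 2).sum())))

    lb = [-np.inf, -2.0, -2.0, 0.3, 0.3, -np.pi, 0.0, 1.2]
    ub = [np.inf, cols + 1.0, rows + 1.0, cols, rows, np.pi, 0.95, 10.0]
    x0_base = np.array([amp0, j_pk, i_pk, sx0, sy0, 0.0, 0.2, 2.0])

    def resid(p):
        return (_dog_model(p, xx, yy) - Fs).ravel()

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        x0 = x0_base.copy()
        if k > 0:
            x0[1] += rng.normal(0, 1)
            x0[2] += rng.normal(0, 1)
            x0[3] *= np.exp(rng.normal(0, 0.3))
            x0[4] *= np.exp(rng.normal(0, 0.3))
            x0[6] = rng.uniform(0, 0.6)
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=xtol)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return DoGResult(fit=None, polarity=0, surround_index=np.nan,
                         center_area_um2=np.nan, sigma_major_um=np.nan,
                         sigma_minor_um=np.nan, low_quality=low_quality,
                         converged=False)

    amp, x0c, y0c, sx, sy, th, s_amp, c_ratio = best.x
    fit = DoGFit(amplitude=float(amp), center_xy=(float(x0c), float(y0c)),
                 sigma_x=float(sx), sigma_y=float(sy), angle_rad=float(th),
                 surround_scale=float(s_amp),
                 surround_sigma_ratio=float(c_ratio), cost=float(best.cost))
    polarity = int(np.sign(amp * (1.0 - s_amp))) or 1

    # surround index in polarity-rectified space: G = p*Fs, Gc = max(0, G)
    G = polarity * Fs
    Gc = np.maximum(0.0, G)
    denom = float(np.sum(np.abs(G)))
    surround_index = float(np.sum(G - Gc) / denom) if denom > 0 else np.nan

    # center size: single Gaussian fit to Gc with the DoG mean fixed
    def resid_center(p):
        a, csx, csy, cth = p
        return (_dog_model(np.array([a, x0c, y0c, csx, csy, cth, 0.0, 2.0]),
                           xx, yy) - Gc).ravel()

    sol_c = least_squares(
        resid_center, np.array([np.max(Gc), sx, sy, th]),
        bounds=([0.0, 0.3, 0.3, -np.pi], [np.inf, cols, rows, np.pi]),
        xtol=xtol)
    _, csx, csy, _ = sol_c.x
    sigma_major = max(csx, csy) * check_um
    sigma_minor = min(csx, csy) * check_um
    center_area = 4.0 * np.pi * sigma_major * sigma_minor  # 2-sigma ellipse

    return DoGResult(fit=fit, polarity=polarity,
                     surround_index=surround_index,
                     center_area_um2=float(center_area),
                     sigma_major_um=float(sigma_major),
                     sigma_minor_um=float(sigma_minor),
                     low_quality=low_quality)


def temporal_fwhm(Ft: np.ndarray, lags_s: np.ndarray
                  ) -> tuple[float, bool]:
    """Full width at half extremum of the dominant temporal lobe, seconds.

    The dominant lobe is located at the maximum of |Ft| (On kernels are
    handled by sign flip so the lobe is measured the same way as the
    half-minimum of an Off kernel). Crossings are linearly interpolated. If
    the extremum sits at the grid boundary or a crossing is missing on one
    side, the returned width covers the available side(s) only and the
    result is flagged unreliable.
    """
    Ft = np.asarray(Ft, dtype=float)
    lags_s = np.asarray(lags_s, dtype=float)
    i_pk = int(np.argmax(np.abs(Ft)))
    y = Ft * np.sign(Ft[i_pk])          # lobe now positive
    half = y[i_pk] / 2.0

    def cross(idx_range):
        prev = i_pk
        for i in idx_range:
            if y[i] <= half:
                # interpolate between i and prev
                t0, t1 = lags_s[prev], lags_s[i]
                y0, y1 = y[prev], y[i]
                return t0 + (half - y0) * (t1 - t0) / (y1 - y0)
            prev = i
        return None

    right = cross(range(i_pk + 1, len(y)))
    left = cross(range(i_pk - 1, -1, -1))
    reliable = (0 < i_pk < len(y) - 1) and right is not None and left is not None
    width = 0.0
    if right is not None:
        width += right - lags_s[i_pk]
    if left is not None:
        width += lags_s[i_pk] - left
    return float(width), bool(reliable)


def null_rf_threshold(weights: Trace, stimulus: DenseNoiseStimulus,
                      n_shuffles: int = 20, quantile: float = 0.99,
                      seed: int = 0, **rf_kwargs) -> float:
    """Null distribution of max|F| from circularly shifted weights.

    Returns the requested quantile of the shuffle maxima; an RF whose
    max|F| stays below it is indistinguishable from chance.
    """
    rng = np.random.default_rng(seed)
    maxima = []
    for _ in range(n_shuffles):
        shift = int(rng.integers(len(weights.samples) // 4,
                                 3 * len(weights.samples) // 4))
        w = Trace(samples=np.roll(weights.samples, shift), fs=weights.fs,
                  t0=weights.t0)
        rf = estimate_rf(w, stimulus, **rf_kwargs)
        maxima.append(float(np.max(np.abs(rf.F))))
    return float(np.quantile(maxima, quantile))
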