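"""Preprocessing of calcium traces and spike trains.

Raw ROI traces are detrended by subtracting a Savitzky-Golay-smoothed copy
(third order, 60 s window), snipped and averaged over stimulus repetitions,
and normalized (baseline of the first second subtracted, then divided by the
maximum absolute amplitude). Spike trains are reduced to trial-averaged
PSTHs. These per-cell response averages are what every downstream metric
consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "ResponseMatrix",
    "ResponseAverage",
    "detrend",
    "snippet_and_average",
    "normalize_average",
    "preferred_direction_average",
    "compute_psth",
]


@dataclass(frozen=True)
class Trace:
    """A single continuous activity trace sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class ResponseMatrix:
    """T x R matrix of aligned response snippets (time samples x repetitions)."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("response matrix must be T x R with R >= 1")
        if np.any(np.all(np.isnan(self.values), axis=0)):
            raise ValueError("response matrix has an all-NaN repetition")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_reps(self) -> int:
        return self.values.shape[1]

    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)


@dataclass(frozen=True)
class ResponseAverage:
    """A normalized repetition-mean response.

    ``baseline`` and ``scale`` record the normalization (value subtracted and
    divisor applied); ``degenerate`` flags traces whose amplitude was below
    numerical resolution, which are returned as zeros rather than errored so
    population pipelines can continue.
    """

    values: np.ndarray
    fs: float
    baseline: float = 0.0
    scale: float = 1.0
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


def detrend(trace: Trace, window_s: float = 60.0, polyorder: int = 3) -> Trace:
    """Remove slow drifts by subtracting a Savitzky-Golay-smoothed copy.

    The filter window is ``round(window_s * fs)`` samples, forced odd; the
    smoothed trace estimates signal components slower than the window, so the
    residual keeps fast light-evoked transients. The operation is linear in
    its input.
    """
    window = int(round(window_s * trace.fs))
    if window % 2 == 0:
        window += 1
    if window <= polyorder:
        raise ValueError("window too short for polynomial order")
    if len(trace.samples) <= window:
        raise ValueError(
            f"trace ({len(trace.samples)} samples) shorter than filter window "
            f"({window} samples); use a shorter window_s")
    smooth = savgol_filter(trace.samples, window, polyorder, mode="interp")
    return Trace(samples=trace.samples - smooth, fs=trace.fs, t0=trace.t0)


def snippet_and_average(trace: Trace, trigger_times: np.ndarray,
                        snippet_s: float) -> tuple[ResponseMatrix, np.ndarray]:
    """Align fixed-length snippets to stimulus triggers and average them.

    Triggers are aligned to the nearest sample (no sub-sample interpolation);
    triggers whose snippet would run past either end of the trace are dropped
    with a logged count.
    """
    trigger_times = np.asarray(trigger_times, dtype=float)
    n_snip = int(round(snippet_s * trace.fs))
    if n_snip < 1:
        raise ValueError("snippet shorter than one sample")
    starts = np.round((trigger_times - trace.t0) * trace.fs).astype(int)
    usable = [s for s in starts if 0 <= s and s + n_snip <= len(trace.samples)]
    n_dropped = len(starts) - len(usable)
    if n_dropped:
        logger.info("snippet_and_average: dropped %d/%d triggers outside trace",
                    n_dropped, len(starts))
    if not usable:
        raise ValueError("no trigger yields a snippet fully inside the trace")
    snippets = np.column_stack([trace.samples[s:s + n_snip] for s in usable])
    matrix = ResponseMatrix(values=snippets, fs=trace.fs)
    return matrix, matrix.mean()


def normalize_average(mean_trace: np.ndarray, fs: float,
                      baseline_s: float = 1.0,
                      eps: float = 1e-12) -> ResponseAverage:
    """Normalize a repetition-mean response.

    Subtracts the mean over the first ``baseline_s`` seconds, then divides by
    the maximum absolute amplitude so that max|r(t)| = 1. Flat traces
    (amplitude < ``eps`` after baseline subtraction) come back as zeros with
    the degenerate flag set.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    n_base = int(round(baseline_s * fs))
    if n_base < 1 or n_base > len(mean_trace):
        raise ValueError("trace shorter than the baseline window")
    baseline = float(np.mean(mean_trace[:n_base]))
    centered = mean_trace - baseline
    amp = float(np.max(np.abs(centered)))
    if amp < eps:
        return ResponseAverage(values=np.zeros_like(centered), fs=fs,
                               baseline=baseline, scale=1.0, degenerate=True)
    return ResponseAverage(values=centered / amp, fs=fs,
                           baseline=baseline, scale=amp)


def preferred_direction_average(
        bar_matrices_by_direction: dict[float, ResponseMatrix],
        baseline_s: float = 1.0) -> ResponseAverage:
    """Reduce 8 direction-wise bar responses to the preferred direction.

    The preferred direction maximizes the energy (sum of squares) of the
    across-repetition mean snippet; exact ties go to the lowest direction
    index. The selected direction's normalized average is returned with the
    direction recorded in ``meta``.
    """
    if len(bar_matrices_by_direction) != 8:
        raise ValueError("expected response matrices for 8 directions")
    directions = sorted(bar_matrices_by_direction)
    energies = []
    for d in directions:
        m = bar_matrices_by_direction[d].mean()
        energies.append(float(np.sum(m ** 2)))
    best = int(np.argmax(energies))  # argmax takes first max: lowest index
    d_best = directions[best]
    matrix = bar_matrices_by_direction[d_best]
    avg = normalize_average(matrix.mean(), matrix.fs, baseline_s=baseline_s)
    avg.meta["preferred_direction_deg"] = d_best
    avg.meta["direction_energies"] = dict(zip(directions, energies))
    return avg


def compute_psth(spike_times: np.ndarray, trigger_times: np.ndarray,
                 snippet_s: float, bin_s: float = 0.1) -> Trace:
    """Trial-averaged firing rate in fixed bins, in Hz.

    Rate per bin = spike count across trials / (n_triggers * bin_s).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    trigger_times = np.asarray(trigger_times, dtype=float)
    if trigger_times.size == 0:
        raise ValueError("at least one trigger is required")
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int(round(snippet_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for trig in trigger_times:
        rel = spike_times - trig
        rel = rel[(rel >= 0) & (rel < n_bins * bin_s)]
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(trigger_times) * bin_s)
    return Trace(samples=rate, fs=1.0 / bin_s)
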