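"""Spike-to-pseudo-calcium bridge and template-correlation type assignment.

MEA spike trains and calcium recordings live in different signal spaces. To
compare them, PSTHs are causally convolved with a decaying exponential
(unit-peak kernel, truncated at 5 tau) — a pseudo-calcium transform that
emulates a calcium-indicator response to spiking. The decay constant is
chosen to maximize the median best-template correlation against reference
calcium templates, and cluster identities are assigned by greedy one-to-one
correlation matching in two rounds (a correlation floor applies in round 1
only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PseudoCalciumConfig",
    "TypeAssignment",
    "pseudo_calcium",
    "optimize_decay",
    "assign_types",
    "default_tau_grid",
]


@dataclass(frozen=True)
class PseudoCalciumConfig:
    """Decay constant and kernel truncation of the transform."""

    tau_s: float = 0.8
    kernel_length_tau: float = 5.0
    target_rate_hz: float = 10.0

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class TypeAssignment:
    """One cluster's template assignment."""

    cluster: int
    label: str | None
    correlation: float
    round: int              # 1 or 2; 0 if unassigned
    unassigned: bool = False


def default_tau_grid() -> np.ndarray:
    """Decay-constant search grid, 0.1-3.0 s in 0.05 s steps."""
    return np.arange(0.1, 3.0 + 1e-9, 0.05)


def pseudo_calcium(psth: np.ndarray, tau: float, fs: float = 10.0,
                   kernel_length_tau: float = 5.0) -> np.ndarray:
    """Causal convolution of a non-negative PSTH with exp(-t/tau).

    The kernel has unit peak (not unit area: downstream correlations are
    scale-invariant and peak normalization keeps the trace in rate-like
    units) and is truncated at ``kernel_length_tau * tau``. Output has the
    input's length; the transform is linear and preserves non-negativity
    and pointwise ordering.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    psth = np.asarray(psth, dtype=float)
    t = np.arange(0, kernel_length_tau * tau, 1.0 / fs)
    kernel = np.exp(-t / tau)
    return np.convolve(psth, kernel)[: len(psth)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def optimize_decay(psths: np.ndarray, templates: dict, tau_grid=None,
                   fs: float = 10.0) -> tuple[float, dict]:
    """Decay constant maximizing the median best-template correlation.

    ``psths`` is (n_cells, T) and ``templates`` maps label -> trace on the
    same time grid. Returns (tau*, correlation table) where the table maps
    tau -> (median best correlation, per-psth best correlations).
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, float)
    if tau_grid.size == 0:
        raise ValueError("empty tau grid")
    psths = np.atleast_2d(np.asarray(psths, float))
    labels = list(templates)
    table = {}
    best_tau, best_med = None, -np.inf
    for tau in tau_grid:
        transformed = [pseudo_calcium(p, tau, fs) for p in psths]
        bests = [max(_pearson(tr, templates[lb]) for lb in labels)
                 for tr in transformed]
        med = float(np.median(bests))
        table[float(tau)] = (med, bests)
        if med > best_med:
            best_med, best_tau = med, float(tau)
    return best_tau, table


def assign_types(transformed_means: dict, templates: dict,
                 round1_min_corr: float = 0.6) -> list:
    """Greedy one-to-one cluster-to-template assignment in two rounds.

    Round 1 assigns cluster-template pairs in descending correlation among
    pairs at or above ``round1_min_corr``, consuming templates; round 2
    repeats over the leftovers with no floor. Clusters left without a
    template are flagged unassigned.
    """
    if not templates:
        raise ValueError("no templates to assign against")
    clusters = list(transformed_means)
    labels = list(templates)
    corr = {(c, lb): _pearson(np.asarray(transformed_means[c], float),
                              np.asarray(templates[lb], float))
            for c in clusters for lb in labels}

    assigned: dict = {}
    free_clusters = set(clusters)
    free_labels = set(labels)
    for round_no, floor in ((1, round1_min_corr), (2, -np.inf)):
        pairs = sorted(
            ((corr[(c, lb)], c, lb) for c in free_clusters
             for lb in free_labels if corr[(c, lb)] >= floor),
            reverse=True)
        for r, c, lb in pairs:
            if c in free_clusters and lb in free_labels:
                assigned[c] = TypeAssignment(cluster=c, label=lb,
                                             correlation=r, round=round_no)
                free_clusters.discard(c)
                free_labels.discard(lb)
    out = []
    for c in clusters:
        if c in assigned:
            out.append(assigned[c])
        else:
            best = max(corr[(c, lb)] for lb in labels)
            out.append(TypeAssignment(cluster=c, label=None, correlation=best,
                                      round=0, unassigned=True))
    return out
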