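"""Response-quality index, spike-train QC, and the inclusion gate.

The quality index (QI) of a T x R response matrix C is

    QI = Var_t[ <C>_r ] / < Var_t[C] >_r

the temporal variance of the repetition mean over the mean per-repetition
temporal variance. Perfectly repeatable responses give QI = 1; for pure
i.i.d. noise the expectation is ~1/R. Cells are kept iff they pass a QI
threshold for the moving bar (QI > 0.6) OR the chirp (QI > 0.45) in BOTH
recordings of the sequential protocol, carry a classifier confidence score
> 0.25, and are labeled with an RGC index (1-32); displaced-amacrine labels
(33-46) are rejected. Spike trains are screened by their fraction of
refractory-period (2 ms) violations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ResponseMatrix

__all__ = [
    "QualityReport",
    "quality_index",
    "refractory_violation_rate",
    "apply_inclusion_criteria",
    "RGC_INDEX_RANGE",
    "DISPLACED_AC_RANGE",
]

RGC_INDEX_RANGE = (1, 32)
DISPLACED_AC_RANGE = (33, 46)


@dataclass(frozen=True)
class QualityReport:
    """Per-cell quality metrics and the inclusion decision with reasons."""

    cell_id: str
    qi_chirp: tuple[float | None, float | None] = (None, None)
    qi_bar: tuple[float | None, float | None] = (None, None)
    refractory_violation_fraction: float | None = None
    classifier_confidence: float | None = None
    type_index: int | None = None
    included: bool = False
    reasons: tuple[str, ...] = ()


def quality_index(C) -> float:
    """Repeatability of a T x R response matrix; scalar in (0, 1].

    Invariant to affine transforms a*C + b (a != 0). Population variance
    (divide by N) is used in both numerator and denominator.
    """
    values = C.values if isinstance(C, ResponseMatrix) else np.asarray(C, float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a T x R matrix with T >= 2 and R >= 2")
    denom = float(np.mean(np.var(values, axis=0)))
    if denom == 0.0:
        raise ValueError("no temporal variance in any repetition")
    num = float(np.var(np.mean(values, axis=1)))
    return num / denom


def refractory_violation_rate(spike_times: np.ndarray,
                              refractory_s: float = 0.002) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if len(spike_times) < 2:
        warnings.warn("fewer than 2 spikes; violation rate set to 0",
                      stacklevel=2)
        return 0.0
    isis = np.diff(spike_times)
    return float(np.mean(isis < refractory_s))


def apply_inclusion_criteria(cells: list[dict], qi_bar_min: float = 0.6,
                             qi_chirp_min: float = 0.45,
                             conf_min: float = 0.25,
                             require_both_conditions: bool = True
                             ) -> tuple[list[dict], list[QualityReport]]:
    """Gate a population of cells on quality, confidence, and type index.

    Each cell dict provides ``cell_id``, per-recording QI values
    ``qi_bar`` / ``qi_chirp`` (each a 2-sequence, None for missing),
    ``confidence``, and ``type_index``. A cell is kept iff
    (QI_bar > qi_bar_min OR QI_chirp > qi_chirp_min) holds in both
    recordings (strict inequalities), confidence > conf_min, and the type
    index is an RGC index (1-32). Returns the surviving cells and a
    QualityReport per cell.
    """
    kept, reports = [], []
    for cell in cells:
        reasons = []
        qi_bar = tuple(cell.get("qi_bar", (None, None)))
        qi_chirp = tuple(cell.get("qi_chirp", (None, None)))
        n_rec = 2 if require_both_conditions else 1
        qi_ok = True
        for rec in range(n_rec):
            qb, qc = qi_bar[rec], qi_chirp[rec]
            if qb is None and qc is None:
                reasons.append(f"missing QI in recording {rec + 1}")
                qi_ok = False
                continue
            passed = ((qb is not None and qb > qi_bar_min)
                      or (qc is not None and qc > qi_chirp_min))
            if not passed:
                reasons.append(f"QI below threshold in recording {rec + 1}")
                qi_ok = False
        conf = cell.get("confidence")
        conf_ok = conf is not None and conf > conf_min
        if not conf_ok:
            reasons.append("confidence at or below threshold")
        idx = cell.get("type_index")
        type_ok = idx is not None and RGC_INDEX_RANGE[0] <= idx <= RGC_INDEX_RANGE[1]
        if not type_ok:
            if idx is not None and DISPLACED_AC_RANGE[0] <= idx <= DISPLACED_AC_RANGE[1]:
                reasons.append("displaced amacrine cell label")
            else:
                reasons.append("not an RGC type index")
        included = qi_ok and conf_ok and type_ok
        reports.append(QualityReport(
            cell_id=cell.get("cell_id", "?"), qi_chirp=qi_chirp,
            qi_bar=qi_bar, classifier_confidence=conf, type_index=idx,
            refractory_violation_fraction=cell.get("refractory_violation_fraction"),
            included=included, reasons=tuple(reasons)))
        if included:
            kept.append(cell)
    return kept, reports
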