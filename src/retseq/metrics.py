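"""Suppression/On-Off metrics and the adaptation-vs-drug disentangling.

The sequential-recording design records every cell twice. The trace
difference Delta(t) = rec2(t) - rec1(t) of a control/control pair measures
*adaptational* drift; the same difference of a control/drug pair mixes
adaptation with the drug effect. Assuming the two components add linearly,
the drug-induced part of a per-type, per-feature response change is
estimated as mean(Delta_drug) - mean(Delta_ctrl), and its significance by an
independent two-sided (Welch) t-test between the per-cell feature-delta
distributions with Bonferroni control across all type x feature tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import (
    ResponseAverage,
    normalize_average,
    preferred_direction_average,
)
from .stimulus import FeatureWindows

__all__ = [
    "SuppressionResult",
    "PairedCellRecord",
    "PairedDelta",
    "EffectMatrix",
    "suppression_index",
    "on_off_index",
    "trace_difference",
    "feature_differences",
    "paired_feature_deltas",
    "records_from_experiment",
    "feature_delta_table",
    "disentangle_effects",
]


@dataclass(frozen=True)
class SuppressionResult:
    """Suppression index with its positive/negative areas under the curve."""

    si: float           # in [0, 1], or NaN if the trace is all zero
    auc_neg: float
    auc_pos: float
    degenerate: bool = False


@dataclass
class PairedCellRecord:
    """One cell's matched rec1/rec2 normalized averages plus type metadata."""

    cell_id: str
    type_label: str
    chirp: tuple[ResponseAverage, ResponseAverage]
    bar: tuple[ResponseAverage, ResponseAverage]
    condition: str = "ctrl-ctrl"
    meta: dict = field(default_factory=dict)


@dataclass
class PairedDelta:
    """Per-cell trace differences (rec2 - rec1) and their summaries."""

    cell_id: str
    type_label: str
    chirp_delta: np.ndarray
    bar_delta: np.ndarray
    fs_chirp: float
    fs_bar: float
    mean_delta: float
    feature_deltas: np.ndarray | None = None    # 8 canonical features
    condition: str = "ctrl-ctrl"


@dataclass
class EffectMatrix:
    """Per-type x per-feature disentangling result.

    ``table`` is tidy: one row per (type, feature) with the mean control
    delta, mean drug delta, their difference (the drug-effect estimate),
    Welch-test p-value, the one-sample adaptation p-value, and significance
    flags at the Bonferroni-corrected alpha. ``categories`` assigns each type
    to stable / adaptational / drug-affected.
    """

    table: pd.DataFrame
    categories: dict
    alpha_family: float
    alpha_per_test: float
    n_types_tested: int


def suppression_index(trace: np.ndarray | ResponseAverage,
                      dt: float = 1.0) -> SuppressionResult:
    """Fraction of a normalized response's area lying below baseline.

    AUC_neg integrates the trace clipped to values < 0 (absolute value),
    AUC_pos the positive part (rectangular rule x dt);
    SI = AUC_neg / (AUC_neg + AUC_pos). An all-zero trace yields NaN with
    the degenerate flag.
    """
    if isinstance(trace, ResponseAverage):
        dt = 1.0 / trace.fs
        trace = trace.values
    trace = np.asarray(trace, dtype=float)
    auc_neg = float(np.sum(np.abs(np.minimum(trace, 0.0))) * dt)
    auc_pos = float(np.sum(np.maximum(trace, 0.0)) * dt)
    total = auc_neg + auc_pos
    if total == 0.0:
        return SuppressionResult(si=float("nan"), auc_neg=0.0, auc_pos=0.0,
                                 degenerate=True)
    return SuppressionResult(si=auc_neg / total, auc_neg=auc_neg,
                             auc_pos=auc_pos)


def on_off_index(bar_trace: np.ndarray | ResponseAverage, split_s: float,
                 fs: float | None = None) -> float:
    """On-Off index of a moving-bar response.

    The trace is split at ``split_s`` into its On (leading-edge) and Off
    (trailing-edge) components; for each, the discrete time differences are
    clipped to [0, 1] and averaged (r_on, r_off), measuring how much rising
    response each component contains. OOI = (r_on - r_off)/(r_on + r_off),
    0 if both are 0; always in [-1, 1].
    """
    if isinstance(bar_trace, ResponseAverage):
        fs = bar_trace.fs
        bar_trace = bar_trace.values
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    bar_trace = np.asarray(bar_trace, dtype=float)
    split = int(round(split_s * fs))
    if split <= 1 or split >= len(bar_trace) - 1:
        raise ValueError("split time outside the trace")
    r_on = float(np.mean(np.clip(np.diff(bar_trace[:split]), 0.0, 1.0)))
    r_off = float(np.mean(np.clip(np.diff(bar_trace[split:]), 0.0, 1.0)))
    if r_on + r_off == 0.0:
        return 0.0
    return (r_on - r_off) / (r_on + r_off)


def trace_difference(rec1: ResponseAverage,
                     rec2: ResponseAverage) -> np.ndarray:
    """Delta(t) = rec2(t) - rec1(t) on identical time grids (no resampling)."""
    if len(rec1.values) != len(rec2.values) or rec1.fs != rec2.fs:
        raise ValueError("rec1/rec2 are not on identical time grids")
    return rec2.values - rec1.values


def feature_differences(delta: np.ndarray, windows, fs: float) -> np.ndarray:
    """Per-window time-mean of a delta trace.

    ``windows`` is a sequence of (name, start_s, end_s). Using the mean (not
    the sum) makes windows of different lengths comparable.
    """
    delta = np.asarray(delta, dtype=float)
    t = np.arange(len(delta)) / fs
    out = []
    for name, start, end in windows:
        mask = (t >= start) & (t < end)
        if not np.any(mask) or end > (len(delta) + 0.5) / fs:
            raise ValueError(f"window '{name}' lies outside the trace")
        out.append(float(np.mean(delta[mask])))
    return np.asarray(out)


def paired_feature_deltas(record: PairedCellRecord,
                          windows: FeatureWindows) -> PairedDelta:
    """All eight canonical feature deltas (6 chirp + 2 bar) for one cell."""
    chirp_delta = trace_difference(*record.chirp)
    bar_delta = trace_difference(*record.bar)
    fs_c = record.chirp[0].fs
    fs_b = record.bar[0].fs
    feats = np.concatenate([
        feature_differences(chirp_delta, windows.chirp, fs_c),
        feature_differences(bar_delta, windows.bar, fs_b),
    ])
    mean_delta = float(np.mean(np.concatenate([chirp_delta, bar_delta])))
    return PairedDelta(cell_id=record.cell_id, type_label=record.type_label,
                       chirp_delta=chirp_delta, bar_delta=bar_delta,
                       fs_chirp=fs_c, fs_bar=fs_b, mean_delta=mean_delta,
                       feature_deltas=feats, condition=record.condition)


def records_from_experiment(exp, baseline_s: float = 1.0) -> list:
    """Normalized paired averages for every cell of a simulated experiment.

    The preferred bar direction is selected on rec1 and reused for rec2 so
    the pair stays matched.
    """
    records = []
    for cell in exp.cells:
        c1, c2 = cell.chirp
        chirp1 = normalize_average(c1.mean(), c1.fs, baseline_s)
        chirp2 = normalize_average(c2.mean(), c2.fs, baseline_s)
        bar1 = preferred_direction_average(cell.bar[0], baseline_s)
        pref = bar1.meta["preferred_direction_deg"]
        m2 = cell.bar[1][pref]
        bar2 = normalize_average(m2.mean(), m2.fs, baseline_s)
        bar2.meta["preferred_direction_deg"] = pref
        records.append(PairedCellRecord(
            cell_id=cell.cell_id, type_label=cell.type_label,
            chirp=(chirp1, chirp2), bar=(bar1, bar2),
            condition=exp.protocol))
    return records


def feature_delta_table(exp) -> dict:
    """type_label -> (n_cells x 8) array of per-cell feature deltas."""
    records = records_from_experiment(exp)
    out: dict[str, list] = {}
    for rec in records:
        delta = paired_feature_deltas(rec, exp.windows)
        out.setdefault(rec.type_label, []).append(delta.feature_deltas)
    return {label: np.vstack(rows) for label, rows in out.items()}


def disentangle_effects(ctrl_deltas: dict, drug_deltas: dict,
                        alpha_family: float = 0.05, min_cells: int = 10,
                        feature_names: tuple = FeatureWindows.CHIRP_NAMES
                        + FeatureWindows.BAR_NAMES,
                        equal_var: bool = False) -> EffectMatrix:
    """Separate drug-induced from adaptational per-feature response changes.

    Inputs map type_label -> (n_cells x 8) per-cell feature-delta arrays from
    the control/control (ctrl) and control/drug (drug) datasets. Only types
    with more than ``min_cells`` cells in each dataset are tested. For every
    type x feature, a two-sided independent t-test (Welch by default)
    compares the drug deltas against the control deltas; the per-comparison
    alpha is alpha_family / (n_types_tested * n_features). A feature is
    *drug-affected* if that test is significant; *adaptational* if the
    control deltas differ from zero (one-sample t-test, parallel family of
    the same size) while the drug test is not significant. A type is
    drug-affected if any feature is, else adaptational if any feature is,
    else stable.
    """
    common = [t for t in ctrl_deltas
              if t in drug_deltas
              and ctrl_deltas[t].shape[0] > min_cells
              and drug_deltas[t].shape[0] > min_cells]
    if not common:
        raise ValueError(f"no type has more than {min_cells} paired cells "
                         "in both datasets")
    n_features = len(feature_names)
    alpha = alpha_family / (len(common) * n_features)

    rows = []
    categories = {}
    for t in common:
        c, d = ctrl_deltas[t], drug_deltas[t]
        any_drug, any_adapt = False, False
        for j, feat in enumerate(feature_names):
            tt = sps.ttest_ind(d[:, j], c[:, j], equal_var=equal_var)
            one = sps.ttest_1samp(c[:, j], 0.0)
            drug_sig = bool(tt.pvalue < alpha)
            adapt_sig = bool(one.pvalue < alpha) and not drug_sig
            any_drug |= drug_sig
            any_adapt |= adapt_sig
            rows.append({
                "type": t, "feature": feat,
                "mean_dctrl": float(np.mean(c[:, j])),
                "mean_ddrug": float(np.mean(d[:, j])),
                "diff": float(np.mean(d[:, j]) - np.mean(c[:, j])),
                "p": float(tt.pvalue), "p_adapt": float(one.pvalue),
                "significant": drug_sig, "adaptational": adapt_sig,
            })
        categories[t] = ("drug-affected" if any_drug
                         else "adaptational" if any_adapt else "stable")
    table = pd.DataFrame(rows)
    table["category"] = table["type"].map(categories)
    return EffectMatrix(table=table, categories=categories,
                        alpha_family=alpha_family, alpha_per_test=alpha,
                        n_types_tested=len(common))
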