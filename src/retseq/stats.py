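"""The testing ladder used throughout the analyses, with full provenance.

Differences between traces or metrics are tested with a normality-gated
procedure: a Shapiro-Wilk test at 0.05 routes the data either to a t-test
(one-sample against zero, paired, or independent two-sided) or to the
matching non-parametric test (Wilcoxon signed-rank / Mann-Whitney U). The
gate only ever switches the test family — never the sidedness or the
comparison target. Multi-condition comparisons use a Kruskal-Wallis (or
repeated-measures ANOVA) omnibus followed by Dunnett-style many-to-one
comparisons against the control condition. Multiplicity is controlled by
Bonferroni division of the family alpha.

The statistical machinery itself comes from scipy/statsmodels; this module
owns the gating, pairing, and multiplicity policy and logs which test
actually ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "gated_difference_test",
    "multi_condition_test",
    "bonferroni_threshold",
    "results_to_frame",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test, with gate provenance."""

    test: str
    statistic: float
    p: float
    n: int
    alpha: float
    significant: bool
    normality_p: float | None = None
    comparison: str = ""

    def __post_init__(self):
        if self.significant != bool(self.p < self.alpha):
            raise ValueError("significance flag inconsistent with p and alpha")


def _is_normal(x: np.ndarray, gate_alpha: float = 0.05) -> tuple[bool, float]:
    stat = sps.shapiro(x)
    return bool(stat.pvalue >= gate_alpha), float(stat.pvalue)


def gated_difference_test(values, values2=None, mode: str = "one-sample",
                          alpha: float = 0.05,
                          gate_alpha: float = 0.05) -> TestResult:
    """Normality-gated difference test.

    ``mode``: "one-sample" tests ``values`` against a population mean of
    zero (t-test or Wilcoxon signed-rank); "paired" tests element-wise
    differences of ``values``/``values2`` the same way; "independent"
    compares the two samples (t-test or Mann-Whitney U). All tests are
    two-sided. The gate is a Shapiro-Wilk test on the tested sample (the
    differences, for paired data).
    """
    x = np.asarray(values, dtype=float)
    if mode in ("one-sample", "paired"):
        if mode == "paired":
            y = np.asarray(values2, dtype=float)
            if len(y) != len(x):
                raise ValueError("paired samples must have equal length")
            x = x - y
        if len(x) < 3:
            raise ValueError("need n >= 3")
        normal, gate_p = _is_normal(x)
        if normal:
            res = sps.ttest_1samp(x, 0.0)
            name = "one-sample t-test"
        else:
            if np.all(x == 0):
                return TestResult(test="wilcoxon signed-rank", statistic=0.0,
                                  p=1.0, n=len(x), alpha=alpha,
                                  significant=False, normality_p=gate_p,
                                  comparison="mean vs 0")
            res = sps.wilcoxon(x)
            name = "wilcoxon signed-rank"
        return TestResult(test=name, statistic=float(res.statistic),
                          p=float(res.pvalue), n=len(x), alpha=alpha,
                          significant=bool(res.pvalue < alpha),
                          normality_p=gate_p, comparison="mean vs 0")
    if mode == "independent":
        y = np.asarray(values2, dtype=float)
        if len(x) < 3 or len(y) < 3:
            raise ValueError("need n >= 3 in both samples")
        norm_x, p_x = _is_normal(x)
        norm_y, p_y = _is_normal(y)
        gate_p = min(p_x, p_y)
        if norm_x and norm_y:
            res = sps.ttest_ind(x, y)
            name = "independent t-test"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            name = "mann-whitney u"
        return TestResult(test=name, statistic=float(res.statistic),
                          p=float(res.pvalue), n=len(x) + len(y), alpha=alpha,
                          significant=bool(res.pvalue < alpha),
                          normality_p=gate_p, comparison="group difference")
    raise ValueError(f"unknown mode '{mode}'")


def multi_condition_test(groups: dict, control: str | None = None,
                         alpha: float = 0.05, repeated: bool = False,
                         bonferroni_posthoc: bool = False) -> list:
    """Omnibus test plus Dunnett many-to-one comparisons vs a control.

    ``groups`` maps condition name -> 1D samples. Independent design:
    Kruskal-Wallis omnibus followed by Dunnett's test against ``control``
    (the first key by default). Repeated design (``repeated=True``):
    one-way repeated-measures ANOVA (equal-length condition vectors
    required) with the same post hoc. With ``bonferroni_posthoc`` the
    post hoc p-values are additionally Bonferroni-scaled.
    """
    names = list(groups)
    if control is None:
        control = names[0]
    if control not in groups:
        raise ValueError(f"control condition '{control}' not in groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    others = [k for k in names if k != control]
    results = []
    if repeated:
        lengths = {len(v) for v in samples.values()}
        if len(lengths) != 1:
            raise ValueError("repeated-measures design needs equal pairing "
                             "across conditions")
        if len(samples) < 2:
            raise ValueError("need >= 2 repeated conditions")
        from statsmodels.stats.anova import AnovaRM
        n = lengths.pop()
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), len(names)),
            "condition": np.repeat(names, n),
            "value": np.concatenate([samples[k] for k in names]),
        })
        fit = AnovaRM(long, depvar="value", subject="subject",
                      within=["condition"]).fit()
        row = fit.anova_table.iloc[0]
        omni_stat, omni_p = float(row["F Value"]), float(row["Pr > F"])
        omni_name = "repeated-measures ANOVA"
    else:
        if len(samples) < 3:
            raise ValueError("need >= 3 groups for the omnibus test")
        res = sps.kruskal(*[samples[k] for k in names])
        omni_stat, omni_p = float(res.statistic), float(res.pvalue)
        omni_name = "kruskal-wallis"
    results.append(TestResult(test=omni_name, statistic=omni_stat, p=omni_p,
                              n=sum(len(v) for v in samples.values()),
                              alpha=alpha, significant=bool(omni_p < alpha),
                              comparison="omnibus"))
    # quasi-Monte-Carlo integration inside Dunnett's test is seeded so the
    # procedure is deterministic given the data
    dunnett = sps.dunnett(*[samples[k] for k in others],
                          control=samples[control],
                          rng=np.random.default_rng(0))
    m = len(others)
    for k, stat, p in zip(others, np.atleast_1d(dunnett.statistic),
                          np.atleast_1d(dunnett.pvalue)):
        p_adj = min(1.0, float(p) * m) if bonferroni_posthoc else float(p)
        results.append(TestResult(
            test="dunnett" + (" + bonferroni" if bonferroni_posthoc else ""),
            statistic=float(stat), p=p_adj,
            n=len(samples[k]) + len(samples[control]), alpha=alpha,
            significant=bool(p_adj < alpha),
            comparison=f"{k} vs {control}"))
    return results


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Per-test alpha under Bonferroni control of ``m`` tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha_family / m


def results_to_frame(results: list) -> pd.DataFrame:
    """Tidy provenance table of a list of TestResult objects."""
    return pd.DataFrame([{
        "test": r.test, "comparison": r.comparison, "statistic": r.statistic,
        "p": r.p, "n": r.n, "alpha": r.alpha, "significant": r.significant,
        "normality_p": r.normality_p,
    } for r in results])
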