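"""The statistical testing ladder used throughout the analyses.

Shows the normality-gated difference test (t-test vs Wilcoxon/Mann-Whitney),
the Kruskal-Wallis + Dunnett multi-condition comparison, and the Bonferroni
threshold of the feature-wise disentangling.
"""

import numpy as np

from retseq.stats import (
    bonferroni_threshold,
    gated_difference_test,
    multi_condition_test,
    results_to_frame,
)

rng = np.random.default_rng(0)

res = gated_difference_test(rng.normal(0.5, 1.0, 40))
print(f"normal data routed to: {res.test} (gate p = {res.normality_p:.2f}), "
      f"p = {res.p:.1e}")
res = gated_difference_test(rng.standard_cauchy(40))
print(f"heavy-tailed data routed to: {res.test} "
      f"(gate p = {res.normality_p:.1e})")

groups = {"ctrl1": rng.normal(0.6, 0.1, 30),
          "ctrl2": rng.normal(0.58, 0.1, 30),
          "drug": rng.normal(0.35, 0.1, 30)}
results = multi_condition_test(groups, control="ctrl1")
print(results_to_frame(results).to_string(index=False))
# The omnibus test asks whether any condition differs; Dunnett's test then
# compares each condition against the control.

alpha = bonferroni_threshold(0.05, 21 * 8)
print(f"per-comparison alpha for 21 types x 8 features: {alpha:.2e} "
      "(printed as p < 0.0003)")
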