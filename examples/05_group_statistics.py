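"""Full synthetic cohort analysis at the study's group sizes (4/7/4/9).

Runs generation -> preprocessing -> FFT metrics -> semblance -> rank-sum
group statistics and prints the cohort summary: mean +/- SE per group for
the pooled period, the regularity index and each semblance pair, plus the
pairwise Wilcoxon rank-sum contrasts for the period.
"""

import tempfile
from pathlib import Path

import pandas as pd

from nirsosc import RunConfig, run_pipeline

pd.set_option("display.width", 120)

with tempfile.TemporaryDirectory() as tmp:
    result = run_pipeline(RunConfig(mode="synthetic", output_dir=Path(tmp), seed=1))

    summary = result.group_summary
    for metric in ("period_min", "regularity_pct", "HHb-oxCCO", "HbDiff-oxCCO"):
        print(f"--- {metric} ---")
        sub = summary[summary["metric"] == metric]
        for _, row in sub.iterrows():
            print(f"  {row['group']:>10s} (n={row['n']}): {row['mean']:7.3f} +/- {row['se']:.3f}")

    print("--- pairwise rank-sum tests, period_min ---")
    tests = result.pairwise[result.pairwise["metric"] == "period_min"]
    for _, row in tests.iterrows():
        print(
            f"  {row['group_a']:>10s} vs {row['group_b']:<10s} "
            f"p={row['pvalue']:.4f} {row['significance']}"
        )

# Periods separate young controls (~8 min) from the slower aged/knockout
# groups (~14-16 min); the young-vs-old C57 contrast is significant by the
# exact rank-sum test.  HHb tracks oxCCO (semblance ~ +1) while HbDiff is
# antiphase (~ -1).  P-values are uncorrected, as flagged in the manifest.
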