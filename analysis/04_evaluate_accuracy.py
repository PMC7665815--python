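#!/usr/bin/env python
"""Score every categorization rule against the HCC reference standard.

Runs the full pipeline: accuracy table (sensitivity/specificity/PPV/NPV/
accuracy with exact 95% CIs and exact McNemar p-values against the
baseline LR-5 rule), AUC table with paired DeLong comparisons, and a JSON
sidecar with all counts at full precision.
"""

import argparse
import sys
from pathlib import Path

from lirads_dta import RunConfig, run_pipeline
from lirads_dta.pipeline import fmt_p, fmt_pct


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort.csv", type=Path)
    parser.add_argument("--out-dir", default="results", type=Path)
    args = parser.parse_args(argv)

    config = RunConfig(input_path=str(args.cohort), out_dir=str(args.out_dir))
    result = run_pipeline(config)

    print(f"{'categorization':<50} {'sens':>6} {'spec':>6} {'acc':>6} {'AUC':>6} {'p(sens)':>8}")
    for row in result.rows:
        rep = row.report
        print(
            f"{row.variant.value:<50} {fmt_pct(rep.sensitivity.value):>6} "
            f"{fmt_pct(rep.specificity.value):>6} {fmt_pct(rep.accuracy.value):>6} "
            f"{rep.auc:>6.3f} {fmt_p(row.p_sens_mcnemar):>8}"
        )
    print(f"tables written under {args.out_dir}/ (metrics.tsv, auc.tsv, report.json)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
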