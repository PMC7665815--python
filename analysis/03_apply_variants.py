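#!/usr/bin/env python
"""Apply the six category-adjustment conditions and audit every move.

Each condition is applied independently to the baseline categorization;
adjusted assignments and a reclassification audit (who moved, from where
to where, and why) are written per condition.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from lirads_dta import (
    ADJUSTMENT_VARIANTS,
    apply_variant,
    read_observations,
    write_assignments,
)
from lirads_dta.observations import read_assignments


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort.csv", type=Path)
    parser.add_argument(
        "--baseline", default="results/assignments_baseline.csv", type=Path
    )
    parser.add_argument("--out-dir", default="results", type=Path)
    args = parser.parse_args(argv)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_observations(args.cohort)
    baseline = read_assignments(args.baseline)

    for vid in ADJUSTMENT_VARIANTS:
        adjusted, audit = apply_variant(cohort, baseline, vid)
        write_assignments(adjusted, args.out_dir / f"assignments_{vid.value}.csv")
        rows = [
            {
                "observation_id": m.observation_id,
                "category_before": m.category_before.value,
                "category_after": m.category_after.value,
                "reason": m.reason,
            }
            for m in audit.moves
        ]
        pd.DataFrame(
            rows, columns=["observation_id", "category_before", "category_after", "reason"]
        ).to_csv(args.out_dir / f"audit_{vid.value}.tsv", sep="\t", index=False)
        transitions = ", ".join(
            f"{a.value}->{b.value}: {n}" for (a, b), n in sorted(
                audit.counts_by_transition.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        )
        print(f"{vid.value}: {len(audit.moves)} reclassification(s) ({transitions or 'none'})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
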