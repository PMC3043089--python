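"""Docking-angle recovery: measured theta against the planted angle.

Runs the full geometric chain (contacts -> charges -> complementary
matching -> groove-plane ellipse -> theta) on all 50 cohort complexes and
compares with the generator's theta_true, covering the full observed
angular range including obtuse dockings (>90 degrees).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, main_cohort, measure_theta


def main():
    pairs, _ = main_cohort()
    rows = []
    for st, ct in pairs:
        theta = measure_theta(st)
        rows.append(
            {
                "complex_id": st.id,
                "theta_true": round(ct.theta_true, 3),
                "theta_measured": round(theta, 3),
                "abs_error": round(abs(theta - ct.theta_true), 3),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "docking_angles.tsv", sep="\t", index=False)
    print(
        f"theta recovery over {len(df)} complexes "
        f"(true range {df.theta_true.min():.0f}-{df.theta_true.max():.0f} deg): "
        f"mean |error| {df.abs_error.mean():.2f} deg, max {df.abs_error.max():.2f} deg"
    )
    obtuse = df[df.theta_true > 90]
    print(
        f"{len(obtuse)} obtuse (>90 deg) dockings recovered without folding; "
        f"their mean |error| {obtuse.abs_error.mean():.2f} deg"
    )


if __name__ == "__main__":
    main()
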