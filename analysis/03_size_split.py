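#!/usr/bin/env python
"""Median size split: does the fraction-circularity coupling depend on size?

Builds a cohort in which small mitochondria carry a strong negative
coupling (r = -0.7) while large ones carry none, splits the measurement
table at the median 2D area, and correlates within each half.  The
construction emulates the hypothesis that membrane-area-driven shaping
dominates in small mitochondria while other factors take over in large
ones.

Writes results/size_split.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from corset.pipeline import measure_cohort, size_split_analysis
from corset.synth import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    small, _ = generate_cohort(CohortSpec(
        n=50, axis_length_dist=(200.0, 700.0), radius_dist=(110.0, 150.0),
        coupling_r=-0.7, seed=seed,
    ))
    large, _ = generate_cohort(CohortSpec(
        n=50, axis_length_dist=(1200.0, 2600.0), radius_dist=(180.0, 240.0),
        coupling_r=0.0, seed=seed + 50_000,
    ))
    table = measure_cohort(small + large)
    sp = size_split_analysis(table)
    df = pd.DataFrame([
        {"group": "small", "n": sp["small"].n, "r": sp["small"].pearson_r,
         "p": sp["small"].p_value},
        {"group": "large", "n": sp["large"].n, "r": sp["large"].pearson_r,
         "p": sp["large"].p_value},
    ])
    df.to_csv(OUT / "size_split.csv", index=False)
    print(f"median area threshold: {sp['threshold']:.0f} nm^2")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        "\nThe negative coupling survives only below the median: the small "
        "group is significantly negative, the large group is not."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
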