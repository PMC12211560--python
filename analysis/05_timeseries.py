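#!/usr/bin/env python
"""Time-resolved cristae retraction under conserved inner-membrane length.

A single stadium-shaped mitochondrion (500 nm straight section, 125 nm cap
radius) retracts its cristae linearly over 10 frames while the total 2D
IMM length P + 2Σl is conserved, so the unfolding cristae lengthen the
boundary and the outline rounds and swells toward a circle.

Writes results/timeseries.csv and a time-profile figure.
"""

import sys
from pathlib import Path

from corset.pipeline import timeseries_profile
from corset.plots import time_profile
from corset.synth import generate_timeseries

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    frames = generate_timeseries(n_frames=10, conserve_imm_length=True,
                                 straight_length=500.0, radius=125.0,
                                 seed=seed)
    prof = timeseries_profile(frames)
    prof.to_csv(OUT / "timeseries.csv", index=False)
    time_profile(prof, path=OUT / "timeseries.svg")
    print(prof.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        f"\n[cristae/IMM]% falls monotonically (Kendall tau = "
        f"{prof.attrs['kendall_tau_fraction_vs_time']:.0f}) while "
        f"circularity rises from {prof['circularity'].iloc[0]:.3f} to "
        f"{prof['circularity'].iloc[-1]:.3f}."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
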