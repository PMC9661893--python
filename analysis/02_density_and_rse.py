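"""Standardize trap densities and summarize how variable seed rain is.

Computes seed density per trap record (seeds m^-2 per 49-day standard
period) and the relative standard error (RSE) of density at each trap
distance, pooled across sites and patches — the study's first-order
description of how dispersal becomes patchier away from the source.
Writes results/rse_by_distance.csv.
"""

import sys
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"

from seedrain.io import read_table  # noqa: E402
from seedrain.preprocess import (  # noqa: E402
    rse_by_distance,
    rse_table,
    seed_density,
    standardize_days,
)


def main() -> None:
    traps = read_table(STUDY / "traps.csv", "traps")
    dens, dist = [], []
    for o in traps:
        if o.trap_kind != "vertical":
            continue
        dens.append(seed_density(o.n_seeds, o.area, standardize_days(o.days_deployed)))
        dist.append(o.dist_trap)
    rows = rse_by_distance(dens, dist)
    df = rse_table(rows)
    df.to_csv(ROOT / "results" / "rse_by_distance.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    defined = df.dropna(subset=["rse"])
    if len(defined) >= 3:
        rho = spearmanr(defined["dist"], defined["rse"]).statistic
        print(f"\nSpearman rank correlation of RSE with distance: {rho:+.2f}")
        print("(positive = dispersal becomes relatively more variable with distance)")


if __name__ == "__main__":
    sys.exit(main())
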