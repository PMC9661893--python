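"""Deterministic field-data derivations.

Effort standardization, trap seed density, relative standard error (RSE)
by distance, per-plant fecundity from stem counts, and the wind-orientation
covariates used by the landscape models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MAX_DAYS_DEFAULT = 49.0
HEADS_PER_CM = 8.2     # mean flower heads per cm of flowering-stalk length
FLOWERS_PER_HEAD = 3.7


@dataclass(frozen=True)
class RseByDistance:
    """RSE summary for one trap distance; ``rse`` is None when undefined."""

    dist: float
    mean_density: float
    se: Optional[float]
    rse: Optional[float]   # percent, 100 * SE / mean
    n_traps: int
    reason: Optional[str] = None  # why rse is undefined, if it is


def standardize_days(days_deployed: float, max_days: float = MAX_DAYS_DEFAULT) -> float:
    """Deployment time as a fraction of the longest deployment (49 days).

    Traps out longer than the standard period yield stdays > 1; that is
    permitted (the standardization is a linear effort scale, not a cap).
    """
    if days_deployed <= 0 or max_days <= 0:
        raise ValueError("days_deployed and max_days must be > 0")
    return days_deployed / max_days


def seed_density(n_seeds: float, area: float, stdays: float) -> float:
    """Seeds per m² per standard trapping period: n / (area * stdays)."""
    if area <= 0 or stdays <= 0:
        raise ValueError("area and stdays must be > 0")
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    return n_seeds / (area * stdays)


def rse_by_distance(densities: Sequence[float], distances: Sequence[float]) -> List[RseByDistance]:
    """Per-distance mean density and relative standard error (percent).

    RSE = 100 * SE / mean with SE = sd / sqrt(n) (ddof=1). Groups with a
    single trap or a zero mean return an undefined-RSE marker rather than
    a number; they carry the reason instead.
    """
    densities = np.asarray(densities, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if densities.shape != distances.shape:
        raise ValueError("densities and distances must align")
    out = []
    for d in np.unique(distances):
        x = densities[distances == d]
        n = x.size
        mean = float(x.mean())
        if n < 2:
            out.append(RseByDistance(float(d), mean, None, None, n, reason="single trap"))
            continue
        se = float(x.std(ddof=1) / math.sqrt(n))
        if mean == 0:
            out.append(RseByDistance(float(d), mean, se, None, n, reason="zero mean density"))
            continue
        out.append(RseByDistance(float(d), mean, se, 100.0 * se / mean, n))
    return out


def rse_table(records: List[RseByDistance]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"dist": r.dist, "mean": r.mean_density, "se": r.se, "rse": r.rse,
          "n": r.n_traps, "reason": r.reason} for r in records]
    )


def estimate_fecundity(
    n_stems: float,
    mean_stem_length: float,
    heads_per_cm: float = HEADS_PER_CM,
    flowers_per_head: float = FLOWERS_PER_HEAD,
) -> float:
    """Maximum seed production per plant.

    stems × mean stalk length (cm) × heads per cm × flowers per head, the
    morphometric proxy for seeds a plant could produce at most.
    """
    for v, name in ((n_stems, "n_stems"), (mean_stem_length, "mean_stem_length"),
                    (heads_per_cm, "heads_per_cm"), (flowers_per_head, "flowers_per_head")):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return n_stems * mean_stem_length * heads_per_cm * flowers_per_head


def total_available_seed(seeds_per_plant: float, n_reproductive: float) -> float:
    """Patch fecundity: per-plant maximum seed production × reproductive plants."""
    if seeds_per_plant < 0 or n_reproductive < 0:
        raise ValueError("inputs must be >= 0")
    return seeds_per_plant * n_reproductive


def _circular_diff(a: float, b: float) -> float:
    """Smallest absolute angular difference between two headings, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def wind_orientation(
    transect_azimuth: float, gust_headings: Iterable[Tuple[float, float]]
) -> float:
    """Angle between a transect and the nearest dominant gust heading.

    Headings are the directions gusts blow *toward*, given as closed degree
    intervals; distance to an interval is 0 inside it, else the circular
    distance to the nearest edge. Result lies in [0, 180].
    """
    az = transect_azimuth % 360.0
    headings = list(gust_headings)
    if not headings:
        raise ValueError("gust_headings must be non-empty")
    best = 180.0
    for lo, hi in headings:
        lo %= 360.0
        hi %= 360.0
        span = (hi - lo) % 360.0
        off = (az - lo) % 360.0
        if off <= span:  # azimuth inside the closed interval
            return 0.0
        best = min(best, _circular_diff(az, lo), _circular_diff(az, hi))
    return best


def wind_face(wind_orient: float) -> bool:
    """True when a transect faces a dominant wind direction (within 45°, inclusive)."""
    if not (0 <= wind_orient <= 180):
        raise ValueError(f"wind_orient must be in [0, 180], got {wind_orient!r}")
    return wind_orient <= 45.0


def scale_covariate(values: Sequence[float]) -> Tuple[np.ndarray, float, float]:
    """Centre at 0 and scale to unit SD; returns (scaled, centre, spread).

    The returned centre and spread invert the transform exactly
    (x = scaled * spread + centre). SD is the sample SD (ddof=1, the R
    convention).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    centre = float(x.mean())
    spread = float(x.std(ddof=1))
    if spread == 0:
        raise ValueError("cannot scale a constant covariate (sd = 0)")
    return (x - centre) / spread, centre, spread
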