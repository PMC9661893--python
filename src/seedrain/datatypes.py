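"""Domain types for the seed-trapping study.

A study is a set of *sites* (site-years), each holding seed-source
*patches*; two (or more) *transects* of vertical seed traps radiate from
each patch, and every trap contributes one record per capture-height band.
Counts are negative-binomial distributed in all models downstream, so the
raw integer count, the trap area and the deployment time are kept separate
here and only combined into densities/offsets by the preprocessing layer.

All quantities are SI: metres, m², days, m s⁻¹, degrees for azimuths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

VERTICAL = "vertical"
UNDER_CROWN = "under_crown"

#: Field bins for surrounding-canopy height (m) and their midpoints; the
#: open-topped bin is assigned 0.85 m.
CANOPY_BIN_MIDPOINTS = (0.15, 0.40, 0.625, 0.85)


class ValidationError(ValueError):
    """A record (or set of rows) violates a type invariant.

    Attributes
    ----------
    rows : list of int
        Zero-based indices of the offending rows when the error was raised
        while validating a table; empty for single-record validation.
    """

    def __init__(self, message: str, rows: Optional[List[int]] = None):
        super().__init__(message)
        self.rows = rows or []


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable dtype."""


@dataclass(frozen=True)
class TrapObservation:
    """One trap × capture-height-band record."""

    site_id: str
    patch_id: str
    transect_id: str
    trap_id: str
    trap_kind: str
    dist_trap: float        # m from patch edge; 0 for under-crown traps
    capture_height: float   # m, midpoint of the height band of capture
    area: float             # m² of trap surface attributed to this record
    days_deployed: float    # days the trap was out
    n_seeds: int

    def validate(self) -> None:
        errs = []
        if self.trap_kind not in (VERTICAL, UNDER_CROWN):
            errs.append(f"trap_kind must be '{VERTICAL}' or '{UNDER_CROWN}', got {self.trap_kind!r}")
        if not (float(self.n_seeds).is_integer() and self.n_seeds >= 0):
            errs.append(f"n_seeds must be a non-negative integer, got {self.n_seeds!r}")
        if not self.area > 0:
            errs.append(f"area must be > 0, got {self.area!r}")
        if not self.days_deployed > 0:
            errs.append(f"days_deployed must be > 0, got {self.days_deployed!r}")
        if self.dist_trap < 0:
            errs.append(f"dist_trap must be >= 0, got {self.dist_trap!r}")
        if self.capture_height < 0:
            errs.append(f"capture_height must be >= 0, got {self.capture_height!r}")
        if self.trap_kind == UNDER_CROWN and self.dist_trap != 0:
            errs.append("under-crown traps must have dist_trap = 0")
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass(frozen=True)
class PatchInfo:
    """A seed-source patch and its fecundity inputs."""

    patch_id: str
    site_id: str
    n_reproductive: int         # reproductive plants in the patch
    seeds_per_plant: float      # mean maximum seed production per plant
    total_available_seed: float  # seeds_per_plant * n_reproductive
    canopy_height_class: float  # m, midpoint of the surrounding-canopy bin

    def validate(self) -> None:
        errs = []
        if self.n_reproductive < 0 or not float(self.n_reproductive).is_integer():
            errs.append(f"n_reproductive must be a non-negative integer, got {self.n_reproductive!r}")
        if self.seeds_per_plant < 0:
            errs.append(f"seeds_per_plant must be >= 0, got {self.seeds_per_plant!r}")
        if self.canopy_height_class <= 0:
            errs.append(f"canopy_height_class must be > 0, got {self.canopy_height_class!r}")
        expected = self.seeds_per_plant * self.n_reproductive
        if not np.isclose(self.total_available_seed, expected, rtol=1e-6, atol=0.51):
            errs.append(
                f"total_available_seed {self.total_available_seed!r} inconsistent with "
                f"seeds_per_plant*n_reproductive = {expected!r}"
            )
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass(frozen=True)
class TransectInfo:
    """A trap transect radiating from a patch."""

    transect_id: str
    patch_id: str
    azimuth: float      # degrees in [0, 360)
    wind_orient: float  # degrees in [0, 180]; angle to nearest dominant gust heading
    wind_face: bool     # wind_orient <= 45

    def validate(self) -> None:
        errs = []
        if not (0 <= self.azimuth < 360):
            errs.append(f"azimuth must be in [0, 360), got {self.azimuth!r}")
        if not (0 <= self.wind_orient <= 180):
            errs.append(f"wind_orient must be in [0, 180], got {self.wind_orient!r}")
        if bool(self.wind_face) != (self.wind_orient <= 45):
            errs.append("wind_face must equal (wind_orient <= 45)")
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass(frozen=True)
class SiteWind:
    """Site-level wind metadata over the deployment window.

    ``gust_headings`` are the directions dominant gusts blow *toward*, as
    closed degree intervals (a single heading is a zero-width interval).
    ``U`` is the average daily maximum wind speed.
    """

    site_id: str
    gust_headings: Tuple[Tuple[float, float], ...]
    U: float  # m s^-1

    def validate(self) -> None:
        errs = []
        if not self.U > 0:
            errs.append(f"U must be > 0, got {self.U!r}")
        if len(self.gust_headings) == 0:
            errs.append("gust_headings must be non-empty")
        for lo, hi in self.gust_headings:
            if not (0 <= lo < 360 and 0 <= hi < 360):
                errs.append(f"headings must lie in [0, 360), got ({lo!r}, {hi!r})")
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass
class Constants:
    """Fixed biological and physical constants shared by all stages."""

    max_days: float = 49.0          # longest deployment; standardization denominator
    heads_per_cm: float = 8.2       # flower heads per cm of flowering stalk
    flowers_per_head: float = 3.7
    k: float = 0.38                 # canopy-density scaling, sparse post-fire canopies
    terminal_velocity: float = 0.41  # m s^-1, median measured seed fall speed
    height_cutoff: float = 0.20     # m; below this, ground distance = trap distance
    fecund_scale: float = 1000.0    # total available seed divided by this in Eq.-7-style mean

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"constant {f.name} must be > 0")
        if not (0.3 <= self.k <= 0.4):
            raise ValidationError(f"k should lie in [0.3, 0.4], got {self.k!r}")


@dataclass
class McmcConfig:
    chains: int = 4          # walker groups reported as chains
    warmup: int = 1500       # ensemble steps discarded
    draws: int = 1500        # ensemble sampling steps after warmup
    thin: int = 10           # keep every thin-th ensemble step
    rhat_threshold: float = 1.05

    def validate(self) -> None:
        if self.chains < 2:
            raise ValidationError("need at least 2 chains for r-hat")
        if self.warmup < 0 or self.draws < 1:
            raise ValidationError("warmup must be >= 0 and draws >= 1")
        if self.rhat_threshold < 1:
            raise ValidationError("rhat_threshold must be >= 1")


@dataclass
class RunConfig:
    random_seed: int = 0
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    constants: Constants = field(default_factory=Constants)

    def validate(self) -> None:
        self.mcmc.validate()
        self.constants.validate()


@dataclass
class PosteriorDraws:
    """Labelled MCMC output.

    ``draws`` maps a parameter name to an array of shape ``(chain, draw)``
    for scalars or ``(chain, draw, k)`` for vector-valued parameters.
    ``pointwise_loglik`` (``(chain, draw, n_obs)``) enables PSIS-LOO.
    """

    draws: Dict[str, np.ndarray]
    rhat: Dict[str, float]
    converged: bool
    pointwise_loglik: Optional[np.ndarray] = None
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        a = next(iter(self.draws.values()))
        return a.shape[0]

    @property
    def n_draws(self) -> int:
        a = next(iter(self.draws.values()))
        return a.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of ``name`` with chains stacked: (chain*draw, ...)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def quantile(self, name: str, q) -> np.ndarray:
        return np.quantile(self.flat(name), q, axis=0)

    def median(self, name: str) -> np.ndarray:
        return self.quantile(name, 0.5)

    def ci(self, name: str, level: float = 0.90) -> Tuple[np.ndarray, np.ndarray]:
        """Central credible interval, default 90%."""
        alpha = (1.0 - level) / 2.0
        return self.quantile(name, alpha), self.quantile(name, 1.0 - alpha)

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def scalar_names(self) -> List[str]:
        """Expanded names, vectors indexed as name[i]."""
        out = []
        for name, a in self.draws.items():
            if a.ndim == 2:
                out.append(name)
            else:
                out.extend(f"{name}[{i}]" for i in range(a.shape[2]))
        return out


@dataclass
class GroundTruth:
    """The exact generator and parameter values behind a synthetic study."""

    generator: str            # "glm" | "fusion"
    params: Dict[str, object]
    seed: int
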