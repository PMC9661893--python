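"""Mechanistic WALD (inverse-Gaussian) wind-dispersal kernel.

Travel distance of a seed released (here: intercepted) at height ``ht`` in
a mean horizontal wind ``U`` follows an inverse-Gaussian (Wald)
distribution with

    mean  mu  = ht * U / V          (V: seed terminal velocity)
    shape lam = (ht / sigma)^2,     sigma^2 = k * c * (2 * sigma_w / U)

where ``k`` scales canopy density (0.3–0.4; 0.38 for sparse post-fire
canopies), ``c`` is the surrounding-canopy height and ``sigma_w`` the
vertical-turbulence boundary term, defaulting to U/2 so that
sigma^2 = k * c.

These parameters are treated as fixed physical inputs: no posterior
uncertainty is propagated through U, c, k or V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

TERMINAL_VELOCITY_DEFAULT = 0.41  # m s^-1, median measured fall speed
K_DEFAULT = 0.38
HEIGHT_CUTOFF_DEFAULT = 0.20  # m; seeds caught lower are treated as grounded


@dataclass(frozen=True)
class WaldInputs:
    """Physical inputs for one capture height at one patch."""

    ht: float                 # m, height of seed capture
    U: float                  # m s^-1, average daily maximum wind speed
    V: float = TERMINAL_VELOCITY_DEFAULT
    k: float = K_DEFAULT
    c: float = 0.40           # m, surrounding-canopy height (bin midpoint)
    sigma_w: Optional[float] = None  # m s^-1; default U/2

    def resolved_sigma_w(self) -> float:
        return self.U / 2.0 if self.sigma_w is None else self.sigma_w

    def validate(self) -> None:
        if self.ht < 0:
            raise ValueError("ht must be >= 0")
        for v, name in ((self.U, "U"), (self.V, "V"), (self.k, "k"), (self.c, "c")):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.resolved_sigma_w() <= 0:
            raise ValueError("sigma_w must be > 0")


@dataclass(frozen=True)
class WaldParams:
    """Inverse-Gaussian parameters; ``degenerate`` marks the ht=0 point mass at 0."""

    mu: float      # m, distribution mean
    lam: float     # m, shape
    sigma: float
    degenerate: bool = False

    @property
    def variance(self) -> float:
        return self.mu ** 3 / self.lam if not self.degenerate else 0.0


def compute_sigma(k: float, c: float, sigma_w: float, U: float) -> float:
    """sigma = sqrt(k * c * (2 * sigma_w / U)); reduces to sqrt(k*c) at sigma_w = U/2."""
    for v, name in ((k, "k"), (c, "c"), (sigma_w, "sigma_w"), (U, "U")):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return math.sqrt(k * c * (2.0 * sigma_w / U))


def wald_params(inputs: WaldInputs) -> WaldParams:
    """Inverse-Gaussian parameters for one capture height.

    A zero capture height yields the degenerate distribution (distance 0
    with probability 1), flagged rather than raised.
    """
    inputs.validate()
    sigma = compute_sigma(inputs.k, inputs.c, inputs.resolved_sigma_w(), inputs.U)
    if inputs.ht == 0:
        return WaldParams(mu=0.0, lam=0.0, sigma=sigma, degenerate=True)
    mu = inputs.ht * inputs.U / inputs.V
    lam = (inputs.ht / sigma) ** 2
    return WaldParams(mu=mu, lam=lam, sigma=sigma)


def sample_wald(params: WaldParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. inverse-Gaussian distances (m).

    Uses the Michael–Schucany–Haas chi-square transform, so draws are
    reproducible from the seed and independent of any library RNG layout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.degenerate:
        return np.zeros(n)
    if params.mu <= 0 or params.lam <= 0:
        raise ValueError("invalid Wald parameters")
    rng = np.random.default_rng(seed)
    mu, lam = params.mu, params.lam
    nu = rng.standard_normal(n)
    y = nu ** 2
    x = mu + (mu ** 2 * y) / (2 * lam) - (mu / (2 * lam)) * np.sqrt(
        4 * mu * lam * y + mu ** 2 * y ** 2
    )
    u = rng.uniform(size=n)
    take_x = u <= mu / (mu + x)
    return np.where(take_x, x, mu ** 2 / x)


def wald_logpdf(x: np.ndarray, params: WaldParams) -> np.ndarray:
    """Inverse-Gaussian log-density; -inf for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    pos = x > 0
    xp = x[pos]
    mu, lam = params.mu, params.lam
    out[pos] = (
        0.5 * np.log(lam / (2.0 * np.pi * xp ** 3))
        - lam * (xp - mu) ** 2 / (2.0 * mu ** 2 * xp)
    )
    return out


def wald_quantiles(params: WaldParams, probs: np.ndarray) -> np.ndarray:
    """Inverse CDF at ``probs``; used for fixed-node marginalization."""
    return stats.invgauss.ppf(probs, mu=params.mu / params.lam, scale=params.lam)


def latent_ground_distance(
    dist_trap: float,
    capture_height: float,
    inputs: WaldInputs,
    cutoff: float = HEIGHT_CUTOFF_DEFAULT,
    n: int = 1,
    seed=None,
) -> np.ndarray:
    """Draws of the ground distance a seed caught at height would have reached.

    Below the cutoff (default 20 cm) the extra travel is negligible and
    every draw equals the trap distance exactly; at or above it, draws are
    dist_trap + Wald(ht·U/V, (ht/σ)²) increments.
    """
    if dist_trap < 0:
        raise ValueError("dist_trap must be >= 0")
    if capture_height < cutoff:
        return np.full(n, float(dist_trap))
    p = wald_params(WaldInputs(ht=capture_height, U=inputs.U, V=inputs.V,
                               k=inputs.k, c=inputs.c, sigma_w=inputs.sigma_w))
    return dist_trap + sample_wald(p, n, seed)
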