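"""The 2Dt empirical dispersal kernel and the fused expected-count mean.

The 2Dt kernel is the bivariate-Student-t-derived seed shadow

    disp(d; a, b) = a / (pi * b) * (1 + d^2 / b)^-(a + 1)

a probability density over the plane (integrates to one against
2*pi*d dd), with shape ``a`` (tail heaviness; smaller = fatter tail) and
scale ``b`` (m²). Transect-level kernels deviate from the global (a, b)
either additively (a_t = a + omega_t * nu1, the paper-form) or on the log
scale (log a_t = log a + omega_t * nu1, the default, which keeps every
transect kernel valid by construction).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

FECUND_SCALE = 1000.0


def kernel_2dt(dist, a: float, b: float):
    """2Dt seed-shadow density (m^-2) at distance ``dist`` (m)."""
    if a <= 0 or b <= 0:
        raise ValueError("kernel parameters a and b must be > 0")
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("dist must be >= 0")
    out = a / (np.pi * b) * (1.0 + d ** 2 / b) ** (-(a + 1.0))
    return out if out.shape else float(out)


def kernel_2dt_cdf(dist, a: float, b: float):
    """P(distance <= d) for the radial 2Dt distance distribution: 1 - (1+d²/b)^-a."""
    d = np.asarray(dist, dtype=float)
    out = 1.0 - (1.0 + d ** 2 / b) ** (-a)
    return out if out.shape else float(out)


def median_dispersal_distance(a: float, b: float) -> float:
    """Median of the radial distance distribution, sqrt(b*(2^(1/a)-1))."""
    return float(np.sqrt(b * (2.0 ** (1.0 / a) - 1.0)))


def transect_kernel(
    a: float, b: float, omega_t: float, delta_t: float, nu1: float, nu2: float,
    log_scale: bool = False,
) -> Tuple[float, float]:
    """Transect-level kernel parameters from the global (a, b) and deviations.

    Additive form (the published structure): a_t = a + omega_t * nu1 and
    b_t = b + delta_t * nu2; a non-positive result raises, the caller is
    expected to use the log-scale parameterization when validity must be
    guaranteed. Log form: log a_t = log a + omega_t * nu1 etc.
    """
    if a <= 0 or b <= 0:
        raise ValueError("global kernel parameters must be > 0")
    if nu1 < 0 or nu2 < 0:
        raise ValueError("deviation scales nu must be >= 0")
    if log_scale:
        return a * np.exp(omega_t * nu1), b * np.exp(delta_t * nu2)
    a_t = a + omega_t * nu1
    b_t = b + delta_t * nu2
    if a_t <= 0 or b_t <= 0:
        raise ValueError(
            f"additive transect deviation produced non-positive kernel parameters "
            f"(a_t={a_t:.4g}, b_t={b_t:.4g}); use the log-scale parameterization"
        )
    return a_t, b_t


def expected_count(
    area: float, disp: float, f: float, fecund: float, stdays: float,
    fecund_scale: float = FECUND_SCALE,
) -> float:
    """Expected trapped seeds: area × kernel density × f·(fecund/1000) × effort."""
    for v, name in ((area, "area"), (disp, "disp"), (f, "f"),
                    (fecund, "fecund"), (stdays, "stdays")):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return area * disp * (f * fecund / fecund_scale) * stdays
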