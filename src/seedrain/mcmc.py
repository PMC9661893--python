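"""Ensemble-MCMC driver shared by the landscape GLM and the fusion model.

Both models expose an unconstrained log-posterior over a flat parameter
vector (positivity handled by log transforms with Jacobians inside the
density). Sampling runs two (configurable) independent differential-
evolution ensembles (emcee), each seeded from a penalized-likelihood mode
found with L-BFGS. Convergence is diagnosed with rank-normalized split
r-hat across chains formed by splitting each ensemble's walkers into two
groups, so disagreement either between or within independent ensembles
raises r-hat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional

import emcee
import numpy as np
from scipy import optimize

from .datatypes import McmcConfig

log = logging.getLogger("seedrain")

GROUPS_PER_ENSEMBLE = 2


@dataclass
class SampleResult:
    """Thinned post-warmup draws from all ensembles.

    ``chain`` has shape (n_ensembles, n_walkers, n_kept, ndim);
    ``diag_chains`` (n_ensembles * 2, draws, ndim) is the grouping used
    for r-hat.
    """

    chain: np.ndarray
    map_point: np.ndarray
    acceptance: float
    seed: int

    @property
    def diag_chains(self) -> np.ndarray:
        E, W, M, D = self.chain.shape
        per = W // GROUPS_PER_ENSEMBLE
        c = self.chain[:, : per * GROUPS_PER_ENSEMBLE]
        return c.reshape(E * GROUPS_PER_ENSEMBLE, per * M, D)

    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])


def find_mode(
    log_prob_vec: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int = 400,
) -> np.ndarray:
    """Posterior mode via L-BFGS on the single-point wrapper; best effort."""

    def neg(x):
        v = float(log_prob_vec(x[None, :])[0])
        return -v if np.isfinite(v) else 1e12

    try:
        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "maxfun": 4 * maxiter})
        if np.isfinite(res.fun):
            return np.asarray(res.x, dtype=float)
    except Exception as exc:  # pragma: no cover - optimizer hiccups are non-fatal
        log.warning("mode finding failed (%s); starting from x0", exc)
    return x0


def _run_one_ensemble(
    log_prob_vec, ndim: int, seed: int, mcmc: McmcConfig, start: np.ndarray,
    n_walkers: int, init_scale: float,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    p0 = start[None, :] + init_scale * rng.standard_normal((n_walkers, ndim))
    lp0 = log_prob_vec(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while np.any(bad) and tries < 50:
        p0[bad] = start[None, :] + 0.2 * init_scale * rng.standard_normal((int(bad.sum()), ndim))
        lp0 = log_prob_vec(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if np.any(bad):
        raise RuntimeError("could not initialize all walkers at finite log-posterior")
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob_vec,
                                    vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, mcmc.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.draws, progress=False)
    chain = sampler.get_chain(thin=mcmc.thin)          # (n_kept, n_walkers, ndim)
    return np.moveaxis(chain, 0, 1), float(np.mean(sampler.acceptance_fraction))


def sample_posterior(
    log_prob_vec: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    seed: int,
    mcmc: McmcConfig,
    x0: Optional[np.ndarray] = None,
    n_walkers: Optional[int] = None,
    n_ensembles: int = 2,
    init_scale: float = 0.05,
) -> SampleResult:
    """Sample with ``n_ensembles`` independent DE ensembles.

    ``log_prob_vec`` must accept an ``(n_points, ndim)`` array and return
    ``(n_points,)`` log-posterior values.
    """
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 32)
        n_walkers += n_walkers % 2
    if x0 is None:
        x0 = np.zeros(ndim)
    start = find_mode(log_prob_vec, x0)
    chains = []
    accs = []
    for e in range(n_ensembles):
        sub = int(np.random.SeedSequence([seed, e]).generate_state(1)[0] % (2 ** 31))
        ch, acc = _run_one_ensemble(log_prob_vec, ndim, sub, mcmc, start,
                                    n_walkers, init_scale)
        chains.append(ch)
        accs.append(acc)
    return SampleResult(chain=np.stack(chains), map_point=start,
                        acceptance=float(np.mean(accs)), seed=seed)


def rhat_per_parameter(result: SampleResult, names_for: Callable[[int], str]) -> Dict[str, float]:
    """Rank-normalized split r-hat per flat coordinate across diagnostic chains."""
    import arviz as az

    diag = result.diag_chains
    out: Dict[str, float] = {}
    for j in range(diag.shape[2]):
        out[names_for(j)] = float(az.rhat(diag[:, :, j], method="rank"))
    return out


def regroup_chains(result: SampleResult, n_chains: int) -> np.ndarray:
    """All kept draws regrouped into ``n_chains`` reported chains."""
    E, W, M, D = result.chain.shape
    flat = result.chain.reshape(E * W, M, D)
    per = (E * W) // n_chains
    return flat[: per * n_chains].reshape(n_chains, per * M, D)
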