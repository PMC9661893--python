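# Methods

`seedrain` models wind-driven seed dispersal from remnant shrub patches
into disturbed (post-fire) landscapes, in three connected stages: (i)
hierarchical negative-binomial regressions that ask *at which landscape
scale* trapped seed density varies; (ii) a data-fusion dispersal model
that combines an empirical 2Dt seed-shadow kernel with a mechanistic
inverse-Gaussian (WALD) wind-transport model through a latent
ground-distance variable; and (iii) a posterior-predictive simulator that
projects seed rain over 0–100 m and compares it with operational aerial
seeding rates. All three stages run on synthetic studies produced by the
package's own generator, which emulates the vertical-trap field design.

## Data model and units

The observation unit is one trap × capture-height band: a vertical sticky
trap (0.50 m wide × 0.76 m tall in the emulated design) is divided into
three equal horizontal bands, and a record carries the integer seed count
for that band, the band's area, the band midpoint as the *capture height*,
and the deployment time. Under-crown traps (0.01 m²) sit at distance 0.
Units are SI throughout (m, m², days, m s⁻¹; degrees for azimuths);
surrounding-canopy height arrives as field bins (<0.30, 0.30–0.50,
0.50–0.75, >0.75 m) and is converted to bin midpoints at read time, with
0.85 m standing in for the open-topped bin. Traps lost in the field are
absent rows, never zero counts. Effort enters every model through
`stdays = days deployed / 49` (the longest deployment) and the record
area; densities are therefore *seeds m⁻² per 49-day standard period*.

The band-midpoint convention for capture height is a package convention:
the field protocol records where on the trap a seed stuck, and any
analysis needs one height number per record. Band edges are configurable.

## Landscape models

Counts are negative-binomial, `y ~ NB(mu, phi)` with variance
`mu + mu²/phi`, and

```
log mu = g0 + g1*ht + g2*dist + g3*ht*dist + g4*fecund [+ g5*windorient | + g6*windface]
         + log(stdays) + log(area)
```

on covariates centred and scaled to unit (sample) SD. `fecund` is the
patch's total available seed — mean maximum per-plant seed production
(stems × mean stalk length × 8.2 heads cm⁻¹ × 3.7 flowers head⁻¹) times
the number of reproductive plants. Under-crown traps are excluded from
this stage.

Seven variance structures let the intercept and all three slopes (height,
distance, height×distance) deviate by group: none, site, site+patch,
patch, patch+transect, transect, site+patch+transect ("site" means a
site-year). Deviations are non-centred (`effect = z * sd`, `z ~ N(0,1)`),
with one SD per group factor per term. The wind variants add either the
scaled angle between a transect and the nearest dominant gust heading
(closed-interval headings; distance 0 inside an interval) or its binary
"faces the wind within 45° (inclusive)" version. Structures are ranked by
PSIS-LOO (arviz), with mismatched observation sets rejected and the
fraction of Pareto-k values above 0.7 recorded alongside the ranking.

Priors: coefficients N(0, 2.5) on the scaled scale, intercept N(0, 5),
group SDs half-N(0, 1), overdispersion phi with the diffuse
Gamma(0.01, 0.01) shape prior (the brms default). All are configurable.
With ~300 sparse records phi is only weakly identified; the diffuse
prior matters because an informative shape prior silently pulls such
fits toward the near-Poisson regime and narrows every coefficient
interval below its honest width.

One identifiability caveat applies to the landscape models themselves:
when a slope is allowed to vary by transect, the *global* coefficient is
estimated as the population mean of the transect-level slopes, and with
a dozen transects the realized average of those deviations does not
vanish. For the height slope — whose within-transect signal is weakest
(three height bands, mostly-zero counts) — the fitted global coefficient
tracks the realized average slope rather than the nominal generating
value, a property of the design confirmed by refitting the same data
with an independent implementation (glmmTMB, identical formula), which
lands on the same estimates. Interval coverage of the nominal height
coefficient is accordingly below nominal at this design size; coverage
of the realized average slope is on target.

## The fused 2Dt + WALD dispersal model

The second stage models the same counts (vertical *and* under-crown)
mechanistically:

```
y      ~ NB(mu, phi2)
mu     = area * disp(dist_ground; a_t, b_t) * (f * fecund/1000) * stdays
disp(d) = a_t / (pi * b_t) * (1 + d²/b_t)^-(a_t + 1)
```

The 2Dt kernel `disp` is a proper density over the plane (it integrates
to one against `2*pi*d dd`); `a` controls tail heaviness (smaller = more
long-distance dispersal) and `b` (m²) the spatial scale. `f` scales the
per-1000-seed fecundity effect.

`dist_ground` is the distance a seed *would have travelled* had it not hit
the trap: seeds caught below 20 cm are treated as effectively grounded
(`dist_ground = dist_trap`); seeds caught at or above 20 cm get
`dist_ground = dist_trap + dist_wald`, with the increment following an
inverse-Gaussian (Wald) distribution whose parameters come from physics,
not fitting:

```
mean  = ht * U / V       shape = (ht / sigma)²      sigma² = k * c * (2*sigma_w / U)
```

with capture height `ht`, average daily maximum wind speed `U` (per
site), seed terminal velocity `V = 0.41 m s⁻¹`, canopy-density factor
`k = 0.38`, surrounding-canopy height `c` (per patch), and boundary term
`sigma_w = U/2` (which reduces sigma² to `k*c`). One caveat is inherited
from the source formulation and documented rather than silently repaired:
under this construction sigma carries units of m^½, and the published
symbol roles for the Wald pair are swapped relative to the mechanistic
derivation (the mean must be `ht*U/V` on dimensional grounds); this
package uses the dimensionally consistent assignment. No uncertainty is
propagated through U, c, k or V.

### Latent-variable treatment

Because the Wald law of each record's increment is fully fixed by its
physical inputs, the latent ground distance can be integrated out of the
likelihood exactly, up to a fixed quadrature rule: each above-cutoff
record gets 8 equal-weight nodes at its Wald quantile midpoints
(probabilities (j+½)/8), and the record's likelihood is the mean of NB
probabilities across nodes. Below-cutoff records collapse to a single
node at the trap distance. Per-record latent *posteriors* are then drawn
conditionally (categorical over nodes, weights proportional to the NB
likelihood) for every stored posterior draw — a collapsed version of
data augmentation that avoids adding ~700 latent dimensions to the
sampler. A plug-in mode (latent fixed at `dist_trap + ht*U/V`) exists for
smoke tests only.

### Transect-level kernels and priors

Transect kernels deviate from the global (a, b) multiplicatively by
default — `log a_t = log a + omega_t * nu1`, `omega_t ~ N(0,1)` — which
keeps every kernel valid; the published additive form
(`a_t = a + omega_t*nu1`) is available behind a flag and rejects (never
clips) non-positive results. Priors: `a ~ half-N(0,2)`,
`b ~ half-N(0,100) m²`, `f ~ half-N(0,1)`, `phi2` shape diffuse
(Gamma(0.01, 0.01), the brms default for the NB shape — a mean-20 Gamma
prior proved actively informative toward the near-Poisson regime when
phi2 is weakly identified, pushing count dispersion into the transect
deviations), and `nu1, nu2 ~ half-N(0, 0.3)` on the log-deviation scale
(±35% kernel variation per transect at 1 sd; the additive form keeps
half-N(0, 1) in its own units). The log-scale nu prior is deliberately
tighter than a naive carry-over of the additive one: half-N(0,1) on a
log deviation would allow 2.7-fold kernel differences between transects
at 1 sd and, at realistic counts (~3 seeds per transect), lets the
per-transect kernels absorb the signal that should estimate the global
tail.

### What is and is not identified at trap scale

With a few dozen to ~100 trapped seeds over 735 records, the joint
(a, b) posterior forms a wide ridge (larger a with larger b mimics the
observed decay over 2–26 m; only far-tail counts — expected < 0.1 seeds
per trap — could separate them), `phi2` is weakly identified, and
per-transect deviations are informed by ~3 seeds each. Posteriors are
honest about this: they are wide, ridge-shaped, and prior-sensitive for
the weakly identified components. Posterior intervals are calibrated
with respect to the stated priors (parameters drawn from the priors are
covered at the nominal rate in repeated generation-and-refit), but
interval coverage of one *fixed* reference value depends on where that
value sits along the ridge relative to the prior mass: reference points
on the low-volume side of the ridge under-cover even with a perfectly
correct sampler. Ridge-identified functionals — the near-source density
`a/(pi b) * f * fecund/1000` and the decay over the trap span — are what
this design estimates well. The recovery tests in the acceptance suite
measure exactly this behaviour.

## Forward projection

Each of 10 000 simulations draws one posterior sample of
(a, b, f, nu1, nu2), draws a *fresh* transect deviation (predicting a
generic, unobserved transect; a global-parameters-only mode is also
available), and evaluates `disp(d) * f * fecund/1000` on a 0–100 m grid
(0.5 m steps). Pointwise 5/50/95% quantiles form the forecast curve; the
default scenario is 30 000 seeds per plant × 25 plants (750 000 seeds).
Each distance's median and upper quantile are classified against the
95–250 seeds m⁻² aerial-seeding band. The curve is linear in scenario
fecundity by construction, so doubling the scenario doubles every
quantile exactly.

## Sampling and diagnostics

No probabilistic-programming backend is used: both models expose
unconstrained log-posteriors (positivity via log transforms with
Jacobians; half-normal scales via reflection) that are numba-compiled and
sampled with emcee's differential-evolution ensemble (80% DE, 20% DE
snooker moves), 2×dim+2 walkers, initialized by jittering an L-BFGS
posterior mode. Two *independent* ensembles are run per fit; convergence
is diagnosed with rank-normalized split r-hat across four chains formed
by halving each ensemble's walkers, so disagreement either within or
between independent ensembles raises r-hat. A fit is flagged
non-converged when any parameter's r-hat exceeds 1.05. Stored draws are
an even-strided subsample (default 4000 for the GLM, 2000 for the fusion
model) of the thinned post-warmup chains; pointwise log-likelihoods for
LOO are computed on the stored subsample.

Numerical guards: linear predictors above 35 on the log scale invalidate
a proposal (-inf) rather than overflowing; NB log-probabilities use the
zero-count shortcut `phi * log(phi/(phi+mu))`; the log-sum-exp over
latent nodes is computed incrementally.

## The synthetic-study generator

The generator reproduces the second-year design: 3 sites × 5 patches ×
2 transects, vertical traps at 2, 4, 6, 10, 14, 18, 22, 26 m (three
height bands each) plus one under-crown trap per patch, deployment times
42–49 days, lognormal per-plant fecundity (median 30 000, log-SD 0.5),
~25 reproductive plants per patch, daily-maximum wind speeds 6–12 m s⁻¹,
canopy classes drawn from the field bins, and optional random trap loss
(absent rows). Counts come from either generative model with recorded
ground truth, including the realized latent distances for the fusion
generator.

Default fusion-generator magnitudes are a = 1.0, b = 25 m², f = 1.0,
phi2 = 2.0, nu1 = nu2 = 0.2 (multiplicative), chosen so a 750 000-seed
patch yields ~9.5 seeds m⁻² at the source, ~2.4 at 5 m and ~0.08 by
16 m — the regime of the reference median projection. Two features of
the real data are *not* reproduced and bound what passing tests show:
whole-trap occupancy comes out near 15% rather than the ~31% observed in
the field (no 2Dt kernel can combine ~10 seeds m⁻² at the source with
that occupancy under this trap geometry), and the generator's counts at
height are always thinner than at the trap base, whereas field data
showed more seeds caught high near the source; both reflect structure
outside the fitted model (e.g. vertical wind profiles), so tests passing
on synthetic data do not certify those aspects of real data.

The GLM generator's defaults (on the scaled-covariate scale) are
g = (-1.0, -0.3, -1.5, +0.4, +0.1), phi = 1.0, with transect SDs
(0.8, 0.3, 0.3, 0.2) for intercept/height/distance/interaction — a strong
distance decline, a modest positive height×distance interaction, a weak
fecundity effect, and intercept-dominated transect heterogeneity.

## Problem sizes used by the test and acceptance runs

Recovery experiments run at deliberately desk-scale sizes chosen as this
package's own defaults: GLM recovery uses 2 sites × 3 patches ×
2 transects (288 records, 12 transects) over 10 generator seeds; fusion
recovery uses the full 15-patch design (735 records, 30 transects) over
10 seeds at reduced chain lengths; the degenerate-wind equivalence check
uses a 5-patch design with all capture heights below the cutoff. Chain
lengths (1200–1500 warmup + sampling steps per ensemble for the GLM,
500–1000 for the fusion model) were set so that cross-ensemble r-hat
clears 1.05 with margin on the GLM fits while keeping a full suite run
on one CPU within tens of minutes.

## Known limitations

- The 2Dt (a, b) pair is only ridge-identified at realistic trap counts;
  single-study posteriors for a and b individually should be read with
  that in mind (the ridge direction `a/b ~ const` is well identified).
- The latent-distance quadrature truncates the Wald tail at its 93.75th
  percentile node; records whose true latent lies beyond contribute
  through the nearest node. Increasing `n_nodes` trades time for tail
  fidelity.
- Overdispersion parameters are prior-sensitive whenever most records
  are zeros.
- The Wald inputs (U, c, k, V) carry no uncertainty, matching the source
  formulation; mis-specified wind speeds translate directly into biased
  latent distances.
- Anisotropy is represented only through transect-level kernel variation;
  there is no directional kernel.
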