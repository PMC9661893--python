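# seedrain

Hierarchical Bayesian modelling of wind-driven seed dispersal from
remnant shrub patches into disturbed landscapes — for restoration
ecologists who need to know whether natural seed rain can substitute for
aerial seeding, and for dispersal modellers who want a worked example of
fusing an empirical seed-shadow kernel with a mechanistic wind-transport
model.

The package implements three connected analyses over vertical-seed-trap
studies (traps at fixed distances along transects radiating from seed
source patches, counts recorded per capture-height band):

1. **Landscape models** — negative-binomial regressions of trapped seed
   counts,

   `log μ = γ₀ + γ₁·ht + γ₂·dist + γ₃·ht·dist + γ₄·fecund (+ wind) + log(stdays) + log(area)`

   with intercept and slopes varying by site, patch and/or transect
   (seven variance structures), ranked by PSIS-LOO to locate the spatial
   scale of variation in seed rain.

2. **Fused 2Dt + WALD dispersal model** — counts follow
   `NB(area · disp(dist_ground; a_t, b_t) · f·fecund/1000 · stdays, φ₂)`
   where `disp(d) = a/(πb) · (1 + d²/b)^-(a+1)` is the 2Dt seed-shadow
   kernel and `dist_ground` is a latent ground distance: the trap
   distance for seeds caught below 20 cm, and the trap distance plus an
   inverse-Gaussian (WALD) increment — mean `ht·U/V`, shape `(ht/σ)²`,
   `σ² = k·c·(2σ_w/U)` — for seeds caught at height. Kernel parameters
   vary by transect around global (a, b).

3. **Forward projection** — 10 000 posterior-predictive simulations of
   seeds m⁻² over 0–100 m for a seed-source scenario, compared against
   the 95–250 seeds m⁻² aerial-seeding band.

Everything runs on synthetic studies from the built-in generator, which
emulates the field design (15 patches, two transects each, traps at
2–26 m plus under-crown, three capture-height bands) and records ground
truth for recovery testing. See `docs/methods.md` for model details,
priors, numerical choices and limitations.

## Worked example

```python
import numpy as np
from seedrain import (
    StudyDesign, generate_design, simulate_counts_fusion,
    build_fusion_frame, fit_fusion, simulate_forecast, Scenario, McmcConfig,
)

tables = generate_design(StudyDesign(), seed=20260930)
tables, truth = simulate_counts_fusion(tables, seed=20260931)
frame = build_fusion_frame(tables.traps, tables.patches,
                           tables.transects, tables.wind)
fit = fit_fusion(frame, mcmc=McmcConfig(warmup=1200, draws=1200, thin=10),
                 seed=20260930)
print(f"a median {fit.median('a'):.2f}, 90% CI [{fit.ci('a')[0]:.2f}, {fit.ci('a')[1]:.2f}]")
print(f"max r-hat {fit.max_rhat():.3f}")

curve = simulate_forecast(fit, Scenario(seeds_per_plant=30000, n_plants=25),
                          n_sims=10000, seed=20260930)
i = np.searchsorted(curve.distances, 5.0)
print(f"median seed rain at 5 m: {curve.q50[i]:.2f} seeds/m^2")
```

On the default synthetic study (the generating kernel has a = 1.0,
b = 25 m², f = 1.0) this prints

```
a median 1.23, 90% CI [0.50, 2.79]
max r-hat 1.013
median seed rain at 5 m: 2.24 seeds/m^2
```

— the shape parameter's interval covers the generating value (the (a, b)
pair is only ridge-identified at realistic trap counts, so intervals are
wide), the fit converges, and a 750 000-seed patch is projected to shed
only a couple of seeds per m² five metres out. The same projection falls
below one seed per m² within ~10 m and sits below the 95–250 seeds/m²
aerial-seeding band at every distance: natural dispersal from a remnant
patch does not substitute for seeding anywhere on the landscape.

The analysis itself lives in numbered drivers:

```
python analysis/01_simulate_study.py      # synthetic study + ground truth
python analysis/02_density_and_rse.py     # densities, RSE vs distance
python analysis/03_landscape_models.py    # GLM ladder + LOO ranking
python analysis/04_fusion_fit.py          # fused dispersal model
python analysis/05_forecast_seed_rain.py  # 0-100 m projection vs seeding band
```

Each prints what it found and writes tables under `results/`. On the
default study, `02` reports relative standard errors rising from ~18% at
2 m to ~100% beyond 14 m (rank correlation +0.99 with distance —
dispersal gets patchier away from the source); `03` ranks the transect
model above the no-structure model by PSIS-LOO (looIC 376 vs 412); and
`05` prints the projection per distance, e.g.

```
d=  5.0 m   median     2.24   90% band [1.32, 3.00] seeds/m^2
d= 16.0 m   median     0.08   90% band [0.01, 0.17] seeds/m^2
median curve is below the 95-250 seeds/m^2 aerial band from 0.0 m outward
```

— the seed-limitation conclusion. There is also a CLI
(`seedrain simulate|preprocess|fit-glm|compare-glm|fit-fusion|forecast`)
wrapping the same library calls.

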