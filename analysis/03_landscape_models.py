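"""Fit the landscape negative-binomial models and rank variance structures.

Fits the no-structure and transect-structure models (the two ends of the
variance-structure ladder; pass --all for the full seven-model ladder plus
the two wind variants) and compares them with PSIS-LOO. Writes the fit
summaries and the LOO ranking under results/.
"""

import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"

from seedrain.datatypes import McmcConfig  # noqa: E402
from seedrain.glm import (  # noqa: E402
    GlmStructure,
    build_design,
    compare_loo,
    fit_glm,
    summarize_fit,
)
from seedrain.io import read_table, write_posterior  # noqa: E402

SEED = 20260930
MCMC = McmcConfig(warmup=1500, draws=1500, thin=10)


def main() -> None:
    structures = ["none", "transect"]
    if "--all" in sys.argv:
        structures = ["none", "site", "site_patch", "patch", "patch_transect",
                      "transect", "site_patch_transect"]
    traps = read_table(STUDY / "traps.csv", "traps")
    patches = read_table(STUDY / "patches.csv", "patches")
    transects = read_table(STUDY / "transects.csv", "transects")
    fits = {}
    for s in structures:
        frame = build_design(traps, patches, transects, GlmStructure(s))
        t0 = time.time()
        fit = fit_glm(frame, mcmc=MCMC, seed=SEED)
        fits[s] = fit
        print(f"{s:22s} max r-hat {fit.max_rhat():.3f} "
              f"({'converged' if fit.converged else 'NOT CONVERGED'}, "
              f"{time.time()-t0:.0f}s)")
        summarize_fit(fit).to_csv(ROOT / "results" / f"glm_summary_{s}.csv", index=False)
    if "--all" in sys.argv:
        for wind in ("orient", "binary"):
            frame = build_design(traps, patches, transects,
                                 GlmStructure("transect", wind=wind))
            fits[f"transect+{wind}"] = fit_glm(frame, mcmc=MCMC, seed=SEED)
    table = compare_loo(fits)
    table.to_csv(ROOT / "results" / "loo_comparison.csv", index=False)
    write_posterior(fits["transect"], ROOT / "results" / "posterior_glm_transect.csv")
    print("\nLOO ranking (best first):")
    print(table[["model", "elpd", "loo_ic", "se"]].to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
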