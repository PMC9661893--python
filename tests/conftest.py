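import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from seedrain.datatypes import (  # noqa: E402
    PatchInfo,
    SiteWind,
    TransectInfo,
    TrapObservation,
)
from seedrain.synthetic import StudyDesign, generate_design, simulate_counts_fusion  # noqa: E402


@pytest.fixture()
def toy_tables():
    """A hand-built minimal study: 1 site, 1 patch, 2 transects, 2 traps each."""
    patches = [PatchInfo("P1", "S1", 25, 30000.0, 750000.0, 0.40)]
    transects = [
        TransectInfo("P1T1", "P1", 90.0, 10.0, True),
        TransectInfo("P1T2", "P1", 270.0, 170.0, False),
    ]
    wind = [SiteWind("S1", ((80.0, 100.0),), 8.0)]
    traps = []
    for t in ("P1T1", "P1T2"):
        for d in (2.0, 10.0):
            for h in (0.1267, 0.38, 0.6333):
                traps.append(TrapObservation(
                    site_id="S1", patch_id="P1", transect_id=t,
                    trap_id=f"{t}D{d:g}", trap_kind="vertical",
                    dist_trap=d, capture_height=h, area=0.1267,
                    days_deployed=49.0, n_seeds=1 if d == 2.0 and h < 0.2 else 0,
                ))
    traps.append(TrapObservation(
        site_id="S1", patch_id="P1", transect_id="P1T1", trap_id="P1UC",
        trap_kind="under_crown", dist_trap=0.0, capture_height=0.05,
        area=0.01, days_deployed=49.0, n_seeds=3,
    ))
    return traps, patches, transects, wind


@pytest.fixture(scope="session")
def small_fusion_study():
    """A small simulated fusion study shared by read-only tests."""
    design = StudyDesign(n_sites=2, patches_per_site=3)
    tables = generate_design(design, seed=42)
    tab, truth = simulate_counts_fusion(tables, seed=43)
    return tab, truth
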