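"""Synthetic study generator.

Emulates the second-year field design — vertical traps at 2, 4, 6, 10, 14,
18, 22 and 26 m plus an under-crown trap, two transects per patch, several
patches per site — and draws counts from either the landscape GLM or the
fusion generative model with known parameters, recorded as ground truth
for recovery tests.

Default magnitudes are chosen so a ~750k-seed patch yields on the order of
ten seeds m^-2 near the source decaying to ~0 within ~15 m at the median,
with most trap records empty — the sparse regime such trapping studies
actually produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    CANOPY_BIN_MIDPOINTS,
    Constants,
    GroundTruth,
    PatchInfo,
    SiteWind,
    TransectInfo,
    TrapObservation,
    UNDER_CROWN,
    VERTICAL,
)
from .glm import GlmFrame, GlmStructure, build_design
from .kernel import transect_kernel
from .preprocess import standardize_days, wind_face, wind_orientation
from .wald import WaldInputs, sample_wald, wald_params


@dataclass
class StudyDesign:
    """Configuration of one synthetic trapping study (Year-2 layout)."""

    n_sites: int = 3
    patches_per_site: int = 5
    transects_per_patch: int = 2
    trap_distances: Tuple[float, ...] = (2, 4, 6, 10, 14, 18, 22, 26)
    include_under_crown: bool = True
    trap_width: float = 0.50          # m, vertical trap fabric width
    trap_height: float = 0.76         # m, vertical trap fabric height
    n_height_bands: int = 3
    under_crown_area: float = 0.01    # m² (10 x 10 cm frame)
    days_range: Tuple[float, float] = (42.0, 49.0)
    seeds_per_plant_meanlog: float = math.log(30000.0)
    seeds_per_plant_sdlog: float = 0.5
    n_reproductive_mean: float = 25.0
    wind_speed_range: Tuple[float, float] = (6.0, 12.0)  # m s^-1 daily max
    trap_loss_rate: float = 0.0       # fraction of vertical traps removed

    def height_band_midpoints(self) -> np.ndarray:
        edges = np.linspace(0.0, self.trap_height, self.n_height_bands + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    def band_area(self) -> float:
        return self.trap_width * self.trap_height / self.n_height_bands

    def validate(self) -> None:
        if self.n_sites < 1 or self.patches_per_site < 1 or self.transects_per_patch < 1:
            raise ValueError("counts in the design must be >= 1")
        d = np.asarray(self.trap_distances, dtype=float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("vertical trap distances must be non-negative and strictly increasing")
        if not (0 <= self.trap_loss_rate < 1):
            raise ValueError("trap_loss_rate must be in [0, 1)")


@dataclass
class StudyTables:
    traps: List[TrapObservation]
    patches: List[PatchInfo]
    transects: List[TransectInfo]
    wind: List[SiteWind]


def generate_design(design: Optional[StudyDesign] = None, seed: int = 0) -> StudyTables:
    """Generate fully-linked study tables with zero counts (filled later).

    Transect azimuths are uniform on [0, 360); canopy classes are drawn
    from the field-bin midpoints; gust headings are one or two random 20°
    intervals per site.
    """
    design = design or StudyDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    patches: List[PatchInfo] = []
    transects: List[TransectInfo] = []
    wind: List[SiteWind] = []
    traps: List[TrapObservation] = []
    mids = design.height_band_midpoints()
    for s in range(design.n_sites):
        site_id = f"S{s+1}"
        n_ranges = rng.integers(1, 3)
        headings = []
        for _ in range(n_ranges):
            lo = float(rng.uniform(0, 340))
            headings.append((lo, lo + 20.0))
        U = float(rng.uniform(*design.wind_speed_range))
        sw = SiteWind(site_id=site_id, gust_headings=tuple(headings), U=U)
        sw.validate()
        wind.append(sw)
        for p in range(design.patches_per_site):
            patch_id = f"{site_id}P{p+1}"
            n_rep = max(5, int(rng.poisson(design.n_reproductive_mean)))
            spp = float(rng.lognormal(design.seeds_per_plant_meanlog,
                                      design.seeds_per_plant_sdlog))
            canopy = float(rng.choice(CANOPY_BIN_MIDPOINTS))
            patch = PatchInfo(
                patch_id=patch_id, site_id=site_id, n_reproductive=n_rep,
                seeds_per_plant=spp, total_available_seed=spp * n_rep,
                canopy_height_class=canopy,
            )
            patch.validate()
            patches.append(patch)
            for t in range(design.transects_per_patch):
                transect_id = f"{patch_id}T{t+1}"
                az = float(rng.uniform(0, 360))
                wo = wind_orientation(az, headings)
                tr = TransectInfo(transect_id=transect_id, patch_id=patch_id,
                                  azimuth=az, wind_orient=wo, wind_face=wind_face(wo))
                tr.validate()
                transects.append(tr)
                days = float(rng.uniform(*design.days_range))
                for di, dist in enumerate(design.trap_distances):
                    if design.trap_loss_rate > 0 and rng.uniform() < design.trap_loss_rate:
                        continue  # trap lost to animals/weather: absent, not zero
                    for h in mids:
                        obs = TrapObservation(
                            site_id=site_id, patch_id=patch_id,
                            transect_id=transect_id,
                            trap_id=f"{transect_id}D{dist:g}",
                            trap_kind=VERTICAL, dist_trap=float(dist),
                            capture_height=float(h), area=design.band_area(),
                            days_deployed=days, n_seeds=0,
                        )
                        obs.validate()
                        traps.append(obs)
                if design.include_under_crown and t == 0:
                    obs = TrapObservation(
                        site_id=site_id, patch_id=patch_id, transect_id=transect_id,
                        trap_id=f"{patch_id}UC", trap_kind=UNDER_CROWN,
                        dist_trap=0.0, capture_height=0.05,
                        area=design.under_crown_area,
                        days_deployed=days, n_seeds=0,
                    )
                    obs.validate()
                    traps.append(obs)
    return StudyTables(traps=traps, patches=patches, transects=transects, wind=wind)


DEFAULT_GLM_TRUTH: Dict[str, object] = {
    # on the scaled-covariate scale of build_design
    "gamma": (-1.0, -0.3, -1.5, 0.4, 0.1),
    "phi": 1.0,
    "sd": {"intercept": 0.8, "height": 0.3, "distance": 0.3, "height_distance": 0.2},
}

DEFAULT_FUSION_TRUTH: Dict[str, object] = {
    # calibrated so a 750k-seed patch gives ~10 seeds/m² at the source,
    # a gradual decline over the trap span (~2 seeds/m² at 5 m) and ~0 by
    # 16 m — the regime of the median projected curve
    "a": 1.0,
    "b": 25.0,     # m²
    "f": 1.0,      # per 1000 available seeds
    "phi2": 2.0,
    "nu1": 0.2,
    "nu2": 0.2,
    "log_scale": True,
}


def simulate_counts_glm(
    tables: StudyTables,
    params: Optional[Dict[str, object]] = None,
    structure: Optional[GlmStructure] = None,
    seed: int = 0,
    constants: Optional[Constants] = None,
) -> Tuple[StudyTables, GroundTruth]:
    """Draw vertical-trap counts from the landscape NB model.

    Coefficients apply to the scaled covariates exactly as the fitting
    design builds them; group deviations are drawn Normal(0, sd) per level
    of the structure's factors for each varying term. Under-crown records
    (outside the landscape models) keep zero counts.
    """
    params = {**DEFAULT_GLM_TRUTH, **(params or {})}
    structure = structure or GlmStructure(variant="transect")
    constants = constants or Constants()
    rng = np.random.default_rng(seed)
    frame = build_design(tables.traps, tables.patches, tables.transects,
                         structure, constants)
    gamma = np.asarray(params["gamma"], dtype=float)
    if gamma.size != frame.X.shape[1]:
        raise ValueError(
            f"gamma has {gamma.size} entries but the design has {frame.X.shape[1]} columns"
        )
    phi = float(params["phi"])
    eta = frame.offset + frame.X @ gamma
    devs: Dict[str, Dict[str, np.ndarray]] = {}
    for fi, f in enumerate(frame.structure.factors):
        L = len(frame.group_levels[f])
        devs[f] = {}
        for t in frame.structure.varying_terms:
            sd = float(params["sd"][t])
            dv = rng.normal(0.0, sd, size=L)
            devs[f][t] = dv
            col = {"intercept": 0, "height": 1, "distance": 2, "height_distance": 3}[t]
            eta = eta + frame.X[:, col] * dv[frame.group_idx[fi]]
    if np.any(eta > 30):
        raise ValueError("exp(linear predictor) overflows; use smaller coefficients")
    mu = np.exp(eta)
    counts = rng.negative_binomial(phi, phi / (phi + mu))
    count_by_obs = dict(zip(frame.obs_ids, counts))
    new_traps = []
    for o in tables.traps:
        key = f"{o.trap_id}@h{o.capture_height:g}"
        n = int(count_by_obs.get(key, 0))
        new_traps.append(TrapObservation(**{**o.__dict__, "n_seeds": n}))
    truth = GroundTruth(
        generator="glm",
        params={
            "gamma": tuple(gamma), "phi": phi,
            "sd": dict(params["sd"]),
            "deviations": {f: {t: v.tolist() for t, v in d.items()} for f, d in devs.items()},
            "structure": structure.variant,
            "scaling": frame.scaling,
        },
        seed=seed,
    )
    return StudyTables(new_traps, tables.patches, tables.transects, tables.wind), truth


def simulate_counts_fusion(
    tables: StudyTables,
    params: Optional[Dict[str, object]] = None,
    seed: int = 0,
    constants: Optional[Constants] = None,
) -> Tuple[StudyTables, GroundTruth]:
    """Draw counts from the fused 2Dt + WALD generative model.

    Every record caught at or above the height cutoff gets one Wald-drawn
    latent increment; the true latents are recorded in the ground truth.
    """
    params = {**DEFAULT_FUSION_TRUTH, **(params or {})}
    constants = constants or Constants()
    rng = np.random.default_rng(seed)
    a, b, f = float(params["a"]), float(params["b"]), float(params["f"])
    phi2 = float(params["phi2"])
    nu1, nu2 = float(params["nu1"]), float(params["nu2"])
    log_scale = bool(params["log_scale"])
    tlevels = sorted({o.transect_id for o in tables.traps})
    omega = params.get("omega")
    delta = params.get("delta")
    omega = rng.standard_normal(len(tlevels)) if omega is None else np.asarray(omega, float)
    delta = rng.standard_normal(len(tlevels)) if delta is None else np.asarray(delta, float)
    kern = {
        t: transect_kernel(a, b, omega[i], delta[i], nu1, nu2, log_scale=log_scale)
        for i, t in enumerate(tlevels)
    }
    patch_by_id = {p.patch_id: p for p in tables.patches}
    U_by_site = {w.site_id: w.U for w in tables.wind}
    new_traps = []
    latents = []
    for o in tables.traps:
        patch = patch_by_id[o.patch_id]
        below = (o.trap_kind == UNDER_CROWN) or (o.capture_height < constants.height_cutoff)
        if below:
            dist_ground = o.dist_trap
        else:
            wi = WaldInputs(ht=o.capture_height, U=U_by_site[o.site_id],
                            V=constants.terminal_velocity, k=constants.k,
                            c=patch.canopy_height_class)
            inc = float(sample_wald(wald_params(wi), 1, int(rng.integers(2 ** 31)))[0])
            dist_ground = o.dist_trap + inc
        a_t, b_t = kern[o.transect_id]
        disp = a_t / (np.pi * b_t) * (1.0 + dist_ground ** 2 / b_t) ** (-(a_t + 1.0))
        stdays = standardize_days(o.days_deployed, constants.max_days)
        mu = o.area * disp * (f * patch.total_available_seed / constants.fecund_scale) * stdays
        n = int(rng.negative_binomial(phi2, phi2 / (phi2 + mu))) if mu > 0 else 0
        latents.append(dist_ground)
        new_traps.append(TrapObservation(**{**o.__dict__, "n_seeds": n}))
    truth = GroundTruth(
        generator="fusion",
        params={
            "a": a, "b": b, "f": f, "phi2": phi2, "nu1": nu1, "nu2": nu2,
            "log_scale": log_scale, "omega": omega.tolist(), "delta": delta.tolist(),
            "transect_levels": tlevels,
            "dist_ground": latents,
        },
        seed=seed,
    )
    return StudyTables(new_traps, tables.patches, tables.transects, tables.wind), truth
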