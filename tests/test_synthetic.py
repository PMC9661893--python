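"""Synthetic-study generator: design arithmetic, integrity, count regimes."""

import collections

import numpy as np
import pytest

from seedrain.datatypes import VERTICAL
from seedrain.glm import GlmStructure
from seedrain.preprocess import rse_by_distance, seed_density, standardize_days
from seedrain.synthetic import (
    StudyDesign,
    generate_design,
    simulate_counts_fusion,
    simulate_counts_glm,
)


class TestGenerateDesign:
    def test_default_counts_match_config_arithmetic(self):
        design = StudyDesign(n_sites=3, patches_per_site=5)
        t = generate_design(design, seed=0)
        assert len(t.patches) == 15
        assert len(t.transects) == 30
        vertical = [o for o in t.traps if o.trap_kind == VERTICAL]
        # 30 transects x 8 distances x 3 height bands
        assert len(vertical) == 30 * 8 * 3
        under = [o for o in t.traps if o.trap_kind != VERTICAL]
        assert len(under) == 15  # one per patch

    def test_referential_integrity(self):
        t = generate_design(seed=3)
        patch_ids = {p.patch_id for p in t.patches}
        transect_ids = {tr.transect_id for tr in t.transects}
        site_ids = {w.site_id for w in t.wind}
        for o in t.traps:
            assert o.patch_id in patch_ids
            assert o.transect_id in transect_ids
            assert o.site_id in site_ids
        for tr in t.transects:
            assert tr.patch_id in patch_ids

    def test_deterministic_under_seed(self):
        assert generate_design(seed=9).traps == generate_design(seed=9).traps
        assert generate_design(seed=9).wind == generate_design(seed=9).wind

    def test_all_records_validate(self):
        t = generate_design(seed=5)
        for group in (t.traps, t.patches, t.transects, t.wind):
            for rec in group:
                rec.validate()

    def test_trap_loss_removes_rows_not_zeroes(self):
        lossy = StudyDesign(trap_loss_rate=0.3)
        t = generate_design(lossy, seed=1)
        full = generate_design(StudyDesign(), seed=1)
        n_lossy = sum(1 for o in t.traps if o.trap_kind == VERTICAL)
        n_full = sum(1 for o in full.traps if o.trap_kind == VERTICAL)
        assert n_lossy < n_full

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            generate_design(StudyDesign(patches_per_site=0), seed=0)


class TestSimulateGlm:
    def test_negative_distance_effect_shows_in_counts(self):
        """Mean count decreasing with distance under strongly negative gamma2."""
        totals = collections.defaultdict(list)
        for seed in range(5):
            t = generate_design(StudyDesign(n_sites=2, patches_per_site=3), seed=seed)
            tab, _ = simulate_counts_glm(t, structure=GlmStructure("transect"), seed=seed)
            for o in tab.traps:
                if o.trap_kind == VERTICAL:
                    totals[o.dist_trap].append(o.n_seeds)
        means = {d: np.mean(v) for d, v in totals.items()}
        dists = sorted(means)
        assert means[dists[0]] > means[dists[-1]]
        near = np.mean([means[d] for d in dists[:3]])
        far = np.mean([means[d] for d in dists[-3:]])
        assert near > 3 * far

    def test_overdispersion_visible_at_small_phi(self):
        t = generate_design(StudyDesign(n_sites=2, patches_per_site=3), seed=2)
        tab, _ = simulate_counts_glm(
            t, params={"phi": 0.3}, structure=GlmStructure("none"), seed=3)
        y = np.array([o.n_seeds for o in tab.traps if o.trap_kind == VERTICAL])
        assert y.var() > 2 * y.mean()

    def test_ground_truth_records_generator(self):
        t = generate_design(StudyDesign(n_sites=1, patches_per_site=2), seed=4)
        _, truth = simulate_counts_glm(t, structure=GlmStructure("transect"), seed=5)
        assert truth.generator == "glm"
        assert len(truth.params["gamma"]) == 5
        assert "transect" in truth.params["deviations"]


class TestSimulateFusion:
    def test_zero_fecundity_patches_all_zero(self):
        t = generate_design(StudyDesign(n_sites=1, patches_per_site=2), seed=6)
        patches = [type(p)(**{**p.__dict__, "seeds_per_plant": 0.0,
                              "total_available_seed": 0.0}) for p in t.patches]
        t2 = type(t)(t.traps, patches, t.transects, t.wind)
        tab, _ = simulate_counts_fusion(t2, seed=7)
        assert all(o.n_seeds == 0 for o in tab.traps)

    def test_far_captures_occur_with_large_scale(self):
        hits = 0
        for seed in range(8):
            t = generate_design(StudyDesign(n_sites=2, patches_per_site=3), seed=seed)
            tab, _ = simulate_counts_fusion(t, params={"b": 120.0}, seed=seed + 50)
            hits += sum(o.n_seeds for o in tab.traps if o.dist_trap == 26.0)
        assert hits > 0

    def test_truth_latents_respect_cutoff_rule(self):
        t = generate_design(StudyDesign(n_sites=1, patches_per_site=2), seed=8)
        tab, truth = simulate_counts_fusion(t, seed=9)
        lat = np.array(truth.params["dist_ground"])
        for o, d in zip(tab.traps, lat):
            if o.trap_kind != VERTICAL or o.capture_height < 0.2:
                assert d == o.dist_trap
            else:
                assert d > o.dist_trap

    def test_rse_increases_with_distance_on_average(self):
        """Dispersal gets relatively more variable away from the source."""
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(6):
            t = generate_design(seed=seed)
            tab, _ = simulate_counts_fusion(t, seed=seed + 30)
            dens, dist = [], []
            for o in tab.traps:
                if o.trap_kind != VERTICAL:
                    continue
                dens.append(seed_density(o.n_seeds, o.area,
                                         standardize_days(o.days_deployed)))
                dist.append(o.dist_trap)
            rows = [r for r in rse_by_distance(dens, dist) if r.rse is not None]
            if len(rows) >= 3:
                rho = spearmanr([r.dist for r in rows], [r.rse for r in rows]).statistic
                rhos.append(rho)
        assert np.mean(rhos) > 0
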