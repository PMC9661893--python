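"""Fusion model: joint likelihood oracle, frame assembly, small-fit contracts."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from seedrain.datatypes import Constants, McmcConfig
from seedrain.fusion import build_fusion_frame, fit_fusion, fusion_loglik
from scipy.special import gammaln
from seedrain.kernel import kernel_2dt
from seedrain.synthetic import StudyDesign, generate_design, simulate_counts_fusion
from seedrain.wald import WaldInputs, wald_logpdf, wald_params

FAST_MCMC = McmcConfig(warmup=300, draws=300, thin=5)


def _params_for(transects, dist_ground, f=1.0, phi2=2.0, a=1.0, b=25.0):
    return {
        "a": a, "b": b, "f": f, "phi2": phi2,
        "transect_kernels": {t.transect_id: (a, b) for t in transects},
        "dist_ground": dist_ground,
    }


class TestFusionLoglik:
    def test_matches_term_by_term_oracle(self, toy_tables):
        """Brute-force recomputation of every NB and Wald term on 5 records."""
        traps, patches, transects, wind = toy_tables
        obs = traps[:5]
        consts = Constants()
        dg = []
        for o in obs:
            dg.append(o.dist_trap if o.capture_height < 0.20 else o.dist_trap + 3.0)
        params = _params_for(transects, np.array(dg))
        got = fusion_loglik(obs, params, patches, wind)

        expect = 0.0
        for o, d in zip(obs, dg):
            disp = params["a"] / (math.pi * params["b"]) \
                * (1 + d ** 2 / params["b"]) ** (-(params["a"] + 1))
            mu = o.area * disp * (params["f"] * 750000.0 / 1000.0) * (o.days_deployed / 49.0)
            expect += stats.nbinom.logpmf(o.n_seeds, params["phi2"],
                                          params["phi2"] / (params["phi2"] + mu))
            if o.capture_height >= 0.20:
                wp = wald_params(WaldInputs(ht=o.capture_height, U=8.0, c=0.40))
                expect += float(wald_logpdf(np.array([3.0]), wp)[0])
        assert got == pytest.approx(float(expect), rel=1e-9)

    def test_poisson_limit_in_phi2(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        obs = traps[:4]
        dg = np.array([o.dist_trap if o.capture_height < 0.2 else o.dist_trap + 2.0
                       for o in obs])
        lls = []
        for phi2 in (1e6, 1e8):
            lls.append(fusion_loglik(obs, _params_for(transects, dg, phi2=phi2),
                                     patches, wind))
        pois = 0.0
        for o, d in zip(obs, dg):
            disp = kernel_2dt(d, 1.0, 25.0)
            mu = o.area * disp * 750.0 * (o.days_deployed / 49.0)
            pois += stats.poisson.logpmf(o.n_seeds, mu)
            if o.capture_height >= 0.2:
                wp = wald_params(WaldInputs(ht=o.capture_height, U=8.0, c=0.40))
                pois += float(wald_logpdf(np.array([2.0]), wp)[0])
        assert lls[1] == pytest.approx(float(pois), abs=1e-4)

    def test_below_cutoff_contributes_no_wald_term(self, toy_tables):
        """Shrinking the Wald-increment scale changes nothing for low records."""
        traps, patches, transects, wind = toy_tables
        low = [o for o in traps if o.capture_height < 0.2][:3]
        dg = np.array([o.dist_trap for o in low])
        v1 = fusion_loglik(low, _params_for(transects, dg), patches, wind)
        # same records with a different wind speed: Wald prior would differ,
        # but below-cutoff records must be insensitive to it
        wind2 = [type(w)(site_id=w.site_id, gust_headings=w.gust_headings, U=3.0)
                 for w in wind]
        v2 = fusion_loglik(low, _params_for(transects, dg), patches, wind2)
        assert v1 == pytest.approx(v2)

    def test_latent_below_trap_distance_rejected(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        high = [o for o in traps if o.capture_height > 0.2][:1]
        with pytest.raises(ValueError, match="latent"):
            fusion_loglik(high, _params_for(transects, np.array([high[0].dist_trap - 1])),
                          patches, wind)


class TestFusionFrame:
    def test_below_cutoff_marking(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        frame = build_fusion_frame(traps, patches, transects, wind)
        heights = np.array([o.capture_height for o in traps])
        kinds = np.array([o.trap_kind for o in traps])
        np.testing.assert_array_equal(
            frame.below, (heights < 0.2) | (kinds == "under_crown"))
        assert np.all(frame.n_nodes[frame.below] == 1)
        assert np.all(frame.n_nodes[~frame.below] == 8)

    def test_nodes_exceed_trap_distance_above_cutoff(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        frame = build_fusion_frame(traps, patches, transects, wind)
        above = ~frame.below
        assert np.all(frame.nodes[above] > frame.dist_trap[above][:, None])

    def test_node_grid_matches_wald_quantiles(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        frame = build_fusion_frame(traps, patches, transects, wind)
        i = int(np.argmax(~frame.below))
        o = traps[i]
        wp = wald_params(WaldInputs(ht=o.capture_height, U=8.0, c=0.40))
        probs = (np.arange(8) + 0.5) / 8
        expect = o.dist_trap + stats.invgauss.ppf(probs, wp.mu / wp.lam, scale=wp.lam)
        np.testing.assert_allclose(frame.nodes[i], expect)


@pytest.fixture(scope="module")
def tiny_fusion_fit():
    design = StudyDesign(n_sites=1, patches_per_site=4)
    tables = generate_design(design, seed=51)
    tab, truth = simulate_counts_fusion(tables, seed=52)
    frame = build_fusion_frame(tab.traps, tab.patches, tab.transects, tab.wind)
    fit = fit_fusion(frame, mcmc=FAST_MCMC, seed=53)
    return frame, fit, truth


class TestFitFusion:
    def test_positivity_and_shapes(self, tiny_fusion_fit):
        frame, fit, _ = tiny_fusion_fit
        for nm in ("a", "b", "f", "phi2", "nu1", "nu2"):
            assert np.all(fit.flat(nm) > 0)
        assert fit.draws["omega"].shape[-1] == frame.n_transects
        assert fit.pointwise_loglik.shape[-1] == frame.n_obs

    def test_latent_contract(self, tiny_fusion_fit):
        """Latent draws sit at dist_trap below the cutoff, above it otherwise."""
        frame, fit, _ = tiny_fusion_fit
        lat = fit.flat("dist_ground")
        below = frame.below
        np.testing.assert_array_equal(
            lat[:, below], np.broadcast_to(frame.dist_trap[below], lat[:, below].shape))
        assert np.all(lat[:, ~below] > frame.dist_trap[~below][None, :])

    def test_plugin_mode_runs_and_matches_contract(self):
        design = StudyDesign(n_sites=1, patches_per_site=2)
        tables = generate_design(design, seed=61)
        tab, _ = simulate_counts_fusion(tables, seed=62)
        frame = build_fusion_frame(tab.traps, tab.patches, tab.transects, tab.wind)
        fit = fit_fusion(frame, mcmc=FAST_MCMC, seed=63, latent_mode="plugin")
        assert fit.meta["latent_mode"] == "plugin"
        assert np.all(fit.flat("a") > 0)

    def test_kernel_normalized_for_posterior_draws(self, tiny_fusion_fit):
        """Every posterior (a_t, b_t) is a proper density over the plane."""
        from scipy.integrate import quad

        _, fit, _ = tiny_fusion_fit
        a = fit.flat("a")
        b = fit.flat("b")
        idx = np.linspace(0, a.size - 1, 10).astype(int)
        for i in idx:
            integral, _ = quad(lambda d: kernel_2dt(d, a[i], b[i]) * 2 * np.pi * d,
                               0, np.inf, limit=200)
            assert integral == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_invariant_to_transect_relabelling(self, toy_tables):
        """Permuting transect labels together with their deviations leaves
        the marginal log-posterior unchanged (exchangeability)."""
        from seedrain.fusion import _N_GLOBAL, _fusion_logpost_many

        traps, patches, transects, wind = toy_tables
        frame = build_fusion_frame(traps, patches, transects, wind)
        T = frame.n_transects
        rng = np.random.default_rng(0)
        p = rng.normal(0, 0.5, size=_N_GLOBAL + 2 * T)
        lg = gammaln(frame.y.astype(float) + 1.0)
        args_tail = (lg, 2.0, 100.0, 1.0, 0.3, 0.01, 0.01, True)
        perm = rng.permutation(T)
        inv = np.argsort(perm)
        p_perm = p.copy()
        p_perm[_N_GLOBAL:_N_GLOBAL + T] = p[_N_GLOBAL:_N_GLOBAL + T][perm]
        p_perm[_N_GLOBAL + T:] = p[_N_GLOBAL + T:][perm]
        tidx_perm = inv[frame.transect_idx]
        v1 = _fusion_logpost_many(p[None, :], frame.y.astype(float), frame.log_eff,
                                  frame.transect_idx,
                                  np.ascontiguousarray(frame.nodes ** 2),
                                  frame.n_nodes, *args_tail)[0]
        v2 = _fusion_logpost_many(p_perm[None, :], frame.y.astype(float),
                                  frame.log_eff, tidx_perm.astype(np.int64),
                                  np.ascontiguousarray(frame.nodes ** 2),
                                  frame.n_nodes, *args_tail)[0]
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_single_transect_rejected(self, toy_tables):
        traps, patches, transects, wind = toy_tables
        only_t1 = [o for o in traps if o.transect_id == "P1T1"]
        frame = build_fusion_frame(only_t1, patches, transects, wind)
        with pytest.raises(ValueError, match="transect"):
            fit_fusion(frame, mcmc=FAST_MCMC, seed=1)
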