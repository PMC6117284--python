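"""Network orchestration, deconvolution recursion and the pooled baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riverunmix import (
    McmcSettings,
    PosteriorDraws,
    RunConfig,
    WatershedGraph,
    assemble_node_sources,
    deconvolute,
    fit_network,
    pooled_fit,
    summarize_composite,
    unmixing_order,
)
from riverunmix import synthetic_data as syn
from riverunmix.io_report import TEST_PROFILE


class TestUnmixingOrder:
    def test_chain_is_upstream_first(self):
        g = syn.make_topology("longitudinal")
        assert unmixing_order(g) == ["M1", "M2", "M3", "M4"]

    def test_distributed_respects_confluences(self):
        g = syn.make_topology("distributed")
        order = unmixing_order(g)
        assert order.index("M1") < order.index("M3")
        assert order.index("M2") < order.index("M3")
        assert order.index("M3") < order.index("M5")
        assert order.index("M4") < order.index("M5")

    def test_singleton(self):
        g = syn.make_topology("simple")
        assert unmixing_order(g) == ["M"]


class TestAssembleNodeSources:
    def test_upstream_pseudo_source_plus_locals(self):
        truth = syn.build_truth(syn.make_topology("longitudinal"), seed=1, n_tracers=3)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        spec = assemble_node_sources(truth.graph, "M3", mixtures, sources)
        assert spec.sources == ["M2", "S_A3", "S_D3"]
        # pseudo-source moments come from the upstream mixture samples
        up = mixtures["M2"].data[spec.panel]
        np.testing.assert_allclose(spec.mean[0], up.mean(axis=0))
        np.testing.assert_allclose(spec.sd[0], up.std(axis=0, ddof=1))

    def test_headwater_has_local_sources_only(self):
        truth = syn.build_truth(syn.make_topology("longitudinal"), seed=1, n_tracers=3)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        spec = assemble_node_sources(truth.graph, "M1", mixtures, sources)
        assert spec.sources == ["S_A1", "S_B1", "S_C1"]

    def test_confluence_without_locals_uses_upstream_nodes(self, confluence_graph):
        truth = syn.pooling_hurts_truth(seed=0)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        spec = assemble_node_sources(truth.graph, "M3", mixtures, sources)
        assert spec.sources == ["M1", "M2"]

    def test_upstream_with_single_sample_rejected(self):
        truth = syn.pooling_hurts_truth(seed=0)
        truth.n_mix = {"M1": 1, "M2": 4, "M3": 4}
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        with pytest.raises(ValueError, match=">= 2"):
            assemble_node_sources(truth.graph, "M3", mixtures, sources)


class TestDeconvolute:
    def test_point_mass_confluence_worked_example(self, confluence_graph, confluence_point_mass):
        """Chaining degenerate node posteriors reproduces exact hand
        arithmetic: e.g. 0.70 x 0.74 = 0.518 for the class reached only
        through the first tributary."""
        comp = deconvolute(confluence_graph, confluence_point_mass, pairing_seed=1)
        assert comp.mean("M3", "EW", "BLF") == pytest.approx(0.518, abs=1e-12)
        assert comp.mean("M3", "EW", "MF") == pytest.approx(0.19 * 0.74 + 0.75 * 0.26, abs=1e-12)
        assert comp.mean("M3", "EW", "LL") == pytest.approx(0.0534, abs=1e-12)
        assert comp.mean("M3", "EW", "UP") == pytest.approx(0.093, abs=1e-12)

    def test_unit_upstream_proportion_is_pass_through(self):
        g = WatershedGraph(
            nodes=["M1", "M2"], edges=[("M1", "M2")],
            local_sources={"M1": {"S_A": "A", "S_B": "B"}, "M2": {}},
            classes=["A", "B"],
        )
        rng = np.random.default_rng(4)
        p1 = rng.dirichlet([2, 2], size=40)
        posts = {
            "M1": PosteriorDraws(
                node_id="M1", sources=["S_A", "S_B"], levels=["all"], panel=[],
                draws=p1[None, :, :], tau_sampled=False,
            ),
            "M2": PosteriorDraws.point_mass("M2", {"all": {"M1": 1.0}}, n_draws=40, n_chains=1),
        }
        comp = deconvolute(g, posts, pairing_seed=0)
        # q = 1 identically: composite equals the (permuted) upstream draws
        assert sorted(comp.draws["M2"]["all"][:, 0]) == pytest.approx(sorted(p1[:, 0]))
        np.testing.assert_allclose(comp.draws["M2"]["all"], comp.draws["M1"]["all"])

    def test_leaf_node_maps_through_class_indicator(self):
        g = WatershedGraph(
            nodes=["M"], edges=[],
            local_sources={"M": {"S_A1": "A", "S_A2": "A", "S_B": "B"}},
            classes=["A", "B"],
        )
        posts = {
            "M": PosteriorDraws.point_mass(
                "M", {"all": {"S_A1": 0.2, "S_A2": 0.3, "S_B": 0.5}}
            )
        }
        comp = deconvolute(g, posts, pairing_seed=0)
        assert comp.mean("M", "all", "A") == pytest.approx(0.5)
        assert comp.mean("M", "all", "B") == pytest.approx(0.5)

    def test_composite_simplex_conservation(self):
        truth = syn.build_truth(syn.make_topology("distributed"), seed=8, n_tracers=3)
        posts = syn.point_mass_posteriors(truth)
        comp = deconvolute(truth.graph, posts, pairing_seed=3)
        for node, by_level in comp.draws.items():
            for arr in by_level.values():
                np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-10)
                assert (arr >= -1e-12).all()

    def test_pairing_seed_invariance_of_means(self, rng):
        g = WatershedGraph(
            nodes=["M1", "M2"], edges=[("M1", "M2")],
            local_sources={"M1": {"S_A": "A", "S_B": "B"}, "M2": {"S_B2": "B"}},
            classes=["A", "B"],
        )
        n = 4000
        posts = {
            "M1": PosteriorDraws(
                node_id="M1", sources=["S_A", "S_B"], levels=["all"], panel=[],
                draws=rng.dirichlet([5, 5], size=n)[None], tau_sampled=False,
            ),
            "M2": PosteriorDraws(
                node_id="M2", sources=["M1", "S_B2"], levels=["all"], panel=[],
                draws=rng.dirichlet([8, 2], size=n)[None], tau_sampled=False,
            ),
        }
        means = []
        for seed in (0, 1):
            comp = deconvolute(g, posts, pairing_seed=seed)
            means.append(comp.mean("M2", "all", "A"))
        # independent node posteriors: any pairing gives the same mean up to MC error
        mc_se = 3 * 0.25 / np.sqrt(n)
        assert abs(means[0] - means[1]) < 3 * mc_se

    def test_monotone_dampening_through_single_edge(self, confluence_graph, confluence_point_mass):
        # BLF reaches M3 only via M1, so its composite cannot exceed M1's share
        comp = deconvolute(confluence_graph, confluence_point_mass, pairing_seed=0)
        q_m1 = 0.74
        assert (comp.draws["M3"]["EW"][:, comp.classes.index("BLF")] <= q_m1 + 1e-12).all()

    def test_unalignable_levels_raise(self, confluence_graph):
        posts = {
            "M1": PosteriorDraws.point_mass("M1", {"EW": {"BLF": 0.7, "MF": 0.19, "LL": 0.03, "UP": 0.08}}),
            "M2": PosteriorDraws.point_mass("M2", {"LW": {"MF": 0.75, "LL": 0.12, "UP": 0.13}}),
            "M3": PosteriorDraws.point_mass("M3", {"EW": {"M1": 0.74, "M2": 0.26}}),
        }
        with pytest.raises(ValueError, match="level map"):
            deconvolute(confluence_graph, posts, pairing_seed=0)
        comp = deconvolute(
            confluence_graph, posts, pairing_seed=0, level_map={("M2", "EW"): "LW"}
        )
        assert comp.mean("M3", "EW", "MF") == pytest.approx(0.3356)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_point_mass_truth_matches_exact_composite(self, seed):
        """Property: on random topologies, deconvoluting point-mass posteriors
        at the truth equals the exact composite recursion."""
        rng = np.random.default_rng(seed)
        graph = syn.random_topology(rng)
        truth = syn.build_truth(graph, seed=seed, n_tracers=3)
        posts = syn.point_mass_posteriors(truth, n_draws=5)
        comp = deconvolute(graph, posts, pairing_seed=seed)
        exact = syn.true_composite(truth)
        for node in graph.nodes:
            for cls in graph.classes:
                assert comp.mean(node, "all", cls) == pytest.approx(
                    exact[node]["all"][cls], abs=1e-10
                )


class TestFitNetwork:
    def test_two_node_chain_fits_in_order(self, test_mcmc):
        g = WatershedGraph(
            nodes=["M1", "M2"], edges=[("M1", "M2")],
            local_sources={"M1": {"S_A": "A", "S_B": "B"}, "M2": {"S_B2": "B"}},
            classes=["A", "B"],
        )
        truth = syn.build_truth(g, seed=21, n_tracers=4, n_mix=6)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        cfg = RunConfig(seed=21, mcmc=McmcSettings(**TEST_PROFILE))
        posts = fit_network(g, mixtures, sources, cfg)
        assert set(posts.posteriors) == {"M1", "M2"}
        assert posts["M2"].sources == ["M1", "S_B2"]
        assert posts.reports["M1"].passed

    def test_single_node_graph_reduces_to_direct_fit(self, test_mcmc):
        from riverunmix.mixing_model import run_mcmc
        from riverunmix.deconvolution import _node_seed

        truth = syn.recovery_truth(seed=2)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        cfg = RunConfig(seed=2, mcmc=McmcSettings(**TEST_PROFILE))
        posts = fit_network(truth.graph, mixtures, sources, cfg)
        spec = assemble_node_sources(truth.graph, "M", mixtures, sources, cfg)
        direct = run_mcmc(
            spec, mixtures["M"], test_mcmc(seed=_node_seed(cfg.seed, 0))
        )
        assert np.array_equal(posts["M"].draws, direct.draws)


class TestPooledFit:
    def test_classes_merged_across_subwatersheds(self, test_mcmc):
        truth = syn.pooling_hurts_truth(seed=5)
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        cfg = RunConfig(seed=5, mcmc=McmcSettings(**TEST_PROFILE))
        post = pooled_fit(truth.graph, mixtures, sources, cfg)
        assert post.sources == ["A", "B"]
        assert post.levels == ["M1", "M2", "M3"]  # node as factor

    def test_missing_class_rejected(self):
        truth = syn.pooling_hurts_truth(seed=5)
        g = truth.graph
        bad = WatershedGraph(
            nodes=g.nodes, edges=g.edges, local_sources=g.local_sources,
            classes=["A", "B", "C"],
        )
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        cfg = RunConfig(seed=5, mcmc=McmcSettings(**TEST_PROFILE))
        with pytest.raises(ValueError, match="no sub-watershed"):
            pooled_fit(bad, mixtures, sources, cfg)

    def test_pooled_agrees_with_deconv_under_exchangeable_sources(self, test_mcmc):
        """When source signatures are identical across sub-watersheds,
        pooling loses nothing: pooled and deconvoluted composite means agree."""
        truth = syn.pooling_hurts_truth(seed=13)
        # make class signatures identical across the two tributaries
        truth.signatures["S_A2"] = truth.signatures["S_A1"].copy()
        truth.signatures["S_B2"] = truth.signatures["S_B1"].copy()
        mixtures = syn.simulate_mixtures(truth)
        sources = syn.simulate_sources(truth)
        cfg = RunConfig(seed=13, mcmc=McmcSettings(**TEST_PROFILE))
        posts = fit_network(truth.graph, mixtures, sources, cfg)
        comp = deconvolute(truth.graph, posts, pairing_seed=13)
        pooled = pooled_fit(truth.graph, mixtures, sources, cfg)
        pooled_a = pooled.p_draws("M3")[:, pooled.sources.index("A")].mean()
        assert abs(comp.mean("M3", "all", "A") - pooled_a) < 0.05


class TestSummarize:
    def test_point_mass_summary_has_zero_sd(self, confluence_graph, confluence_point_mass):
        comp = deconvolute(confluence_graph, confluence_point_mass, pairing_seed=0)
        summary = summarize_composite(comp)
        m3 = summary[(summary["node"] == "M3") & (summary["source"] == "BLF")]
        assert m3["sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert set(summary.columns) >= {"node", "level", "source", "mean", "sd", "q2.5", "q97.5"}

    def test_mean_of_product_equals_product_of_means(self, rng):
        g = WatershedGraph(
            nodes=["M1", "M2"], edges=[("M1", "M2")],
            local_sources={"M1": {"S_A": "A", "S_B": "B"}, "M2": {"S_C": "B"}},
            classes=["A", "B"],
        )
        n = 6000
        p_up = rng.dirichlet([3, 3], size=n)
        q = rng.dirichlet([4, 4], size=n)
        posts = {
            "M1": PosteriorDraws(node_id="M1", sources=["S_A", "S_B"], levels=["all"],
                                 panel=[], draws=p_up[None], tau_sampled=False),
            "M2": PosteriorDraws(node_id="M2", sources=["M1", "S_C"], levels=["all"],
                                 panel=[], draws=q[None], tau_sampled=False),
        }
        comp = deconvolute(g, posts, pairing_seed=2)
        got = comp.mean("M2", "all", "A")
        expected = q[:, 0].mean() * p_up[:, 0].mean()
        se = 3 * 0.25 / np.sqrt(n)
        assert abs(got - expected) < 3 * se
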