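import networkx as nx
import numpy as np
import pytest

from oracles import anchors_connected_bfs
from tppin.geneset import GeneSet
from tppin import synthetic
from tppin.synthetic import (
    ScenarioParameterError,
    SyntheticScenario,
    anchor_sets,
    backbone_link_set,
    correlation_matrix,
    generate_annotations,
    generate_expression,
    generate_network,
    scenario_from_manifest,
    write_scenario,
)


def tiny_scenario(**kw):
    base = dict(n_genes=10, n_samples=30, n_links=9, module_spec=[],
                anchor_sizes=(1, 1, 1), backbone_length=3, missing_rate=0.0,
                seed=0)
    base.update(kw)
    return SyntheticScenario(**base)


class TestGenerateNetwork:
    def test_counts_forced_by_construction(self):
        g = generate_network(tiny_scenario())
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 9
        anchors = anchor_sets(g)
        assert anchors_connected_bfs(
            g, anchors["tcr_complex"].members, anchors["nfkb"].members
        )

    def test_same_seed_identical_edge_sets(self):
        g1 = generate_network(tiny_scenario(seed=7))
        g2 = generate_network(tiny_scenario(seed=7))
        assert set(g1.edges()) == set(g2.edges())
        g3 = generate_network(tiny_scenario(seed=8))
        assert set(g1.edges()) != set(g3.edges())

    def test_simple_undirected_no_self_loops(self):
        sc = SyntheticScenario(n_genes=120, n_links=400, seed=3)
        g = generate_network(sc)
        assert g.number_of_edges() == 400
        assert all(u != v for u, v in g.edges())

    def test_anchor_pairs_connected_at_scale(self):
        sc = SyntheticScenario(n_genes=300, n_links=1500,
                               module_spec=[(30, 0.8)], seed=1)
        g = generate_network(sc)
        anchors = anchor_sets(g)
        names = list(anchors)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert anchors_connected_bfs(
                    g, anchors[a].members, anchors[b].members
                )

    def test_backbone_links_present_in_graph(self):
        g = generate_network(tiny_scenario())
        for u, v in backbone_link_set(g):
            assert g.has_edge(u, v)

    def test_infeasible_link_count_rejected(self):
        with pytest.raises(ScenarioParameterError):
            tiny_scenario(n_links=100)  # > C(10, 2)
        with pytest.raises(ScenarioParameterError):
            tiny_scenario(n_links=2)  # below backbone length


class TestGenerateExpression:
    def test_perfectly_correlated_module_degenerate(self):
        sc = SyntheticScenario(
            n_genes=20, n_samples=40, n_links=30, module_spec=[(2, 1.0)],
            rho_out=0.0, anchor_sizes=(1, 1, 1), backbone_length=2,
            missing_rate=0.0, seed=2,
        )
        g = generate_network(sc)
        expr = generate_expression(sc, g)
        module = [m for m, rho in synthetic._module_assignment(sc, g) if rho == 1.0][0]
        a, b = module
        r = np.corrcoef(expr.loc[a], expr.loc[b])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_cross_module_correlation_near_zero(self):
        sc = SyntheticScenario(
            n_genes=30, n_samples=500, n_links=40,
            module_spec=[(10, 0.9), (10, 0.9)], rho_out=0.0,
            anchor_sizes=(1, 1, 1), backbone_length=2, missing_rate=0.0,
            seed=4,
        )
        g = generate_network(sc)
        expr = generate_expression(sc, g)
        modules = synthetic._module_assignment(sc, g)
        m1, m2 = modules[0][0], modules[1][0]
        cross = [abs(np.corrcoef(expr.loc[a], expr.loc[b])[0, 1])
                 for a in m1 for b in m2]
        assert np.mean(cross) < 0.1

    def test_within_module_correlation_converges(self):
        # tolerance 3/sqrt(n_samples) around the target rho
        n_samples = 400
        sc = SyntheticScenario(
            n_genes=30, n_samples=n_samples, n_links=40,
            module_spec=[(10, 0.6)], rho_out=0.0, anchor_sizes=(1, 1, 1),
            backbone_length=2, missing_rate=0.0, seed=5,
        )
        g = generate_network(sc)
        expr = generate_expression(sc, g)
        module = synthetic._module_assignment(sc, g)[0][0]
        within = [np.corrcoef(expr.loc[a], expr.loc[b])[0, 1]
                  for i, a in enumerate(module) for b in module[i + 1:]]
        assert abs(np.mean(within) - 0.6) < 3 / np.sqrt(n_samples)

    def test_missing_fraction_matches_rate(self):
        sc = SyntheticScenario(
            n_genes=100, n_samples=50, n_links=300, module_spec=[],
            missing_rate=0.2, seed=6,
        )
        g = generate_network(sc)
        expr = generate_expression(sc, g)
        assert float(expr.isna().to_numpy().mean()) == pytest.approx(0.2, abs=0.02)

    def test_backbone_path_links_heavily_correlated(self):
        sc = tiny_scenario(n_samples=200)
        g = generate_network(sc)
        expr = generate_expression(sc, g)
        for u, v in backbone_link_set(g):
            r = np.corrcoef(expr.loc[u], expr.loc[v])[0, 1]
            assert r > 0.6  # target 0.9, finite-sample noise allowed

    def test_non_psd_matrix_rejected(self):
        sc = tiny_scenario()
        g = generate_network(sc)
        sc.rho_out = -0.5  # strongly negative equicorrelation is not PSD
        with pytest.raises(ScenarioParameterError, match="positive semi-definite"):
            generate_expression(sc, g)

    def test_same_seed_bit_identical(self):
        sc = tiny_scenario(missing_rate=0.1)
        g = generate_network(sc)
        e1 = generate_expression(sc, g)
        e2 = generate_expression(sc, g)
        assert e1.equals(e2)


class TestGenerateAnnotations:
    @pytest.mark.parametrize("overall,backbone,expected", [
        (0.0, 0.0, 0), (1.0, 1.0, None),
    ])
    def test_degenerate_fractions(self, overall, backbone, expected):
        sc = tiny_scenario(essential_fraction_overall=overall,
                           essential_fraction_backbone=backbone)
        g = generate_network(sc)
        labels = generate_annotations(sc, g)
        total = int(labels["is_essential"].sum())
        assert total == (expected if expected is not None else len(labels))

    def test_planted_enrichment_detectable(self):
        from tppin.enrichment import hypergeom_enrichment

        sc = SyntheticScenario(
            n_genes=300, n_links=900, module_spec=[],
            essential_fraction_overall=0.2, essential_fraction_backbone=0.8,
            backbone_length=20, anchor_sizes=(5, 5, 5), seed=0,
        )
        g = generate_network(sc)
        labels = generate_annotations(sc, g)
        essential = GeneSet("ess", set(labels.loc[labels.is_essential == 1, "gene"]))
        universe = GeneSet("all", set(labels["gene"]))
        backbone = GeneSet("backbone", set(g.graph["backbone_nodes"]))
        res = hypergeom_enrichment(universe, essential, backbone)
        assert res.p_value < 0.01


def test_correlation_matrix_is_psd_and_blocked():
    sc = SyntheticScenario(n_genes=60, n_links=150,
                           module_spec=[(10, 0.8), (10, 0.4)], seed=9)
    g = generate_network(sc)
    corr = correlation_matrix(sc, g)
    assert np.allclose(corr, corr.T)
    assert np.linalg.eigvalsh(corr).min() > -1e-8
    assert np.all(np.diag(corr) == 1.0)


def test_write_scenario_round_trips_manifest(tmp_path):
    sc = tiny_scenario(seed=12)
    paths = write_scenario(sc, tmp_path)
    assert all(p.exists() for p in paths.values())
    back = scenario_from_manifest(paths["manifest"])
    assert back == sc
    # edge list re-loads to the generated network
    from tppin.network_io import load_edge_list

    g1 = generate_network(sc)
    g2 = load_edge_list(paths["edges"])
    assert {frozenset(e) for e in g1.edges()} == \
        {frozenset(e) for e in g2.edges()}
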