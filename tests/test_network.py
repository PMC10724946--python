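"""Screening, PMFG construction, multiscale modules, hub calling."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pancanet as pc
from pancanet.network import _is_planar, build_pmfg

from conftest import complete_edge_list, random_complete_edges, two_clique_edges


def oracle_greedy_pmfg(edges: pd.DataFrame) -> set[tuple[str, str]]:
    """Independently coded greedy insertion: rebuild a fresh graph and
    test planarity from scratch at every step (no shortcuts)."""
    ordered = edges.sort_values(["weight", "gene_a", "gene_b"],
                                ascending=[False, True, True])
    kept: list[tuple[str, str]] = []
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    bound = 3 * (len(nodes) - 2)
    for _, row in ordered.iterrows():
        if len(kept) == bound:
            break
        trial = nx.Graph(kept + [(row["gene_a"], row["gene_b"])])
        if nx.check_planarity(trial)[0]:
            kept.append((row["gene_a"], row["gene_b"]))
    return {tuple(sorted(e)) for e in kept}


class TestCorrelationScreen:
    def test_duplicated_gene_row_survives_any_screen(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 20))
        vals[1] = vals[0]  # exact duplicate, rho = 1
        frame = pd.DataFrame(vals, index=[f"g{i:02d}" for i in range(30)],
                             columns=[f"s{i}" for i in range(20)])
        edges = pc.correlation_screen(frame, n_perm=20, fdr_cut=0.05, seed=0)
        pair = edges[(edges["gene_a"] == "g00") & (edges["gene_b"] == "g01")]
        assert len(pair) == 1
        assert pair.iloc[0]["rho"] == pytest.approx(1.0)

    def test_constant_rows_dropped(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 15))
        vals[3] = 7.0
        frame = pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                             columns=[f"s{i}" for i in range(15)])
        edges = pc.correlation_screen(frame, n_perm=20, seed=1)
        assert edges.attrs["n_constant_dropped"] == 1
        assert not ((edges["gene_a"] == "g3") | (edges["gene_b"] == "g3")).any()

    def test_null_matrix_retention_controlled(self):
        """On independent Gaussians the retained fraction stays near FDR."""
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(60, 40)),
                             index=[f"g{i:02d}" for i in range(60)],
                             columns=[f"s{i}" for i in range(40)])
        edges = pc.correlation_screen(frame, n_perm=30, fdr_cut=0.05, seed=2)
        frac = len(edges) / edges.attrs["n_pairs"]
        assert frac <= 0.05 + 2 * np.sqrt(0.05 / edges.attrs["n_pairs"])

    def test_planted_module_pairs_all_retained(self):
        panel = pc.generate_cohort_panel(
            [pc.CohortSpec("C1", 20, 3, noise_sd=1e-4)], 40,
            [pc.PlantedModule("M", tuple(f"M{j:02d}" for j in range(10)),
                              is_pan=True)],
            seed=3, shift_module_members=False, n_background_dep=0)
        mat = panel.proteome["C1"][panel.tumor_samples("C1")]
        edges = pc.correlation_screen(mat, n_perm=20, seed=3)
        members = {f"M{j:02d}" for j in range(10)}
        got = {(a, b) for a, b in zip(edges["gene_a"], edges["gene_b"])
               if a in members and b in members}
        assert len(got) == 45  # all within-module pairs

    def test_output_sorted_and_oriented(self, c1_network):
        edges, _, _ = c1_network
        assert (edges["gene_a"] < edges["gene_b"]).all()
        assert (np.diff(edges["weight"]) <= 1e-12).all()


class TestPMFG:
    def test_k4_fully_accepted(self):
        edges = random_complete_edges(4, seed=0)
        net = build_pmfg(edges)
        assert net.n_edges == 6  # K4 is planar

    def test_k5_truncated_to_euler_bound(self):
        edges = random_complete_edges(5, seed=1)
        net = build_pmfg(edges)
        assert net.n_edges == 9  # 3(5-2); K5 is not planar

    @pytest.mark.parametrize("n,seed", [(10, 2), (30, 3)])
    def test_matches_independent_oracle(self, n, seed):
        edges = random_complete_edges(n, seed=seed)
        net = build_pmfg(edges)
        ours = {tuple(sorted(e)) for e in net.graph.edges}
        assert ours == oracle_greedy_pmfg(edges)
        assert net.n_edges == 3 * (n - 2)
        assert net.embedding_certified

    def test_input_row_order_invariance(self):
        edges = random_complete_edges(15, seed=4)
        shuffled = edges.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = {tuple(sorted(e)) for e in build_pmfg(edges).graph.edges}
        b = {tuple(sorted(e)) for e in build_pmfg(shuffled).graph.edges}
        assert a == b

    def test_two_nodes_complete_graph(self):
        edges = complete_edge_list(["a", "b"], [0.5])
        net = build_pmfg(edges)
        assert net.n_edges == 1

    def test_signs_preserved(self):
        edges = complete_edge_list(["a", "b", "c"], [0.9, 0.8, 0.7],
                                   rhos=[-0.9, 0.8, -0.7])
        net = build_pmfg(edges)
        assert net.graph["a"]["b"]["sign"] == -1
        assert net.graph["a"]["c"]["sign"] == 1

    def test_planarity_certified_on_panel(self, c1_network):
        _, net, _ = c1_network
        assert net.embedding_certified
        assert _is_planar(net.graph)
        n = net.graph.number_of_nodes()
        assert net.n_edges <= max(3 * (n - 2), 1)


class TestMultiscaleCluster:
    def test_two_cliques_split_exactly_at_alpha_one(self):
        net = build_pmfg(two_clique_edges())
        hierarchy = pc.multiscale_cluster(net, min_size=10, n_perm=20, seed=1)
        mods = hierarchy.modules_at(1.0)
        parts = {frozenset(g) for g in mods.values()}
        assert parts == {frozenset(f"A{i:02d}" for i in range(20)),
                         frozenset(f"B{i:02d}" for i in range(20))}

    def test_random_weights_usually_root_only(self):
        hits = 0
        for s in range(3):
            net = build_pmfg(random_complete_edges(50, seed=200 + s))
            h = pc.multiscale_cluster(net, min_size=10, n_perm=20, seed=s)
            hits += len(h.modules_at(1.0)) == 1
        assert hits >= 2

    def test_tree_contract(self, c1_network):
        _, net, hierarchy = c1_network
        mods = hierarchy.modules
        root = mods[hierarchy.root_id]
        assert set(root.genes) == set(net.graph.nodes)
        for mid, m in mods.items():
            if m.parent is None:
                continue
            assert set(m.genes) <= set(mods[m.parent].genes)
            assert len(m.genes) >= 10
            assert m.alpha <= mods[m.parent].alpha
        for mid in mods:
            kids = hierarchy.children(mid)
            for a, b in itertools.combinations(kids, 2):
                assert not (set(mods[a].genes) & set(mods[b].genes))

    def test_alpha_monotonicity(self, c1_network):
        """More stringent resolutions never yield more modules."""
        _, _, hierarchy = c1_network
        n_fine = len(hierarchy.modules_at(0.5))
        n_mid = len(hierarchy.modules_at(1.0))
        n_coarse = len(hierarchy.modules_at(2.0))
        assert n_coarse <= n_mid <= n_fine

    def test_deterministic_given_seed(self):
        net = build_pmfg(two_clique_edges(seed=5))
        h1 = pc.multiscale_cluster(net, n_perm=20, seed=9)
        h2 = pc.multiscale_cluster(net, n_perm=20, seed=9)
        assert {m: h1.modules[m].genes for m in h1.modules} == \
               {m: h2.modules[m].genes for m in h2.modules}


class TestHubs:
    def test_star_center_is_hub(self):
        center = "hub"
        leaves = [f"leaf{i:02d}" for i in range(25)]
        rows = [(min(center, l), max(center, l), 0.9) for l in leaves]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
        edges["rho"] = edges["weight"]
        edges["perm_fdr"] = 0.0
        net = build_pmfg(edges)
        hubs = pc.call_hubs(net, n_perm=20, seed=0)
        assert bool(hubs.loc[center, "is_hub"])
        assert not hubs.drop(index=center)["is_hub"].any()

    def test_regular_graph_has_no_hubs(self):
        genes = [f"g{i:02d}" for i in range(20)]
        rows = [(min(genes[i], genes[(i + 1) % 20]),
                 max(genes[i], genes[(i + 1) % 20]), 0.8) for i in range(20)]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
        edges["rho"] = edges["weight"]
        edges["perm_fdr"] = 0.0
        net = build_pmfg(edges)
        hubs = pc.call_hubs(net, n_perm=20, seed=1)
        assert not hubs["is_hub"].any()

    def test_planted_regulator_called_hub(self, small_panel, c1_network):
        _, net, hierarchy = c1_network
        hubs = pc.call_hubs(net, hierarchy, n_perm=30, seed=2)
        regs = sorted(small_panel.truth.regulators["C1"])
        present = [g for g in regs if g in hubs.index]
        assert present, "regulators missing from network"
        assert hubs.loc[present, "is_hub"].all()
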