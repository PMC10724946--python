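"""Shared fixtures: small synthetic panels and toy edge lists."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import pancanet as pc


def complete_edge_list(genes, weights, rhos=None) -> pd.DataFrame:
    """Candidate edge list over all pairs of ``genes``."""
    pairs = list(itertools.combinations(genes, 2))
    weights = np.asarray(weights, float)
    assert len(weights) == len(pairs)
    rhos = weights if rhos is None else np.asarray(rhos, float)
    return pd.DataFrame({
        "gene_a": [a for a, _ in pairs],
        "gene_b": [b for _, b in pairs],
        "rho": rhos,
        "weight": weights,
        "perm_fdr": 0.0,
    })


def random_complete_edges(n: int, seed: int, low=0.1, high=0.9) -> pd.DataFrame:
    genes = [f"g{i:03d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    k = n * (n - 1) // 2
    return complete_edge_list(genes, rng.uniform(low, high, k))


def two_clique_edges(n1=20, n2=20, seed=0, bridge=0.2) -> pd.DataFrame:
    """Two internally dense cliques joined by one weak edge."""
    rng = np.random.default_rng(seed)
    g1 = [f"A{i:02d}" for i in range(n1)]
    g2 = [f"B{i:02d}" for i in range(n2)]
    rows = [(a, b, rng.uniform(0.7, 0.9))
            for a, b in itertools.combinations(g1, 2)]
    rows += [(a, b, rng.uniform(0.7, 0.9))
             for a, b in itertools.combinations(g2, 2)]
    rows.append((g1[0], g2[0], bridge))
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    frame["rho"] = frame["weight"]
    frame["perm_fdr"] = 0.0
    return frame


@pytest.fixture(scope="session")
def small_panel() -> pc.CohortPanel:
    """3 cohorts, 300 genes, pan + two cohort-specific planted modules."""
    return pc.generate_cohort_panel(
        pc.reference_panel_specs(n_cohorts=3, n_tumor=30, n_normal=20),
        n_genes=300,
        module_plan=pc.reference_module_plan(),
        seed=11,
    )


@pytest.fixture(scope="session")
def c1_network(small_panel):
    """Screened edges + PMFG + hierarchy for cohort C1 of small_panel."""
    mat = small_panel.proteome["C1"][small_panel.tumor_samples("C1")]
    edges = pc.correlation_screen(mat, n_perm=20, seed=11)
    net = pc.build_pmfg(edges)
    hierarchy = pc.multiscale_cluster(net, n_perm=20, seed=11)
    return edges, net, hierarchy
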