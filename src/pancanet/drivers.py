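"""Key-regulator ranking by network-neighborhood signature enrichment.

A candidate oncogenic regulator is a network node whose h-step
neighborhood on the planar backbone is enriched (Fisher's exact test,
BH-corrected across nodes) for the cohort's up- or down-regulated
differential signature.  Per-cohort driver records are aggregated into
a pan-cancer ranking ordered by the number of cohorts in which a gene
is called a driver, then its hub recurrence, best FDR and gene id.
"""

from __future__ import annotations

from collections.abc import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_enrichment
from .network import PlanarNetwork

__all__ = ["neighborhood", "score_drivers", "rank_pan_cancer"]


def neighborhood(net: PlanarNetwork, gene: str, h: int = 2) -> set[str]:
    """Nodes within ``h`` edges of ``gene`` on the backbone, excluding it."""
    if h < 1:
        raise ValueError("h must be >= 1")
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} is not in the network")
    reached = nx.single_source_shortest_path_length(net.graph, gene, cutoff=h)
    return set(reached) - {gene}


def score_drivers(
    net: PlanarNetwork,
    signatures: Mapping[str, set[str]],
    hubs: pd.DataFrame | None = None,
    h: int = 2,
    q_driver: float = 0.05,
    min_neighbors: int = 5,
) -> pd.DataFrame:
    """Neighborhood enrichment scores for every well-connected node.

    ``signatures`` maps ``"up"``/``"down"`` to gene sets (restricted to
    the network universe).  Nodes with fewer than ``min_neighbors``
    neighbors are skipped.  FDR is computed per signature across the
    tested nodes; ``is_driver`` iff min(fdr_up, fdr_down) < q_driver.
    ``is_hub`` is joined from a hub-call table when given.
    """
    universe = set(net.graph.nodes)
    up = signatures.get("up", set()) & universe
    down = signatures.get("down", set()) & universe
    rows = []
    for gene in sorted(universe):
        nbrs = neighborhood(net, gene, h)
        if len(nbrs) < min_neighbors:
            continue
        p_up = fisher_enrichment(nbrs, up, universe).p if up else 1.0
        p_down = fisher_enrichment(nbrs, down, universe).p if down else 1.0
        rows.append((gene, len(nbrs), p_up, p_down))
    table = pd.DataFrame(rows, columns=["gene_id", "n_neighbors", "p_up", "p_down"])
    if len(table):
        table["fdr_up"] = multipletests(table["p_up"], method="fdr_bh")[1]
        table["fdr_down"] = multipletests(table["p_down"], method="fdr_bh")[1]
    else:
        table["fdr_up"] = table["fdr_down"] = []
    if hubs is not None:
        hub_map = hubs["is_hub"].to_dict()
        table["is_hub"] = table["gene_id"].map(hub_map).fillna(False).astype(bool)
    else:
        table["is_hub"] = False
    table["is_driver"] = np.minimum(table["fdr_up"], table["fdr_down"]) < q_driver
    return table.set_index("gene_id")


def rank_pan_cancer(records: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-cohort driver records into a pan-cancer ranking.

    Ordered by: cohorts-as-driver (desc), cohorts-as-hub (desc), best
    FDR across cohorts (asc), gene id (asc) — a total order.
    ``n_up``/``n_down`` count cohorts whose neighborhood enrichment was
    significant for the up / down signature respectively.
    """
    if len(records) < 2:
        raise ValueError("need driver records from at least 2 cohorts")
    stats_: dict[str, dict[str, float]] = {}
    for cohort in sorted(records):
        table = records[cohort]
        for gene, row in table.iterrows():
            entry = stats_.setdefault(gene, {
                "n_cohorts_driver": 0, "n_cohorts_hub": 0,
                "n_up": 0, "n_down": 0, "best_fdr": 1.0})
            if row["is_driver"]:
                entry["n_cohorts_driver"] += 1
                if row["fdr_up"] <= row["fdr_down"]:
                    entry["n_up"] += 1
                else:
                    entry["n_down"] += 1
            if row["is_hub"]:
                entry["n_cohorts_hub"] += 1
            entry["best_fdr"] = min(entry["best_fdr"],
                                    row["fdr_up"], row["fdr_down"])
    ranking = pd.DataFrame.from_dict(stats_, orient="index")
    ranking.index.name = "gene_id"
    ranking = ranking.reset_index()
    ranking = ranking.sort_values(
        by=["n_cohorts_driver", "n_cohorts_hub", "best_fdr", "gene_id"],
        ascending=[False, False, True, True]).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking.set_index("gene_id")
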