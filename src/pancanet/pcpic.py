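"""Pan-cancer protein interaction communities (PCPICs).

Modules that are strongly preserved across cohorts are merged into
communities: the module overlap graph has one node per (cohort, module)
and an edge wherever a cross-cohort best-match preservation call is
*strong*; connected components spanning enough distinct cohorts become
PCPICs.  Each PCPIC has a **core** — the genes recurring in member
modules from at least ``core_min`` cohorts — a per-cohort summary
expression (mean z-score of core genes), differential-signature
enrichment, and a signed cross-talk network linking PCPIC pairs whose
summary expressions correlate consistently across cohorts.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, fisher_enrichment

__all__ = [
    "PCPIC",
    "build_overlap_graph",
    "detect_communities",
    "extract_core",
    "summarize_and_correlate",
]


@dataclass
class PCPIC:
    community_id: str
    member_modules: frozenset[tuple[str, str]]  # (cohort, module_id)
    cohorts_spanned: frozenset[str]
    core: set[str] = field(default_factory=set)
    summary_expression: dict[str, pd.Series] = field(default_factory=dict)
    dep_enrichment: dict[tuple[str, str], EnrichmentResult] = field(default_factory=dict)


def build_overlap_graph(calls: pd.DataFrame) -> nx.Graph:
    """Module overlap graph from a preservation-call table.

    Nodes: every (cohort, module_id) that was scored against a
    cross-cohort proteome target.  Edges: undirected, between
    cross-cohort module pairs whose best-match call is *strong* in at
    least one direction.  Transcriptome targets (``rna:``) are ignored.
    """
    g = nx.Graph()
    cross = calls[~calls["target"].astype(str).str.startswith("rna:")]
    for _, row in cross.iterrows():
        g.add_node((row["cohort"], row["module_id"]))
    for _, row in cross.iterrows():
        if row["klass"] != "strong" or row["best_match"] is None:
            continue
        a = (row["cohort"], row["module_id"])
        b = (str(row["target"]), str(row["best_match"]))
        if a[0] == b[0]:
            continue  # never link modules of the same cohort
        g.add_edge(a, b, fdr=float(row["fdr"]), fold=float(row["fold"]))
    return g


def detect_communities(g: nx.Graph, span_min: int) -> list[PCPIC]:
    """Connected components spanning >= ``span_min`` cohorts.

    Components spanning fewer cohorts are discarded.  Communities are
    numbered in decreasing size, ties broken by member order, so the
    output is deterministic.
    """
    if span_min < 2:
        raise ValueError("span_min must be >= 2")
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    out: list[PCPIC] = []
    for members in comps:
        cohorts = frozenset(c for c, _ in members)
        if len(cohorts) < span_min:
            continue
        out.append(PCPIC(
            community_id=f"PCPIC{len(out) + 1}",
            member_modules=frozenset(members),
            cohorts_spanned=cohorts,
        ))
    return out


def extract_core(
    pcpic: PCPIC,
    module_genes: Mapping[tuple[str, str], set[str]],
    core_min: int | None = None,
) -> set[str]:
    """Core = genes present in member modules from >= ``core_min`` cohorts.

    Default ``core_min`` is the majority of the spanned cohorts,
    ``ceil(span / 2)``.  Raising ``core_min`` can only shrink the core.
    """
    span = len(pcpic.cohorts_spanned)
    if core_min is None:
        core_min = math.ceil(span / 2)
    if core_min > span:
        raise ValueError("core_min cannot exceed the number of spanned cohorts")
    gene_cohorts: dict[str, set[str]] = {}
    for cohort, module_id in sorted(pcpic.member_modules):
        for gene in module_genes.get((cohort, module_id), set()):
            gene_cohorts.setdefault(gene, set()).add(cohort)
    return {g for g, cs in gene_cohorts.items() if len(cs) >= core_min}


def _summary_expression(expr: pd.DataFrame, core: set[str]) -> pd.Series | None:
    genes = sorted(core & set(expr.index))
    if len(genes) < 2:
        return None
    mat = expr.loc[genes].to_numpy(float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        return None
    z = (mat[keep] - mat[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.Series(z.mean(axis=0), index=expr.columns)


def summarize_and_correlate(
    pcpics: Sequence[PCPIC],
    proteomes: Mapping[str, pd.DataFrame],
    signatures: Mapping[tuple[str, str], set[str]] | None = None,
    universes: Mapping[str, set[str]] | None = None,
    p_edge: float = 0.05,
) -> tuple[list[PCPIC], pd.DataFrame]:
    """Per-cohort summary expression, DEP enrichment, cross-talk edges.

    Summary expression of a PCPIC in a cohort is the mean z-scored
    expression of its core genes over that cohort's samples (cohorts
    where fewer than two core genes are measured are skipped).  For
    each PCPIC pair the per-cohort Spearman correlations between
    summaries are combined as the median rho with Fisher's method on
    the two-sided p-values; an edge is kept iff the combined p is below
    ``p_edge`` and its sign is the sign of the median rho.
    """
    pcpics = list(pcpics)
    for pc in pcpics:
        pc.summary_expression = {}
        for cohort in sorted(proteomes):
            summ = _summary_expression(proteomes[cohort], pc.core)
            if summ is not None:
                pc.summary_expression[cohort] = summ
        pc.dep_enrichment = {}
        if signatures:
            for (cohort, direction), sig in sorted(signatures.items()):
                uni = (universes or {}).get(cohort) or set(
                    proteomes[cohort].index)
                pc.dep_enrichment[(cohort, direction)] = fisher_enrichment(
                    pc.core, sig, uni,
                    query_name=pc.community_id,
                    target_name=f"{cohort}_{direction}")

    rows = []
    for i in range(len(pcpics)):
        for j in range(i + 1, len(pcpics)):
            a, b = pcpics[i], pcpics[j]
            rhos, pvals = [], []
            for cohort in sorted(set(a.summary_expression) & set(b.summary_expression)):
                sa = a.summary_expression[cohort]
                sb = b.summary_expression[cohort]
                rho, p = stats.spearmanr(sa.to_numpy(), sb.to_numpy())
                if np.isfinite(rho):
                    rhos.append(float(rho))
                    pvals.append(float(min(max(p, 1e-300), 1.0)))
            if not rhos:
                continue
            med_rho = float(np.median(rhos))
            comb_p = float(stats.combine_pvalues(pvals, method="fisher")[1])
            if comb_p < p_edge and med_rho != 0:
                rows.append((a.community_id, b.community_id, med_rho,
                             "+" if med_rho > 0 else "-", comb_p, len(rhos)))
    edges = pd.DataFrame(rows, columns=["a", "b", "rho", "sign", "p", "n_cohorts"])
    return pcpics, edges
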