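"""Multiscale co-expression networks on a planar backbone.

The per-cohort network pipeline is:

1. **Correlation screening** — all-pairs Spearman correlation with a
   permutation-based FDR on |rho|; only significant pairs become
   candidate edges.
2. **PMFG** — the planar maximally filtered graph: candidate edges are
   inserted greedily in decreasing weight order, an edge is kept iff
   the graph remains planar, so the backbone carries at most 3(n-2)
   edges while retaining the strongest correlation structure.
3. **Multiscale modules** — recursive top-down splitting of the
   *positive* backbone (modules are sign-coherent: negative edges
   express antagonism between communities, which the PCPIC cross-talk
   stage consumes, and never bind genes into one module).  Within a
   parent module, nodes are partitioned by k-medoids (k = 2..4) on
   shortest-path distances with edge length 1 - rho; a split is
   accepted at resolution ``alpha`` iff its
   quality — the coverage-weighted contrast between within-child and
   between-child similarity — exceeds ``alpha`` times the 95th
   percentile of the same statistic on null replicates of the parent:
   the parent's own positive candidate correlations are assigned to
   uniformly random pairs and greedily re-filtered to a planar
   backbone, so the null shares the observed graph's node count,
   weight multiset, candidate supply and saturation level but has no
   community structure.  Larger ``alpha`` is therefore more stringent
   (coarser modules); reporting defaults to alpha = 1.
4. **Hub calling** — a node is a hub when its backbone degree exceeds
   the (1 - hub_q) quantile of degrees from PMFGs rebuilt on
   weight-shuffled candidate lists.

The split null deliberately (a) re-optimizes the split search on every
replicate — comparing an optimized observed statistic against
un-optimized random partitions would accept splits on any graph, since
graph distances always cluster — and (b) randomizes the edge *pair
assignment*, not merely the weights: both the backbone topology and
the candidate pair set carry the module signal, so weight shuffling
alone leaves the null block-structured and powerless.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rng import substream

__all__ = [
    "correlation_screen",
    "build_pmfg",
    "multiscale_cluster",
    "call_hubs",
    "PlanarNetwork",
    "Module",
    "ModuleHierarchy",
]

EDGE_COLUMNS = ["gene_a", "gene_b", "rho", "weight", "perm_fdr"]


# ----------------------------------------------------------------------
# correlation screening
# ----------------------------------------------------------------------

def correlation_screen(
    expr: pd.DataFrame,
    n_perm: int = 50,
    fdr_cut: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-screened all-pairs Spearman edge list.

    ``expr`` is genes x samples (log scale).  Constant rows are dropped.
    The permutation null shuffles each gene's values across samples
    independently, ``n_perm`` times; the per-edge FDR at threshold
    t = |rho| is (mean null pairs >= t) / (observed pairs >= t), made
    monotone in t.  Edges with FDR < ``fdr_cut`` are returned sorted by
    weight descending (ties broken by gene-id pair).
    """
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples for screening")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    values = expr.to_numpy(float)
    keep = values.std(axis=1) > 0
    n_constant = int((~keep).sum())
    genes = expr.index[keep].to_list()
    ranks = stats.rankdata(values[keep], axis=1)
    m = len(genes)
    if m < 2:
        raise ValueError("fewer than 2 non-constant genes")

    iu = np.triu_indices(m, k=1)
    rho = np.corrcoef(ranks)[iu]
    obs_abs = np.abs(rho)

    rng = substream(seed, "screen")
    null_abs = np.empty(n_perm * len(obs_abs))
    for r in range(n_perm):
        perm = rng.permuted(ranks, axis=1)
        null_abs[r * len(obs_abs):(r + 1) * len(obs_abs)] = np.abs(
            np.corrcoef(perm)[iu])
    null_abs.sort()

    order = np.argsort(-obs_abs, kind="stable")
    sorted_abs = obs_abs[order]
    # null count >= t, averaged over permutations
    null_ge = (len(null_abs) - np.searchsorted(null_abs, sorted_abs, "left")) / n_perm
    fdr_at = null_ge / np.arange(1, len(sorted_abs) + 1)
    qvals_sorted = np.minimum(np.minimum.accumulate(fdr_at[::-1])[::-1], 1.0)
    qvals = np.empty_like(qvals_sorted)
    qvals[order] = qvals_sorted

    keep_edge = qvals < fdr_cut
    ii, jj = iu[0][keep_edge], iu[1][keep_edge]
    ga = [genes[i] for i in ii]
    gb = [genes[j] for j in jj]
    # enforce gene_a < gene_b lexicographically
    flip = [a > b for a, b in zip(ga, gb)]
    ga2 = [b if f else a for a, b, f in zip(ga, gb, flip)]
    gb2 = [a if f else b for a, b, f in zip(ga, gb, flip)]
    edges = pd.DataFrame({
        "gene_a": ga2,
        "gene_b": gb2,
        "rho": rho[keep_edge],
        "weight": obs_abs[keep_edge],
        "perm_fdr": qvals[keep_edge],
    })
    edges = edges.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    edges.attrs["n_constant_dropped"] = n_constant
    edges.attrs["n_genes_screened"] = m
    edges.attrs["n_pairs"] = len(obs_abs)
    return edges


# ----------------------------------------------------------------------
# planar maximally filtered graph
# ----------------------------------------------------------------------

def _is_planar(graph: nx.Graph) -> bool:
    """Planarity predicate (single internal interface; left-right test)."""
    return nx.check_planarity(graph, counterexample=False)[0]


@dataclass
class PlanarNetwork:
    """A certified-planar weighted, signed co-expression backbone."""

    graph: nx.Graph
    embedding_certified: bool
    candidate_edges: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (min(u, v), max(u, v), d["rho"], d["weight"], d["sign"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            sorted(rows), columns=["gene_a", "gene_b", "rho", "weight", "sign"]
        )


class _UnionFind:
    """Union-find that also tracks the member set of each component."""

    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.members = {x: {x} for x in items}
        self.n_edges = {x: 0 for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra] |= self.members.pop(rb)
        self.n_edges[ra] += self.n_edges.pop(rb)
        return True

    def component(self, x) -> set:
        return self.members[self.find(x)]

    def saturated(self, x) -> bool:
        """Component already at the planar edge bound 3(n-2)."""
        r = self.find(x)
        n = len(self.members[r])
        return n >= 3 and self.n_edges[r] >= 3 * (n - 2)


def _sorted_candidates(edges: pd.DataFrame) -> pd.DataFrame:
    return edges.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def _greedy_planar_core(pairs, nodes) -> list[int]:
    """Positions of candidates accepted by greedy planar insertion.

    ``pairs`` is an iterable of (index, node_a, node_b) already sorted
    by insertion priority.
    """
    n = len(nodes)
    max_edges = max(3 * (n - 2), 1) if n >= 3 else n * (n - 1) // 2
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    uf = _UnionFind(nodes)
    accepted: list[int] = []
    for idx, a, b in pairs:
        if len(accepted) >= max_edges:
            break
        if uf.union(a, b):
            # bridging two planar components keeps the graph planar
            graph.add_edge(a, b)
            uf.n_edges[uf.find(a)] += 1
            accepted.append(idx)
            continue
        if uf.saturated(a):
            continue  # Euler bound: no planar graph can take this edge
        # planarity can only break inside the touched component
        graph.add_edge(a, b)
        if _is_planar(graph.subgraph(uf.component(a))):
            uf.n_edges[uf.find(a)] += 1
            accepted.append(idx)
        else:
            graph.remove_edge(a, b)
    return accepted


def _greedy_planar_edges(edges: pd.DataFrame) -> list[int]:
    """Indices of candidate rows accepted by greedy planar insertion."""
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return _greedy_planar_core(
        zip(edges.index, edges["gene_a"], edges["gene_b"]), nodes)


def build_pmfg(edges: pd.DataFrame) -> PlanarNetwork:
    """Build the planar maximally filtered graph from a candidate list.

    Candidates are processed in decreasing weight order (ties by
    lexicographic gene pair); an edge is kept iff the graph stays
    planar; insertion stops at the planar bound 3(n-2).  Planarity of
    the result is re-certified at the end.
    """
    edges = _sorted_candidates(edges)
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if len(nodes) < 3:
        accepted = list(edges.index)
    else:
        accepted = _greedy_planar_edges(edges)
    for idx in accepted:
        row = edges.loc[idx]
        rho = float(row["rho"])
        graph.add_edge(row["gene_a"], row["gene_b"], weight=float(row["weight"]),
                       rho=rho, sign=1 if rho >= 0 else -1)
    certified = _is_planar(graph)
    return PlanarNetwork(graph=graph, embedding_certified=certified,
                         candidate_edges=edges)


# ----------------------------------------------------------------------
# multiscale module detection
# ----------------------------------------------------------------------

@dataclass
class Module:
    module_id: str
    parent: str | None
    genes: tuple[str, ...]
    alpha: float
    compactness: float
    split_p: float


@dataclass
class ModuleHierarchy:
    """Nested module tree; each non-root module records the largest
    resolution ``alpha`` at which its parent split was accepted."""

    modules: dict[str, Module]
    root_id: str = "M0"

    def children(self, module_id: str) -> list[str]:
        return sorted(m for m, mod in self.modules.items()
                      if mod.parent == module_id)

    def modules_at(self, alpha: float) -> dict[str, set[str]]:
        """Partition (of covered genes) at one resolution.

        A module is reported when it has no child accepted at a
        resolution >= ``alpha``; coarser splits (accepted at larger
        alpha) remain visible at finer query resolutions.
        """
        out: dict[str, set[str]] = {}

        def walk(mid: str) -> None:
            kids = [k for k in self.children(mid)
                    if self.modules[k].alpha >= alpha]
            if not kids:
                out[mid] = set(self.modules[mid].genes)
            else:
                for k in kids:
                    walk(k)

        walk(self.root_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid in sorted(self.modules):
            m = self.modules[mid]
            for g in sorted(m.genes):
                rows.append((mid, m.parent if m.parent is not None else "",
                             m.alpha, m.compactness, m.split_p, g))
        return pd.DataFrame(rows, columns=[
            "module_id", "parent_id", "alpha", "compactness", "split_p",
            "gene_id"])


def _kmedoids(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids on a precomputed distance matrix.

    Initialization: most central point, then farthest-point additions;
    assignment and medoid updates break ties by lowest index, so the
    result depends only on the distances.
    """
    m = dist.shape[0]
    # PAM BUILD: greedily add the medoid that most reduces total cost;
    # unlike farthest-point seeding this is robust to dangling outliers
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    d_near = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -1.0
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        d_near = np.minimum(d_near, dist[:, nxt])
    medoids_arr = np.array(medoids)
    labels = np.argmin(dist[:, medoids_arr], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids_arr.copy()
        for j in range(k):
            members = np.nonzero(labels == j)[0]
            if len(members) == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_labels, labels) and np.array_equal(
                new_medoids, medoids_arr):
            break
        medoids_arr, labels = new_medoids, new_labels
    return labels


def _split_compactness(sim: np.ndarray, labels: np.ndarray) -> float:
    """Pair-weighted mean within-child similarity of a partition."""
    total = 0.0
    pairs = 0
    for j in np.unique(labels):
        if j < 0:  # dropped (undersized) cluster
            continue
        members = np.nonzero(labels == j)[0]
        if len(members) < 2:
            continue
        sub = sim[np.ix_(members, members)]
        npairs = len(members) * (len(members) - 1) // 2
        total += (sub.sum() - np.trace(sub)) / 2.0
        pairs += npairs
    return total / pairs if pairs else 0.0


def _split_contrast(sim: np.ndarray, labels: np.ndarray) -> float:
    """Within-child minus between-children mean similarity.

    The split-quality statistic: high when children are internally
    tight *and* mutually separated; a partition that merely inherits a
    globally tight parent scores near zero.
    """
    within = _split_compactness(sim, labels)
    kept = [np.nonzero(labels == j)[0] for j in np.unique(labels) if j >= 0]
    between_total = 0.0
    between_pairs = 0
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            block = sim[np.ix_(kept[a], kept[b])]
            between_total += block.sum()
            between_pairs += block.size
    between = between_total / between_pairs if between_pairs else 0.0
    return within - between


def _best_split(dist: np.ndarray, k_range: Sequence[int], min_size: int
                ) -> tuple[float, np.ndarray] | None:
    """Best k-medoids partition over the k grid.

    Clusters smaller than ``min_size`` are dropped from the proposal
    (their nodes get label -1) rather than invalidating it — dangling
    low-degree nodes otherwise veto every split; a proposal needs at
    least two surviving children.  Compactness is computed over the
    surviving children only.
    """
    finite = dist[np.isfinite(dist)]
    dmax = finite.max() if len(finite) else 0.0
    if dmax <= 0:
        return None
    dn = np.where(np.isfinite(dist), dist / dmax, 1.0)
    sim = 1.0 - dn
    best: tuple[float, np.ndarray] | None = None
    m = dist.shape[0]
    for k in k_range:
        if k * min_size > m:
            continue
        labels = _kmedoids(np.where(np.isfinite(dist), dist, dmax * 2), k)
        sizes = np.bincount(labels, minlength=k)
        labels = labels.copy()
        labels[sizes[labels] < min_size] = -1
        if len({l for l in labels if l >= 0}) < 2:
            continue
        # coverage-weighted: a split must explain the parent, not just
        # keep a tight core and shed the rest
        coverage = (labels >= 0).sum() / m
        comp = _split_contrast(sim, labels) * coverage
        if best is None or comp > best[0]:
            best = (comp, labels)
    return best


def _subgraph_arrays(graph: nx.Graph, genes: Sequence[str]
                     ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Positive-backbone edge arrays of the induced subgraph.

    Modules are sign-coherent: only positively correlated edges bind
    genes into the same module.  Negative backbone edges express
    antagonism between communities and are consumed downstream (module
    cross-talk), not by module membership.
    """
    nodes = sorted(genes)
    index = {g: i for i, g in enumerate(nodes)}
    us, vs, rs = [], [], []
    for u, v, d in graph.subgraph(nodes).edges(data=True):
        if d["rho"] <= 0:
            continue
        us.append(index[u])
        vs.append(index[v])
        rs.append(d["rho"])
    order = np.lexsort((vs, us))
    return (nodes, np.array(us)[order] if len(us) else np.array([], int),
            np.array(vs)[order] if len(vs) else np.array([], int),
            np.array(rs)[order] if len(rs) else np.array([]))


def _distance_matrix(n: int, us: np.ndarray, vs: np.ndarray,
                     rhos: np.ndarray) -> np.ndarray:
    lengths = np.clip(1.0 - rhos, 0.0, None)
    mat = csr_matrix((np.concatenate([lengths, lengths]),
                      (np.concatenate([us, vs]), np.concatenate([vs, us]))),
                     shape=(n, n))
    return shortest_path(mat, method="D", directed=False)


def multiscale_cluster(
    net: PlanarNetwork,
    alphas: Sequence[float] = (0.5, 1.0, 2.0),
    min_size: int = 10,
    n_perm: int = 50,
    seed: int = 0,
    k_range: Sequence[int] = (2, 3, 4),
    null_percentile: float = 95.0,
) -> ModuleHierarchy:
    """Recursive top-down multiscale module detection on the PMFG.

    See the module docstring for the split rule.  Disconnected parents
    fall apart into their connected components directly (components
    smaller than ``min_size`` are dropped from the hierarchy).
    Deterministic given ``seed``.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    alphas = sorted(float(a) for a in alphas)
    alpha_top = max(alphas)
    rng = substream(seed, "cluster")

    # positive candidate edges: the null rebuilds a backbone from the
    # parent's own candidate supply so observed and null graphs face
    # the same construction pressure (saturation, triangulation)
    cand = net.candidate_edges
    if cand is not None and len(cand):
        pos_cand = cand[cand["rho"] > 0]
        cand_a = pos_cand["gene_a"].to_numpy()
        cand_b = pos_cand["gene_b"].to_numpy()
        cand_rho = pos_cand["rho"].to_numpy(float)
    else:
        cand_a = cand_b = cand_rho = None

    def candidate_rhos(geneset: set) -> np.ndarray | None:
        if cand_rho is None:
            return None
        mask = np.fromiter(
            (a in geneset and b in geneset
             for a, b in zip(cand_a, cand_b)), bool, len(cand_rho))
        return cand_rho[mask]

    all_nodes = tuple(sorted(net.graph.nodes))
    modules: dict[str, Module] = {
        "M0": Module("M0", None, all_nodes, float("inf"), float("nan"), float("nan"))
    }
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def recurse(mid: str, parent_alpha: float) -> None:
        genes = modules[mid].genes
        if len(genes) < 2 * min_size:
            return
        sub_nodes, us, vs, ws = _subgraph_arrays(net.graph, genes)
        n = len(sub_nodes)
        dist = _distance_matrix(n, us, vs, ws)

        # disconnected parent: components become children directly
        comp_labels = np.full(n, -1)
        if np.isinf(dist).any():
            label = 0
            for i in range(n):
                if comp_labels[i] < 0:
                    comp_labels[np.isfinite(dist[i])] = label
                    label += 1
            if label > 1:
                for j in range(label):
                    members = [sub_nodes[i] for i in np.nonzero(comp_labels == j)[0]]
                    if len(members) < min_size:
                        continue
                    cid = new_id()
                    modules[cid] = Module(cid, mid, tuple(sorted(members)),
                                          parent_alpha, float("nan"), 0.0)
                    recurse(cid, parent_alpha)
                return

        result = _best_split(dist, k_range, min_size)
        if result is None:
            return
        comp_obs, labels = result

        # Null: the parent's positive candidate correlations assigned
        # to uniformly random pairs and greedily re-filtered to a
        # planar backbone — community structure is destroyed while
        # node count, candidate supply, weight multiset and the
        # saturation level of the backbone are preserved; the same
        # optimized split search runs on every replicate so observed
        # and null statistics are exchangeable when there are no
        # modules.  The supply is capped at 3.5n candidates (the
        # strongest) for tractability: the planar bound is 3n-6, so
        # the capped null still saturates its backbone like the
        # observed graph does.
        rhos_c = candidate_rhos(set(genes))
        if rhos_c is None or len(rhos_c) < len(ws):
            rhos_c = ws
        m_eff = min(len(rhos_c), int(3.5 * n))
        if len(rhos_c) > m_eff:
            rhos_c = np.sort(rhos_c)[-m_eff:]
        iu = np.triu_indices(n, k=1)
        n_pairs = len(iu[0])
        m_eff = min(m_eff, n_pairs)
        null_comp = np.zeros(n_perm)
        for r in range(n_perm):
            pos = rng.choice(n_pairs, size=m_eff, replace=False)
            ia, jb = iu[0][pos], iu[1][pos]
            rho_r = rng.permutation(rhos_c)[:m_eff]
            order = np.lexsort((jb, ia, -np.abs(rho_r)))
            pairs = zip(order, ia[order], jb[order])
            kept = np.array(_greedy_planar_core(pairs, range(n)), dtype=int)
            dist_r = _distance_matrix(n, ia[kept], jb[kept], rho_r[kept])
            res_r = _best_split(dist_r, k_range, min_size)
            null_comp[r] = res_r[0] if res_r is not None else 0.0
        q = float(np.percentile(null_comp, null_percentile))
        accepted = [a for a in alphas if comp_obs > a * q]
        split_p = float((null_comp >= comp_obs).mean())
        if not accepted:
            return
        alpha_acc = min(max(accepted), parent_alpha)

        dmax = dist[np.isfinite(dist)].max()
        sim = 1.0 - dist / dmax
        for j in sorted(np.unique(labels)):
            if j < 0:
                continue
            members_idx = np.nonzero(labels == j)[0]
            members = tuple(sorted(sub_nodes[i] for i in members_idx))
            child_sim = sim[np.ix_(members_idx, members_idx)]
            npair = len(members_idx) * (len(members_idx) - 1) / 2.0
            child_comp = ((child_sim.sum() - np.trace(child_sim)) / 2.0 / npair
                          if npair else 1.0)
            cid = new_id()
            modules[cid] = Module(cid, mid, members, alpha_acc,
                                  float(child_comp), split_p)
            recurse(cid, alpha_acc)

    recurse("M0", alpha_top)
    return ModuleHierarchy(modules=modules)


# ----------------------------------------------------------------------
# hub calling
# ----------------------------------------------------------------------

def call_hubs(
    net: PlanarNetwork,
    modules: ModuleHierarchy | None = None,
    n_perm: int = 50,
    hub_q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Degree-based hub calls against a weight-shuffled PMFG null.

    The null degree distribution pools node degrees from ``n_perm``
    PMFGs rebuilt after shuffling the weights of the candidate edge
    list (which reorders greedy insertion).  A node is a hub iff its
    observed backbone degree exceeds the (1 - ``hub_q``) null quantile.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    cand = net.candidate_edges
    if cand is None or not len(cand):
        cand = net.edge_frame()
    rng = substream(seed, "hubs")

    null_degrees: list[np.ndarray] = []
    base = cand[["gene_a", "gene_b", "rho", "weight"]].copy()
    nodes = sorted(set(base["gene_a"]) | set(base["gene_b"]) | set(net.graph.nodes))
    for _ in range(n_perm):
        shuf = base.copy()
        shuf["weight"] = rng.permutation(base["weight"].to_numpy())
        shuf = _sorted_candidates(shuf)
        accepted = _greedy_planar_edges(shuf) if len(nodes) >= 3 else list(shuf.index)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            zip(shuf.loc[accepted, "gene_a"], shuf.loc[accepted, "gene_b"]))
        null_degrees.append(np.array([g.degree[v] for v in nodes], float))
    pooled = np.concatenate(null_degrees)
    threshold = float(np.quantile(pooled, 1.0 - hub_q))

    records = []
    module_of: dict[str, str] = {}
    if modules is not None:
        for mid, genes in modules.modules_at(1.0).items():
            for g in genes:
                module_of[g] = mid
    for v in sorted(net.graph.nodes):
        deg = net.graph.degree[v]
        wdeg = sum(d["weight"] for _, _, d in net.graph.edges(v, data=True))
        records.append((v, deg, wdeg, float((pooled < deg).mean()),
                        bool(deg > threshold), module_of.get(v, "")))
    table = pd.DataFrame(records, columns=[
        "gene_id", "degree", "weighted_degree", "null_quantile", "is_hub",
        "module_id"]).set_index("gene_id")
    table.attrs["null_degree_threshold"] = threshold
    return table
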