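"""Differential protein expression and cross-cohort recurrence.

Per cohort, tumor vs matched-normal differential expression is tested
gene-by-gene with Welch's two-sample t-test on log-scale values and
corrected by Benjamini-Hochberg FDR.  Proteome-specific DEPs are
proteins differential at the protein level whose matched transcript is
not differential.  Recurrence of proteome-specific DEPs across cohorts
is scored with an exact multi-set intersection test (the
super-exact-test statistic): the null distribution of the size of the
intersection of m independent uniform random subsets of fixed sizes
drawn from a common universe, computed exactly as a Markov chain of
hypergeometric transitions.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "call_deps",
    "proteome_specific",
    "multiset_intersection_test",
    "multiset_intersection_distribution",
    "recurrent_specific_deps",
    "signature_collection",
    "MultisetTestResult",
    "ProteomeSpecificResult",
]

_DEP_COLUMNS = ["log2fc", "t", "p", "fdr", "direction"]


def _empty_dep_table(status: str) -> pd.DataFrame:
    table = pd.DataFrame(columns=_DEP_COLUMNS)
    table.index.name = "gene_id"
    table.attrs["status"] = status
    table.attrs["n_dropped"] = 0
    return table


def call_deps(
    proteome: pd.DataFrame,
    metadata: pd.DataFrame,
    q_dep: float = 0.05,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Welch-t differential expression, tumor vs normal, one cohort.

    Parameters
    ----------
    proteome
        Genes x samples log-scale matrix.
    metadata
        Table with ``sample_id`` and ``condition`` in {tumor, normal};
        only samples present in the matrix are used.
    q_dep
        FDR threshold deciding the up/down/ns direction call.
    min_obs
        Genes with fewer finite values than this in either group are
        dropped (count recorded in ``attrs['n_dropped']``).

    Returns
    -------
    DataFrame indexed by gene with columns log2fc, t, p, fdr,
    direction.  A cohort without normal samples yields an empty table
    with ``attrs['status'] == 'no_normals'`` rather than an error.
    """
    md = metadata.set_index("sample_id")["condition"]
    cols = [s for s in proteome.columns if s in md.index]
    tumor = [s for s in cols if md[s] == "tumor"]
    normal = [s for s in cols if md[s] == "normal"]
    if len(normal) == 0:
        return _empty_dep_table("no_normals")
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError("need at least 3 tumor and 3 normal samples")

    tv = proteome[tumor].to_numpy(float)
    nv = proteome[normal].to_numpy(float)
    ok = (np.isfinite(tv).sum(axis=1) >= min_obs) & (
        np.isfinite(nv).sum(axis=1) >= min_obs)
    n_dropped = int((~ok).sum())
    genes = proteome.index[ok]
    tv, nv = tv[ok], nv[ok]

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(tv, nv, axis=1, equal_var=False,
                              nan_policy="omit")
    tstat = np.asarray(res.statistic, float)
    pval = np.asarray(res.pvalue, float)
    log2fc = np.nanmean(tv, axis=1) - np.nanmean(nv, axis=1)

    # zero-variance degenerate rows: identical groups -> null; constant
    # but different groups -> maximally significant
    bad = ~np.isfinite(tstat)
    same = bad & (np.abs(log2fc) < 1e-12)
    diff = bad & ~same
    tstat[same], pval[same] = 0.0, 1.0
    tstat[diff] = np.sign(log2fc[diff]) * np.inf
    pval[diff] = 0.0

    fdr = multipletests(pval, method="fdr_bh")[1]
    direction = np.where(fdr < q_dep,
                         np.where(log2fc > 0, "up",
                                  np.where(log2fc < 0, "down", "ns")),
                         "ns")
    table = pd.DataFrame(
        {"log2fc": log2fc, "t": tstat, "p": pval, "fdr": fdr,
         "direction": direction},
        index=genes,
    )
    table.index.name = "gene_id"
    table.attrs["status"] = "ok"
    table.attrs["n_dropped"] = n_dropped
    return table


def proteome_specific(
    dep_prot: pd.DataFrame,
    dep_rna: pd.DataFrame,
    q_dep: float = 0.05,
    q_rna: float = 0.05,
) -> "ProteomeSpecificResult":
    """Proteome-specific DEPs per direction.

    A gene is proteome-specific iff its protein FDR < ``q_dep`` (with
    the corresponding direction) while its mRNA FDR >= ``q_rna``.
    Evaluated on the shared gene universe of the two tables.
    """
    shared = dep_prot.index.intersection(dep_rna.index)
    if len(shared) == 0:
        raise ValueError("empty shared gene universe between layers")
    prot = dep_prot.loc[shared]
    rna = dep_rna.loc[shared]
    rna_not_dep = rna["fdr"] >= q_rna
    sets = {}
    for direction in ("up", "down"):
        sel = (prot["fdr"] < q_dep) & (prot["direction"] == direction) & rna_not_dep
        sets[direction] = set(shared[sel.to_numpy()])
    return ProteomeSpecificResult(sets["up"], sets["down"], len(shared))


@dataclass(frozen=True)
class ProteomeSpecificResult:
    """Up/down proteome-specific gene sets on the shared universe."""

    up: set[str]
    down: set[str]
    n_shared: int

    @property
    def all_genes(self) -> set[str]:
        return self.up | self.down


@dataclass(frozen=True)
class MultisetTestResult:
    expected_overlap: float
    observed_overlap: int
    p: float
    method: str = "exact"


def multiset_intersection_distribution(
    sizes: Sequence[int], universe_size: int
) -> np.ndarray:
    """Exact pmf of the intersection size of m random subsets.

    Sets are independent uniform subsets of fixed sizes from a common
    universe of ``universe_size`` elements.  The running intersection
    is a Markov chain: given the first k-1 sets intersect in j
    elements, the overlap with the k-th (size n_k) is hypergeometric
    with j "successes" in the universe.  Chaining the transitions gives
    the full distribution in closed form.
    """
    n = int(universe_size)
    sizes = [int(s) for s in sizes]
    if any(s < 0 or s > n for s in sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    pmf = np.zeros(sizes[0] + 1)
    pmf[sizes[0]] = 1.0
    for nk in sizes[1:]:
        support = np.nonzero(pmf > 0)[0]
        new_max = min(int(support.max(initial=0)), nk)
        i = np.arange(new_max + 1)
        # transition matrix: P(next = i | current = j)
        trans = stats.hypergeom.pmf(i[:, None], n, support[None, :], nk)
        new = trans @ pmf[support]
        pmf = np.zeros(new_max + 1)
        pmf[: new_max + 1] = new
    s = pmf.sum()
    if not math.isclose(s, 1.0, rel_tol=1e-9):
        pmf = pmf / s
    return pmf


def multiset_intersection_test(
    sets: Sequence[set[str]],
    universe_size: int,
    observed_overlap: int | None = None,
    *,
    seed: int = 0,
    mc_draws: int = 200_000,
) -> MultisetTestResult:
    """Exact upper-tail test for the size of an m-way intersection.

    ``expected_overlap = n * prod(n_i / n)`` under independence.  The
    p-value is the exact probability that the intersection of
    independent uniform random sets of the given sizes is at least the
    observed size.  For very large problems (universe > 10^4 and more
    than 5 sets) a seeded Monte-Carlo estimate replaces the exact
    summation; the switch is reported in ``method``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    sizes = [len(s) for s in sets]
    n = int(universe_size)
    if max(sizes, default=0) > n:
        raise ValueError("a set is larger than the universe")
    if observed_overlap is None:
        inter = set(sets[0])
        for s in sets[1:]:
            inter &= set(s)
        observed_overlap = len(inter)
    expected = n * float(np.prod([s / n for s in sizes])) if n else 0.0

    if n > 10_000 and len(sets) > 5:
        rng = substream(seed, "multiset-mc")
        hits = 0
        for _ in range(mc_draws):
            x = rng.permutation(n)[: sizes[0]]
            inter_arr = np.zeros(n, bool)
            inter_arr[x] = True
            for sz in sizes[1:]:
                cur = np.zeros(n, bool)
                cur[rng.permutation(n)[:sz]] = True
                inter_arr &= cur
            if inter_arr.sum() >= observed_overlap:
                hits += 1
        p = (hits + 1) / (mc_draws + 1)
        return MultisetTestResult(expected, observed_overlap, p, "monte-carlo")

    pmf = multiset_intersection_distribution(sizes, n)
    if observed_overlap <= 0:
        p = 1.0
    elif observed_overlap >= len(pmf):
        p = 0.0
    else:
        p = float(pmf[observed_overlap:].sum())
    return MultisetTestResult(expected, int(observed_overlap), min(p, 1.0), "exact")


def recurrent_specific_deps(
    per_cohort_sets: Mapping[str, set[str]],
    universe: set[str],
    min_cohorts: int = 3,
) -> pd.DataFrame:
    """Rank genes by recurrence across cohort-level gene sets.

    Genes appearing in at least ``min_cohorts`` of the per-cohort sets
    are retained, annotated with the exact multi-set intersection
    p-value computed over the cohorts in which each gene appears.
    Sorted by recurrence (desc), then p (asc), then gene id.
    """
    if min_cohorts < 2:
        raise ValueError("min_cohorts must be >= 2")
    n = len(universe)
    counts: dict[str, list[str]] = {}
    for cohort in sorted(per_cohort_sets):
        for g in per_cohort_sets[cohort]:
            counts.setdefault(g, []).append(cohort)
    rows = []
    p_cache: dict[tuple[str, ...], float] = {}
    for gene in sorted(counts):
        cohorts = counts[gene]
        if len(cohorts) < min_cohorts:
            continue
        key = tuple(cohorts)
        if key not in p_cache:
            member_sets = [per_cohort_sets[c] for c in cohorts]
            inter = set.intersection(*map(set, member_sets))
            res = multiset_intersection_test(member_sets, n, len(inter))
            p_cache[key] = res.p
        rows.append((gene, len(cohorts), ",".join(cohorts), p_cache[key]))
    table = pd.DataFrame(rows, columns=["gene_id", "recurrence", "cohorts", "p"])
    if len(table):
        table = table.sort_values(
            ["recurrence", "p", "gene_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return table


def signature_collection(
    dep_tables: Mapping[str, pd.DataFrame]
) -> dict[tuple[str, str], set[str]]:
    """DEP signatures keyed by (cohort, direction) from DEP tables."""
    sigs: dict[tuple[str, str], set[str]] = {}
    for cohort, table in sorted(dep_tables.items()):
        if table.attrs.get("status") == "no_normals" or not len(table):
            continue
        for direction in ("up", "down"):
            genes = set(table.index[table["direction"] == direction])
            sigs[(cohort, direction)] = genes
    return sigs
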