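"""Module preservation across networks via best-match overlap tests.

A module from one network is scored against every module of a target
network with the one-sided Fisher exact test, FDR-corrected across the
target modules; the best match (smallest FDR) determines a three-way
call: *strong* (best FDR below ``q_strong`` and fold enrichment at
least ``fold_min``), *weak* (not strong, but best raw p below
``p_weak``), or *none*.  The universe of each comparison is the
intersection of the gene sets covered by the two networks.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_enrichment

__all__ = ["PreservationCall", "best_match_preservation", "preservation_matrix"]

CALL_COLUMNS = ["module_id", "cohort", "target", "best_match", "overlap",
                "fold", "p", "fdr", "klass", "universe_size"]


@dataclass
class PreservationCall:
    module_id: str
    target_network: str
    best_match_module: str | None
    best_p: float
    best_fdr: float
    fold: float
    overlap: int
    klass: str  # strong | weak | none
    universe_size: int = 0


def best_match_preservation(
    module: set[str],
    target_modules: Mapping[str, set[str]],
    universe: set[str],
    q_strong: float = 0.05,
    p_weak: float = 0.05,
    fold_min: float = 2.0,
    module_id: str = "query",
    target_network: str = "target",
) -> PreservationCall:
    """Score one module against a target network's module set."""
    if not target_modules:
        raise ValueError("target_modules must be non-empty")
    restricted = module & universe
    if not restricted:
        return PreservationCall(module_id, target_network, None, 1.0, 1.0,
                                0.0, 0, "none", len(universe))
    names = sorted(target_modules)
    results = [
        fisher_enrichment(restricted, target_modules[name], universe,
                          query_name=module_id, target_name=name)
        for name in names
    ]
    fdrs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    # best match: smallest FDR, ties by raw p then label
    best_idx = min(range(len(results)),
                   key=lambda i: (results[i].fdr, results[i].p, names[i]))
    best = results[best_idx]
    if best.fdr < q_strong and best.fold >= fold_min:
        klass = "strong"
    elif best.p < p_weak:
        klass = "weak"
    else:
        klass = "none"
    return PreservationCall(module_id, target_network, names[best_idx],
                            float(best.p), float(best.fdr), float(best.fold),
                            int(best.overlap), klass, len(universe))


def preservation_matrix(
    proteome_modules: Mapping[str, Mapping[str, set[str]]],
    universes: Mapping[str, set[str]],
    transcriptome_modules: Mapping[str, Mapping[str, set[str]]] | None = None,
    transcriptome_universes: Mapping[str, set[str]] | None = None,
    q_strong: float = 0.05,
    p_weak: float = 0.05,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Score every module of every cohort against every other cohort.

    ``proteome_modules[cohort]`` maps module id -> gene set; cross-cancer
    targets are the other cohorts' proteome module sets, and, when
    transcriptome modules are supplied, each cohort additionally gets a
    ``rna:<cohort>`` target (transcriptome preservation).  One row per
    (module, target).
    """
    cohorts = sorted(proteome_modules)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    rows = []
    for cohort in cohorts:
        mods = proteome_modules[cohort]
        targets: list[tuple[str, Mapping[str, set[str]], set[str]]] = [
            (other, proteome_modules[other],
             universes[cohort] & universes[other])
            for other in cohorts if other != cohort
        ]
        if transcriptome_modules is not None and cohort in transcriptome_modules:
            rna_uni = (transcriptome_universes or universes)[cohort]
            targets.append((f"rna:{cohort}", transcriptome_modules[cohort],
                            universes[cohort] & rna_uni))
        for module_id in sorted(mods):
            for target_name, target_mods, uni in targets:
                if not target_mods or not uni:
                    rows.append((module_id, cohort, target_name, None, 0,
                                 0.0, 1.0, 1.0, "none", len(uni)))
                    continue
                call = best_match_preservation(
                    mods[module_id], target_mods, uni, q_strong, p_weak,
                    fold_min, module_id=module_id, target_network=target_name)
                rows.append((call.module_id, cohort, call.target_network,
                             call.best_match_module, call.overlap, call.fold,
                             call.best_p, call.best_fdr, call.klass,
                             call.universe_size))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
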