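"""End-to-end pipeline: DEP -> networks -> preservation -> PCPIC -> drivers.

A single validated :class:`RunConfig` drives all stages; every file the
run produces is listed with a SHA-256 checksum in ``manifest.json`` so
reruns with the same config and seed can be verified byte-for-byte.
All stage randomness derives from the master seed through named
substreams (documented in :mod:`pancanet._rng`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__ as _version
from ._rng import substream_seed
from .dep import (call_deps, proteome_specific, recurrent_specific_deps,
                  signature_collection)
from .drivers import rank_pan_cancer, score_drivers
from .enrichment import read_gmt, write_gmt
from .network import (Module, ModuleHierarchy, PlanarNetwork, build_pmfg,
                      call_hubs, correlation_screen, multiscale_cluster)
from .pcpic import (build_overlap_graph, detect_communities, extract_core,
                    summarize_and_correlate)
from .preservation import preservation_matrix

__all__ = ["RunConfig", "CohortFiles", "run_pipeline", "load_config",
           "rerun_stage", "load_hierarchy_table"]


class CohortFiles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    proteome: str
    transcriptome: Optional[str] = None


class RunConfig(BaseModel):
    """All pipeline inputs and stage parameters; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    cohorts: dict[str, CohortFiles]
    metadata: str
    seed: int = 0

    # DEP stage
    q_dep: float = Field(0.05, gt=0, lt=1)
    q_rna: float = Field(0.05, gt=0, lt=1)
    min_cohorts_recurrent: int = Field(3, ge=2)

    # network stage
    fdr_cut: float = Field(0.05, gt=0, lt=1)
    screen_n_perm: int = Field(50, ge=20)
    alphas: list[float] = [0.5, 1.0, 2.0]
    report_alpha: float = 1.0
    min_size: int = Field(10, ge=3)
    cluster_n_perm: int = Field(50, ge=20)
    hub_n_perm: int = Field(50, ge=20)
    hub_q: float = Field(0.05, gt=0, lt=1)
    max_genes: Optional[int] = 2000
    transcriptome_networks: bool = True

    # preservation stage
    q_strong: float = Field(0.05, gt=0, lt=1)
    p_weak: float = Field(0.05, gt=0, lt=1)
    fold_min: float = Field(2.0, gt=0)

    # pcpic stage
    span_min: Optional[int] = None  # default: all cohorts
    core_min: Optional[int] = None  # default: majority of span
    p_edge: float = Field(0.05, gt=0, lt=1)

    # drivers stage
    h: int = Field(2, ge=1)
    q_driver: float = Field(0.05, gt=0, lt=1)
    min_neighbors: int = Field(5, ge=1)

    @model_validator(mode="after")
    def _check_span(self) -> "RunConfig":
        if self.span_min is not None and self.span_min > len(self.cohorts):
            raise ValueError(
                f"span_min={self.span_min} exceeds the {len(self.cohorts)} "
                "configured cohorts")
        if not self.cohorts:
            raise ValueError("at least one cohort required")
        if sorted(self.alphas) != list(self.alphas):
            raise ValueError("alphas must be sorted ascending")
        return self


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> Path:
    frame.to_csv(path, sep="\t", index=index)
    return path


def _hierarchy_json(h: ModuleHierarchy) -> dict:
    return {
        mid: {
            "parent": m.parent,
            "alpha": m.alpha if m.alpha != float("inf") else "inf",
            "compactness": None if pd.isna(m.compactness) else m.compactness,
            "split_p": None if pd.isna(m.split_p) else m.split_p,
            "genes": sorted(m.genes),
        }
        for mid, m in sorted(h.modules.items())
    }


def _compute_and_write_preservation(prot_modules, universes, rna_modules,
                                    rna_universes, config: RunConfig,
                                    out: Path) -> pd.DataFrame:
    calls = preservation_matrix(
        prot_modules, universes, rna_modules, rna_universes,
        q_strong=config.q_strong, p_weak=config.p_weak,
        fold_min=config.fold_min)
    _write_tsv(calls, out / "preservation.tsv", index=False)
    return calls


def _compute_and_write_pcpic(calls, prot_modules, universes, tumor_proteomes,
                             sigs, config: RunConfig, n_cohorts: int,
                             out: Path):
    graph = build_overlap_graph(calls)
    span_min = config.span_min or n_cohorts
    communities = detect_communities(graph, span_min)
    module_genes = {(c, m): genes for c, mods in prot_modules.items()
                    for m, genes in mods.items()}
    for community in communities:
        community.core = extract_core(community, module_genes, config.core_min)
    communities, pc_edges = summarize_and_correlate(
        communities, tumor_proteomes, sigs, universes, p_edge=config.p_edge)
    (out / "pcpic").mkdir(exist_ok=True)
    _write_tsv(pc_edges, out / "pcpic" / "pcpic_network.tsv", index=False)
    if communities:
        write_gmt({community.community_id: community.core
                   for community in communities},
                  out / "pcpic" / "pcpic_cores.gmt")
    (out / "pcpic" / "pcpic.json").write_text(json.dumps({
        community.community_id: {
            "members": sorted(map(list, community.member_modules)),
            "cohorts": sorted(community.cohorts_spanned),
            "core": sorted(community.core),
            "dep_enrichment": {
                f"{c}_{d}": {"overlap": e.overlap, "fold": e.fold, "p": e.p}
                for (c, d), e in sorted(community.dep_enrichment.items())},
        } for community in communities}, indent=1, sort_keys=True))
    return communities, pc_edges


def _compute_and_write_drivers(nets_hubs, sigs, config: RunConfig, out: Path,
                               notices: list[str]):
    (out / "drivers").mkdir(exist_ok=True)
    records: dict[str, pd.DataFrame] = {}
    for c in sorted(nets_hubs):
        cohort_sigs = {d: sigs.get((c, d), set()) for d in ("up", "down")}
        if not (cohort_sigs["up"] or cohort_sigs["down"]):
            notices.append(f"cohort {c}: no DEP signatures, excluded "
                           "from driver scoring")
            continue
        net, hubs = nets_hubs[c]
        rec = score_drivers(net, cohort_sigs, hubs, h=config.h,
                            q_driver=config.q_driver,
                            min_neighbors=config.min_neighbors)
        records[c] = rec
        _write_tsv(rec, out / "drivers" / f"{c}_drivers.tsv")
    ranking = None
    if len(records) >= 2:
        ranking = rank_pan_cancer(records)
        _write_tsv(ranking, out / "drivers" / "pan_ranking.tsv")
    return records, ranking


def _network_stage(expr: pd.DataFrame, tumor_samples: list[str],
                   cfg: RunConfig, seed: int):
    cols = [s for s in expr.columns if s in set(tumor_samples)]
    mat = expr[cols]
    if cfg.max_genes is not None and len(mat) > cfg.max_genes:
        variances = mat.var(axis=1)
        keep = variances.sort_values(ascending=False).index[: cfg.max_genes]
        mat = mat.loc[sorted(keep)]
    edges = correlation_screen(mat, n_perm=cfg.screen_n_perm,
                               fdr_cut=cfg.fdr_cut, seed=seed)
    net = build_pmfg(edges)
    hierarchy = multiscale_cluster(
        net, alphas=cfg.alphas, min_size=cfg.min_size,
        n_perm=cfg.cluster_n_perm, seed=seed)
    return net, hierarchy


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and persist outputs under ``out_dir``.

    Returns a dictionary of in-memory stage results; a stage failure
    raises with the failing stage named, keeping partial outputs on
    disk.  A cohort without normal samples skips DEP calling (logged in
    the manifest) and is excluded from driver scoring but still
    contributes a network, preservation calls and PCPIC membership.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "deps").mkdir(exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    (out / "pcpic").mkdir(exist_ok=True)
    (out / "drivers").mkdir(exist_ok=True)

    notices: list[str] = []
    results: dict = {}
    manifest: dict = {
        "pancanet_version": _version,
        "config": json.loads(config.model_dump_json()),
        "notices": notices,
        "inputs": {},
        "outputs": {},
    }
    metadata = pd.read_csv(config.metadata, sep="\t")
    manifest["inputs"][str(config.metadata)] = _sha256(Path(config.metadata))
    cohort_ids = sorted(config.cohorts)

    def stage(name: str):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - reraise with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return deco

    # ---------------- load expression ---------------------------------
    proteomes: dict[str, pd.DataFrame] = {}
    transcriptomes: dict[str, pd.DataFrame] = {}

    @stage("load")
    def _load():
        for c in cohort_ids:
            files = config.cohorts[c]
            proteomes[c] = pd.read_csv(files.proteome, sep="\t",
                                       index_col="gene_id")
            manifest["inputs"][files.proteome] = _sha256(Path(files.proteome))
            if files.transcriptome:
                transcriptomes[c] = pd.read_csv(files.transcriptome, sep="\t",
                                                index_col="gene_id")
                manifest["inputs"][files.transcriptome] = _sha256(
                    Path(files.transcriptome))

    # ---------------- DEP stage ---------------------------------------
    dep_prot: dict[str, pd.DataFrame] = {}
    dep_rna: dict[str, pd.DataFrame] = {}
    pspec_sets: dict[str, dict[str, set[str]]] = {}

    @stage("dep")
    def _dep():
        for c in cohort_ids:
            md = metadata[metadata["cohort"] == c]
            table = call_deps(proteomes[c], md, q_dep=config.q_dep)
            dep_prot[c] = table
            if table.attrs.get("status") == "no_normals":
                notices.append(f"cohort {c}: no normal samples, DEP skipped")
                continue
            _write_tsv(table, out / "deps" / f"{c}_proteome_dep.tsv")
            if c in transcriptomes:
                rna = call_deps(transcriptomes[c], md, q_dep=config.q_rna)
                dep_rna[c] = rna
                if rna.attrs.get("status") == "ok":
                    _write_tsv(rna, out / "deps" / f"{c}_rna_dep.tsv")
                    ps = proteome_specific(table, rna, config.q_dep, config.q_rna)
                    pspec_sets[c] = {"up": ps.up, "down": ps.down}

        sigs = signature_collection(dep_prot)
        if sigs:
            write_gmt({f"{c}_{d}": genes for (c, d), genes in sigs.items()},
                      out / "deps" / "dep_signatures.gmt")
        if pspec_sets:
            write_gmt({f"{c}_pspec_{d}": genes
                       for c, dd in pspec_sets.items()
                       for d, genes in dd.items()},
                      out / "deps" / "proteome_specific.gmt")
            per_cohort = {c: dd["up"] | dd["down"] for c, dd in pspec_sets.items()}
            universe = set().union(*(set(t.index) for t in dep_prot.values()))
            rec = recurrent_specific_deps(per_cohort, universe,
                                          config.min_cohorts_recurrent)
            _write_tsv(rec, out / "deps" / "recurrent_proteome_specific.tsv",
                       index=False)
            results["recurrent"] = rec
    results["dep_proteome"] = dep_prot
    results["dep_rna"] = dep_rna
    results["proteome_specific"] = pspec_sets

    # ---------------- network stage -----------------------------------
    networks: dict[str, tuple] = {}
    rna_networks: dict[str, tuple] = {}

    @stage("network")
    def _network():
        for c in cohort_ids:
            tumor = metadata.loc[(metadata["cohort"] == c)
                                 & (metadata["condition"] == "tumor"),
                                 "sample_id"].tolist()
            seed_c = substream_seed(config.seed, "network", c)
            net, hierarchy = _network_stage(proteomes[c], tumor, config, seed_c)
            hubs = call_hubs(net, hierarchy, n_perm=config.hub_n_perm,
                             hub_q=config.hub_q,
                             seed=substream_seed(config.seed, "hubs", c))
            networks[c] = (net, hierarchy, hubs)
            edge_frame = net.candidate_edges.copy()
            in_pmfg = {(a, b) for a, b in net.graph.edges}
            edge_frame["in_pmfg"] = [
                (a, b) in in_pmfg or (b, a) in in_pmfg
                for a, b in zip(edge_frame["gene_a"], edge_frame["gene_b"])]
            _write_tsv(edge_frame, out / "networks" / f"{c}_edges.tsv", index=False)
            _write_tsv(hierarchy.to_frame(), out / "networks" / f"{c}_modules.tsv",
                       index=False)
            (out / "networks" / f"{c}_hierarchy.json").write_text(
                json.dumps(_hierarchy_json(hierarchy), indent=1, sort_keys=True))
            _write_tsv(hubs, out / "networks" / f"{c}_hubs.tsv")
            if config.transcriptome_networks and c in transcriptomes:
                seed_r = substream_seed(config.seed, "network-rna", c)
                rnet, rhier = _network_stage(transcriptomes[c], tumor, config,
                                             seed_r)
                rna_networks[c] = (rnet, rhier)
                _write_tsv(rhier.to_frame(),
                           out / "networks" / f"{c}_rna_modules.tsv", index=False)
    results["networks"] = networks
    results["rna_networks"] = rna_networks

    # ---------------- preservation stage ------------------------------
    @stage("preservation")
    def _preservation():
        prot_modules = {
            c: {m: set(g) for m, g in networks[c][1].modules_at(
                config.report_alpha).items()}
            for c in cohort_ids
        }
        # universe of a comparison = genes measured in both datasets
        universes = {c: set(proteomes[c].index) for c in cohort_ids}
        rna_modules = {
            c: {m: set(g) for m, g in rna_networks[c][1].modules_at(
                config.report_alpha).items()}
            for c in rna_networks
        } or None
        rna_universes = {c: set(transcriptomes[c].index)
                         for c in rna_networks} or None
        calls = _compute_and_write_preservation(
            prot_modules, universes, rna_modules, rna_universes, config, out)
        results["preservation"] = calls
        results["prot_modules"] = prot_modules
        results["universes"] = universes

    # ---------------- pcpic stage -------------------------------------
    @stage("pcpic")
    def _pcpic():
        sigs = signature_collection(dep_prot)
        tumor_proteomes = {
            c: proteomes[c][metadata.loc[(metadata["cohort"] == c)
                                         & (metadata["condition"] == "tumor"),
                                         "sample_id"].tolist()]
            for c in cohort_ids
        }
        communities, pc_edges = _compute_and_write_pcpic(
            results["preservation"], results["prot_modules"],
            results["universes"], tumor_proteomes, sigs, config,
            len(cohort_ids), out)
        results["pcpics"] = communities
        results["pcpic_network"] = pc_edges

    # ---------------- drivers stage -----------------------------------
    @stage("drivers")
    def _drivers():
        sigs = signature_collection(dep_prot)
        nets_hubs = {c: (networks[c][0], networks[c][2]) for c in cohort_ids}
        records, ranking = _compute_and_write_drivers(
            nets_hubs, sigs, config, out, notices)
        results["driver_records"] = records
        if ranking is not None:
            results["driver_ranking"] = ranking

    # ---------------- manifest ----------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


# ----------------------------------------------------------------------
# stage re-execution from persisted intermediates
# ----------------------------------------------------------------------

def load_hierarchy_table(path: str | Path) -> ModuleHierarchy:
    """Rebuild a ModuleHierarchy from a persisted modules TSV."""
    frame = pd.read_csv(path, sep="\t")
    modules: dict[str, Module] = {}
    for mid, grp in frame.groupby("module_id"):
        parent = grp["parent_id"].iloc[0]
        parent = None if pd.isna(parent) or parent == "" else str(parent)
        modules[str(mid)] = Module(
            str(mid), parent, tuple(sorted(grp["gene_id"])),
            float(grp["alpha"].iloc[0]), float(grp["compactness"].iloc[0]),
            float(grp["split_p"].iloc[0]))
    return ModuleHierarchy(modules=modules)


def _load_network_table(path: str | Path) -> PlanarNetwork:
    """Rebuild a PlanarNetwork from a persisted edges TSV."""
    import networkx as nx
    frame = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    graph.add_nodes_from(sorted(set(frame["gene_a"]) | set(frame["gene_b"])))
    for row in frame[frame["in_pmfg"]].itertuples(index=False):
        rho = float(row.rho)
        graph.add_edge(row.gene_a, row.gene_b, weight=float(row.weight),
                       rho=rho, sign=1 if rho >= 0 else -1)
    return PlanarNetwork(graph=graph, embedding_certified=True,
                         candidate_edges=frame)


def _load_signatures(run_dir: Path) -> dict[tuple[str, str], set[str]]:
    gmt = run_dir / "deps" / "dep_signatures.gmt"
    if not gmt.exists():
        return {}
    out = {}
    for name, genes in read_gmt(gmt).items():
        cohort, direction = name.rsplit("_", 1)
        out[(cohort, direction)] = genes
    return out


def rerun_stage(run_dir: str | Path, stage: str,
                out_dir: str | Path | None = None) -> Path:
    """Re-execute one late pipeline stage from persisted intermediates.

    ``stage`` is one of ``preservation``, ``pcpic``, ``drivers``.  The
    stage reads its inputs (module tables, network edge lists, hub
    calls, DEP signatures, expression files named in the manifest's
    config) from ``run_dir`` and writes its outputs under ``out_dir``
    (default: ``run_dir``, overwriting).  These stages are
    deterministic given their inputs, so a rerun reproduces the
    original output files byte-for-byte.
    """
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir is not None else run_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    config = RunConfig(**manifest["config"])
    cohort_ids = sorted(config.cohorts)
    metadata = pd.read_csv(config.metadata, sep="\t")

    proteomes = {c: pd.read_csv(config.cohorts[c].proteome, sep="\t",
                                index_col="gene_id") for c in cohort_ids}
    prot_modules = {
        c: {m: set(g) for m, g in load_hierarchy_table(
            run_dir / "networks" / f"{c}_modules.tsv"
        ).modules_at(config.report_alpha).items()}
        for c in cohort_ids
    }
    universes = {c: set(proteomes[c].index) for c in cohort_ids}

    if stage == "preservation":
        rna_modules = {}
        rna_universes = {}
        for c in cohort_ids:
            rna_path = run_dir / "networks" / f"{c}_rna_modules.tsv"
            if rna_path.exists() and config.cohorts[c].transcriptome:
                rna_modules[c] = {
                    m: set(g) for m, g in load_hierarchy_table(
                        rna_path).modules_at(config.report_alpha).items()}
                rna = pd.read_csv(config.cohorts[c].transcriptome, sep="\t",
                                  index_col="gene_id")
                rna_universes[c] = set(rna.index)
        _compute_and_write_preservation(
            prot_modules, universes, rna_modules or None,
            rna_universes or None, config, out)
        return out / "preservation.tsv"

    if stage == "pcpic":
        calls = pd.read_csv(run_dir / "preservation.tsv", sep="\t",
                            dtype={"best_match": "string"})
        calls["best_match"] = calls["best_match"].astype(object).where(
            calls["best_match"].notna(), None)
        sigs = _load_signatures(run_dir)
        tumor_proteomes = {
            c: proteomes[c][metadata.loc[(metadata["cohort"] == c)
                                         & (metadata["condition"] == "tumor"),
                                         "sample_id"].tolist()]
            for c in cohort_ids
        }
        _compute_and_write_pcpic(calls, prot_modules, universes,
                                 tumor_proteomes, sigs, config,
                                 len(cohort_ids), out)
        return out / "pcpic"

    if stage == "drivers":
        sigs = _load_signatures(run_dir)
        nets_hubs = {}
        for c in cohort_ids:
            net = _load_network_table(run_dir / "networks" / f"{c}_edges.tsv")
            hubs = pd.read_csv(run_dir / "networks" / f"{c}_hubs.tsv",
                               sep="\t", index_col="gene_id")
            nets_hubs[c] = (net, hubs)
        _compute_and_write_drivers(nets_hubs, sigs, config, out, [])
        return out / "drivers"

    raise ValueError(f"unknown stage {stage!r}; expected preservation, "
                     "pcpic or drivers")
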