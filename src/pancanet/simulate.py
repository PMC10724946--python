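"""Synthetic multi-cohort proteogenomic panel generator.

Emulates the structure of a pan-cancer proteogenomic study: several
tumor cohorts measured on a shared gene universe, with a proteome and a
partially concordant transcriptome per cohort.  The generator plants

* **co-expression modules** — groups of genes sharing a single latent
  factor per cohort (gene value = loading x factor + noise), some
  present in every cohort ("pan" modules), some cohort-specific;
* **differential effects** — tumor-vs-normal mean shifts on module
  members and on scattered background genes, a configurable fraction of
  which are applied to the proteome only (proteome-specific DEPs);
* **hub regulators** — one designated member per module receives the
  maximal loading and reduced noise, making it the most strongly
  connected member of its module in any correlation-derived network.

Every quantity of interest downstream (module labels, DEP status,
proteome-specificity, regulator identity) is returned as ground truth,
so each pipeline stage has a parameter-recovery test surface.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CohortSpec",
    "PlantedModule",
    "PlantedTruth",
    "CohortPanel",
    "generate_cohort_panel",
    "write_panel",
    "read_panel",
    "reference_panel_specs",
    "reference_module_plan",
]

# Multiplier applied to a regulator gene's noise so that it is the
# cleanest readout of its module factor (and hence the module hub).
_HUB_NOISE_SCALE = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Sample-size and noise description of one synthetic cohort."""

    cohort_id: str
    n_tumor: int
    n_normal: int
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 0:
            raise ValueError("need n_tumor >= 3 and n_normal >= 0")
        if self.n_normal and self.n_normal < 3:
            raise ValueError("n_normal must be 0 (no-normal cohort) or >= 3")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module.

    ``cohorts=None`` (or ``is_pan=True``) means the module's latent
    factor is active in every cohort.  ``regulator`` optionally names a
    member gene seeded as the module hub.  ``dep_direction`` in
    {-1, 0, +1} says whether members receive a tumor shift and its sign;
    the generator assigns a random direction when left at ``None``.
    """

    module_id: str
    member_genes: tuple[str, ...]
    cohorts: tuple[str, ...] | None = None
    latent_effect_sd: float = 1.0
    is_pan: bool = False
    regulator: str | None = None
    dep_direction: int | None = None

    def __post_init__(self) -> None:
        if len(self.member_genes) < 10:
            raise ValueError(f"module {self.module_id}: needs >= 10 member genes")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise ValueError(f"module {self.module_id}: duplicate member genes")
        if not self.latent_effect_sd > 0:
            raise ValueError("latent_effect_sd must be positive")
        if self.regulator is not None and self.regulator not in self.member_genes:
            raise ValueError("regulator must be a member gene")

    def active_in(self, cohort_id: str) -> bool:
        return self.is_pan or self.cohorts is None or cohort_id in self.cohorts


@dataclass
class PlantedTruth:
    """Ground truth emitted with a generated panel."""

    modules: list[PlantedModule]
    dep_genes: dict[str, dict[str, float]]           # cohort -> gene -> signed shift
    proteome_specific_genes: dict[str, set[str]]     # cohort -> genes
    regulators: dict[str, set[str]]                  # cohort -> genes
    module_directions: dict[str, int] = field(default_factory=dict)

    def module_labels(self, cohort_id: str) -> dict[str, str]:
        """gene -> module_id map for modules active in a cohort."""
        labels: dict[str, str] = {}
        for m in self.modules:
            if m.active_in(cohort_id):
                for g in m.member_genes:
                    labels[g] = m.module_id
        return labels


@dataclass
class CohortPanel:
    """A generated multi-cohort panel: matrices, metadata and truth."""

    proteome: dict[str, pd.DataFrame]       # cohort -> genes x samples
    transcriptome: dict[str, pd.DataFrame]
    metadata: pd.DataFrame                  # sample_id, cohort, condition
    truth: PlantedTruth

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.proteome)

    def tumor_samples(self, cohort_id: str) -> list[str]:
        md = self.metadata
        sel = (md["cohort"] == cohort_id) & (md["condition"] == "tumor")
        return md.loc[sel, "sample_id"].tolist()

    def normal_samples(self, cohort_id: str) -> list[str]:
        md = self.metadata
        sel = (md["cohort"] == cohort_id) & (md["condition"] == "normal")
        return md.loc[sel, "sample_id"].tolist()


def _validate_plan(n_genes: int, plan: Sequence[PlantedModule]) -> None:
    seen: set[str] = set()
    total = 0
    for m in plan:
        overlap = seen.intersection(m.member_genes)
        if overlap:
            raise ValueError(f"planted modules overlap on genes {sorted(overlap)[:5]}")
        seen.update(m.member_genes)
        total += len(m.member_genes)
        if len(m.member_genes) > n_genes:
            raise ValueError("n_genes smaller than largest module")
    if total > n_genes:
        raise ValueError("sum of module sizes exceeds n_genes")


def _gene_universe(n_genes: int, plan: Sequence[PlantedModule]) -> list[str]:
    genes: list[str] = []
    for m in plan:
        genes.extend(m.member_genes)
    n_fill = n_genes - len(genes)
    width = max(4, len(str(n_genes)))
    genes.extend(f"BG{j:0{width}d}" for j in range(n_fill))
    return genes


def _factor_cov(modules: Sequence[PlantedModule],
                coupling: Sequence[tuple[str, str, float]]) -> np.ndarray:
    idx = {m.module_id: i for i, m in enumerate(modules)}
    cov = np.eye(len(modules))
    for a, b, r in coupling:
        if a in idx and b in idx:
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = float(r)
    return cov


def generate_cohort_panel(
    specs: Sequence[CohortSpec],
    n_genes: int,
    module_plan: Sequence[PlantedModule],
    dep_effect: float = 2.0,
    frac_proteome_specific: float = 0.3,
    seed: int = 0,
    *,
    rna_noise_sd: float | None = None,
    n_background_dep: int = 40,
    shift_module_members: bool = True,
    factor_coupling: Sequence[tuple[str, str, float]] = (),
) -> CohortPanel:
    """Generate proteome + transcriptome matrices for every cohort.

    Parameters
    ----------
    specs
        One :class:`CohortSpec` per cohort.
    n_genes
        Size of the shared gene universe (module members plus
        background genes named ``BG####``).
    module_plan
        Planted modules; member sets must be disjoint.
    dep_effect
        Absolute tumor-vs-normal mean shift (log-scale units) given to
        differential genes.
    frac_proteome_specific
        Fraction of each cohort's differential genes whose shift is
        applied to the proteome layer only.
    seed
        Master seed; all randomness is drawn from named substreams of
        it, so identical inputs give byte-identical output.
    rna_noise_sd
        Transcriptome noise level; defaults to the cohort's
        ``noise_sd``.
    n_background_dep
        Number of non-module genes per cohort that receive a shift
        (random sign each).
    shift_module_members
        When True (default), members of each planted module are
        differential with a coherent per-module direction, mimicking
        dysregulated pathways around a hub regulator.
    factor_coupling
        ``(module_a, module_b, rho)`` triples correlating two module
        factors within each cohort (used to plant cross-community
        correlation structure).
    """
    if not 0 <= frac_proteome_specific <= 1:
        raise ValueError("frac_proteome_specific must lie in [0, 1]")
    if not dep_effect > 0:
        raise ValueError("dep_effect must be positive")
    if len({s.cohort_id for s in specs}) != len(specs):
        raise ValueError("duplicate cohort ids")
    _validate_plan(n_genes, module_plan)

    genes = _gene_universe(n_genes, module_plan)
    gene_index = {g: i for i, g in enumerate(genes)}
    module_genes = {g for m in module_plan for g in m.member_genes}
    background = [g for g in genes if g not in module_genes]

    # Per-module quantities shared across cohorts: loadings, direction,
    # regulator.  Loadings are drawn from a module-named substream so a
    # module looks the same wherever it is active.
    loadings: dict[str, np.ndarray] = {}
    directions: dict[str, int] = {}
    for m in module_plan:
        rng_m = substream(seed, "module", m.module_id)
        lo = rng_m.uniform(0.6, 1.0, size=len(m.member_genes))
        if m.regulator is not None:
            lo[m.member_genes.index(m.regulator)] = 1.0
        loadings[m.module_id] = lo
        if m.dep_direction is not None:
            directions[m.module_id] = int(m.dep_direction)
        else:
            directions[m.module_id] = int(rng_m.choice([-1, 1]))

    baseline = substream(seed, "baseline").normal(0.0, 1.0, size=n_genes)

    proteome: dict[str, pd.DataFrame] = {}
    transcriptome: dict[str, pd.DataFrame] = {}
    meta_rows: list[tuple[str, str, str]] = []
    dep_genes: dict[str, dict[str, float]] = {}
    pspec: dict[str, set[str]] = {}
    regulators: dict[str, set[str]] = {}

    for spec in specs:
        c = spec.cohort_id
        n_samp = spec.n_tumor + spec.n_normal
        samples = [f"{c}_T{i:03d}" for i in range(spec.n_tumor)] + [
            f"{c}_N{i:03d}" for i in range(spec.n_normal)
        ]
        is_tumor = np.array([1] * spec.n_tumor + [0] * spec.n_normal, dtype=float)
        meta_rows += [(s, c, "tumor") for s in samples[: spec.n_tumor]]
        meta_rows += [(s, c, "normal") for s in samples[spec.n_tumor:]]

        active = [m for m in module_plan if m.active_in(c)]
        rng_c = substream(seed, "cohort", c)
        if active:
            cov = _factor_cov(active, factor_coupling)
            chol = np.linalg.cholesky(cov)  # raises if coupling not PD
            factors = rng_c.standard_normal((n_samp, len(active))) @ chol.T
            factors *= np.array([m.latent_effect_sd for m in active])
        else:
            factors = np.zeros((n_samp, 0))

        signal = np.tile(baseline[:, None], (1, n_samp))
        noise_scale = np.full(n_genes, spec.noise_sd)
        for k, m in enumerate(active):
            rows = [gene_index[g] for g in m.member_genes]
            signal[rows, :] += loadings[m.module_id][:, None] * factors[:, k][None, :]
            if m.regulator is not None:
                noise_scale[gene_index[m.regulator]] = spec.noise_sd * _HUB_NOISE_SCALE

        # --- differential effects -------------------------------------
        shifts: dict[str, float] = {}
        if shift_module_members:
            for m in active:
                d = directions[m.module_id]
                if d:
                    for g in m.member_genes:
                        shifts[g] = d * dep_effect
        rng_dep = substream(seed, "dep", c)
        n_bg = min(n_background_dep, len(background))
        if n_bg and spec.n_normal:
            bg_pick = rng_dep.choice(len(background), size=n_bg, replace=False)
            bg_sign = rng_dep.choice([-1.0, 1.0], size=n_bg)
            for j, sgn in zip(bg_pick, bg_sign):
                shifts[background[j]] = sgn * dep_effect
        if not spec.n_normal:
            shifts = {}  # no normals: differential truth undefined

        dep_list = sorted(shifts)
        n_ps = int(round(frac_proteome_specific * len(dep_list)))
        rng_ps = substream(seed, "pspec", c)
        if n_ps:
            picks = rng_ps.choice(len(dep_list), size=n_ps, replace=False)
            ps_set = {dep_list[j] for j in picks}
        else:
            ps_set = set()

        shift_mat = np.zeros((n_genes, n_samp))
        shift_rna = np.zeros((n_genes, n_samp))
        for g, s in shifts.items():
            shift_mat[gene_index[g]] += s * is_tumor
            if g not in ps_set:
                shift_rna[gene_index[g]] += s * is_tumor

        rna_sd = spec.noise_sd if rna_noise_sd is None else rna_noise_sd
        rna_scale = np.where(noise_scale < spec.noise_sd,
                             rna_sd * _HUB_NOISE_SCALE, rna_sd)
        eps_p = rng_c.standard_normal((n_genes, n_samp)) * noise_scale[:, None]
        eps_r = substream(seed, "cohort", c, "rna").standard_normal(
            (n_genes, n_samp)) * rna_scale[:, None]

        proteome[c] = pd.DataFrame(signal + shift_mat + eps_p,
                                   index=genes, columns=samples)
        transcriptome[c] = pd.DataFrame(signal + shift_rna + eps_r,
                                        index=genes, columns=samples)
        proteome[c].index.name = transcriptome[c].index.name = "gene_id"

        dep_genes[c] = shifts
        pspec[c] = ps_set
        regulators[c] = {m.regulator for m in active if m.regulator is not None}

    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "cohort", "condition"])
    truth = PlantedTruth(
        modules=list(module_plan),
        dep_genes=dep_genes,
        proteome_specific_genes=pspec,
        regulators=regulators,
        module_directions=directions,
    )
    return CohortPanel(proteome, transcriptome, metadata, truth)


# ----------------------------------------------------------------------
# Reference study conditions
# ----------------------------------------------------------------------

def reference_panel_specs(n_cohorts: int = 7, n_tumor: int = 50,
                          n_normal: int = 30, noise_sd: float = 0.5
                          ) -> list[CohortSpec]:
    """Cohort specs for the reference synthetic study (7 cohorts)."""
    return [CohortSpec(f"C{i + 1}", n_tumor, n_normal, noise_sd)
            for i in range(n_cohorts)]


def reference_module_plan(pan_size: int = 40, specific_size: int = 30,
                          specific_cohorts: tuple[str, str] = ("C1", "C2")
                          ) -> list[PlantedModule]:
    """One pan-cohort module plus two cohort-specific modules.

    Mirrors the canonical test panel: a 40-gene module active in all
    cohorts (with a hub regulator) and two 30-gene modules confined to
    one cohort each.
    """
    def ids(prefix: str, n: int) -> tuple[str, ...]:
        return tuple(f"{prefix}{j:03d}" for j in range(n))

    pan_members = ids("PAN", pan_size)
    plan = [PlantedModule("Mpan", pan_members, is_pan=True,
                          regulator=pan_members[0])]
    for k, cohort in enumerate(specific_cohorts, start=1):
        members = ids(f"SP{k}_", specific_size)
        plan.append(PlantedModule(f"Mspec{k}", members, cohorts=(cohort,),
                                  regulator=members[0]))
    return plan


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def _truth_to_json(truth: PlantedTruth) -> dict:
    return {
        "modules": [
            {**dataclasses.asdict(m),
             "member_genes": list(m.member_genes),
             "cohorts": list(m.cohorts) if m.cohorts is not None else None}
            for m in truth.modules
        ],
        "dep_genes": {c: dict(sorted(d.items())) for c, d in sorted(truth.dep_genes.items())},
        "proteome_specific_genes": {c: sorted(s) for c, s in sorted(truth.proteome_specific_genes.items())},
        "regulators": {c: sorted(s) for c, s in sorted(truth.regulators.items())},
        "module_directions": dict(sorted(truth.module_directions.items())),
    }


def _truth_from_json(obj: Mapping) -> PlantedTruth:
    modules = [
        PlantedModule(
            module_id=m["module_id"],
            member_genes=tuple(m["member_genes"]),
            cohorts=tuple(m["cohorts"]) if m["cohorts"] is not None else None,
            latent_effect_sd=m["latent_effect_sd"],
            is_pan=m["is_pan"],
            regulator=m["regulator"],
            dep_direction=m["dep_direction"],
        )
        for m in obj["modules"]
    ]
    return PlantedTruth(
        modules=modules,
        dep_genes={c: dict(d) for c, d in obj["dep_genes"].items()},
        proteome_specific_genes={c: set(v) for c, v in obj["proteome_specific_genes"].items()},
        regulators={c: set(v) for c, v in obj["regulators"].items()},
        module_directions=dict(obj["module_directions"]),
    )


def write_panel(panel: CohortPanel, directory: str | Path) -> dict[str, Path]:
    """Write one TSV per cohort per layer, sample metadata, and truth JSON.

    Expression TSVs have a ``gene_id`` first column and sample-id
    columns; values round-trip exactly through :func:`read_panel`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for c in panel.cohorts:
        for layer, mats in (("proteome", panel.proteome),
                            ("transcriptome", panel.transcriptome)):
            p = directory / f"{c}_{layer}.tsv"
            mats[c].to_csv(p, sep="\t")
            paths[f"{c}_{layer}"] = p
    mp = directory / "samples.tsv"
    panel.metadata.to_csv(mp, sep="\t", index=False)
    paths["metadata"] = mp
    tp = directory / "truth.json"
    tp.write_text(json.dumps(_truth_to_json(panel.truth), indent=1, sort_keys=True))
    paths["truth"] = tp
    return paths


def read_panel(directory: str | Path) -> CohortPanel:
    """Inverse of :func:`write_panel`."""
    directory = Path(directory)
    metadata = pd.read_csv(directory / "samples.tsv", sep="\t")
    truth = _truth_from_json(json.loads((directory / "truth.json").read_text()))
    cohorts = sorted(metadata["cohort"].unique())
    proteome, transcriptome = {}, {}
    for c in cohorts:
        proteome[c] = pd.read_csv(directory / f"{c}_proteome.tsv",
                                  sep="\t", index_col="gene_id")
        transcriptome[c] = pd.read_csv(directory / f"{c}_transcriptome.tsv",
                                       sep="\t", index_col="gene_id")
    return CohortPanel(proteome, transcriptome, metadata, truth)
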