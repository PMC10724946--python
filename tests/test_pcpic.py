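"""PCPIC assembly: overlap graph, communities, cores, cross-talk."""

import numpy as np
import pandas as pd
import pytest

import pancanet as pc
from pancanet.pcpic import (build_overlap_graph, detect_communities,
                            extract_core, summarize_and_correlate)
from pancanet.preservation import CALL_COLUMNS


def _call_row(module_id, cohort, target, best_match, klass):
    return (module_id, cohort, target, best_match, 10, 5.0, 1e-6, 1e-5,
            klass, 400)


def _calls(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestOverlapGraph:
    def test_no_strong_calls_edgeless(self):
        calls = _calls([_call_row("M1", "C1", "C2", "M1", "weak"),
                        _call_row("M1", "C2", "C1", "M1", "none")])
        g = build_overlap_graph(calls)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_strong_call_creates_cross_cohort_edge(self):
        calls = _calls([_call_row("M1", "C1", "C2", "M9", "strong")])
        g = build_overlap_graph(calls)
        assert g.has_edge(("C1", "M1"), ("C2", "M9"))

    def test_never_links_same_cohort(self):
        calls = _calls([_call_row("M1", "C1", "C1", "M2", "strong"),
                        _call_row("M1", "C1", "rna:C1", "R1", "strong")])
        g = build_overlap_graph(calls)
        assert g.number_of_edges() == 0


class TestCommunities:
    def _graph(self, spans):
        rows = []
        for name, cohorts in spans.items():
            for a, b in zip(cohorts, cohorts[1:]):
                rows.append(_call_row(name, a, b, name, "strong"))
        return build_overlap_graph(_calls(rows))

    def test_span_filter(self):
        g = self._graph({"M1": ["C1", "C2", "C3"],
                         "M2": ["C1", "C2", "C3", "C4", "C5", "C6", "C7"]})
        assert len(detect_communities(g, span_min=7)) == 1
        assert len(detect_communities(g, span_min=3)) == 2
        assert len(detect_communities(g, span_min=2)) == 2

    def test_disjoint_communities_not_merged(self):
        g = self._graph({"M1": ["C1", "C2", "C3"], "M2": ["C1", "C2", "C3"]})
        comms = detect_communities(g, span_min=3)
        assert len(comms) == 2
        members = [set(c.member_modules) for c in comms]
        assert not (members[0] & members[1])

    def test_span_min_validated(self):
        with pytest.raises(ValueError):
            detect_communities(self._graph({}), span_min=1)


class TestCore:
    def _pcpic(self, n_cohorts=7):
        members = frozenset((f"C{i}", "M1") for i in range(1, n_cohorts + 1))
        return pc.PCPIC("PCPIC1", members,
                        frozenset(f"C{i}" for i in range(1, n_cohorts + 1)))

    def test_ubiquitous_gene_always_in_core(self):
        p = self._pcpic()
        genes = {(f"C{i}", "M1"): {"everywhere", f"only{i}"}
                 for i in range(1, 8)}
        for cm in (1, 4, 7):
            assert "everywhere" in extract_core(p, genes, core_min=cm)

    def test_rare_gene_excluded(self):
        p = self._pcpic()
        genes = {(f"C{i}", "M1"): {"shared"} for i in range(1, 8)}
        genes[("C1", "M1")] = {"shared", "solo"}
        core = extract_core(p, genes, core_min=4)
        assert core == {"shared"}

    def test_core_monotone_in_core_min(self):
        rng = np.random.default_rng(0)
        p = self._pcpic()
        pool = [f"g{i}" for i in range(40)]
        genes = {(f"C{i}", "M1"): set(rng.choice(pool, 20, replace=False))
                 for i in range(1, 8)}
        cores = [extract_core(p, genes, core_min=k) for k in range(1, 8)]
        for small, big in zip(cores[1:], cores):
            assert small <= big

    def test_core_min_beyond_span_rejected(self):
        with pytest.raises(ValueError):
            extract_core(self._pcpic(3), {}, core_min=5)


class TestSummarize:
    def _panel_twin_modules(self, coupling=-0.8, seed=3):
        ids = lambda p, n: tuple(f"{p}{j:03d}" for j in range(n))
        plan = [pc.PlantedModule("MA", ids("A", 15), is_pan=True),
                pc.PlantedModule("MB", ids("B", 15), is_pan=True)]
        return pc.generate_cohort_panel(
            pc.reference_panel_specs(3, 30, 3), 60, plan, seed=seed,
            factor_coupling=[("MA", "MB", coupling)],
            shift_module_members=False, n_background_dep=0), plan

    def _communities(self, plan):
        out = []
        for k, mod in enumerate(plan, start=1):
            members = frozenset((f"C{i}", mod.module_id) for i in (1, 2, 3))
            p = pc.PCPIC(f"PCPIC{k}", members,
                         frozenset(f"C{i}" for i in (1, 2, 3)))
            p.core = set(mod.member_genes)
            out.append(p)
        return out

    def test_summary_tracks_latent_factor(self):
        panel, plan = self._panel_twin_modules(coupling=0.0)
        comms = self._communities(plan)
        tumor = {c: panel.proteome[c][panel.tumor_samples(c)]
                 for c in panel.cohorts}
        comms, _ = summarize_and_correlate(comms, tumor)
        summ = comms[0].summary_expression["C1"]
        gene = panel.proteome["C1"].loc["A000", summ.index]
        assert np.corrcoef(summ, gene)[0, 1] > 0.7

    def test_anticorrelated_factors_negative_edge(self):
        panel, plan = self._panel_twin_modules(coupling=-0.8)
        comms = self._communities(plan)
        tumor = {c: panel.proteome[c][panel.tumor_samples(c)]
                 for c in panel.cohorts}
        comms, edges = summarize_and_correlate(comms, tumor)
        assert len(edges) == 1
        assert edges.iloc[0]["sign"] == "-"
        assert edges.iloc[0]["rho"] < -0.5

    def test_sign_flip_flips_edge(self):
        panel, plan = self._panel_twin_modules(coupling=0.8)
        comms = self._communities(plan)
        tumor = {c: panel.proteome[c][panel.tumor_samples(c)]
                 for c in panel.cohorts}
        comms, edges = summarize_and_correlate(comms, tumor)
        assert len(edges) == 1
        assert edges.iloc[0]["sign"] == "+"

    def test_core_of_up_deps_enriched(self):
        panel, plan = self._panel_twin_modules(coupling=0.0)
        comms = self._communities(plan)[:1]
        tumor = {c: panel.proteome[c][panel.tumor_samples(c)]
                 for c in panel.cohorts}
        sigs = {("C1", "up"): set(plan[0].member_genes) | {"BG0000"},
                ("C1", "down"): set()}
        unis = {c: set(panel.proteome[c].index) for c in panel.cohorts}
        comms, _ = summarize_and_correlate(comms, tumor, sigs, unis)
        enr = comms[0].dep_enrichment[("C1", "up")]
        assert enr.p < 1e-6
        assert enr.fold > 2
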