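"""Differential-expression calling and the exact multi-set test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pancanet as pc
from pancanet.dep import (multiset_intersection_distribution,
                          multiset_intersection_test, proteome_specific,
                          recurrent_specific_deps)


def _matrix(values: np.ndarray, prefix="g"):
    genes = [f"{prefix}{i:04d}" for i in range(values.shape[0])]
    cols = ([f"T{i}" for i in range(values.shape[1] // 2)]
            + [f"N{i}" for i in range(values.shape[1] - values.shape[1] // 2)])
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=cols)


def _meta(frame):
    return pd.DataFrame({
        "sample_id": frame.columns,
        "cohort": "C1",
        "condition": ["tumor" if c.startswith("T") else "normal"
                      for c in frame.columns],
    })


class TestCallDeps:
    def test_identical_groups_are_null(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 12))
        frame = _matrix(vals)
        table = pc.call_deps(frame, _meta(frame))
        assert (table["t"] == 0).all()
        assert (table["p"] == 1).all()
        assert (table["direction"] == "ns").all()

    def test_constant_but_shifted_gene_is_extreme(self):
        vals = np.zeros((5, 12))
        vals[0, :6] = 3.0  # constant in both groups, different means
        frame = _matrix(vals)
        table = pc.call_deps(frame, _meta(frame))
        assert table.iloc[0]["p"] == 0.0
        assert table.iloc[0]["direction"] == "up"

    def test_no_normals_yields_explicit_empty_result(self):
        frame = _matrix(np.random.default_rng(0).normal(size=(5, 8)))
        meta = _meta(frame)
        meta["condition"] = "tumor"
        table = pc.call_deps(frame, meta)
        assert len(table) == 0
        assert table.attrs["status"] == "no_normals"

    def test_low_coverage_genes_dropped(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 12))
        vals[2, :10] = np.nan  # < 3 finite tumor values
        frame = _matrix(vals)
        table = pc.call_deps(frame, _meta(frame))
        assert table.attrs["n_dropped"] == 1
        assert "g0002" not in table.index

    def test_planted_shift_detected_with_high_power(self):
        """A 2-sigma shift at n=50/50 is found at FDR < 0.05 for >=90%."""
        rng = np.random.default_rng(2)
        sd = 0.5
        vals = rng.normal(0, sd, size=(1000, 100))
        shifted = rng.choice(1000, 100, replace=False)
        vals[shifted, :50] += 2 * sd
        frame = _matrix(vals)
        table = pc.call_deps(frame, _meta(frame))
        hit = table.iloc[shifted]["fdr"] < 0.05
        assert hit.mean() >= 0.9

    def test_fdr_invariants(self):
        rng = np.random.default_rng(3)
        frame = _matrix(rng.normal(size=(200, 30)))
        table = pc.call_deps(frame, _meta(frame))
        assert (table["fdr"] >= table["p"] - 1e-12).all()
        up = table["direction"] == "up"
        assert ((table.loc[up, "fdr"] < 0.05) & (table.loc[up, "log2fc"] > 0)).all()

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=100))
    def test_bh_matches_bruteforce(self, pvals):
        """The BH-FDR column reproduces the textbook step-up procedure."""
        pvals = np.array(pvals)
        n = len(pvals)
        order = np.argsort(pvals)
        brute = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            running = min(running, pvals[order[rank]] * n / (rank + 1))
            brute[order[rank]] = running
        from statsmodels.stats.multitest import multipletests
        ours = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, brute, atol=1e-12)


class TestProteomeSpecific:
    def _table(self, genes, fdrs, direction):
        return pd.DataFrame({
            "log2fc": [1.0 if direction == "up" else -1.0] * len(genes),
            "t": 1.0, "p": fdrs, "fdr": fdrs,
            "direction": [direction if f < 0.05 else "ns" for f in fdrs],
        }, index=pd.Index(genes, name="gene_id"))

    def test_rule_includes_and_excludes(self):
        prot = self._table(["a", "b"], [0.01, 0.01], "up")
        rna_in = self._table(["a", "b"], [0.5, 0.01], "up")
        res = proteome_specific(prot, rna_in)
        assert res.up == {"a"}          # mRNA null -> proteome-specific
        assert "b" not in res.up        # mRNA significant too -> excluded

    def test_empty_shared_universe_raises(self):
        prot = self._table(["a"], [0.01], "up")
        rna = self._table(["z"], [0.5], "up")
        with pytest.raises(ValueError, match="universe"):
            proteome_specific(prot, rna)

    def test_planted_recovery_on_panel(self, small_panel):
        """Planted proteome-specific genes recovered with high precision."""
        md = small_panel.metadata[small_panel.metadata["cohort"] == "C1"]
        dep_p = pc.call_deps(small_panel.proteome["C1"], md)
        dep_r = pc.call_deps(small_panel.transcriptome["C1"], md)
        res = proteome_specific(dep_p, dep_r)
        called = res.all_genes
        truth = small_panel.truth.proteome_specific_genes["C1"]
        from pancanet.evaluate import set_precision_recall
        precision, recall = set_precision_recall(called, truth)
        assert recall >= 0.9
        assert precision >= 0.8


class TestMultisetIntersection:
    def test_expected_overlap_closed_form(self):
        sets = [set(map(str, range(50))) for _ in range(3)]
        res = multiset_intersection_test(sets, 100)
        assert res.expected_overlap == pytest.approx(12.5)

    def test_reduces_to_hypergeometric_at_m2(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            na, nb = int(rng.integers(1, n)), int(rng.integers(1, n))
            a = set(map(str, rng.choice(n, na, replace=False)))
            b = set(map(str, rng.choice(n, nb, replace=False)))
            res = multiset_intersection_test([a, b], n)
            expect = stats.hypergeom.sf(len(a & b) - 1, n, nb, na)
            assert res.p == pytest.approx(expect, abs=1e-10)

    def test_matches_monte_carlo_at_m3(self):
        """Exact tail for 10/10/10 from 20 sits inside the MC interval."""
        pmf = multiset_intersection_distribution([10, 10, 10], 20)
        rng = np.random.default_rng(5)
        draws = 200_000
        obs = 5
        inter = np.ones((draws, 20), bool)
        for _ in range(3):
            idx = np.argpartition(rng.random((draws, 20)), 10, axis=1)[:, :10]
            mask = np.zeros((draws, 20), bool)
            np.put_along_axis(mask, idx, True, axis=1)
            inter &= mask
        p_mc = (inter.sum(axis=1) >= obs).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / draws)
        assert pmf[obs:].sum() == pytest.approx(p_mc, abs=2.58 * se + 1e-9)

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(6)
        sets = [set(map(str, rng.choice(30, k, replace=False)))
                for k in (10, 15, 20)]
        p1 = multiset_intersection_test(sets, 30).p
        p2 = multiset_intersection_test(sets[::-1], 30).p
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert 0 < p1 <= 1

    def test_p_is_one_when_nothing_observed(self):
        a, b = {"x"}, {"y"}
        assert multiset_intersection_test([a, b], 10).p == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            multiset_intersection_test([{"a"}], 10)
        with pytest.raises(ValueError):
            multiset_intersection_test([set("abcdef"), {"a"}], 3)

    def test_expected_matches_monte_carlo_mean(self):
        rng = np.random.default_rng(7)
        n, sizes = 40, [20, 25, 10]
        reps = 3000
        means = []
        for _ in range(reps):
            inter = None
            for k in sizes:
                s = set(rng.choice(n, k, replace=False).tolist())
                inter = s if inter is None else inter & s
            means.append(len(inter))
        expected = n * np.prod([k / n for k in sizes])
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - expected) < 3 * se + 1e-9


class TestRecurrence:
    def test_counting_and_annotation(self):
        sets = {f"C{i}": {"shared", f"only{i}"} for i in range(1, 8)}
        sets["C1"].add("trio"); sets["C2"].add("trio"); sets["C3"].add("trio")
        table = recurrent_specific_deps(sets, {f"u{i}" for i in range(100)}
                                        | {"shared", "trio"}, min_cohorts=3)
        assert table.iloc[0]["gene_id"] == "shared"
        assert table.iloc[0]["recurrence"] == 7
        trio = table[table["gene_id"] == "trio"].iloc[0]
        assert trio["recurrence"] == 3
        assert 0 < trio["p"] <= 1

    def test_min_cohorts_above_available_is_empty(self):
        sets = {f"C{i}": {"g"} for i in range(7)}
        table = recurrent_specific_deps(sets, {"g", "h"}, min_cohorts=8)
        assert len(table) == 0

    def test_planted_pan_gene_ranks_first(self, small_panel):
        truth = small_panel.truth
        per_cohort = {}
        for c in small_panel.cohorts:
            md = small_panel.metadata[small_panel.metadata["cohort"] == c]
            dp = pc.call_deps(small_panel.proteome[c], md)
            dr = pc.call_deps(small_panel.transcriptome[c], md)
            per_cohort[c] = proteome_specific(dp, dr).all_genes
        universe = set(small_panel.proteome["C1"].index)
        table = recurrent_specific_deps(per_cohort, universe, min_cohorts=2)
        pan_specific = [g for g in truth.proteome_specific_genes["C1"]
                        if all(g in truth.proteome_specific_genes[c]
                               for c in small_panel.cohorts)]
        if pan_specific:  # recurrence of planted genes tops the list
            top = set(table.head(len(pan_specific) + 5)["gene_id"])
            assert set(pan_specific) <= top
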