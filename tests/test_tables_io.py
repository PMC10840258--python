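import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from nichelda.tables_io import (OtuTable, aggregate_taxa, arcsinh_transform,
                                filter_contamination, first_visit,
                                intersect_samples, parse_lineage, rarefy,
                                read_count_table, taxon_labels,
                                write_count_table)


def _meta(sample_ids, subjects, niches, visits=None):
    d = {"sample_id": sample_ids, "subject_id": subjects, "niche": niches}
    if visits is not None:
        d["visit"] = visits
    return pd.DataFrame(d)


class TestReadWrite:
    def test_roundtrip_identity(self, toy_table, tmp_path):
        path = tmp_path / "toy.tsv"
        write_count_table(toy_table, path)
        back = read_count_table(path)
        assert back.counts.sum() == 14
        assert back.n_samples == 3 and back.n_otus == 2
        np.testing.assert_array_equal(back.counts, toy_table.counts)
        assert back.sample_ids == toy_table.sample_ids

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            OtuTable(np.ones((2, 2), dtype=int), ["s", "s"], ["a", "b"])

    def test_bad_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\to1\to2\ns1\t3\t-1\n")
        with pytest.raises(ValueError, match="s1.*o2"):
            read_count_table(path)
        path.write_text("sample_id\to1\to2\ns1\t3\t2.5\n")
        with pytest.raises(ValueError):
            read_count_table(path)

    def test_lineage_bearing_ids_become_taxonomy(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text(
            "sample_id\tk__Bacteria;g__Rothia\tk__Bacteria;g__Neisseria\n"
            "s1\t1\t2\n"
        )
        table = read_count_table(path)
        assert table.taxonomy is not None
        assert parse_lineage(table.taxonomy[0])["genus"] == "Rothia"


class TestRarefy:
    def test_boundary_sample_kept_unchanged(self):
        counts = np.array([[4000, 6000]])
        t = OtuTable(counts, ["s"], ["a", "b"])
        out = rarefy(t, 10_000, seed=0)
        np.testing.assert_array_equal(out.counts, counts)

    def test_row_sums_equal_depth_and_shallow_dropped(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 60, size=(20, 30))
        counts[3] = 0  # empty sample is dropped
        t = OtuTable(counts, [f"s{i}" for i in range(20)],
                     [f"o{j}" for j in range(30)])
        depth = int(np.sort(counts.sum(axis=1))[5])
        out = rarefy(t, depth, seed=1)
        assert np.all(out.depths() == depth)
        assert out.n_samples == int(np.sum(counts.sum(axis=1) >= depth))
        assert np.all(out.counts.sum(axis=0) > 0)  # all-zero columns removed

    def test_hypergeometric_expectation(self):
        # 20,000 reads subsampled to 10,000: per-OTU expectation is half the
        # original count; check the Monte-Carlo mean over 500 seeds against
        # the hypergeometric expectation within 3 binomial standard errors.
        counts = np.array([[12000, 5000, 2500, 500]])
        t = OtuTable(counts, ["s"], list("abcd"))
        acc = np.zeros(4)
        n_rep = 500
        for seed in range(n_rep):
            acc += rarefy(t, 10_000, seed=seed).to_frame().reindex(
                columns=list("abcd"), fill_value=0).to_numpy()[0]
        mean = acc / n_rep
        expect = counts[0] * 10_000 / 20_000
        p = counts[0] / 20_000
        se = np.sqrt(10_000 * p * (1 - p) * (1 - 9999 / 19999)) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expect) < 3 * np.maximum(se, 1e-9))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        t = OtuTable(rng.integers(0, 50, size=(5, 20)),
                     [f"s{i}" for i in range(5)], [f"o{j}" for j in range(20)])
        a = rarefy(t, 200, seed=7)
        b = rarefy(t, 200, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_all_below_depth_is_error(self, toy_table):
        with pytest.raises(ValueError, match="empty table"):
            rarefy(toy_table, 1000, seed=0)
        with pytest.raises(ValueError):
            rarefy(toy_table, 0, seed=0)


class TestContamination:
    def _table(self):
        counts = np.array([
            [5, 95],    # subj1 saliva: 5% contaminant
            [0, 100],   # subj1 plaque
            [2, 98],    # subj2 saliva: exactly 2%
            [0, 100],   # subj3 skin: contaminated but not an oral niche
        ])
        tax = ["k__Bacteria;g__Propionibacterium", "k__Bacteria;g__Streptococcus"]
        t = OtuTable(counts, ["a", "b", "c", "d"], ["o1", "o2"], tax)
        meta = _meta(["a", "b", "c", "d"], ["subj1", "subj1", "subj2", "subj3"],
                     ["saliva", "plaque", "saliva", "skin"])
        return t, meta

    def test_subject_level_exclusion_above_threshold(self):
        t, meta = self._table()
        out, excluded = filter_contamination(t, meta, "Propionibacterium", 0.02,
                                             oral_niches=["saliva", "plaque"])
        assert excluded == ["subj1"]
        assert out.sample_ids == ["c", "d"]  # both of subj1's samples gone

    def test_exactly_at_threshold_retained(self):
        t, meta = self._table()
        _, excluded = filter_contamination(t, meta, "Propionibacterium", 0.02,
                                           oral_niches=["saliva"])
        assert "subj2" not in excluded  # strict '>' rule

    def test_absent_taxon_counts_leave_table_unchanged(self):
        counts = np.array([[0, 10], [0, 20]])
        t = OtuTable(counts, ["a", "b"],
                     ["o1", "o2"],
                     ["k__Bacteria;g__Propionibacterium", "k__Bacteria;g__X"])
        meta = _meta(["a", "b"], ["s1", "s2"], ["saliva", "saliva"])
        out, excluded = filter_contamination(t, meta, "Propionibacterium", 0.02,
                                             oral_niches=["saliva"])
        assert excluded == [] and out.sample_ids == ["a", "b"]

    def test_unknown_taxon_is_error(self):
        t, meta = self._table()
        with pytest.raises(ValueError, match="not found"):
            filter_contamination(t, meta, "Borrelia", 0.02, ["saliva"])


class TestFirstVisit:
    def test_keeps_minimum_visit_per_subject(self):
        t = OtuTable(np.ones((4, 2), dtype=int), list("abcd"), ["o1", "o2"])
        meta = _meta(list("abcd"), ["s1"] * 3 + ["s2"],
                     ["saliva"] * 4, visits=[1, 2, 3, 2])
        out = first_visit(t, meta)
        assert out.sample_ids == ["a", "d"]  # s2's first visit is 2

    def test_single_visit_unchanged(self):
        t = OtuTable(np.ones((2, 2), dtype=int), list("ab"), ["o1", "o2"])
        meta = _meta(list("ab"), ["s1", "s2"], ["x", "x"], visits=[1, 1])
        assert first_visit(t, meta).sample_ids == ["a", "b"]

    def test_missing_visits_error_lists_samples(self):
        t = OtuTable(np.ones((2, 2), dtype=int), list("ab"), ["o1", "o2"])
        meta = _meta(list("ab"), ["s1", "s2"], ["x", "x"], visits=[1, None])
        with pytest.raises(ValueError, match="b"):
            first_visit(t, meta)


class TestArcsinh:
    def test_closed_forms(self):
        assert arcsinh_transform(np.array([0.0]))[0] == 0.0
        assert arcsinh_transform(np.array([1.0]))[0] == pytest.approx(
            float(sympy.log(1 + sympy.sqrt(2))), abs=1e-12)

    def test_matches_high_precision_reference(self):
        rng = np.random.default_rng(0)
        xs = rng.uniform(0, 500, size=100)
        ours = arcsinh_transform(xs)
        for x, o in zip(xs, ours):
            ref = float(sympy.asinh(sympy.Float(x, 30)))
            assert o == pytest.approx(ref, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_strictly_increasing_and_fixes_zero(self, a, b):
        fa, fb = arcsinh_transform(np.array([a, b]))
        if a < b:
            assert fa < fb
        assert arcsinh_transform(np.array([0.0]))[0] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            arcsinh_transform(np.array([np.nan]))


class TestAggregate:
    def test_same_genus_columns_summed(self):
        counts = np.array([[3, 4, 2]])
        tax = ["k__B;g__Streptococcus", "k__B;g__Streptococcus", "k__B;g__Rothia"]
        t = OtuTable(counts, ["s"], ["o1", "o2", "o3"], tax)
        out = aggregate_taxa(t, "genus")
        assert out.to_frame().loc["s", "Streptococcus"] == 7

    def test_unclassified_kept_at_higher_rank(self):
        counts = np.array([[5, 1]])
        tax = ["k__B;f__Veillonellaceae", "k__B;g__Rothia"]
        t = OtuTable(counts, ["s"], ["o1", "o2"], tax)
        out = aggregate_taxa(t, "genus")
        assert "f__Veillonellaceae" in out.otu_ids

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        S, V = 4, 12
        counts = rng.integers(0, 40, size=(S, V))
        genera = [f"g__G{rng.integers(4)}" for _ in range(V)]
        t = OtuTable(counts, [f"s{i}" for i in range(S)],
                     [f"o{j}" for j in range(V)],
                     [f"k__B;{g}" for g in genera])
        out = aggregate_taxa(t, "genus")
        np.testing.assert_array_equal(out.depths(), t.depths())

    def test_unknown_rank_is_error(self, toy_table):
        with pytest.raises(ValueError, match="rank"):
            taxon_labels(toy_table.otu_ids, None, rank="tribe")


class TestIntersect:
    def _pair(self, subj_a, subj_b):
        ta = OtuTable(np.arange(len(subj_a) * 2).reshape(-1, 2),
                      [f"a{i}" for i in range(len(subj_a))], ["o1", "o2"])
        tb = OtuTable(np.arange(len(subj_b) * 2).reshape(-1, 2),
                      [f"b{i}" for i in range(len(subj_b))], ["o1", "o2"])
        ma = _meta(ta.sample_ids, subj_a, ["A"] * len(subj_a))
        mb = _meta(tb.sample_ids, subj_b, ["B"] * len(subj_b))
        return ta, ma, tb, mb

    def test_common_subjects_same_order(self):
        ta, ma, tb, mb = self._pair(["1", "2", "3"], ["2", "3", "4"])
        a2, b2, common = intersect_samples(ta, ma, tb, mb)
        assert common == ["2", "3"]
        assert a2.sample_ids == ["a1", "a2"]
        assert b2.sample_ids == ["b0", "b1"]

    def test_identical_sets_aligned(self):
        ta, ma, tb, mb = self._pair(["x", "y"], ["y", "x"])
        a2, b2, common = intersect_samples(ta, ma, tb, mb)
        assert common == ["x", "y"]
        assert b2.sample_ids == ["b1", "b0"]

    def test_disjoint_sets_error(self):
        ta, ma, tb, mb = self._pair(["1"], ["2"])
        with pytest.raises(ValueError, match="no subjects"):
            intersect_samples(ta, ma, tb, mb)
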