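"""Interval containers, format round-trips, and the interval algebra
checked against a per-bp boolean-mask oracle."""
import numpy as np
import pandas as pd
import pytest

from dmvscan.genomic_io import (
    ExpressionMatrix,
    GenomeLayout,
    IntervalSet,
    coverage_fraction,
    filter_by_length,
    intersect,
    jaccard,
    read_bed,
    read_methyl_calls,
    subtract,
    write_bed,
    write_methyl_calls,
    MethylCalls,
)

from conftest import coverage_mask, random_interval_set


class TestGenomeLayout:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_chrom_sizes_round_trip(self, small_layout, tmp_path):
        path = tmp_path / "g.chrom.sizes"
        small_layout.to_file(path)
        assert GenomeLayout.from_file(path).lengths == small_layout.lengths


class TestBedIO:
    def test_parses_named_interval(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t0\t1000\tCGI1\n")
        iset = read_bed(path)
        (rec,) = list(iset)
        assert (rec.chrom, rec.start, rec.end, rec.name) == ("chr1", 0, 1000, "CGI1")

    def test_empty_interval_is_an_error(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t5\t5\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\tnope\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    def test_round_trip_identity_on_random_set(self, rng, small_layout, tmp_path):
        iset = random_interval_set(rng, small_layout, 100, with_names=True)
        path = tmp_path / "rt.bed"
        write_bed(iset, path)
        back = read_bed(path, layout=small_layout)
        pd.testing.assert_frame_equal(
            back.df[["chrom", "start", "end", "name"]],
            iset.df[["chrom", "start", "end", "name"]],
        )

    def test_overlap_merge_on_load_warns(self, tmp_path, caplog):
        path = tmp_path / "ov.bed"
        path.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        with caplog.at_level("WARNING"):
            iset = read_bed(path, merge_overlaps=True)
        assert [(r.start, r.end) for r in iset] == [(0, 150)]
        assert "union-merged" in caplog.text

    def test_chrom_absent_from_layout_is_hard_error(self, tmp_path, small_layout):
        path = tmp_path / "x.bed"
        path.write_text("chrUn\t0\t100\n")
        with pytest.raises(ValueError, match="chrUn"):
            read_bed(path, layout=small_layout)


class TestMethylCallsIO:
    def test_bedgraph_counts_row(self, tmp_path):
        path = tmp_path / "m.bedgraph"
        path.write_text("chr1\t100\t101\t3\t5\n")
        calls = read_methyl_calls(path, dialect="bedgraph-counts")
        pos, meth, total = calls.sites("chr1")
        assert (pos[0], meth[0], total[0]) == (100, 3, 5)

    def test_meth_exceeding_total_is_error(self, tmp_path):
        path = tmp_path / "m.bedgraph"
        path.write_text("chr1\t100\t101\t6\t5\n")
        with pytest.raises(ValueError, match="6 > total 5"):
            read_methyl_calls(path)

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("chr1\t1\t+\t1\t1\n")
        with pytest.raises(ValueError, match="dialect"):
            read_methyl_calls(path, dialect="wig")

    def test_cpg_report_strand_merge(self, tmp_path):
        # 1-based report: plus C at 101, minus G at 102 -> one 0-based site at 100
        path = tmp_path / "r.txt"
        path.write_text("chr1\t101\t+\t3\t2\tCG\nchr1\t102\t-\t1\t4\tCG\n")
        calls = read_methyl_calls(path, dialect="cpg-report")
        pos, meth, total = calls.sites("chr1")
        assert len(pos) == 1
        assert (pos[0], meth[0], total[0]) == (100, 4, 10)

    def test_cpg_report_zero_based_flag(self, tmp_path):
        path = tmp_path / "r.txt"
        path.write_text("chr1\t100\t+\t3\t2\nchr1\t101\t-\t1\t4\n")
        calls = read_methyl_calls(path, dialect="cpg-report", one_based=False)
        pos, meth, total = calls.sites("chr1")
        assert (pos[0], meth[0], total[0]) == (100, 4, 10)

    def test_write_read_round_trip(self, rng, small_layout, tmp_path):
        pos = np.sort(rng.choice(100_000, size=500, replace=False))
        total = rng.integers(1, 40, size=500)
        meth = rng.binomial(total, 0.5)
        calls = MethylCalls({"chr1": (pos, meth, total)}, layout=small_layout)
        path = tmp_path / "rt.bedgraph"
        write_methyl_calls(calls, path)
        back = read_methyl_calls(path, layout=small_layout)
        for a, b in zip(calls.sites("chr1"), back.sites("chr1")):
            np.testing.assert_array_equal(a, b)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MethylCalls({"chr1": ([10, 10], [1, 1], [2, 2])})


class TestIntervalAlgebra:
    def test_subtract_worked_example(self):
        a = IntervalSet.from_records([("chr1", 0, 10_000)])
        b = IntervalSet.from_records([("chr1", 1000, 2000), ("chr1", 5000, 6000)])
        got = [(r.start, r.end) for r in subtract(a, b)]
        assert got == [(0, 1000), (2000, 5000), (6000, 10_000)]

    def test_coverage_fraction_union_merges_b(self):
        b = IntervalSet.from_records([("chr1", 0, 3000), ("chr1", 2000, 6000)])
        assert coverage_fraction(("chr1", 0, 10_000), b) == pytest.approx(0.6)

    def test_filter_by_length_is_strict(self):
        iset = IntervalSet.from_records(
            [("chr1", 0, 4000), ("chr1", 10_000, 15_000), ("chr1", 20_000, 25_001)]
        )
        kept = filter_by_length(iset, 5000)
        assert [(r.start, r.end) for r in kept] == [(20_000, 25_001)]

    def test_filter_matches_brute_force_on_random_set(self, rng, small_layout):
        iset = random_interval_set(rng, small_layout, 1000, max_len=8000)
        threshold = 3000
        expected = sum(1 for r in iset if r.end - r.start > threshold)
        assert len(filter_by_length(iset, threshold)) == expected

    @pytest.mark.parametrize("trial", range(5))
    def test_algebra_matches_bp_mask_oracle(self, trial, small_layout):
        rng = np.random.default_rng(1000 + trial)
        a = random_interval_set(rng, small_layout, 30)
        b = random_interval_set(rng, small_layout, 30)
        mask_b = coverage_mask(b, small_layout)
        sub = subtract(a, b)
        inter = intersect(a, b)
        # rebuild per-record masks and compare bp-for-bp
        for name, result, keep_covered in (("sub", sub, False), ("inter", inter, True)):
            got = coverage_mask(result, small_layout)
            expected = {c: np.zeros(small_layout[c], dtype=bool) for c in small_layout.chroms}
            for rec in a:
                span = slice(rec.start, rec.end)
                m = mask_b[rec.chrom][span]
                expected[rec.chrom][span] |= m if keep_covered else ~m
            for c in small_layout.chroms:
                np.testing.assert_array_equal(got[c], expected[c], err_msg=f"{name}:{c}")
        # coverage fractions against the mask
        for rec in a:
            frac = coverage_fraction(rec, b)
            expect = mask_b[rec.chrom][rec.start:rec.end].mean()
            assert frac == pytest.approx(expect)
            assert 0 <= frac <= 1

    def test_subtract_intersect_partition_each_record(self, rng, small_layout):
        a = random_interval_set(rng, small_layout, 50, with_names=True)
        b = random_interval_set(rng, small_layout, 50)
        sub = subtract(a, b).df.groupby("name").apply(lambda d: (d.end - d.start).sum(), include_groups=False)
        inter = intersect(a, b).df.groupby("name").apply(lambda d: (d.end - d.start).sum(), include_groups=False)
        for rec in a:
            total = sub.get(rec.name, 0) + inter.get(rec.name, 0)
            assert total == rec.end - rec.start

    def test_jaccard_identity_and_disjoint(self):
        a = IntervalSet.from_records([("chr1", 0, 1000)])
        b = IntervalSet.from_records([("chr1", 5000, 6000)])
        assert jaccard(a, a) == 1.0
        assert jaccard(a, b) == 0.0


class TestExpressionMatrix:
    def test_requires_lineage_for_every_sample(self):
        fpkm = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
        with pytest.raises(ValueError, match="s2"):
            ExpressionMatrix(fpkm, {"s1": "blood"})

    def test_rejects_negative_fpkm(self):
        fpkm = pd.DataFrame({"s1": [-1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            ExpressionMatrix(fpkm, {"s1": "blood"})

    def test_lineage_means_are_unweighted_sample_means(self):
        fpkm = pd.DataFrame(
            {"b1": [2.0], "b2": [4.0], "e1": [10.0]}, index=["g1"]
        )
        expr = ExpressionMatrix(fpkm, {"b1": "blood", "b2": "blood", "e1": "endoderm"})
        means = expr.lineage_means()
        assert means.loc["g1", "blood"] == pytest.approx(3.0)
        assert means.loc["g1", "endoderm"] == pytest.approx(10.0)

    def test_tsv_round_trip(self, tmp_path):
        fpkm = pd.DataFrame({"b1": [1.5, 0.0], "e1": [2.0, 3.0]}, index=["g1", "g2"])
        expr = ExpressionMatrix(fpkm, {"b1": "blood", "e1": "endoderm"})
        expr.write(tmp_path / "f.tsv", tmp_path / "l.tsv")
        back = ExpressionMatrix.read(tmp_path / "f.tsv", tmp_path / "l.tsv")
        pd.testing.assert_frame_equal(back.fpkm, expr.fpkm)
        assert back.sample_lineage.to_dict() == expr.sample_lineage.to_dict()
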