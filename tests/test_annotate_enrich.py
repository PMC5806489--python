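"""Chromatin-state annotation, CGI partitioning, KO-WT methylation change,
meta-profiles, length-matched controls and the enrichment test."""
import numpy as np
import pandas as pd
import pytest

from dmvscan import annotate_enrich as ae
from dmvscan.genomic_io import GenomeLayout, IntervalSet, MethylCalls

from conftest import coverage_mask, random_interval_set


class TestChromatinState:
    def make(self, k4_rows, k27_rows):
        dmvs = IntervalSet.from_records([("chr1", 0, 10_000, "D1")])
        k4 = IntervalSet.from_records(k4_rows)
        k27 = IntervalSet.from_records(k27_rows)
        return ae.chromatin_state(dmvs, k4, k27)

    def test_k4_only(self):
        got = self.make([("chr1", 500, 1500)], [("chr1", 50_000, 60_000)])
        assert got.loc["D1", "state"] == "K4-only"

    def test_both_marks(self):
        got = self.make([("chr1", 500, 1500)], [("chr1", 2000, 9000)])
        assert got.loc["D1", "state"] == "K4+K27"

    def test_none(self):
        got = self.make([("chr2", 0, 100)], [("chr1", 10_000, 11_000)])
        assert got.loc["D1", "state"] == "none"

    def test_random_placements_match_mask_oracle(self, rng, small_layout):
        dmvs = random_interval_set(rng, small_layout, 30, with_names=True)
        dmvs = IntervalSet(
            dmvs.df.assign(name=[f"D{i}" for i in range(len(dmvs))]), layout=small_layout
        )
        k4 = random_interval_set(rng, small_layout, 15)
        k27 = random_interval_set(rng, small_layout, 15)
        eed = random_interval_set(rng, small_layout, 10)
        got = ae.chromatin_state(dmvs, k4, k27, eed)
        m4, m27, meed = (coverage_mask(s, small_layout) for s in (k4, k27, eed))
        for rec in dmvs:
            has4 = m4[rec.chrom][rec.start:rec.end].any()
            has27 = m27[rec.chrom][rec.start:rec.end].any()
            expected = ("K4+K27" if has4 and has27 else
                        "K4-only" if has4 else "K27-only" if has27 else "none")
            assert got.loc[rec.name, "state"] == expected
            assert got.loc[rec.name, "polycomb"] == meed[rec.chrom][rec.start:rec.end].any()


class TestPartitionCgi:
    def test_worked_example(self):
        cgis = IntervalSet.from_records([("chr1", 1000, 2000), ("chr1", 5000, 6000)])
        cgi, non = ae.partition_cgi(("chr1", 0, 10_000), cgis)
        assert [(r.start, r.end) for r in non] == [(0, 1000), (2000, 5000), (6000, 10_000)]
        assert [(r.start, r.end) for r in cgi] == [(1000, 2000), (5000, 6000)]

    def test_dmv_inside_cgi_has_empty_non_cgi_part(self):
        cgis = IntervalSet.from_records([("chr1", 0, 20_000)])
        cgi, non = ae.partition_cgi(("chr1", 5000, 8000), cgis)
        assert len(non) == 0
        assert [(r.start, r.end) for r in cgi] == [(5000, 8000)]

    def test_parts_conserve_length_on_random_cases(self, rng, small_layout):
        for _ in range(200):
            start = int(rng.integers(0, 90_000))
            dmv = ("chr1", start, start + int(rng.integers(1000, 10_000)))
            cgis = random_interval_set(rng, small_layout, 10, max_len=3000)
            cgi, non = ae.partition_cgi(dmv, cgis)
            total = sum(r.end - r.start for r in cgi) + sum(r.end - r.start for r in non)
            assert total == dmv[2] - dmv[1]


class TestMethylationChange:
    def make_calls(self, layout, levels, lam=30, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.arange(50, layout["chr1"], 100)
        m = np.full(len(pos), levels)
        total = rng.poisson(lam, size=len(pos)) + 1
        meth = rng.binomial(total, m)
        return MethylCalls({"chr1": (pos, meth, total)}, layout=layout)

    def test_identical_methylomes_have_zero_delta(self, small_layout):
        calls = self.make_calls(small_layout, 0.3)
        regions = IntervalSet.from_records([("chr1", 0, 50_000, "R1")], layout=small_layout)
        cgis = IntervalSet.from_records([("chr1", 10_000, 12_000)], layout=small_layout)
        out = ae.methylation_change(calls, calls, regions, cgis)
        assert out.loc["R1", "delta"] == 0.0
        assert not out.loc["R1", "hypermethylated"]

    def test_planted_gain_is_recovered_and_flagged(self, small_layout):
        wt = self.make_calls(small_layout, 0.05, seed=1)
        ko = self.make_calls(small_layout, 0.35, seed=2)
        regions = IntervalSet.from_records([("chr1", 0, 50_000, "R1")], layout=small_layout)
        cgis = IntervalSet.empty()
        out = ae.methylation_change(wt, ko, regions, cgis)
        assert out.loc["R1", "delta"] == pytest.approx(0.30, abs=0.02)
        assert bool(out.loc["R1", "hypermethylated"])

    def test_uncovered_region_is_missing_and_logged(self, small_layout, caplog):
        calls = MethylCalls({"chr1": ([10], [1], [2])}, layout=small_layout)
        regions = IntervalSet.from_records([("chr2", 0, 10_000, "R1")], layout=small_layout)
        with caplog.at_level("WARNING"):
            out = ae.methylation_change(calls, calls, regions, IntervalSet.empty())
        assert np.isnan(out.loc["R1", "delta"])
        assert "R1" in caplog.text


class TestSiteDensityProfile:
    def test_uniform_body_sites(self):
        layout = GenomeLayout({"chr1": 100_000})
        region = IntervalSet.from_records([("chr1", 40_000, 50_000, "R")], layout=layout)
        mids = np.arange(40_250, 50_000, 500)  # 20 sites spread over the body
        sites = IntervalSet.from_records([("chr1", int(p), int(p) + 1) for p in mids], layout=layout)
        prof = ae.site_density_profile(sites, region, flank_bp=5000, body_bins=20,
                                       flank_bin_bp=1000)
        nf = prof.n_flank_bins
        np.testing.assert_allclose(prof.density[nf:nf + 20], 2.0)
        np.testing.assert_allclose(prof.density[:nf], 0.0)
        np.testing.assert_allclose(prof.density[nf + 20:], 0.0)

    def test_no_sites_gives_zero_profile(self):
        layout = GenomeLayout({"chr1": 100_000})
        region = IntervalSet.from_records([("chr1", 40_000, 50_000)], layout=layout)
        prof = ae.site_density_profile(IntervalSet.empty(), region)
        np.testing.assert_allclose(prof.density, 0.0)

    def test_uniform_genome_density_flat_profile(self, rng):
        layout = GenomeLayout({"chr1": 1_000_000})
        n_sites = 2000  # 2 per kb genome-wide
        pos = np.sort(rng.choice(1_000_000, size=n_sites, replace=False))
        sites = IntervalSet.from_records([("chr1", int(p), int(p) + 1) for p in pos], layout=layout)
        rows = [("chr1", s, s + 10_000) for s in range(100_000, 900_000, 40_000)]
        regions = IntervalSet.from_records(rows, layout=layout)
        prof = ae.site_density_profile(sites, regions, flank_bp=10_000, body_bins=10)
        # every bin's density should sit near the global 2/kb within CLT error
        global_density = n_sites / 1000.0
        se = np.sqrt(global_density / (len(regions) * 1.0))  # Poisson, ~1 kb bins
        assert np.all(np.abs(prof.density - global_density) < 4 * se + 0.5)


class TestRandomControls:
    def test_same_seed_reproduces(self, small_layout):
        regions = IntervalSet.from_records([("chr1", 0, 5000), ("chr2", 0, 2000)])
        a = ae.random_length_matched_controls(regions, small_layout, n_draws=3, seed=5)
        b = ae.random_length_matched_controls(regions, small_layout, n_draws=3, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_length_multiset_is_conserved(self, rng, small_layout):
        regions = random_interval_set(rng, small_layout, 20)
        (draw,) = ae.random_length_matched_controls(regions, small_layout, seed=1)
        assert sorted(draw.lengths()) == sorted(regions.lengths())

    def test_exclusion_is_respected(self, small_layout):
        exclude = IntervalSet.from_records([("chr1", 0, 99_000)], layout=small_layout)
        regions = IntervalSet.from_records([("chr1", 0, 30_000)])
        for draw in ae.random_length_matched_controls(regions, small_layout, n_draws=20,
                                                      seed=2, exclude=exclude):
            for rec in draw:
                if rec.chrom == "chr1":
                    assert rec.start >= 99_000

    def test_impossible_placement_errors(self, small_layout):
        exclude = IntervalSet.from_records(
            [("chr1", 0, 100_000), ("chr2", 0, 60_000)], layout=small_layout
        )
        regions = IntervalSet.from_records([("chr1", 0, 30_000, "R1")])
        with pytest.raises(RuntimeError, match="R1"):
            ae.random_length_matched_controls(regions, small_layout, seed=3, exclude=exclude,
                                              max_tries=50)

    def test_control_density_is_unbiased(self, rng):
        layout = GenomeLayout({"chr1": 500_000})
        pos = np.sort(rng.choice(500_000, size=1000, replace=False))
        sites = IntervalSet.from_records([("chr1", int(p), int(p) + 1) for p in pos],
                                         layout=layout)
        regions = IntervalSet.from_records([("chr1", 0, 10_000), ("chr1", 50_000, 70_000)])
        dens = ae.control_densities(sites, regions, layout, n_draws=1000, seed=9)
        global_density = 1000 / 500.0  # sites per kb
        se = dens.std() / np.sqrt(len(dens))
        assert abs(dens.mean() - global_density) < 3 * se + 0.01


class TestEnrichmentTest:
    def test_observed_below_all_controls(self):
        out = ae.enrichment_test(0.1, np.full(999, 1.0))
        assert out["p"] == 1.0

    def test_observed_above_all_controls(self):
        out = ae.enrichment_test(5.0, np.linspace(0.1, 1.0, 999))
        assert out["p"] == pytest.approx(1 / 1000)
        assert out["fold"] == pytest.approx(5.0 / np.linspace(0.1, 1.0, 999).mean())

    def test_zero_control_mean_flags_fold(self):
        out = ae.enrichment_test(1.0, np.zeros(200))
        assert np.isnan(out["fold"])
        assert 0 < out["p"] <= 1

    def test_requires_100_draws(self):
        with pytest.raises(ValueError):
            ae.enrichment_test(1.0, np.ones(50))


class TestStratifiedScoreCompare:
    def make_tables(self, rng, n=80, shift=0.0):
        dens = rng.uniform(0, 10, size=n)
        scores = rng.normal(0.5, 0.1, size=n)
        a = pd.DataFrame({"cg_density": dens, "score": scores + shift})
        b = pd.DataFrame({"cg_density": dens, "score": scores})
        return a, b

    def test_identical_sets_identical_medians(self, rng):
        a, b = self.make_tables(rng)
        out = ae.stratified_score_compare(b, b)
        for k in out["stratum"].unique():
            sub = out[out["stratum"] == k]
            assert sub[sub["set"] == "a"]["median"].iloc[0] == sub[sub["set"] == "b"]["median"].iloc[0]

    def test_uniform_shift_moves_every_stratum_median(self, rng):
        a, b = self.make_tables(rng, shift=-0.1)
        out = ae.stratified_score_compare(a, b)
        for k in out["stratum"].unique():
            sub = out[out["stratum"] == k]
            ma = sub[sub["set"] == "a"]["median"].iloc[0]
            mb = sub[sub["set"] == "b"]["median"].iloc[0]
            assert ma == pytest.approx(mb - 0.1)

    def test_empty_stratum_reported_with_n_zero(self):
        a = pd.DataFrame({"cg_density": [1.0, 1.0], "score": [0.5, 0.6]})
        b = pd.DataFrame({"cg_density": [1.0], "score": [0.4]})
        out = ae.stratified_score_compare(a, b, n_strata=4)
        assert (out["n"] == 0).any()
        assert len(out) == 8


class TestOverlapPercentage:
    def test_quarter_overlap(self):
        group = IntervalSet.from_records(
            [("chr1", i * 20_000, i * 20_000 + 5000) for i in range(4)]
        )
        features = IntervalSet.from_records([("chr1", 1000, 2000)])
        out = ae.overlap_percentage({"I": group}, features)
        assert out.loc["I", "percent"] == 25.0

    def test_no_features_zero_percent(self):
        group = IntervalSet.from_records([("chr1", 0, 5000)])
        out = ae.overlap_percentage({"I": group}, IntervalSet.empty())
        assert out.loc["I", "percent"] == 0.0

    def test_empty_group_undefined(self):
        out = ae.overlap_percentage({"II": IntervalSet.empty()},
                                    IntervalSet.from_records([("chr1", 0, 100)]))
        assert np.isnan(out.loc["II", "percent"])
        assert out.loc["II", "n"] == 0

    def test_matches_brute_force_overlap_count(self, rng, small_layout):
        group = random_interval_set(rng, small_layout, 40)
        features = random_interval_set(rng, small_layout, 20)
        out = ae.overlap_percentage({"g": group}, features)
        fmask = coverage_mask(features, small_layout)
        expected = sum(1 for r in group if fmask[r.chrom][r.start:r.end].any())
        assert out.loc["g", "n_overlapping"] == expected
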