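"""Methylation ingestion, region aggregation, profiles and random regions."""

import math

import numpy as np
import pandas as pd
import pytest

from demethylome.intervals import GenomicInterval, ParseError
from demethylome.methylome import (
    MethylationTable,
    aggregate_region_methylation,
    classify_promoter_methylation,
    compartment_medians,
    methylation_profile,
    sample_random_regions,
)
from oracles import brute_profile, brute_region_mean, random_calls, random_intervals


def _table(calls, condition="parental"):
    frame = pd.DataFrame(calls, columns=["chrom", "pos", "meth", "cov"])
    return MethylationTable(condition, frame)


class TestReader:
    def test_percent_dialect_scaled_to_fraction(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t10\t84\t5\nchr1\t20\t0\t3\nchr1\t30\t100\t2\n")
        t = MethylationTable.read(p, "x", dialect="percent")
        pos, meth, cov = t.arrays("chr1")
        assert len(t) == 3
        assert meth.tolist() == [0.84, 0.0, 1.0]

    def test_duplicate_position_rejected_with_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t10\t50\t5\nchr1\t10\t60\t5\n")
        with pytest.raises(ParseError, match="m.tsv:2"):
            MethylationTable.read(p, "x")

    def test_out_of_range_value_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t10\t1.5\t5\n")
        with pytest.raises(ParseError, match="outside"):
            MethylationTable.read(p, "x", dialect="fraction")

    def test_zero_coverage_rows_retained(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t10\t40\t0\n")
        t = MethylationTable.read(p, "x")
        assert len(t) == 1

    def test_roundtrip_write_read(self, tmp_path):
        t = _table([("chr1", 5, 0.25, 4), ("chr2", 9, 0.8, 7)])
        p = tmp_path / "out.tsv"
        t.write(p, "percent")
        back = MethylationTable.read(p, "x", "percent")
        assert np.allclose(back.arrays("chr1")[1], [0.25])
        assert np.allclose(back.arrays("chr2")[1], [0.8])


class TestAggregation:
    def test_coverage_filter_excludes_low_coverage_cpg(self):
        t = _table([("c", 10, 0.8, 5), ("c", 20, 0.6, 2), ("c", 30, 0.4, 3)])
        out = aggregate_region_methylation(t, [GenomicInterval("c", 0, 100)], 3)
        assert out.loc[0, "mean_meth"] == pytest.approx(0.6)
        assert out.loc[0, "n_cpgs"] == 2

    def test_region_without_cpgs_is_missing(self):
        t = _table([("c", 10, 0.8, 5)])
        out = aggregate_region_methylation(t, [GenomicInterval("c", 500, 600)], 3)
        assert math.isnan(out.loc[0, "mean_meth"]) and out.loc[0, "n_cpgs"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, int(rng.integers(5, 200)))
        t = _table(calls)
        regions = random_intervals(rng, 20, max_len=2000)
        min_cov = int(rng.integers(1, 5))
        out = aggregate_region_methylation(t, regions, min_cov)
        for i, r in enumerate(regions):
            mean, n = brute_region_mean(calls, r, min_cov)
            assert out.loc[i, "n_cpgs"] == n
            if n == 0:
                assert math.isnan(out.loc[i, "mean_meth"])
            else:
                assert out.loc[i, "mean_meth"] == pytest.approx(mean)

    def test_raising_min_coverage_never_adds_cpgs(self):
        rng = np.random.default_rng(42)
        calls = random_calls(rng, 300)
        t = _table(calls)
        regions = random_intervals(rng, 30, max_len=3000)
        prev = None
        for mc in (1, 3, 5, 8):
            n = aggregate_region_methylation(t, regions, mc)["n_cpgs"]
            if prev is not None:
                assert (n <= prev).all()
            prev = n

    def test_means_bounded(self):
        rng = np.random.default_rng(3)
        t = _table(random_calls(rng, 400))
        out = aggregate_region_methylation(t, random_intervals(rng, 50, max_len=3000), 2)
        vals = out["mean_meth"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestPromoterClassification:
    @pytest.mark.parametrize("value,expected", [
        (0.62, "high"),
        (0.50, "low"),      # strictly greater than 50%
        (0.499, "low"),
        (float("nan"), "missing"),
    ])
    def test_threshold_rule(self, value, expected):
        assert classify_promoter_methylation(value) == expected

    def test_threshold_must_be_inside_unit_interval(self):
        with pytest.raises(ValueError):
            classify_promoter_methylation(0.5, threshold=1.0)


class TestProfile:
    def test_single_cpg_lands_in_first_downstream_bin(self):
        t = _table([("c", 1050, 0.9, 5)])
        prof = methylation_profile(t, [("c", 1000, "+")], flank=2500, bin_size=100)
        row = prof[(prof.offset_start == 0)].iloc[0]
        assert row["mean_meth"] == pytest.approx(0.9)
        assert prof["n_pairs"].sum() == 1

    def test_minus_strand_orientation(self):
        # CpG 50 bp left of a minus-strand anchor is downstream of it
        t = _table([("c", 950, 0.7, 5)])
        prof = methylation_profile(t, [("c", 1000, "-")], flank=2500, bin_size=100)
        row = prof[(prof.offset_start == 0)].iloc[0]
        assert row["mean_meth"] == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        calls = random_calls(rng, int(rng.integers(5, 150)), span=4000)
        t = _table(calls)
        anchors = [
            (("chrA", "chrB")[int(rng.integers(2))], int(rng.integers(0, 4000)),
             ("+", "-")[int(rng.integers(2))])
            for _ in range(int(rng.integers(1, 6)))
        ]
        flank, bin_size = 1000, 50
        prof = methylation_profile(t, anchors, flank, bin_size)
        expected = brute_profile(calls, anchors, flank, bin_size)
        for i, (mean, count) in enumerate(expected):
            assert prof.loc[i, "n_pairs"] == count
            if count:
                assert prof.loc[i, "mean_meth"] == pytest.approx(mean)

    def test_flank_must_divide_into_bins(self):
        t = _table([("c", 10, 0.5, 5)])
        with pytest.raises(ValueError):
            methylation_profile(t, [("c", 100, "+")], flank=2500, bin_size=300)


class TestRandomRegions:
    def test_deterministic_per_seed(self):
        sizes = {"chr1": 100_000, "chr2": 50_000}
        a = sample_random_regions(sizes, 50, 1000, seed=9)
        b = sample_random_regions(sizes, 50, 1000, seed=9)
        assert a == b

    def test_chromosome_length_weighting(self):
        sizes = {"big": 900_000, "small": 100_000}
        regions = sample_random_regions(sizes, 1000, 1000, seed=0)
        n_big = sum(1 for r in regions if r.chrom == "big")
        # binomial(1000, 0.9): 3 sigma is about 28
        assert abs(n_big - 900) < 30

    def test_regions_within_bounds(self):
        sizes = {"chr1": 20_000}
        for r in sample_random_regions(sizes, 200, 5000, seed=1):
            assert 0 <= r.start and r.end <= 20_000 and r.length == 5000

    def test_errors(self):
        with pytest.raises(ValueError):
            sample_random_regions({"c": 1000}, 0, 100)
        with pytest.raises(ValueError):
            sample_random_regions({"c": 1000}, 5, 2000)


class TestCompartmentMedians:
    def _tiny_world(self, scale=1.0):
        from demethylome.intervals import Gene, GenomeAnnotation

        genes = {}
        for i in range(4):
            s = 10_000 + i * 20_000
            span = GenomicInterval("c", s, s + 5000, "+")
            genes[f"g{i}"] = Gene(f"g{i}", f"g{i}", span,
                                  (GenomicInterval("c", s, s + 5000, "+"),))
        ann = GenomeAnnotation(genes, {"c": 100_000})
        calls = [("c", p, min(1.0, 0.5 * scale), 5) for p in range(0, 100_000, 97)]
        return ann, _table(calls, "a"), _table([
            (c, p, m * 0.1, cov) for c, p, m, cov in calls], "b")

    def test_constant_input_gives_constant_medians(self):
        ann, ta, tb = self._tiny_world()
        regions = sample_random_regions({"c": 100_000}, 20, 2000, seed=2)
        med = compartment_medians(ta, tb, ann, regions)
        for comp in med["a"].values():
            assert comp == pytest.approx(0.5)
        for comp in med["b"].values():
            assert comp == pytest.approx(0.05)

    def test_scaling_derived_scales_medians(self):
        ann, ta, tb = self._tiny_world()
        regions = sample_random_regions({"c": 100_000}, 20, 2000, seed=2)
        med = compartment_medians(ta, tb, ann, regions)
        for key in med["a"]:
            assert med["b"][key] == pytest.approx(0.1 * med["a"][key])

    def test_empty_compartment_errors(self):
        ann, ta, tb = self._tiny_world()
        empty = _table([("c", 1, 0.5, 5)], "a")  # 1 CpG, outside most regions
        regions = [GenomicInterval("c", 90_000, 92_000)]
        with pytest.raises(ValueError, match="no region with a qualifying CpG"):
            compartment_medians(empty, empty, ann, regions)
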