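"""Cross-dataset analyses: promoter H3K4me3 states, alternative promoters,
enhancer-gene distances, intragenic enhancers, CGI and TATA features."""

import math

import numpy as np
import pytest

from demethylome.integrate import (
    alternative_promoter_scan,
    count_intragenic_enhancers,
    derepressed_h3k4me3_overlap,
    gene_enhancer_distances,
    intragenic_histogram,
    promoter_cgi_classification,
    tata_scan,
)
from demethylome.intervals import Gene, GenomeAnnotation, GenomicInterval
from demethylome.peaks import EnhancerComparison, PeakSet
from oracles import brute_nearest, brute_point_distance, random_intervals


def _ann(tss_list, chrom_len=10_000_000, span_len=5000):
    genes = {}
    for i, tss in enumerate(tss_list):
        span = GenomicInterval("c", tss, tss + span_len, "+")
        genes[f"g{i}"] = Gene(f"g{i}", f"g{i}", span,
                              (GenomicInterval("c", tss, tss + span_len, "+"),))
    return GenomeAnnotation(genes, {"c": chrom_len})


def _peaks(intervals, mark="H3K4me3"):
    return PeakSet(mark, "x", "consensus",
                   tuple(GenomicInterval(*iv) for iv in intervals))


class TestDerepressedOverlap:
    def test_partition_conserves_input(self):
        ann = _ann([10_000, 50_000, 90_000])
        part = derepressed_h3k4me3_overlap(
            ["g0", "g1", "g2"],
            new_peaks=_peaks([("c", 9_900, 10_100)]),
            common_peaks=_peaks([("c", 49_900, 50_100)]),
            ann=ann,
        )
        assert part["gained_new"] == ["g0"]
        assert part["in_common"] == ["g1"]
        assert part["neither"] == ["g2"]
        assert sum(len(v) for v in part.values()) == 3

    def test_new_takes_precedence_over_common(self):
        ann = _ann([10_000])
        part = derepressed_h3k4me3_overlap(
            ["g0"], _peaks([("c", 9_900, 10_100)]), _peaks([("c", 9_900, 10_100)]),
            ann)
        assert part["gained_new"] == ["g0"]

    def test_planted_states_recovered(self, bundle, analysis):
        _cfg, manifest = analysis
        truth = bundle.ground_truth["h3k4me3_status"]
        expected = {s: sum(1 for v in truth.values() if v == s)
                    for s in ("gained_new", "in_common", "neither")}
        assert manifest["derepressed_h3k4me3"] == expected


class TestAlternativePromoterScan:
    def test_gene_within_near_counted(self):
        ann = _ann([100_000])
        table, summary = alternative_promoter_scan(
            ["g0"], _peaks([("c", 110_000, 110_500)]), ann, near=20_000)
        assert table.loc["g0", "distance"] == 10_000
        assert summary["n_within"] == 1

    def test_other_chromosome_unreachable(self):
        ann = _ann([100_000])
        peaks = PeakSet("H3K4me3", "x", "c",
                        (GenomicInterval("other", 0, 100),))
        table, summary = alternative_promoter_scan(["g0"], peaks, ann)
        assert math.isinf(table.loc["g0", "distance"])
        assert summary["n_within"] == 0 and math.isnan(summary["median_distance"])

    def test_empty_peak_set_all_unreachable(self):
        ann = _ann([100_000])
        table, summary = alternative_promoter_scan(
            ["g0"], PeakSet("H3K4me3", "x", "c", ()), ann)
        assert math.isinf(table.loc["g0", "distance"])

    @pytest.mark.parametrize("seed", range(15))
    def test_summary_matches_brute_force(self, seed):
        rng = np.random.default_rng(400 + seed)
        tss = sorted(rng.choice(900_000, size=10, replace=False).tolist())
        ann = _ann(tss)
        peaks = _peaks([
            ("c", int(s), int(s) + int(rng.integers(100, 400)))
            for s in rng.integers(0, 900_000, int(rng.integers(1, 30)))
        ])
        table, summary = alternative_promoter_scan(list(ann.genes), peaks, ann,
                                                   near=20_000)
        expected = [brute_nearest("c", t, peaks.intervals)[0] for t in tss]
        assert table["distance"].tolist() == expected
        assert summary["n_within"] == sum(1 for d in expected if d <= 20_000)
        assert summary["median_distance"] == pytest.approx(np.median(expected))


class TestGeneEnhancerDistances:
    def _cmp(self, common=(), ua=(), ub=()):
        return EnhancerComparison(
            "a", "b",
            common=tuple(GenomicInterval(*iv) for iv in common),
            unique_a=tuple(GenomicInterval(*iv) for iv in ua),
            unique_b=tuple(GenomicInterval(*iv) for iv in ub),
        )

    def test_tss_inside_enhancer_is_distance_zero(self):
        ann = _ann([100_000])
        cmp = self._cmp(ub=[("c", 99_000, 101_000)])
        table, summary = gene_enhancer_distances(["g0"], cmp, ann)
        assert table.loc["g0", "unique_b"] == 0
        assert summary["unique_b"]["frac_within"] == 1.0

    def test_single_enhancer_median(self):
        ann = _ann([100_000])
        cmp = self._cmp(common=[("c", 142_000, 142_500)])
        _table, summary = gene_enhancer_distances(["g0"], cmp, ann)
        assert summary["common"]["median_distance"] == 42_000
        assert summary["common"]["frac_within"] == 0.0

    def test_empty_category_fraction_zero(self):
        ann = _ann([100_000])
        _table, summary = gene_enhancer_distances(["g0"], self._cmp(), ann)
        assert summary["common"]["frac_within"] == 0.0
        assert math.isnan(summary["common"]["median_distance"])

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(700 + seed)
        tss = sorted(rng.choice(500_000, size=8, replace=False).tolist())
        ann = _ann(tss)
        cmp = self._cmp(
            common=[(iv.chrom, iv.start, iv.end) for iv in
                    random_intervals(rng, int(rng.integers(1, 25)),
                                     span=500_000, chroms=("c",))],
            ub=[(iv.chrom, iv.start, iv.end) for iv in
                random_intervals(rng, int(rng.integers(1, 25)),
                                 span=500_000, chroms=("c",))],
        )
        table, _summary = gene_enhancer_distances(list(ann.genes), cmp, ann)
        for gid, t in zip(ann.genes, tss):
            for cat, ivs in (("common", cmp.common), ("unique_b", cmp.unique_b)):
                assert table.loc[gid, cat] == brute_nearest("c", t, ivs)[0]


class TestIntragenicEnhancers:
    def test_midpoint_at_gene_end_not_counted(self):
        ann = _ann([100_000], span_len=5000)  # span [100000, 105000)
        cmp = EnhancerComparison(
            "a", "b", common=(), unique_a=(),
            unique_b=(GenomicInterval("c", 104_500, 105_500),),  # midpoint 105000
        )
        out = count_intragenic_enhancers(["g0"], cmp, ann)
        assert out.loc["g0", "unique_b_total"] == 0

    def test_counts_and_spreading_flag(self):
        ann = _ann([100_000], span_len=8000)
        ub = tuple(GenomicInterval("c", 101_000 + k * 2000, 101_400 + k * 2000)
                   for k in range(3))
        cmp = EnhancerComparison("a", "b", common=(), unique_a=(), unique_b=ub)
        out = count_intragenic_enhancers(["g0"], cmp, ann)
        assert out.loc["g0", "unique_b_total"] == 3
        assert bool(out.loc["g0", "spreading"]) is True
        assert (out.loc["g0", "unique_b_intronic"]
                + out.loc["g0", "unique_b_exonic"]) == 3

    def test_histogram_sums_to_gene_count(self):
        import pandas as pd

        counts = pd.Series([0, 0, 1, 3, 12])
        hist = intragenic_histogram(counts, max_count=5)
        assert sum(hist.values()) == 5
        assert hist[5] == 1  # open last bin

    def test_planted_counts_recovered(self, bundle):
        """Per-gene planted intragenic new-enhancer counts are recovered."""
        from demethylome.intervals import read_annotation, read_chrom_sizes

        sizes = read_chrom_sizes(bundle.paths["chrom_sizes"])
        ann = read_annotation(bundle.paths["annotation"], sizes)
        truth = bundle.ground_truth
        cmp = EnhancerComparison(
            "a", "b", common=(), unique_a=(),
            unique_b=tuple(
                GenomicInterval(e["chrom"], e["start"], e["end"])
                for e in truth["enhancers"]
                if e["category"] == "unique_b" and e["planted_intragenic"]
            ),
        )
        hosts = truth["intragenic_unique_b"]
        out = count_intragenic_enhancers(sorted(hosts), cmp, ann)
        for gid, expected in hosts.items():
            assert out.loc[gid, "unique_b_total"] == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(900 + seed)
        tss = sorted(rng.choice(200_000, size=6, replace=False).tolist())
        ann = _ann(tss, span_len=4000)
        ub = tuple(random_intervals(rng, 40, span=210_000, chroms=("c",)))
        cmp = EnhancerComparison("a", "b", common=(), unique_a=(), unique_b=ub)
        out = count_intragenic_enhancers(list(ann.genes), cmp, ann)
        for gid in ann.genes:
            span = ann.genes[gid].span
            expected = sum(1 for iv in ub if span.start <= iv.midpoint < span.end)
            assert out.loc[gid, "unique_b_total"] == expected


class TestCgiClassification:
    def test_tss_inside_island(self):
        ann = _ann([1500])
        table, mean_len = promoter_cgi_classification(
            ["g0"], [GenomicInterval("c", 1000, 2000)], ann)
        assert bool(table.loc["g0", "cgi_promoter"]) is True
        assert mean_len == 1000

    def test_half_open_boundary(self):
        ann = _ann([2000])
        table, mean_len = promoter_cgi_classification(
            ["g0"], [GenomicInterval("c", 1000, 2000)], ann)
        assert bool(table.loc["g0", "cgi_promoter"]) is False
        assert math.isnan(mean_len)

    def test_empty_island_set(self):
        ann = _ann([1500])
        table, mean_len = promoter_cgi_classification(["g0"], [], ann)
        assert not table["cgi_promoter"].any() and math.isnan(mean_len)

    def test_planted_cgi_promoters_recovered(self, bundle):
        from demethylome.intervals import read_annotation, read_chrom_sizes
        from demethylome.pipeline import _read_bed_intervals

        sizes = read_chrom_sizes(bundle.paths["chrom_sizes"])
        ann = read_annotation(bundle.paths["annotation"], sizes)
        cgi = _read_bed_intervals(bundle.paths["cgi"])
        truth = bundle.ground_truth["cgi_promoter"]
        table, mean_len = promoter_cgi_classification(sorted(truth), cgi, ann)
        assert {g: bool(v) for g, v in table["cgi_promoter"].items()} == truth
        assert 700 < mean_len < 1300  # planted islands average about 1 kb


class TestTataScan:
    def _seq(self, box, offset, L=120):
        """Place `box` so its first base sits at `offset` relative to the TSS
        (= last base); pad elsewhere with a motif-free filler."""
        filler = "C" * L
        start = (L - 1) + offset
        return filler[:start] + box + filler[start + len(box):]

    def test_perfect_match(self):
        found, off, mm = tata_scan(self._seq("TATAAAA", -30))
        assert (found, off, mm) == (True, -30, 0)

    def test_one_mismatch_at_w_position(self):
        found, off, mm = tata_scan(self._seq("TATACAA", -30))
        assert (found, off, mm) == (True, -30, 1)

    def test_two_mismatches_rejected(self):
        found, off, mm = tata_scan(self._seq("TACACAA", -30))
        assert found is False and off is None

    def test_motif_outside_window_not_found(self):
        assert tata_scan(self._seq("TATAAAA", -50))[0] is False
        assert tata_scan(self._seq("TATAAAA", -10))[0] is False

    def test_mismatch_allowance_is_monotone(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, 80)])
            if tata_scan(seq, max_mismatch=0)[0]:
                assert tata_scan(seq, max_mismatch=1)[0]

    def test_n_matches_nothing(self):
        assert tata_scan(self._seq("TATANAA", -30))[2] == 1  # N costs a mismatch

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError):
            tata_scan("TATAAAA")

    def test_planted_tata_promoters_recovered(self, bundle):
        from demethylome.pipeline import _read_fasta

        seqs = _read_fasta(bundle.paths["promoter_fasta"])
        truth = bundle.ground_truth["tata_promoter"]
        got = {g: tata_scan(seqs[g])[0] for g in truth}
        assert got == truth
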