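"""Peak sets: replicate consensus, proximity splitting, enhancer definition,
two-condition comparison, compartment annotation, poised fraction."""

import math

import numpy as np
import pandas as pd
import pytest

from demethylome.intervals import Gene, GenomeAnnotation, GenomicInterval
from demethylome.methylome import MethylationTable
from demethylome.peaks import (
    EnhancerComparison,
    PeakSet,
    annotate_compartment,
    compare_enhancers,
    consensus_peaks,
    define_enhancers,
    enhancer_parental_methylation,
    poised_fraction,
    split_by_tss_proximity,
)
from oracles import brute_compare, brute_consensus_indices, random_intervals


def _peaks(intervals, mark="H3K27ac", condition="parental", replicate="rep1"):
    return PeakSet(mark, condition, replicate,
                   tuple(GenomicInterval(*iv) for iv in intervals))


def _one_gene_ann(tss=1000, strand="+", chrom_len=1_000_000):
    if strand == "+":
        span = GenomicInterval("c", tss, tss + 5000, "+")
    else:
        span = GenomicInterval("c", tss - 4999, tss + 1, "-")
    g = Gene("g1", "g1", span, (GenomicInterval("c", span.start, span.end, strand),))
    return GenomeAnnotation({"g1": g}, {"c": chrom_len})


class TestConsensus:
    def test_keeps_rep1_peaks_overlapping_rep2(self):
        r1 = _peaks([("c", 0, 100), ("c", 500, 600)])
        r2 = _peaks([("c", 50, 150)], replicate="rep2")
        out = consensus_peaks(r1, r2)
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 100)]

    def test_identical_replicates_idempotent(self):
        r1 = _peaks([("c", 0, 100), ("c", 500, 600)])
        out = consensus_peaks(r1, _peaks([("c", 0, 100), ("c", 500, 600)],
                                         replicate="rep2"))
        assert out.intervals == r1.intervals

    def test_mark_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            consensus_peaks(_peaks([("c", 0, 10)], mark="H3K27ac"),
                            _peaks([("c", 0, 10)], mark="H3K4me3"))

    def test_intersection_mode_trims(self):
        r1 = _peaks([("c", 0, 100)])
        r2 = _peaks([("c", 50, 150)], replicate="rep2")
        out = consensus_peaks(r1, r2, mode="intersection")
        assert [(iv.start, iv.end) for iv in out.intervals] == [(50, 100)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        r1 = random_intervals(rng, int(rng.integers(1, 60)))
        r2 = random_intervals(rng, int(rng.integers(1, 60)))
        out = consensus_peaks(
            PeakSet("H3K27ac", "x", "rep1", tuple(r1)),
            PeakSet("H3K27ac", "x", "rep2", tuple(r2)),
        )
        expected = sorted(
            (r1[i].chrom, r1[i].start, r1[i].end)
            for i in brute_consensus_indices(r1, r2)
        )
        assert [(iv.chrom, iv.start, iv.end) for iv in out.intervals] == expected


class TestProximitySplit:
    def test_distal_peak(self):
        prox, dist = split_by_tss_proximity(
            _peaks([("c", 2500, 2600)], "H3K4me3"), _one_gene_ann(tss=0))
        assert len(prox) == 0 and len(dist) == 1

    def test_boundary_overlap_is_proximal(self):
        # window around tss=1000 is [ -1000, 3001 ); peak ends at 3100
        prox, dist = split_by_tss_proximity(
            _peaks([("c", 2500, 3100)], "H3K4me3"), _one_gene_ann(tss=1000))
        assert len(prox) == 1 and len(dist) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_is_exhaustive_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        peaks = PeakSet("H3K27ac", "x", "rep1",
                        tuple(random_intervals(rng, 50, span=50_000,
                                               chroms=("c",))))
        prox, dist = split_by_tss_proximity(peaks, _one_gene_ann(tss=20_000))
        assert len(prox) + len(dist) == len(peaks)
        got = sorted((iv.start, iv.end) for iv in prox.intervals + dist.intervals)
        assert got == sorted((iv.start, iv.end) for iv in peaks.intervals)


class TestDefineEnhancers:
    def test_all_proximal_gives_empty_set(self):
        ann = _one_gene_ann(tss=1000)
        enh = define_enhancers(_peaks([("c", 900, 1100)]), ann)
        assert len(enh) == 0

    def test_zero_genes_makes_everything_an_enhancer(self):
        ann = GenomeAnnotation({}, {"c": 1_000_000})
        enh = define_enhancers(_peaks([("c", 0, 100), ("c", 500, 600)]), ann)
        assert len(enh) == 2

    def test_wrong_mark_rejected(self):
        with pytest.raises(ValueError, match="H3K27ac"):
            define_enhancers(_peaks([("c", 0, 100)], mark="H3K4me3"),
                             _one_gene_ann())

    def test_planted_enhancers_recovered_exactly(self, bundle):
        """The synthetic condition-B enhancer set is exactly the planted one."""
        from demethylome.config import RunConfig
        from demethylome.intervals import read_annotation, read_chrom_sizes

        sizes = read_chrom_sizes(bundle.paths["chrom_sizes"])
        ann = read_annotation(bundle.paths["annotation"], sizes)
        files = bundle.paths["peaks"]["H3K27ac"]["demethylated"]
        reps = [PeakSet.read_bed(f, "H3K27ac", "demethylated", f"rep{i+1}")
                for i, f in enumerate(files)]
        enh = define_enhancers(consensus_peaks(*reps), ann)
        planted = sorted(
            (e["chrom"], e["start"], e["end"])
            for e in bundle.ground_truth["enhancers"]
            if e["category"] in ("common", "unique_b")
        )
        assert sorted((iv.chrom, iv.start, iv.end) for iv in enh.intervals) == planted


class TestCompareEnhancers:
    def test_example_partition(self):
        a = _peaks([("c", 0, 100)])
        b = _peaks([("c", 50, 150), ("c", 900, 950)], condition="demethylated")
        cmp = compare_enhancers(a, b)
        assert cmp.counts() == {
            "common_a": 1, "common_b": 1, "unique_a": 0, "unique_b": 1,
            "total_a": 1, "total_b": 2,
        }

    def test_disjoint_sets_all_unique(self):
        a = _peaks([("c", 0, 100)])
        b = _peaks([("c", 500, 600)], condition="demethylated")
        cmp = compare_enhancers(a, b)
        assert len(cmp.common) == 0
        assert len(cmp.unique_a) == 1 and len(cmp.unique_b) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, int(rng.integers(1, 60)))
        b = random_intervals(rng, int(rng.integers(1, 60)))
        cmp = compare_enhancers(PeakSet("H3K27ac", "a", "c", tuple(a)),
                                PeakSet("H3K27ac", "b", "c", tuple(b)))
        ca, ua, cb, ub = brute_compare(a, b)
        assert (len(cmp.common), len(cmp.unique_a)) == (ca, ua)
        assert (cmp.common_b_count, len(cmp.unique_b)) == (cb, ub)
        # conservation on each side
        assert len(cmp.common) + len(cmp.unique_a) == len(a)
        assert cmp.common_b_count + len(cmp.unique_b) == len(b)


class TestCompartments:
    def _ann(self):
        span = GenomicInterval("c", 100, 400, "+")
        g = Gene("g", "g", span, (GenomicInterval("c", 100, 200, "+"),
                                  GenomicInterval("c", 300, 400, "+")))
        return GenomeAnnotation({"g": g}, {"c": 10_000})

    def test_midpoint_rules(self):
        ann = self._ann()
        labels = annotate_compartment(
            [GenomicInterval("c", 120, 180),   # midpoint 150 in exon
             GenomicInterval("c", 230, 270),   # midpoint 250 in intron
             GenomicInterval("c", 900, 1000)], # outside gene
            ann,
        )
        assert labels == ["exonic", "intronic", "intergenic"]


class TestEnhancerMethylation:
    def test_region_mean_over_enhancer(self):
        cmp = EnhancerComparison(
            "a", "b", common=(GenomicInterval("c", 0, 100),),
            unique_a=(), unique_b=(),
        )
        table = MethylationTable("parental", pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [10, 20], "meth": [0.9, 0.7],
             "cov": [4, 8]}))
        out = enhancer_parental_methylation(cmp, table)
        common = out[out.category == "common"]
        assert common["mean_meth"].iloc[0] == pytest.approx(0.8)

    def test_enhancer_without_cpgs_is_missing(self):
        cmp = EnhancerComparison(
            "a", "b", common=(), unique_a=(), unique_b=(GenomicInterval("c", 0, 100),),
        )
        table = MethylationTable("parental", pd.DataFrame(
            {"chrom": ["c"], "pos": [5000], "meth": [0.9], "cov": [4]}))
        out = enhancer_parental_methylation(cmp, table)
        assert math.isnan(out["mean_meth"].iloc[0])

    def test_new_enhancers_parental_methylated_vs_common(self, analysis):
        """Planted condition-B-unique enhancers were methylated in the
        parental condition; common (already active) enhancers were not."""
        _cfg, manifest = analysis
        med = manifest["enhancer_parental_meth_median_percent"]
        assert med["unique_b"] > 50
        assert med["common"] < 20
        assert med["unique_b"] > med["common"]


class TestPoisedFraction:
    def test_zero_and_full_overlap(self):
        k4 = _peaks([("c", 0, 100)], mark="H3K4me1")
        assert poised_fraction([GenomicInterval("c", 50, 80)], k4) == 1.0
        assert poised_fraction([GenomicInterval("c", 500, 600)], k4) == 0.0

    def test_empty_enhancers_error(self):
        with pytest.raises(ValueError):
            poised_fraction([], _peaks([("c", 0, 10)], mark="H3K4me1"))
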