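"""ChIP-seq peak sets: replicate consensus, promoter proximity, enhancer
definition and the two-condition enhancer comparison.

Enhancers follow the standard operational definition used throughout this
package: replicate-consensus H3K27ac peaks more than 2 kb from every TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalIndex,
    ParseError,
)

MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "RNAPII")


@dataclass
class PeakSet:
    """Called peaks for one mark / condition / replicate.

    Intervals are kept sorted by (chrom, start, end); scores are carried but
    unused by any classification here.
    """

    mark: str
    condition: str
    replicate: str
    intervals: tuple[GenomicInterval, ...]
    scores: tuple[float, ...] = ()
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start,
                           self.intervals[i].end),
        )
        self.intervals = tuple(self.intervals[i] for i in order)
        if self.scores:
            if len(self.scores) != len(self.intervals):
                raise ValueError("scores length mismatch")
            self.scores = tuple(self.scores[i] for i in order)
        if self.names:
            if len(self.names) != len(self.intervals):
                raise ValueError("names length mismatch")
            self.names = tuple(self.names[i] for i in order)

    def __len__(self) -> int:
        return len(self.intervals)

    def subset(self, keep: Sequence[int], replicate: str | None = None) -> "PeakSet":
        keep = list(keep)
        return PeakSet(
            self.mark,
            self.condition,
            self.replicate if replicate is None else replicate,
            tuple(self.intervals[i] for i in keep),
            tuple(self.scores[i] for i in keep) if self.scores else (),
            tuple(self.names[i] for i in keep) if self.names else (),
        )

    @classmethod
    def read_bed(cls, path, mark: str, condition: str, replicate: str) -> "PeakSet":
        """BED3+/BED6 reader (name/score/strand columns optional)."""
        intervals: list[GenomicInterval] = []
        scores: list[float] = []
        names: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(path, lineno, "expected >= 3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer coordinates")
                if end <= start or start < 0:
                    raise ParseError(path, lineno, f"bad interval {start}..{end}")
                intervals.append(GenomicInterval(parts[0], start, end))
                names.append(parts[3] if len(parts) > 3 else f"peak_{lineno}")
                try:
                    scores.append(float(parts[4]) if len(parts) > 4 else 0.0)
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {parts[4]!r}")
        return cls(mark, condition, replicate, tuple(intervals),
                   tuple(scores), tuple(names))

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, iv in enumerate(self.intervals):
                name = self.names[i] if self.names else f"{self.mark}_{i}"
                score = self.scores[i] if self.scores else 0.0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n")


def consensus_peaks(rep1: PeakSet, rep2: PeakSet, mode: str = "rep1") -> PeakSet:
    """Peaks reproducible across both replicates.

    Keeps every replicate-1 peak that overlaps at least one replicate-2 peak.
    ``mode="rep1"`` (default) retains the replicate-1 coordinates;
    ``mode="intersection"`` trims each kept peak to its intersection with the
    best-overlapping replicate-2 peak.
    """
    if rep1.mark != rep2.mark or rep1.condition != rep2.condition:
        raise ValueError(
            f"replicates disagree: {rep1.mark}/{rep1.condition} vs "
            f"{rep2.mark}/{rep2.condition}"
        )
    if mode not in ("rep1", "intersection"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    idx2 = IntervalIndex(rep2.intervals)
    keep = [
        i for i, iv in enumerate(rep1.intervals)
        if idx2.overlaps_any(iv.chrom, iv.start, iv.end)
    ]
    out = rep1.subset(keep, replicate="consensus")
    if mode == "intersection":
        trimmed = []
        for iv in out.intervals:
            partners = [
                p for p in rep2.intervals
                if p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end
            ]
            best = max(partners, key=lambda p: min(p.end, iv.end) - max(p.start, iv.start))
            trimmed.append(
                GenomicInterval(iv.chrom, max(iv.start, best.start),
                                min(iv.end, best.end), iv.strand)
            )
        out = PeakSet(out.mark, out.condition, out.replicate, tuple(trimmed),
                      out.scores, out.names)
    return out


def split_by_tss_proximity(
    peaks: PeakSet, ann: GenomeAnnotation, window: int = 2000
) -> tuple[PeakSet, PeakSet]:
    """Partition peaks into promoter-proximal and promoter-distal.

    A peak is proximal iff it overlaps the +/-``window`` bp window around any
    TSS (both boundary bases included, i.e. ``[tss-window, tss+window+1)``).
    The partition is exhaustive and disjoint.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    tss_windows = [
        GenomicInterval(chrom, max(0, tss - window), tss + window + 1)
        for _gid, chrom, tss, _strand in ann.tss_sites()
    ]
    idx = IntervalIndex(tss_windows)
    proximal, distal = [], []
    for i, iv in enumerate(peaks.intervals):
        (proximal if idx.overlaps_any(iv.chrom, iv.start, iv.end) else distal).append(i)
    return (
        peaks.subset(proximal),
        peaks.subset(distal),
    )


def define_enhancers(
    h3k27ac_consensus: PeakSet, ann: GenomeAnnotation, window: int = 2000
) -> PeakSet:
    """Enhancers: promoter-distal H3K27ac consensus peaks (> ``window`` bp
    from every TSS)."""
    if h3k27ac_consensus.mark != "H3K27ac":
        raise ValueError(
            f"enhancers are defined from H3K27ac peaks, got {h3k27ac_consensus.mark}"
        )
    _proximal, distal = split_by_tss_proximity(h3k27ac_consensus, ann, window)
    return distal


@dataclass
class EnhancerComparison:
    """Common / unique-A / unique-B partition of two enhancer sets.

    ``common`` is reported from side A's coordinates with the number of
    matching B enhancers per interval; because overlaps can be many-to-one
    the B-side common count (``common_b_count``) may differ and is reported
    alongside. Compartment labels and parental methylation are attached by
    the corresponding operations.
    """

    condition_a: str
    condition_b: str
    common: tuple[GenomicInterval, ...]
    unique_a: tuple[GenomicInterval, ...]
    unique_b: tuple[GenomicInterval, ...]
    n_b_matched: tuple[int, ...] = ()
    common_b_count: int = 0
    compartments: dict[str, tuple[str, ...]] = field(default_factory=dict)
    parental_meth: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "common_a": len(self.common),
            "common_b": self.common_b_count,
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "total_a": len(self.common) + len(self.unique_a),
            "total_b": self.common_b_count + len(self.unique_b),
        }

    def category_intervals(self) -> dict[str, tuple[GenomicInterval, ...]]:
        return {
            "common": self.common,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
        }


def compare_peak_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[list[int], list[int], list[int], list[int], int]:
    """Overlap partition of two interval collections.

    Returns (common-A indices, unique-A indices, unique-B indices,
    per-common-A matched-B counts, B-side common count).
    """
    idx_b = IntervalIndex(b)
    idx_a = IntervalIndex(a)
    common_a, unique_a, matched = [], [], []
    for i, iv in enumerate(a):
        n = idx_b.count_overlaps(iv.chrom, iv.start, iv.end)
        if n > 0:
            common_a.append(i)
            matched.append(n)
        else:
            unique_a.append(i)
    unique_b = [
        j for j, iv in enumerate(b)
        if not idx_a.overlaps_any(iv.chrom, iv.start, iv.end)
    ]
    common_b_count = len(b) - len(unique_b)
    return common_a, unique_a, unique_b, matched, common_b_count


def compare_enhancers(a: PeakSet, b: PeakSet) -> EnhancerComparison:
    """Venn-style comparison of two conditions' enhancer sets.

    An A enhancer is common iff it overlaps >= 1 B enhancer (and
    symmetrically for B); every enhancer on each side lands in exactly one
    category.
    """
    if a.mark != b.mark:
        raise ValueError(f"mark mismatch: {a.mark} vs {b.mark}")
    common_a, unique_a, unique_b, matched, common_b_count = compare_peak_intervals(
        a.intervals, b.intervals
    )
    return EnhancerComparison(
        condition_a=a.condition,
        condition_b=b.condition,
        common=tuple(a.intervals[i] for i in common_a),
        unique_a=tuple(a.intervals[i] for i in unique_a),
        unique_b=tuple(b.intervals[j] for j in unique_b),
        n_b_matched=tuple(matched),
        common_b_count=common_b_count,
    )


def annotate_compartment(
    intervals: Sequence[GenomicInterval], ann: GenomeAnnotation
) -> list[str]:
    """Label each interval intergenic / intronic / exonic by its midpoint.

    Precedence: exonic if the midpoint falls in any exon, else intronic if it
    falls in any gene span, else intergenic. Midpoint labelling avoids double
    counting peaks that straddle boundaries.
    """
    exon_idx = IntervalIndex(ann.all_exons())
    span_idx = IntervalIndex(ann.gene_spans())
    labels = []
    for iv in intervals:
        mid = iv.midpoint
        if exon_idx.contains_point(iv.chrom, mid):
            labels.append("exonic")
        elif span_idx.contains_point(iv.chrom, mid):
            labels.append("intronic")
        else:
            labels.append("intergenic")
    return labels


def annotate_comparison_compartments(
    cmp: EnhancerComparison, ann: GenomeAnnotation
) -> EnhancerComparison:
    """Attach compartment labels to every category of a comparison."""
    for cat, ivs in cmp.category_intervals().items():
        cmp.compartments[cat] = tuple(annotate_compartment(ivs, ann))
    return cmp


def enhancer_parental_methylation(
    cmp: EnhancerComparison, parental, min_coverage: int = 3
) -> pd.DataFrame:
    """Parental-condition mean methylation of every enhancer in a comparison.

    Returns one row per enhancer: category, coordinates, mean methylation
    (NaN if no CpG qualifies) and CpGs used. Also stores the values on the
    comparison object.
    """
    from .methylome import aggregate_region_methylation

    frames = []
    for cat, ivs in cmp.category_intervals().items():
        agg = aggregate_region_methylation(parental, list(ivs), min_coverage)
        agg.insert(0, "category", cat)
        cmp.parental_meth[cat] = tuple(agg["mean_meth"].tolist())
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def poised_fraction(
    new_enhancers: Sequence[GenomicInterval], parental_h3k4me1: PeakSet
) -> float:
    """Fraction of newly acquired enhancers that overlap a parental H3K4me1
    peak — i.e. were already poised before demethylation."""
    if len(new_enhancers) == 0:
        raise ValueError("poised_fraction: empty enhancer collection")
    idx = IntervalIndex(parental_h3k4me1.intervals)
    hits = sum(
        1 for iv in new_enhancers if idx.overlaps_any(iv.chrom, iv.start, iv.end)
    )
    return hits / len(new_enhancers)
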