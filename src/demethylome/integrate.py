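"""Cross-dataset analyses: promoter chromatin state of de-repressed genes,
alternative-promoter search, enhancer-gene distances, intragenic enhancer
enumeration, and promoter sequence features (CpG islands, TATA boxes).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalIndex,
    nearest_distance,
)
from .peaks import EnhancerComparison, PeakSet

UNREACHABLE = math.inf

ENHANCER_CATEGORIES = ("common", "unique_a", "unique_b")


def derepressed_h3k4me3_overlap(
    derepressed: Sequence[str],
    new_peaks: PeakSet,
    common_peaks: PeakSet,
    ann: GenomeAnnotation,
    window: int = 2000,
) -> dict[str, list[str]]:
    """Partition de-repressed genes by the promoter H3K4me3 they carry.

    ``gained_new``: the +/-window promoter region overlaps a
    demethylated-condition-unique H3K4me3 peak; else ``in_common`` if it
    overlaps a peak shared by both conditions; else ``neither``. The three
    lists partition the input.
    """
    new_idx = IntervalIndex(new_peaks.intervals)
    common_idx = IntervalIndex(common_peaks.intervals)
    out: dict[str, list[str]] = {"gained_new": [], "in_common": [], "neither": []}
    for gid in derepressed:
        gene = ann.genes[gid]
        start = max(0, gene.tss - window)
        end = gene.tss + window + 1
        if new_idx.overlaps_any(gene.chrom, start, end):
            out["gained_new"].append(gid)
        elif common_idx.overlaps_any(gene.chrom, start, end):
            out["in_common"].append(gid)
        else:
            out["neither"].append(gid)
    return out


def alternative_promoter_scan(
    genes: Sequence[str],
    new_h3k4me3: PeakSet,
    ann: GenomeAnnotation,
    near: int = 20_000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Distance from each gene's TSS to the nearest newly acquired H3K4me3
    site — a proxy for an alternative promoter.

    Returns a per-gene table (distance; inf when no same-chromosome site
    exists) and a summary: genes with a new site within ``near`` bp
    (inclusive) and the median distance over reachable genes (NaN when none
    are reachable or the peak set is empty).
    """
    dists = []
    for gid in genes:
        gene = ann.genes[gid]
        if len(new_h3k4me3) == 0:
            dists.append(UNREACHABLE)
        else:
            d, _ = nearest_distance(gene.chrom, gene.tss, new_h3k4me3.intervals)
            dists.append(d)
    table = pd.DataFrame({"distance": dists}, index=pd.Index(list(genes), name="gene_id"))
    reachable = [d for d in dists if d != UNREACHABLE]
    summary = {
        "n_within": float(sum(1 for d in reachable if d <= near)),
        "median_distance": float(np.median(reachable)) if reachable else float("nan"),
    }
    return table, summary


def gene_enhancer_distances(
    genes: Sequence[str],
    cmp: EnhancerComparison,
    ann: GenomeAnnotation,
    near: int = 20_000,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """TSS-to-nearest-enhancer distance per gene and enhancer category.

    Distances are bp to the nearest covered base (0 when the TSS lies inside
    an enhancer); "within ``near``" is inclusive. Genes with no
    same-chromosome enhancer of a category are unreachable (inf) and are
    excluded from that category's median; an empty category yields fraction 0
    and a NaN median.
    """
    cats = cmp.category_intervals()
    rows = {}
    for cat, ivs in cats.items():
        dists = []
        for gid in genes:
            gene = ann.genes[gid]
            if len(ivs) == 0:
                dists.append(UNREACHABLE)
            else:
                d, _ = nearest_distance(gene.chrom, gene.tss, ivs)
                dists.append(d)
        rows[cat] = dists
    table = pd.DataFrame(rows, index=pd.Index(list(genes), name="gene_id"))
    summary: dict[str, dict[str, float]] = {}
    for cat in cats:
        dists = rows[cat]
        reachable = [d for d in dists if d != UNREACHABLE]
        n = len(dists)
        summary[cat] = {
            "frac_within": (sum(1 for d in reachable if d <= near) / n) if n else 0.0,
            "median_distance": float(np.median(reachable)) if reachable else float("nan"),
        }
    return table, summary


def count_intragenic_enhancers(
    genes: Sequence[str],
    cmp: EnhancerComparison,
    ann: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-gene counts of enhancers whose midpoint lies inside the gene span.

    For each category the count is split into intronic and exonic by the
    enhancer midpoint's exon membership (intronic + exonic = total). Genes
    with more than one demethylated-condition-unique intragenic enhancer are
    flagged ``spreading``.
    """
    gene_objs = [ann.genes[g] for g in genes]
    span_idx = IntervalIndex([g.span for g in gene_objs])
    data = {
        f"{cat}_{sub}": np.zeros(len(genes), dtype=np.int64)
        for cat in ENHANCER_CATEGORIES
        for sub in ("total", "intronic", "exonic")
    }
    for cat, ivs in cmp.category_intervals().items():
        for iv in ivs:
            mid = iv.midpoint
            for gi in span_idx.covering(iv.chrom, mid):
                gene = gene_objs[gi]
                data[f"{cat}_total"][gi] += 1
                in_exon = any(e.start <= mid < e.end for e in gene.exons)
                data[f"{cat}_{'exonic' if in_exon else 'intronic'}"][gi] += 1
    out = pd.DataFrame(data, index=pd.Index(list(genes), name="gene_id"))
    out["spreading"] = out["unique_b_total"] > 1
    return out


def intragenic_histogram(counts: pd.Series, max_count: int = 10) -> dict[int, int]:
    """Histogram of genes by intragenic enhancer count (last bin open)."""
    hist = {k: 0 for k in range(max_count + 1)}
    for v in counts:
        hist[min(int(v), max_count)] += 1
    return hist


def promoter_cgi_classification(
    genes: Sequence[str],
    cgi: Sequence[GenomicInterval],
    ann: GenomeAnnotation,
) -> tuple[pd.DataFrame, float]:
    """Which genes have CpG-island promoters, and the islands' mean length.

    A gene is a CGI promoter iff its TSS base lies inside a CpG island
    (half-open). The mean length is taken over islands containing at least
    one queried TSS; with an empty island set every gene is False and the
    mean is NaN.
    """
    idx = IntervalIndex(list(cgi))
    flags = []
    used: set[int] = set()
    for gid in genes:
        gene = ann.genes[gid]
        covering = idx.covering(gene.chrom, gene.tss)
        flags.append(bool(covering))
        used.update(covering)
    table = pd.DataFrame({"cgi_promoter": flags}, index=pd.Index(list(genes), name="gene_id"))
    mean_len = (
        float(np.mean([cgi[i].length for i in sorted(used)])) if used else float("nan")
    )
    return table, mean_len


_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "W": {"A", "T"}, "S": {"C", "G"}, "R": {"A", "G"}, "Y": {"C", "T"},
}


def tata_scan(
    promoter_seq: str,
    motif: str = "TATAWAW",
    max_mismatch: int = 1,
    window: tuple[int, int] = (-40, -20),
) -> tuple[bool, int | None, int | None]:
    """Scan for a degenerate TATA box upstream of the TSS.

    ``promoter_seq`` is the sense-strand sequence aligned so its **last base
    is the TSS** (offset 0). The motif start offset must lie in ``window``
    (inclusive, e.g. -40..-20); a hit needs at most ``max_mismatch``
    mismatches against the IUPAC motif (W = A or T; an N in the sequence
    matches nothing). Sense strand only.

    Returns (found, best start offset, best mismatch count); ties prefer
    fewer mismatches, then the most upstream offset.
    """
    seq = promoter_seq.upper()
    lo, hi = min(window), max(window)
    if len(seq) < -lo:
        raise ValueError(
            f"promoter sequence ({len(seq)} bp) does not cover offset {lo}"
        )
    best: tuple[int, int] | None = None  # (mismatches, offset)
    tss_index = len(seq) - 1
    for offset in range(lo, hi + 1):
        start = tss_index + offset
        kmer = seq[start : start + len(motif)]
        if len(kmer) < len(motif):
            continue
        mm = sum(
            1 for s, m in zip(kmer, motif) if s not in _IUPAC.get(m, {m})
        )
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, offset)
    if best is None:
        return False, None, None
    return True, best[1], best[0]
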