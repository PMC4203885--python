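"""Independent brute-force oracles used by the property and acceptance tests.

Every function here is a deliberately naive O(n*m) pure-Python
implementation, kept separate from the package's vectorized/sorted-array
code paths so the two can be compared on random instances.
"""

from __future__ import annotations

import math

import numpy as np

from demethylome.intervals import GenomicInterval


def brute_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_point_distance(pos: int, iv: GenomicInterval) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def brute_nearest(chrom: str, pos: int, targets) -> tuple[float, int | None]:
    best = None
    for i, t in enumerate(targets):
        if t.chrom != chrom:
            continue
        key = (brute_point_distance(pos, t), t.start, t.end, i)
        if best is None or key < best:
            best = key
    if best is None:
        return math.inf, None
    return float(best[0]), best[3]


def brute_region_mean(calls, region: GenomicInterval, min_coverage: int):
    """calls: iterable of (chrom, pos, meth, cov)."""
    vals = [
        m for c, p, m, cov in calls
        if c == region.chrom and region.start <= p < region.end and cov >= min_coverage
    ]
    if not vals:
        return float("nan"), 0
    return sum(vals) / len(vals), len(vals)


def brute_profile(calls, anchors, flank: int, bin_size: int):
    n_bins = 2 * flank // bin_size
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for chrom, apos, strand in anchors:
        for c, p, m, _cov in calls:
            if c != chrom:
                continue
            off = p - apos if strand != "-" else apos - p
            if -flank <= off < flank:
                b = (off + flank) // bin_size
                sums[b] += m
                counts[b] += 1
    return [
        (sums[i] / counts[i] if counts[i] else float("nan"), counts[i])
        for i in range(n_bins)
    ]


def brute_consensus_indices(rep1, rep2) -> list[int]:
    return [
        i for i, a in enumerate(rep1)
        if any(brute_overlaps(a, b) for b in rep2)
    ]


def brute_compare(a, b):
    """Returns (n_common_a, n_unique_a, n_common_b, n_unique_b)."""
    ca = sum(1 for x in a if any(brute_overlaps(x, y) for y in b))
    cb = sum(1 for y in b if any(brute_overlaps(y, x) for x in a))
    return ca, len(a) - ca, cb, len(b) - cb


def random_intervals(rng: np.random.Generator, n: int, span: int = 10_000,
                     max_len: int = 400, chroms=("chrA", "chrB")) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_calls(rng: np.random.Generator, n: int, span: int = 10_000,
                 chroms=("chrA", "chrB")):
    """Unique-position random methylation calls as (chrom, pos, meth, cov)."""
    seen = set()
    out = []
    while len(out) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, span))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        out.append((chrom, pos, float(rng.random()), int(rng.integers(0, 12))))
    return out
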