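"""Genomic coordinate primitives: intervals, genes, annotations, overlap and
nearest-feature queries.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
GTF input (1-based, inclusive) is converted on read, so a single convention
holds everywhere downstream. Strand is ``+``, ``-`` or ``.``; a gene's TSS is
the strand-oriented 5' end of its span (``span.start`` on ``+``,
``span.end - 1`` on ``-``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(ValueError):
    """Input parsed, but violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} must exceed start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open semantics: ``[0,100)`` and ``[100,200)`` abut but do not
    overlap. Intervals on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Gene:
    """One transcript model per gene: body span, strand-oriented TSS, exons.

    Introns are the complement of the exons within the span.
    """

    gene_id: str
    name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.span.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for e in exons:
            if e.chrom != self.span.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon on wrong chrom")
            if e.start < self.span.start or e.end > self.span.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{e.start},{e.end}) outside "
                    f"span [{self.span.start},{self.span.end})"
                )
            if prev_end is not None and e.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.chrom, left.end, right.start, self.strand)
                )
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """Gene models keyed by gene_id plus chromosome sizes."""

    genes: dict[str, Gene]
    chrom_sizes: dict[str, int]

    def __post_init__(self):
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValidationError(
                    f"gene {g.gene_id}: unknown chromosome {g.chrom}"
                )
            if g.span.end > size:
                raise ValidationError(
                    f"gene {g.gene_id}: span exceeds {g.chrom} length {size}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def tss_sites(self) -> list[tuple[str, str, int, str]]:
        """(gene_id, chrom, tss, strand) for every gene."""
        return [(g.gene_id, g.chrom, g.tss, g.strand) for g in self.genes.values()]

    def promoter_windows(
        self, upstream: int = 100, downstream: int = 700
    ) -> dict[str, GenomicInterval]:
        return {
            gid: promoter_window(g, upstream, downstream, self.chrom_sizes[g.chrom])
            for gid, g in self.genes.items()
        }

    def all_exons(self) -> list[GenomicInterval]:
        return [e for g in self.genes.values() for e in g.exons]

    def gene_spans(self) -> list[GenomicInterval]:
        return [g.span for g in self.genes.values()]


def promoter_window(
    gene: Gene,
    upstream: int = 100,
    downstream: int = 700,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS.

    Covers ``upstream`` bases 5' of the TSS, the TSS base itself, and
    ``downstream`` bases 3' of it — ``upstream + downstream + 1`` bp before
    clipping to chromosome bounds.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    t = gene.tss
    if gene.strand == "+":
        start, end = t - upstream, t + downstream + 1
    else:
        start, end = t - downstream, t + upstream + 1
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


class IntervalIndex:
    """Sorted-array index over a fixed interval collection.

    Supports membership-style overlap tests, overlap counting and point
    containment in O(log n) using the start-sorted prefix maximum of ends.
    Insertion order of the input is retained as the stable identity of each
    interval (used for deterministic tie-breaking).
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(self.intervals):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in per_chrom.items():
            arr = np.asarray(sorted(rows), dtype=np.int64)
            starts, ends, orig = arr[:, 0], arr[:, 1], arr[:, 2]
            self._by_chrom[chrom] = {
                "starts": starts,
                "ends": ends,
                "orig": orig,
                "prefmax_end": np.maximum.accumulate(ends),
                "ends_sorted": np.sort(ends),
            }

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) on chrom overlaps >=1 indexed interval."""
        c = self._by_chrom.get(chrom)
        if c is None:
            return False
        k = int(np.searchsorted(c["starts"], end, side="left"))
        return k > 0 and int(c["prefmax_end"][k - 1]) > start

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        c = self._by_chrom.get(chrom)
        if c is None:
            return 0
        n_start_lt = int(np.searchsorted(c["starts"], end, side="left"))
        n_end_le = int(np.searchsorted(c["ends_sorted"], start, side="right"))
        return n_start_lt - n_end_le

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps_any(chrom, pos, pos + 1)

    def covering(self, chrom: str, pos: int) -> list[int]:
        """Original indices of all intervals containing ``pos`` (may be empty)."""
        c = self._by_chrom.get(chrom)
        if c is None:
            return []
        mask = (c["starts"] <= pos) & (c["ends"] > pos)
        return sorted(int(i) for i in c["orig"][mask])


def point_interval_distance(pos: int, start: int, end: int) -> int:
    """bp gap from a point to the closest covered base of ``[start, end)``.

    0 if the point lies inside; ``start - pos`` left of it; ``pos - (end-1)``
    right of it.
    """
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def nearest_distance(
    chrom: str, pos: int, targets: Sequence[GenomicInterval]
) -> tuple[float, int | None]:
    """Distance from an anchor point to the nearest target interval.

    Only same-chromosome targets are considered; if none exist the distance
    is ``math.inf`` with index ``None`` (an "unreachable" sentinel, excluded
    from medians downstream). Ties are broken deterministically by
    (start, end, insertion order). Raises on an empty target collection.

    Returns (distance, index-into-targets).
    """
    if len(targets) == 0:
        raise ValueError("nearest_distance: empty target collection")
    rows = [
        (point_interval_distance(pos, t.start, t.end), t.start, t.end, i)
        for i, t in enumerate(targets)
        if t.chrom == chrom
    ]
    if not rows:
        return math.inf, None
    best = min(rows)
    return float(best[0]), best[3]


def read_chrom_sizes(path) -> dict[str, int]:
    """2-column TSV: chrom <tab> length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, lineno, "expected 2 tab-separated columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer length {parts[1]!r}")
            if length <= 0:
                raise ParseError(path, lineno, "chromosome length must be > 0")
            sizes[parts[0]] = length
    return sizes


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(
    path, chrom_sizes: Mapping[str, int] | str | Path, fmt: str | None = None
) -> GenomeAnnotation:
    """Read a GTF-like or BED12 gene annotation into a :class:`GenomeAnnotation`.

    ``fmt`` is ``"gtf"`` or ``"bed12"``; inferred from the file extension when
    omitted. GTF coordinates (1-based inclusive) are converted to 0-based
    half-open. One transcript model per gene_id is assumed.
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "bed12" if suffix == "bed" or suffix == ".bed" else "gtf"
    if fmt == "gtf":
        genes = _read_gtf_genes(path)
    elif fmt == "bed12":
        genes = _read_bed12_genes(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GenomeAnnotation(genes, dict(chrom_sizes))


def _read_gtf_genes(path) -> dict[str, Gene]:
    spans: dict[str, GenomicInterval] = {}
    names: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if start1 < 1 or end1 < start1:
                raise ParseError(path, lineno, f"bad coordinates {start1}..{end1}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            attrs = _parse_gtf_attributes(attrs_s)
            gid = attrs.get("gene_id")
            if not gid:
                raise ParseError(path, lineno, "missing gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                if gid in spans:
                    raise ParseError(path, lineno, f"duplicate gene {gid}")
                spans[gid] = iv
                names[gid] = attrs.get("gene_name", gid)
                order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append(iv)
                if gid not in names:
                    names[gid] = attrs.get("gene_name", gid)
                    order.append(gid)
    genes: dict[str, Gene] = {}
    for gid in order:
        ex = tuple(sorted(exons.get(gid, []), key=lambda e: e.start))
        span = spans.get(gid)
        if span is None:
            if not ex:
                continue
            span = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        if not ex:
            ex = (GenomicInterval(span.chrom, span.start, span.end, span.strand),)
        genes[gid] = Gene(gid, names[gid], span, ex)
    return genes


def _read_bed12_genes(path) -> dict[str, Gene]:
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(path, lineno, f"expected 12 columns, got {len(parts)}")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            strand = parts[5]
            try:
                start, end = int(start_s), int(end_s)
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "non-integer BED12 fields")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(path, lineno, "block count mismatch")
            if name in genes:
                raise ParseError(path, lineno, f"duplicate gene {name}")
            span = GenomicInterval(chrom, start, end, strand)
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            genes[name] = Gene(name, name, span, exons)
    return genes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_gtf(genes: Iterable[Gene], path, source: str = "demethylome") -> None:
    """Write gene+exon features in the GTF dialect read_annotation accepts."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span.start + 1}\t{g.span.end}\t."
                f"\t{g.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t."
                    f"\t{g.strand}\t.\t{attrs}\n"
                )
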