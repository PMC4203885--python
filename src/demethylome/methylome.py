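"""Per-CpG methylation calls and region-level aggregation.

A :class:`MethylationTable` holds whole-genome-bisulfite-style calls for one
condition: per CpG a methylated fraction in [0, 1] and a read coverage.
Aggregation follows the field's standard recipe: only CpGs with coverage at
or above a minimum (default 3x) contribute, and a region's value is the
unweighted mean of the qualifying CpG fractions (coverage weighting is
available behind a flag).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ParseError, ValidationError

MISSING = float("nan")


class MethylationTable:
    """Sorted per-chromosome CpG methylation calls for one condition."""

    def __init__(self, condition: str, frame: pd.DataFrame):
        required = {"chrom", "pos", "meth", "cov"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"methylation frame needs columns {sorted(required)}")
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if ((frame["meth"] < 0) | (frame["meth"] > 1)).any():
            raise ValidationError("meth fractions must lie in [0, 1]")
        if (frame["cov"] < 0).any():
            raise ValidationError("coverage must be >= 0")
        dup = frame.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValidationError(
                f"duplicate CpG position {row['chrom']}:{int(row['pos'])}"
            )
        self.condition = condition
        self._chroms: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            self._chroms[str(chrom)] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "meth": sub["meth"].to_numpy(np.float64),
                "cov": sub["cov"].to_numpy(np.int64),
            }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def __len__(self) -> int:
        return sum(len(c["pos"]) for c in self._chroms.values())

    def arrays(self, chrom: str):
        """(pos, meth, cov) numpy arrays for one chromosome (may be empty)."""
        c = self._chroms.get(chrom)
        if c is None:
            empty = np.empty(0)
            return empty.astype(np.int64), empty, empty.astype(np.int64)
        return c["pos"], c["meth"], c["cov"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {"chrom": chrom, "pos": c["pos"], "meth": c["meth"], "cov": c["cov"]}
            )
            for chrom, c in sorted(self._chroms.items())
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "meth", "cov"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def read(cls, path, condition: str, dialect: str = "percent") -> "MethylationTable":
        """Read a headerless bedGraph-like 4-column TSV.

        Columns: chrom, 0-based position, methylation value, coverage.
        ``dialect`` declares whether the value column is a ``"percent"``
        (0..100, the usual %methyl-C/C convention) or a ``"fraction"``
        (0..1); it is never guessed.
        """
        if dialect not in ("percent", "fraction"):
            raise ValueError(f"unknown methylation dialect {dialect!r}")
        hi = 100.0 if dialect == "percent" else 1.0
        chroms: list[str] = []
        positions: list[int] = []
        meths: list[float] = []
        covs: list[int] = []
        seen: set[tuple[str, int]] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ParseError(path, lineno, f"expected 4 columns, got {len(parts)}")
                try:
                    pos = int(parts[1])
                    value = float(parts[2])
                    cov = int(parts[3])
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric field")
                if pos < 0:
                    raise ParseError(path, lineno, f"negative position {pos}")
                if not (0.0 <= value <= hi):
                    raise ParseError(
                        path, lineno,
                        f"methylation value {value} outside [0, {hi:g}] "
                        f"({dialect} dialect)",
                    )
                if cov < 0:
                    raise ParseError(path, lineno, f"negative coverage {cov}")
                key = (parts[0], pos)
                if key in seen:
                    raise ParseError(path, lineno, f"duplicate position {parts[0]}:{pos}")
                seen.add(key)
                chroms.append(parts[0])
                positions.append(pos)
                meths.append(value / hi)
                covs.append(cov)
        frame = pd.DataFrame(
            {"chrom": chroms, "pos": positions, "meth": meths, "cov": covs}
        )
        return cls(condition, frame)

    def write(self, path, dialect: str = "percent") -> None:
        if dialect not in ("percent", "fraction"):
            raise ValueError(f"unknown methylation dialect {dialect!r}")
        scale = 100.0 if dialect == "percent" else 1.0
        with open(path, "w") as fh:
            for chrom in self.chroms:
                pos, meth, cov = self.arrays(chrom)
                for p, m, c in zip(pos, meth, cov):
                    fh.write(f"{chrom}\t{p}\t{m * scale:.6g}\t{c}\n")


def aggregate_region_methylation(
    table: MethylationTable,
    regions: Sequence[GenomicInterval],
    min_coverage: int = 3,
    coverage_weighted: bool = False,
) -> pd.DataFrame:
    """Mean methylation per region over CpGs passing the coverage filter.

    Returns a DataFrame aligned with ``regions``: chrom, start, end,
    ``mean_meth`` (NaN when no CpG qualifies) and ``n_cpgs``.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    # prefix sums over qualifying CpGs make each region O(log n)
    cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    means = np.full(len(regions), MISSING)
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        chrom = region.chrom
        if chrom not in cache:
            pos, meth, cov = table.arrays(chrom)
            ok = cov >= min_coverage
            weight = cov.astype(np.float64) if coverage_weighted else np.ones_like(meth)
            w = np.where(ok, weight, 0.0)
            cum_wm = np.concatenate([[0.0], np.cumsum(w * meth)])
            cum_w = np.concatenate([[0.0], np.cumsum(w)])
            cum_n = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
            cache[chrom] = (pos, (cum_wm, cum_w, cum_n))  # type: ignore[assignment]
        pos, (cum_wm, cum_w, cum_n) = cache[chrom]  # type: ignore[misc]
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        n = int(cum_n[hi] - cum_n[lo])
        counts[i] = n
        wsum = cum_w[hi] - cum_w[lo]
        if n > 0 and wsum > 0:
            means[i] = (cum_wm[hi] - cum_wm[lo]) / wsum
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "mean_meth": means,
            "n_cpgs": counts,
        }
    )


def classify_promoter_methylation(mean_meth: float, threshold: float = 0.5) -> str:
    """Label a promoter ``high`` iff its mean methylation strictly exceeds
    the threshold (default 50%); NaN propagates as ``missing``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if mean_meth is None or (isinstance(mean_meth, float) and np.isnan(mean_meth)):
        return "missing"
    return "high" if mean_meth > threshold else "low"


def compartment_medians(
    parental: MethylationTable,
    derived: MethylationTable,
    ann,
    random_regions: Sequence[GenomicInterval],
    min_coverage: int = 3,
    upstream: int = 100,
    downstream: int = 700,
) -> dict[str, dict[str, float]]:
    """Median region-mean methylation per compartment and condition.

    Compartments: promoter windows (strand-oriented -upstream..+downstream
    around each TSS), gene bodies (full spans) and the supplied random
    regions. Missing regions are excluded; an all-missing compartment is an
    error.
    """
    promoters = list(ann.promoter_windows(upstream, downstream).values())
    bodies = ann.gene_spans()
    out: dict[str, dict[str, float]] = {}
    for table in (parental, derived):
        comp: dict[str, float] = {}
        for name, regions in (
            ("promoters", promoters),
            ("gene_bodies", bodies),
            ("random", list(random_regions)),
        ):
            agg = aggregate_region_methylation(table, regions, min_coverage)
            vals = agg["mean_meth"].dropna()
            if vals.empty:
                raise ValueError(
                    f"compartment {name!r} has no region with a qualifying CpG "
                    f"({table.condition})"
                )
            comp[name] = float(vals.median())
        out[table.condition] = comp
    return out


def methylation_profile(
    table: MethylationTable,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 2500,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Binned mean methylation around anchor points (e.g. TSSs).

    Each (anchor, CpG) pair contributes to the bin of its strand-oriented
    offset (CpG downstream of a minus-strand anchor gets a positive offset).
    Offsets cover [-flank, flank) in ``2*flank/bin_size`` bins; empty bins
    are NaN. Anchors are (chrom, position, strand) triples.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, apos, strand in anchors:
        pos, meth, _cov = table.arrays(chrom)
        lo = int(np.searchsorted(pos, apos - flank))
        hi = int(np.searchsorted(pos, apos + flank + 1))
        if hi <= lo:
            continue
        offsets = pos[lo:hi] - apos
        if strand == "-":
            offsets = -offsets
        keep = (offsets >= -flank) & (offsets < flank)
        idx = (offsets[keep] + flank) // bin_size
        np.add.at(sums, idx, meth[lo:hi][keep])
        np.add.at(counts, idx, 1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), MISSING)
    starts = np.arange(n_bins) * bin_size - flank
    return pd.DataFrame(
        {"offset_start": starts, "offset_end": starts + bin_size,
         "mean_meth": means, "n_pairs": counts}
    )


def sample_random_regions(
    chrom_sizes: Mapping[str, int],
    n: int,
    length: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Uniform, chromosome-length-weighted random fixed-length regions.

    Reproducible for a given seed (or caller-supplied Generator). Errors if
    ``n <= 0`` or the requested length exceeds the shortest chromosome.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    if length > sizes.min():
        raise ValueError(
            f"region length {length} exceeds shortest chromosome ({int(sizes.min())})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    out = []
    for k in picks:
        start = int(rng.integers(0, chrom_sizes[chroms[k]] - length + 1))
        out.append(GenomicInterval(chroms[k], start, start + length))
    return out
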