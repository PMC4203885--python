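"""Seedable synthetic paired-condition epigenome generator.

Emulates the statistical structure of a parental colorectal-cancer-like
methylome/epigenome and a globally demethylated derivative:

* bimodal parental promoter methylation (beta mixture, median calibrated to
  30%), high gene-body/background methylation (median 84%);
* residual methylation in the demethylated condition (promoter median below
  1%, gene bodies 13%, random regions 9%), obtained by calibrating
  per-compartment scale factors against the realized parental draw;
* condition-unique distal H3K27ac peaks (enhancers), the new ones planted
  preferentially inside the bodies of designated up-regulated genes and a
  configured fraction pre-marked by parental H3K4me1 (poised);
* expression classes (de-repressed / up / down / unchanged / silent) with
  replicate noise, plus CpG islands, TATA boxes and a tumor-suppressor list.

Every planted label is recorded in a ground-truth bundle so downstream
operations can be tested against known answers. Output is reproducible per
seed.
"""

from __future__ import annotations

import bisect
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .intervals import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    write_chrom_sizes,
    write_gtf,
)
from .methylome import MethylationTable, sample_random_regions
from .peaks import PeakSet


class GeneratorError(ValueError):
    """Infeasible synthetic configuration."""


# ---------------------------------------------------------------------------
# beta-mixture calibration


def beta_with_median(median: float, conc: float):
    """Frozen beta distribution with the requested median at fixed
    concentration (a + b = conc)."""
    if not (0.0 < median < 1.0):
        raise ValueError("median must lie strictly inside (0, 1)")

    def offset(mu):
        return stats.beta(mu * conc, (1 - mu) * conc).median() - median

    mu = optimize.brentq(offset, 1e-6, 1 - 1e-6, xtol=1e-10)
    return stats.beta(mu * conc, (1 - mu) * conc)


def calibrate_mixture(
    target_median: float,
    low_median: float = 0.03,
    high_median: float = 0.90,
    conc: float = 4.0,
) -> float:
    """High-mode weight for a two-beta mixture whose median hits the target.

    Components are betas parameterized by their medians (so a target equal to
    a mode value yields weight 0 or 1 exactly). The weight solves
    ``(1-w)*F_low(t) + w*F_high(t) = 1/2``; the resulting analytic mixture
    median matches the target to well under 1e-3.
    """
    if not low_median < high_median:
        raise GeneratorError("low mode must lie below high mode")
    low = beta_with_median(low_median, conc)
    high = beta_with_median(high_median, conc)
    fl, fh = low.cdf(target_median), high.cdf(target_median)
    if fl == fh:
        raise GeneratorError("mixture median target unattainable: flat CDF region")
    w = (fl - 0.5) / (fl - fh)
    if w < -1e-9 or w > 1 + 1e-9:
        raise GeneratorError(
            f"mixture median target {target_median} unattainable with modes "
            f"{low_median}/{high_median}"
        )
    return float(min(max(w, 0.0), 1.0))


def mixture_median(w_high: float, low, high) -> float:
    """Analytic median of a two-component beta mixture (for verification)."""

    def cdf_minus_half(x):
        return (1 - w_high) * low.cdf(x) + w_high * high.cdf(x) - 0.5

    return float(optimize.brentq(cdf_minus_half, 1e-9, 1 - 1e-9, xtol=1e-9))


def _mid_quantiles(dist, n: int) -> np.ndarray:
    """Stratified (mid-quantile) sample of size n: the i-th value is the
    ((i+0.5)/n)-quantile. Reproduces population quantiles at small n, which
    iid draws from a sharply bimodal distribution do not."""
    if n <= 0:
        return np.empty(0)
    return dist.ppf((np.arange(n) + 0.5) / n)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticConfig:
    """Defaults are the desk-scale study conditions (2 x 10 Mb, 2,000 genes).

    Methylation targets are medians of region means: parental promoters 0.30,
    gene bodies / background 0.84; demethylated condition 0.005 (so the
    promoter median stays under the 1% bound), 0.13 and 0.09.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 15_000_000
    n_genes: int = 2000
    gene_length_min: int = 3000
    gene_length_max: int = 12_000
    min_intergenic_gap: int = 3000
    frac_open_gaps: float = 0.2
    exon_count_min: int = 2
    exon_count_max: int = 10

    cpg_rate_intergenic: float = 0.0075
    cpg_rate_genic: float = 0.0075
    cpg_rate_cgi: float = 0.018
    cpg_rate_enhancer_extra: float = 0.005

    promoter_low_median: float = 0.03
    promoter_high_median: float = 0.90
    promoter_meth_median: float = 0.30
    mixture_concentration: float = 4.0
    body_meth_median: float = 0.84
    body_concentration: float = 30.0
    cpg_noise_sd: float = 0.04
    active_enhancer_meth_median: float = 0.08

    derived_promoter_target: float = 0.005
    derived_body_target: float = 0.13
    derived_background_target: float = 0.09
    derived_noise_sd: float = 0.003
    coverage_mean: float = 10.0

    n_derepressed: int = 100
    n_up: int = 80
    n_down: int = 120
    replicate_noise_sd: float = 0.1
    n_expression_replicates: int = 3

    frac_up_with_intragenic_enhancers: float = 0.40
    frac_spreading: float = 0.59
    max_intragenic_enhancers: int = 5
    frac_intragenic_exonic: float = 0.08
    n_common_enhancers: int = 400
    n_unique_a_enhancers: int = 100
    n_unique_b_extra: int = 200
    frac_enhancers_intragenic: float = 0.5
    enhancer_length_min: int = 400
    enhancer_length_max: int = 800
    frac_new_enhancers_poised: float = 0.47
    n_extra_h3k4me1: int = 50

    frac_derepressed_gain_h3k4me3: float = 0.40
    frac_neither_in_common_h3k4me3: float = 0.13
    promoter_peak_halfwidth: int = 500
    peak_jitter: int = 50
    n_replicate_noise_peaks: int = 15

    frac_cgi_derepressed: float = 0.58
    frac_cgi_up: float = 0.75
    frac_cgi_down: float = 0.83
    frac_cgi_other: float = 0.70
    cgi_length_mean: float = 1000.0
    cgi_length_sd: float = 150.0
    n_nonpromoter_cgi: int = 50
    frac_tata_derepressed: float = 0.10
    frac_tata_up: float = 0.10
    frac_tata_down: float = 0.07
    frac_tata_other: float = 0.08
    promoter_seq_length: int = 120
    tata_motif: str = "TATAWAW"

    n_tsg_derepressed: int = 25
    n_tsg_up: int = 8
    n_tsg_extra: int = 20

    promoter_upstream: int = 100
    promoter_downstream: int = 700
    condition_a: str = "parental"
    condition_b: str = "demethylated"
    methylation_dialect: str = "percent"

    def validate(self) -> None:
        fracs = [
            self.frac_open_gaps, self.frac_up_with_intragenic_enhancers,
            self.frac_spreading, self.frac_intragenic_exonic,
            self.frac_enhancers_intragenic, self.frac_new_enhancers_poised,
            self.frac_derepressed_gain_h3k4me3, self.frac_neither_in_common_h3k4me3,
            self.frac_cgi_derepressed, self.frac_cgi_up, self.frac_cgi_down,
            self.frac_cgi_other, self.frac_tata_derepressed, self.frac_tata_up,
            self.frac_tata_down, self.frac_tata_other,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise GeneratorError("all fractions must lie in [0, 1]")
        if min(self.n_chroms, self.chrom_length, self.n_genes) <= 0:
            raise GeneratorError("counts must be positive")
        if self.n_derepressed + self.n_up + self.n_down > self.n_genes:
            raise GeneratorError("gene classes exceed the number of genes")
        if not 0 < self.gene_length_min <= self.gene_length_max:
            raise GeneratorError("bad gene length range")
        if not 0 < self.enhancer_length_min <= self.enhancer_length_max:
            raise GeneratorError("bad enhancer length range")
        if self.min_intergenic_gap < 2600:
            raise GeneratorError(
                "min_intergenic_gap below 2,600 bp lets neighbouring promoter "
                "peaks bleed into other genes' +/-2 kb windows"
            )
        if not (0 < self.promoter_low_median < self.promoter_meth_median
                < self.promoter_high_median < 1):
            raise GeneratorError("promoter methylation medians must be ordered")
        if self.promoter_seq_length < 47:
            raise GeneratorError("promoter sequences must cover the -40..-20 window")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise GeneratorError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Bundle:
    """Paths of every emitted file plus the in-memory ground truth."""

    outdir: Path
    paths: dict[str, object]
    ground_truth: dict
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# placement helpers


class _Placer:
    """Tracks occupied intervals per chromosome; offers collision-free slots
    inside designated open intergenic windows."""

    def __init__(self, rng: np.random.Generator, margin: int = 300):
        self.rng = rng
        self.margin = margin
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self.windows: dict[str, list[tuple[int, int]]] = {}

    def block(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)

    def fits(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom, [])
        ends = self._ends.get(chrom, [])
        i = bisect.bisect_left(starts, start)
        if i > 0 and ends[i - 1] + self.margin > start:
            return False
        if i < len(starts) and starts[i] < end + self.margin:
            return False
        return True

    def add_window(self, chrom: str, start: int, end: int) -> None:
        if end > start:
            self.windows.setdefault(chrom, []).append((start, end))

    def place_intergenic(self, length: int, max_tries: int = 400) -> GenomicInterval:
        chroms = sorted(self.windows)
        weights = np.array(
            [sum(max(0, e - s) for s, e in self.windows[c]) for c in chroms],
            dtype=float,
        )
        if not chroms or weights.sum() <= 0:
            raise GeneratorError("no intergenic space available for placement")
        for _ in range(max_tries):
            chrom = chroms[int(self.rng.choice(len(chroms), p=weights / weights.sum()))]
            wins = self.windows[chrom]
            ws, we = wins[int(self.rng.integers(len(wins)))]
            if we - ws < length:
                continue
            start = int(self.rng.integers(ws, we - length + 1))
            if self.fits(chrom, start, start + length):
                self.block(chrom, start, start + length)
                return GenomicInterval(chrom, start, start + length)
        raise GeneratorError("could not place an intergenic feature (genome too full)")

    def place_in_segment(
        self, chrom: str, seg_start: int, seg_end: int, length: int,
        max_tries: int = 60,
    ) -> GenomicInterval | None:
        if seg_end - seg_start < length:
            return None
        for _ in range(max_tries):
            start = int(self.rng.integers(seg_start, seg_end - length + 1))
            if self.fits(chrom, start, start + length):
                self.block(chrom, start, start + length)
                return GenomicInterval(chrom, start, start + length)
        return None


def _jitter_peaks(
    peaks: PeakSet, rng: np.random.Generator, jitter: int, replicate: str
) -> PeakSet:
    out = []
    for iv in peaks.intervals:
        d = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        start = max(0, iv.start + d)
        out.append(GenomicInterval(iv.chrom, start, start + iv.length, iv.strand))
    return PeakSet(peaks.mark, peaks.condition, replicate, tuple(out))


# ---------------------------------------------------------------------------
# the generator


def generate(config: SyntheticConfig, outdir) -> Bundle:
    """Write a full synthetic bundle to ``outdir`` and return it with ground
    truth. Deterministic per config (``config.seed`` drives all randomness).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)

    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }

    # ---- gene classes (before layout: enhancer hosts need room) ----
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    perm = rng.permutation(n)
    classes = np.array(["unchanged"] * n, dtype=object)
    k = 0
    derepressed_idx = perm[k:k + config.n_derepressed]; k += config.n_derepressed
    up_idx = perm[k:k + config.n_up]; k += config.n_up
    down_idx = perm[k:k + config.n_down]; k += config.n_down
    rest_idx = perm[k:]
    classes[derepressed_idx] = "de_repressed"
    classes[up_idx] = "up"
    classes[down_idx] = "down"

    # promoter methylation mixture: the high mode is carried by de-repressed
    # plus silent genes; the silent count follows from the calibrated weight
    w_high = calibrate_mixture(
        config.promoter_meth_median, config.promoter_low_median,
        config.promoter_high_median, config.mixture_concentration,
    )
    low_dist = beta_with_median(config.promoter_low_median, config.mixture_concentration)
    high_dist = beta_with_median(config.promoter_high_median, config.mixture_concentration)
    n_high = int(round(w_high * n))
    n_silent = n_high - config.n_derepressed
    if n_silent < 0 or n_silent > len(rest_idx):
        raise GeneratorError(
            "calibrated high-methylation promoter count incompatible with the "
            "configured gene classes"
        )
    silent_idx = rest_idx[:n_silent]  # rest_idx is already a random permutation
    classes[silent_idx] = "not_expressed"

    # enhancer hosts: up-regulated genes that receive planted intragenic new
    # enhancers; a configured fraction get several ("spreading")
    n_hosts = int(round(config.frac_up_with_intragenic_enhancers * config.n_up))
    host_idx = up_idx[:n_hosts]
    host_counts: dict[int, int] = {}
    for gi in host_idx:
        if rng.random() < config.frac_spreading and config.max_intragenic_enhancers > 1:
            host_counts[int(gi)] = int(rng.integers(2, config.max_intragenic_enhancers + 1))
        else:
            host_counts[int(gi)] = 1

    # ---- gene layout ----
    log_lo, log_hi = np.log(config.gene_length_min), np.log(config.gene_length_max)
    lengths = np.exp(rng.uniform(log_lo, log_hi, n)).astype(int)
    for gi, kcnt in host_counts.items():
        required = 5000 + kcnt * (config.enhancer_length_max + 600)
        lengths[gi] = max(lengths[gi], required)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    chroms = sorted(chrom_sizes)
    order = rng.permutation(n)
    total_len = sum(chrom_sizes.values())
    counts = [int(round(n * chrom_sizes[c] / total_len)) for c in chroms]
    counts[-1] = n - sum(counts[:-1])
    placer = _Placer(rng)
    gene_coords: dict[int, tuple[str, int, int]] = {}
    pos0 = 0
    for chrom, n_c in zip(chroms, counts):
        idxs = order[pos0:pos0 + n_c]
        pos0 += n_c
        genic = int(lengths[idxs].sum())
        min_gaps = (n_c + 1) * config.min_intergenic_gap
        slack = chrom_sizes[chrom] - genic - min_gaps
        if slack < 0:
            raise GeneratorError(
                f"{chrom}: genes plus minimum gaps exceed the chromosome "
                f"({genic + min_gaps} > {chrom_sizes[chrom]} bp)"
            )
        n_open = max(1, int(round(config.frac_open_gaps * (n_c + 1))))
        open_gaps = sorted(rng.choice(n_c + 1, size=n_open, replace=False).tolist())
        shares = rng.dirichlet(np.ones(n_open)) * slack
        extra = {g: int(s) for g, s in zip(open_gaps, shares)}
        cursor = 0
        for j, gi in enumerate(idxs):
            gap = config.min_intergenic_gap + extra.get(j, 0)
            if gap - 4600 >= 600:
                placer.add_window(chrom, cursor + 2300, cursor + gap - 2300)
            cursor += gap
            gene_coords[int(gi)] = (chrom, cursor, cursor + int(lengths[gi]))
            cursor += int(lengths[gi])
        last_gap = chrom_sizes[chrom] - cursor + extra.get(n_c, 0) * 0
        if last_gap - 4600 >= 600:
            placer.add_window(chrom, cursor + 2300, chrom_sizes[chrom] - 2300)

    # ---- exon structure and planted enhancer slots ----
    enhancers: list[dict] = []  # planted unique-B intragenic first
    genes: dict[str, Gene] = {}
    exonic_flags = rng.random(int(sum(host_counts.values()))) < config.frac_intragenic_exonic
    slot_counter = 0
    for gi in range(n):
        chrom, s, e = gene_coords[gi]
        strand = str(strands[gi])
        span = GenomicInterval(chrom, s, e, strand)
        exons: list[GenomicInterval] = [GenomicInterval(chrom, s, s + 250, strand)]
        if gi in host_counts:
            zone_start = (s + 2300) if strand == "+" else (s + 300)
            zone_end = (e - 300) if strand == "+" else (e - 2300)
            kcnt = host_counts[gi]
            seg = (zone_end - zone_start) // kcnt
            for j in range(kcnt):
                length = int(rng.integers(config.enhancer_length_min,
                                          config.enhancer_length_max + 1))
                lo = zone_start + j * seg + 200
                hi = zone_start + (j + 1) * seg - 200 - length
                start = int(rng.integers(lo, max(lo + 1, hi)))
                iv = GenomicInterval(chrom, start, start + length)
                placer.block(chrom, start, start + length)
                exonic = bool(exonic_flags[slot_counter])
                slot_counter += 1
                if exonic:
                    mid = iv.midpoint
                    exons.append(GenomicInterval(chrom, mid - 100, mid + 100, strand))
                enhancers.append({
                    "category": "unique_b", "chrom": chrom,
                    "start": iv.start, "end": iv.end,
                    "compartment": "exonic" if exonic else "intronic",
                    "host_gene": gene_ids[gi], "planted_intragenic": True,
                })
        else:
            n_ex = int(rng.integers(config.exon_count_min, config.exon_count_max + 1))
            n_mid = max(0, n_ex - 2)
            interior_start, interior_end = s + 300, e - 300
            if n_mid > 0 and interior_end - interior_start >= n_mid * 460:
                seg = (interior_end - interior_start) // n_mid
                for j in range(n_mid):
                    ex_len = int(rng.integers(150, 401))
                    lo = interior_start + j * seg + 20
                    hi = interior_start + (j + 1) * seg - 20 - ex_len
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    exons.append(GenomicInterval(chrom, start, start + ex_len, strand))
        exons.append(GenomicInterval(chrom, e - 250, e, strand))
        genes[gene_ids[gi]] = Gene(gene_ids[gi], gene_ids[gi], span, tuple(exons))

    ann = GenomeAnnotation(genes, dict(chrom_sizes))

    # ---- remaining enhancers (common / unique-A / extra unique-B) ----
    def _eligible_segments(gi: int) -> list[tuple[str, int, int]]:
        gene = genes[gene_ids[gi]]
        s, e = gene.span.start, gene.span.end
        zone = (s + 2300, e - 300) if gene.strand == "+" else (s + 300, e - 2300)
        segs = []
        for intron in gene.introns:
            lo, hi = max(intron.start, zone[0]), min(intron.end, zone[1])
            if hi - lo >= config.enhancer_length_max + 2 * placer.margin:
                segs.append((gene.chrom, lo, hi))
        return segs

    eligible = [gi for gi in range(n)
                if gi not in host_counts and _eligible_segments(gi)]

    def _place_enhancer(category: str) -> dict:
        length = int(rng.integers(config.enhancer_length_min,
                                  config.enhancer_length_max + 1))
        go_intragenic = bool(eligible) and (
            rng.random() < config.frac_enhancers_intragenic
        )
        if go_intragenic:
            for _ in range(40):
                gi = int(eligible[int(rng.integers(len(eligible)))])
                segs = _eligible_segments(gi)
                if not segs:
                    continue
                chrom, lo, hi = segs[int(rng.integers(len(segs)))]
                iv = placer.place_in_segment(chrom, lo, hi, length)
                if iv is not None:
                    gene = genes[gene_ids[gi]]
                    mid = iv.midpoint
                    in_exon = any(ex.start <= mid < ex.end for ex in gene.exons)
                    return {
                        "category": category, "chrom": iv.chrom,
                        "start": iv.start, "end": iv.end,
                        "compartment": "exonic" if in_exon else "intronic",
                        "host_gene": gene_ids[gi], "planted_intragenic": False,
                    }
        iv = placer.place_intergenic(length)
        return {
            "category": category, "chrom": iv.chrom, "start": iv.start,
            "end": iv.end, "compartment": "intergenic", "host_gene": None,
            "planted_intragenic": False,
        }

    for _ in range(config.n_common_enhancers):
        enhancers.append(_place_enhancer("common"))
    for _ in range(config.n_unique_a_enhancers):
        enhancers.append(_place_enhancer("unique_a"))
    for _ in range(config.n_unique_b_extra):
        enhancers.append(_place_enhancer("unique_b"))
    for i, enh in enumerate(enhancers):
        enh["enhancer_id"] = f"ENH{i + 1:05d}"

    unique_b = [e for e in enhancers if e["category"] == "unique_b"]
    n_poised = int(round(config.frac_new_enhancers_poised * len(unique_b)))
    poised_pick = set(
        rng.choice(len(unique_b), size=n_poised, replace=False).tolist()
    ) if unique_b else set()
    for j, enh in enumerate(unique_b):
        enh["poised"] = j in poised_pick
    for enh in enhancers:
        enh.setdefault("poised", False)

    # ---- promoter chromatin states ----
    derep_list = [int(i) for i in derepressed_idx]
    derep_perm = rng.permutation(len(derep_list))
    n_gain = int(round(config.frac_derepressed_gain_h3k4me3 * len(derep_list)))
    gainers = {derep_list[j] for j in derep_perm[:n_gain]}
    non_gainers = [derep_list[j] for j in derep_perm[n_gain:]]
    n_incommon = int(round(config.frac_neither_in_common_h3k4me3 * len(non_gainers)))
    in_common = set(non_gainers[:n_incommon])

    h3k4me3_status = {
        gene_ids[gi]: ("gained_new" if gi in gainers
                       else "in_common" if gi in in_common else "neither")
        for gi in derep_list
    }

    expressed_idx = sorted(
        i for i in range(n) if classes[i] in ("up", "down", "unchanged")
    )

    def _promoter_peak(gi: int) -> GenomicInterval:
        gene = genes[gene_ids[gi]]
        half = config.promoter_peak_halfwidth
        return GenomicInterval(gene.chrom, max(0, gene.tss - half), gene.tss + half)

    h3k4me3_a = [_promoter_peak(gi) for gi in expressed_idx] + \
        [_promoter_peak(gi) for gi in sorted(in_common)]
    h3k4me3_b = h3k4me3_a + [_promoter_peak(gi) for gi in sorted(gainers)]
    k27_prox_a = [_promoter_peak(gi) for gi in expressed_idx]
    k27_prox_b = k27_prox_a + [_promoter_peak(gi) for gi in sorted(derep_list)]

    def _enh_ivs(cats: tuple[str, ...]) -> list[GenomicInterval]:
        return [
            GenomicInterval(e["chrom"], e["start"], e["end"])
            for e in enhancers if e["category"] in cats
        ]

    k27_a = k27_prox_a + _enh_ivs(("common", "unique_a"))
    k27_b = k27_prox_b + _enh_ivs(("common", "unique_b"))
    k4me1_par = [
        GenomicInterval(e["chrom"], max(0, e["start"] - 200), e["end"] + 200)
        for e in enhancers if e["poised"]
    ]
    for _ in range(config.n_extra_h3k4me1):
        k4me1_par.append(placer.place_intergenic(int(rng.integers(400, 801))))

    def _peak_files(mark: str, condition: str, intervals: list[GenomicInterval]):
        rep1 = PeakSet(mark, condition, "rep1", tuple(intervals))
        rep2 = _jitter_peaks(rep1, rng, config.peak_jitter, "rep2")
        noise1 = tuple(placer.place_intergenic(int(rng.integers(300, 601)))
                       for _ in range(config.n_replicate_noise_peaks))
        noise2 = tuple(placer.place_intergenic(int(rng.integers(300, 601)))
                       for _ in range(config.n_replicate_noise_peaks))
        rep1 = PeakSet(mark, condition, "rep1", rep1.intervals + noise1)
        rep2 = PeakSet(mark, condition, "rep2", rep2.intervals + noise2)
        return rep1, rep2

    peak_sets = {}
    for mark, cond, ivs in (
        ("H3K4me3", config.condition_a, h3k4me3_a),
        ("H3K4me3", config.condition_b, h3k4me3_b),
        ("H3K27ac", config.condition_a, k27_a),
        ("H3K27ac", config.condition_b, k27_b),
        ("RNAPII", config.condition_a, k27_prox_a),
        ("RNAPII", config.condition_b, k27_prox_b),
        ("H3K4me1", config.condition_a, k4me1_par),
    ):
        peak_sets[(mark, cond)] = _peak_files(mark, cond, ivs)

    # ---- CpG islands ----
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for g in genes.values():
        tss_by_chrom[g.chrom].append(g.tss)
    for c in tss_by_chrom:
        tss_by_chrom[c].sort()

    other_idx = np.array(
        [i for i in range(n) if classes[i] in ("unchanged", "not_expressed")]
    )
    cgi_flags = _pick_flags(rng, n, (
        (derepressed_idx, config.frac_cgi_derepressed),
        (up_idx, config.frac_cgi_up),
        (down_idx, config.frac_cgi_down),
        (other_idx, config.frac_cgi_other),
    ))

    cgi_intervals: list[GenomicInterval] = []
    cgi_is_promoter: list[bool] = []
    for gi in range(n):
        if not cgi_flags[gi]:
            continue
        gene = genes[gene_ids[gi]]
        length = int(np.clip(rng.normal(config.cgi_length_mean, config.cgi_length_sd),
                             400, 1600))
        # island mostly 5' of the TSS so gene-body CpG load stays realistic
        if gene.strand == "+":
            start = gene.tss - int(round(0.90 * length))
        else:
            start = gene.tss - int(round(0.10 * length)) + 1
        end = start + length
        # never cover another gene's TSS (planted labels must be exact)
        sites = tss_by_chrom[gene.chrom]
        i = bisect.bisect_left(sites, gene.tss)
        if i > 0:
            start = max(start, sites[i - 1] + 1)
        if i + 1 < len(sites):
            end = min(end, sites[i + 1])
        start = max(0, start)
        cgi_intervals.append(GenomicInterval(gene.chrom, start, end))
        cgi_is_promoter.append(True)
    for _ in range(config.n_nonpromoter_cgi):
        iv = placer.place_intergenic(
            int(np.clip(rng.normal(config.cgi_length_mean, config.cgi_length_sd),
                        400, 1600))
        )
        cgi_intervals.append(iv)
        cgi_is_promoter.append(False)

    # ---- methylation ----
    parental_table, derived_table, meth_truth = _build_methylation(
        config, rng, ann, gene_ids, enhancers, cgi_intervals,
        low_dist, high_dist, derepressed_idx, silent_idx,
    )

    # ---- expression ----
    expr_frame = _build_expression(config, rng, gene_ids, classes)

    # ---- promoter sequences (TATA) ----
    tata_flags = _pick_flags(rng, n, (
        (derepressed_idx, config.frac_tata_derepressed),
        (up_idx, config.frac_tata_up),
        (down_idx, config.frac_tata_down),
        (other_idx, config.frac_tata_other),
    ))
    sequences = _build_promoter_sequences(config, rng, gene_ids, tata_flags)

    # ---- tumor-suppressor list ----
    tsg_derep = [gene_ids[int(i)] for i in rng.choice(
        derepressed_idx, size=min(config.n_tsg_derepressed, len(derep_list)),
        replace=False)]
    tsg_up = [gene_ids[int(i)] for i in rng.choice(
        up_idx, size=min(config.n_tsg_up, len(up_idx)), replace=False)]
    tsg_extra = [f"TSGEXT{j + 1:03d}" for j in range(config.n_tsg_extra)]
    tsg_names = sorted(tsg_derep + tsg_up) + tsg_extra

    # ---- ground truth ----
    truth = {
        "classes": {gene_ids[i]: str(classes[i]) for i in range(n)},
        "class_counts": {
            c: int((classes == c).sum())
            for c in ("de_repressed", "up", "down", "unchanged", "not_expressed")
        },
        "enhancers": enhancers,
        "enhancer_counts": {
            c: sum(1 for e in enhancers if e["category"] == c)
            for c in ("common", "unique_a", "unique_b")
        },
        "poised_fraction": (
            sum(1 for e in unique_b if e["poised"]) / len(unique_b) if unique_b else 0.0
        ),
        "h3k4me3_status": h3k4me3_status,
        "intragenic_unique_b": {
            gene_ids[gi]: cnt for gi, cnt in sorted(host_counts.items())
        },
        "cgi_promoter": {gene_ids[i]: bool(cgi_flags[i]) for i in range(n)},
        "tata_promoter": {gene_ids[i]: bool(tata_flags[i]) for i in range(n)},
        "tsg": {"listed": tsg_names,
                "derepressed_members": sorted(tsg_derep),
                "up_members": sorted(tsg_up)},
        "promoter_state": meth_truth["promoter_state"],
        "calibration": meth_truth["calibration"],
    }

    # ---- write everything ----
    paths: dict[str, object] = {}
    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf([genes[gid] for gid in gene_ids], paths["annotation"])
    paths["methylation_a"] = outdir / f"methylation_{config.condition_a}.tsv"
    paths["methylation_b"] = outdir / f"methylation_{config.condition_b}.tsv"
    parental_table.write(paths["methylation_a"], config.methylation_dialect)
    derived_table.write(paths["methylation_b"], config.methylation_dialect)
    peak_paths: dict[str, dict[str, list[str]]] = {}
    for (mark, cond), (rep1, rep2) in sorted(peak_sets.items()):
        entry = peak_paths.setdefault(mark, {})
        files = []
        for rep in (rep1, rep2):
            p = outdir / "peaks" / f"{mark.lower()}_{cond}_{rep.replicate}.bed"
            rep.write_bed(p)
            files.append(str(p))
        entry[cond] = files
    paths["peaks"] = peak_paths
    paths["expression"] = outdir / "expression.tsv"
    expr_frame.to_csv(paths["expression"], sep="\t", index_label="gene_id",
                      float_format="%.6g")
    paths["cgi"] = outdir / "cgi.bed"
    with open(paths["cgi"], "w") as fh:
        for j, iv in enumerate(cgi_intervals):
            kind = "promoter" if cgi_is_promoter[j] else "orphan"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tCGI{j + 1:05d}_{kind}\n")
    paths["tsg"] = outdir / "tsg.tsv"
    with open(paths["tsg"], "w") as fh:
        for name in tsg_names:
            fh.write(name.lower() + "\n")  # exercises case-insensitive matching
    paths["promoter_fasta"] = outdir / "promoters.fasta"
    with open(paths["promoter_fasta"], "w") as fh:
        for gid in gene_ids:
            fh.write(f">{gid}\n{sequences[gid]}\n")
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])
    return Bundle(outdir, paths, truth, config)


def _pick_flags(rng, n: int, pools) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    for idx_pool, frac in pools:
        idx_pool = np.asarray(idx_pool)
        if len(idx_pool) == 0:
            continue
        n_pick = int(round(frac * len(idx_pool)))
        pick = rng.choice(len(idx_pool), size=n_pick, replace=False)
        flags[idx_pool[pick]] = True
    return flags


# ---------------------------------------------------------------------------
# methylation internals


def _build_methylation(config, rng, ann, gene_ids, enhancers, cgi_intervals,
                       low_dist, high_dist, derepressed_idx, silent_idx):
    n = len(gene_ids)
    chroms = sorted(ann.chrom_sizes)
    windows = ann.promoter_windows(config.promoter_upstream, config.promoter_downstream)
    gene_order = {gid: i for i, gid in enumerate(gene_ids)}

    # promoter levels: stratified per component; high mode carried by the
    # de-repressed + silent genes, low mode by the expressed ones
    high_set = {int(i) for i in derepressed_idx} | {int(i) for i in silent_idx}
    low_vals = _mid_quantiles(low_dist, n - len(high_set))
    high_vals = _mid_quantiles(high_dist, len(high_set))
    rng.shuffle(low_vals)
    rng.shuffle(high_vals)
    prom_level = np.empty(n)
    lo_i = hi_i = 0
    for gi in range(n):
        if gi in high_set:
            prom_level[gi] = high_vals[hi_i]; hi_i += 1
        else:
            prom_level[gi] = low_vals[lo_i]; lo_i += 1

    body_dist = beta_with_median(config.body_meth_median, config.body_concentration)

    # active (parental) enhancers are hypomethylated islands
    active_enh = [e for e in enhancers if e["category"] in ("common", "unique_a")]
    enh_dist = beta_with_median(config.active_enhancer_meth_median, 6.0)
    enh_levels = enh_dist.ppf(rng.random(len(active_enh)))

    rows = []  # per chrom: dict of arrays
    for chrom in chroms:
        L = ann.chrom_sizes[chrom]
        spans = sorted(
            (g.span.start, g.span.end, gene_order[g.gene_id])
            for g in ann.genes.values() if g.chrom == chrom
        )
        span_starts = np.array([s for s, _e, _i in spans], dtype=np.int64)
        span_ends = np.array([e for _s, e, _i in spans], dtype=np.int64)
        span_gene = np.array([i for _s, _e, i in spans], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(span_ends - span_starts)])
        genic_bp = int(cum[-1])

        # genic CpGs: uniform over the concatenated gene space
        n_genic = int(round(genic_bp * config.cpg_rate_genic))
        off = np.sort(rng.integers(0, genic_bp, n_genic))
        j = np.searchsorted(cum, off, side="right") - 1
        genic_pos = span_starts[j] + (off - cum[j])
        # intergenic CpGs: uniform over the whole chromosome, thinned to the
        # intergenic space
        n_inter_target = int(round((L - genic_bp) * config.cpg_rate_intergenic))
        cand = rng.integers(0, L, int(n_inter_target * 1.6) + 10)
        jc = np.searchsorted(span_starts, cand, side="right") - 1
        in_gene = (jc >= 0) & (cand < span_ends[np.clip(jc, 0, None)])
        inter_pos = cand[~in_gene][:n_inter_target]
        # CGI enrichment on top of the local baseline
        extra = []
        for iv in cgi_intervals:
            if iv.chrom != chrom:
                continue
            n_e = int(round(iv.length * (config.cpg_rate_cgi - config.cpg_rate_genic)))
            if n_e > 0:
                extra.append(iv.start + rng.integers(0, iv.length, n_e))
        # enhancers get a small extra CpG load so their region means are
        # measurable at desk scale
        for e in enhancers:
            if e["chrom"] != chrom:
                continue
            n_e = int(round((e["end"] - e["start"]) * config.cpg_rate_enhancer_extra))
            if n_e > 0:
                extra.append(e["start"] + rng.integers(0, e["end"] - e["start"], n_e))
        pos = np.unique(np.concatenate([genic_pos, inter_pos] + extra))
        pos = pos[(pos >= 0) & (pos < L)]

        j = np.searchsorted(span_starts, pos, side="right") - 1
        in_gene = (j >= 0) & (pos < span_ends[np.clip(j, 0, None)])
        gene_of = np.where(in_gene, span_gene[np.clip(j, 0, None)], -1)

        win_rows = sorted(
            (windows[gid].start, windows[gid].end, gene_order[gid])
            for gid in gene_ids if windows[gid].chrom == chrom
        )
        w_starts = np.array([s for s, _e, _i in win_rows], dtype=np.int64)
        w_ends = np.array([e for _s, e, _i in win_rows], dtype=np.int64)
        w_gene = np.array([i for _s, _e, i in win_rows], dtype=np.int64)
        jw = np.searchsorted(w_starts, pos, side="right") - 1
        in_win = (jw >= 0) & (pos < w_ends[np.clip(jw, 0, None)])
        win_of = np.where(in_win, w_gene[np.clip(jw, 0, None)], -1)

        # background: 5-kb blocks tile the chromosome
        n_blocks = L // 5000 + 1
        block_vals = _mid_quantiles(body_dist, n_blocks)
        rng.shuffle(block_vals)
        level = block_vals[pos // 5000].copy()

        comp = np.zeros(len(pos), dtype=np.int8)  # 0 bg, 1 body, 2 promoter
        comp[gene_of >= 0] = 1
        comp[win_of >= 0] = 2
        level[win_of >= 0] = prom_level[win_of[win_of >= 0]]

        # enhancer hypomethylation override (parental-active enhancers only)
        ovr = np.zeros(len(pos), dtype=bool)
        e_rows = sorted(
            (active_enh[k_e]["start"], active_enh[k_e]["end"], float(enh_levels[k_e]))
            for k_e in range(len(active_enh)) if active_enh[k_e]["chrom"] == chrom
        )
        if e_rows:
            es = np.array([r[0] for r in e_rows]); ee = np.array([r[1] for r in e_rows])
            ev = np.array([r[2] for r in e_rows])
            je = np.searchsorted(es, pos, side="right") - 1
            inside = (je >= 0) & (pos < ee[np.clip(je, 0, None)]) & (comp != 2)
            level[inside] = ev[np.clip(je, 0, None)][inside]
            ovr[inside] = True

        rows.append({"chrom": chrom, "pos": pos, "comp": comp,
                     "gene_of": gene_of, "win_of": win_of,
                     "level": level, "ovr": ovr})

    # gene-body compensation: free body CpGs get the level that makes the
    # CpG-weighted span mean hit the per-gene body target, given the promoter
    # dip and any enhancer island already fixed inside the span
    fixed_sum = np.zeros(n); fixed_cnt = np.zeros(n); free_cnt = np.zeros(n)
    for r in rows:
        g = r["gene_of"]; sel = g >= 0
        fixed = sel & ((r["comp"] == 2) | r["ovr"])
        free = sel & ~fixed
        np.add.at(fixed_sum, g[fixed], r["level"][fixed])
        np.add.at(fixed_cnt, g[fixed], 1)
        np.add.at(free_cnt, g[free], 1)
    total = fixed_cnt + free_cnt
    # assortative target assignment: each gene's achievable span mean is
    # bounded above by its fixed (promoter/enhancer) CpG load, so the sorted
    # stratified targets are matched to the sorted per-gene ceilings --
    # without this, short genes with unmethylated promoters cannot reach
    # high body targets and clipping would bias the median downward
    with np.errstate(invalid="ignore", divide="ignore"):
        cap = np.where(total > 0, (fixed_sum + free_cnt) / np.maximum(total, 1), 1.0)
    body_target = np.empty(n)
    body_target[np.argsort(cap, kind="stable")] = _mid_quantiles(body_dist, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        l_g = (body_target * total - fixed_sum) / np.maximum(free_cnt, 1)
    l_g = np.clip(np.nan_to_num(l_g, nan=config.body_meth_median), 0.0, 1.0)
    for r in rows:
        g = r["gene_of"]
        sel = (g >= 0) & (r["comp"] == 1) & ~r["ovr"]
        r["level"][sel] = l_g[g[sel]]

    # parental per-CpG values
    for r in rows:
        r["meth"] = np.clip(
            r["level"] + rng.normal(0, config.cpg_noise_sd, len(r["pos"])), 0, 1
        )

    # ---- calibrate derived-condition compartment factors ----
    prom_sum = np.zeros(n); prom_cnt = np.zeros(n)
    body_sum_free = np.zeros(n); body_cnt_free = np.zeros(n)
    prom_in_span_sum = np.zeros(n); prom_in_span_cnt = np.zeros(n)
    for r in rows:
        w = r["win_of"]; selw = w >= 0
        np.add.at(prom_sum, w[selw], r["meth"][selw])
        np.add.at(prom_cnt, w[selw], 1)
        g = r["gene_of"]
        selg = (g >= 0) & (r["comp"] == 1)
        np.add.at(body_sum_free, g[selg], r["meth"][selg])
        np.add.at(body_cnt_free, g[selg], 1)
        selp = (g >= 0) & (r["comp"] == 2)
        np.add.at(prom_in_span_sum, g[selp], r["meth"][selp])
        np.add.at(prom_in_span_cnt, g[selp], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        prom_means = np.where(prom_cnt > 0, prom_sum / np.maximum(prom_cnt, 1), np.nan)
    parental_prom_median = float(np.nanmedian(prom_means))
    f_p = min(1.0, config.derived_promoter_target / max(parental_prom_median, 1e-9))

    span_total = body_cnt_free + prom_in_span_cnt

    def body_median(f_b):
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (prom_in_span_sum * f_p + body_sum_free * f_b) \
                / np.maximum(span_total, 1)
        return float(np.nanmedian(np.where(span_total > 0, vals, np.nan)))

    f_b = _solve_factor(body_median, config.derived_body_target)

    # background factor: solved over an internal random-region sample because
    # random windows mix genic and intergenic CpGs
    calib_regions = sample_random_regions(
        ann.chrom_sizes, 1000, 10_000,
        seed=np.random.default_rng([config.seed, 104729]),
    )
    reg: dict[str, list] = {c: [] for c in chroms}
    for i, region in enumerate(calib_regions):
        reg[region.chrom].append((region.start, region.end, i))
    m = len(calib_regions)
    s_prom = np.zeros(m); s_body = np.zeros(m); s_bg = np.zeros(m)
    n_tot = np.zeros(m)
    for r in rows:
        pos, comp, meth = r["pos"], r["comp"], r["meth"]
        for start, end, i in reg[r["chrom"]]:
            lo = int(np.searchsorted(pos, start)); hi = int(np.searchsorted(pos, end))
            if hi <= lo:
                continue
            c = comp[lo:hi]; v = meth[lo:hi]
            s_prom[i] += v[c == 2].sum()
            s_body[i] += v[c == 1].sum()
            s_bg[i] += v[c == 0].sum()
            n_tot[i] += hi - lo

    def bg_median(f_bg):
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (s_prom * f_p + s_body * f_b + s_bg * f_bg) / np.maximum(n_tot, 1)
        return float(np.nanmedian(np.where(n_tot > 0, vals, np.nan)))

    f_bg = _solve_factor(bg_median, config.derived_background_target)

    factors = np.array([f_bg, f_b, f_p])  # indexed by compartment code
    frames_a, frames_b = [], []
    for r in rows:
        npos = len(r["pos"])
        derived = np.clip(
            r["meth"] * factors[r["comp"]] + rng.normal(0, config.derived_noise_sd, npos),
            0, 1,
        )
        frames_a.append(pd.DataFrame(
            {"chrom": r["chrom"], "pos": r["pos"], "meth": r["meth"],
             "cov": rng.poisson(config.coverage_mean, npos)}))
        frames_b.append(pd.DataFrame(
            {"chrom": r["chrom"], "pos": r["pos"], "meth": derived,
             "cov": rng.poisson(config.coverage_mean, npos)}))

    parental_table = MethylationTable(
        config.condition_a, pd.concat(frames_a, ignore_index=True))
    derived_table = MethylationTable(
        config.condition_b, pd.concat(frames_b, ignore_index=True))
    truth = {
        "promoter_state": {
            gene_ids[i]: ("high" if i in high_set else "low") for i in range(n)
        },
        "calibration": {
            "mixture_high_weight": len(high_set) / n,
            "derived_factor_promoter": float(f_p),
            "derived_factor_body": float(f_b),
            "derived_factor_background": float(f_bg),
            "parental_promoter_median": parental_prom_median,
        },
    }
    return parental_table, derived_table, truth


def _solve_factor(median_fn, target: float) -> float:
    lo_v, hi_v = median_fn(0.0), median_fn(1.0)
    if target <= lo_v:
        return 0.0
    if target >= hi_v:
        return 1.0
    return float(optimize.brentq(lambda f: median_fn(f) - target, 0.0, 1.0,
                                 xtol=1e-6))


# ---------------------------------------------------------------------------
# expression and sequences


def _build_expression(config, rng, gene_ids, classes) -> pd.DataFrame:
    n = len(gene_ids)
    log_a = np.zeros(n)
    log_b = np.zeros(n)
    for i in range(n):
        c = classes[i]
        if c == "de_repressed":
            log_a[i] = rng.uniform(0.3, 1.35)
            log_b[i] = rng.uniform(2.7, 5.5)
        elif c == "up":
            log_a[i] = rng.uniform(2.0, 7.0)
            log_b[i] = log_a[i] + rng.uniform(0.7, 2.0)
        elif c == "down":
            log_a[i] = rng.uniform(2.7, 7.7)
            log_b[i] = log_a[i] - rng.uniform(0.7, 2.0)
        elif c == "unchanged":
            log_a[i] = rng.uniform(2.0, 7.0)
            log_b[i] = log_a[i] + rng.uniform(-0.08, 0.08)
        # not_expressed stays at 0 in both conditions
    data = {}
    for cond, base in ((config.condition_a, log_a), (config.condition_b, log_b)):
        for r in range(config.n_expression_replicates):
            noisy = base + rng.normal(0, config.replicate_noise_sd, n)
            data[f"{cond}_rep{r + 1}"] = np.where(
                base > 0, np.maximum(2.0 ** noisy - 1.0, 0.0), 0.0
            )
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


_BASES = np.array(list("ACGT"))


def _build_promoter_sequences(config, rng, gene_ids, tata_flags) -> dict[str, str]:
    from .integrate import tata_scan

    motif = config.tata_motif
    L = config.promoter_seq_length
    seqs: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        for _attempt in range(500):
            seq = "".join(_BASES[rng.integers(0, 4, L)])
            if tata_flags[i]:
                inst = [
                    (b if b != "W" else ("A" if rng.random() < 0.5 else "T"))
                    for b in motif
                ]
                if rng.random() < 0.5:  # half the planted boxes carry 1 mismatch
                    j = int(rng.integers(len(inst)))
                    allowed = {"A", "T"} if motif[j] == "W" else {motif[j]}
                    choices = [b for b in "ACGT" if b not in allowed]
                    inst[j] = choices[int(rng.integers(len(choices)))]
                offset = int(rng.integers(-40, -19))  # motif start in [-40, -20]
                start = (L - 1) + offset
                seq = seq[:start] + "".join(inst) + seq[start + len(inst):]
            found, _off, _mm = tata_scan(seq, motif, 1)
            if found == bool(tata_flags[i]):
                seqs[gid] = seq
                break
        else:
            raise GeneratorError(f"could not synthesize promoter sequence for {gid}")
    return seqs
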