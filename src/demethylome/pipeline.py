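"""End-to-end analysis: from input files to a manifest of headline numbers.

``run_full_analysis`` reproduces the package's full comparison of a parental
and a demethylated epigenome: compartment methylation medians, promoter
chromatin state of de-repressed genes, the enhancer landscape (Venn,
compartments, parental methylation, poised fraction), enhancer-gene
distances, intragenic enhancer counts and promoter sequence features.
Deterministic given inputs and seed; every stage error is re-raised with the
stage name.
"""

from __future__ import annotations

import contextlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrate
from .config import RunConfig
from .expression import (
    ExpressionTable,
    annotate_tsg,
    build_gene_class_table,
    read_tsg_list,
)
from .intervals import GenomicInterval, ParseError, read_annotation, read_chrom_sizes
from .methylome import (
    MethylationTable,
    aggregate_region_methylation,
    classify_promoter_methylation,
    compartment_medians,
    methylation_profile,
    sample_random_regions,
)
from .peaks import (
    PeakSet,
    annotate_comparison_compartments,
    compare_enhancers,
    compare_peak_intervals,
    consensus_peaks,
    define_enhancers,
    enhancer_parental_methylation,
    poised_fraction,
    split_by_tss_proximity,
)


class StageError(RuntimeError):
    pass


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {name!r} failed: {err}") from err


def _round(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "unreachable"
        return round(x, nd)
    return x


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every analysis stage and return the manifest (also written to
    ``<outdir>/manifest.json`` along with the per-stage tables)."""
    config.validate()
    config.check_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed}

    with _stage("load_inputs"):
        sizes = read_chrom_sizes(config.chrom_sizes)
        ann = read_annotation(config.annotation, sizes)
        meth_a = MethylationTable.read(config.methylation_a, config.condition_a,
                                       config.methylation_dialect)
        meth_b = MethylationTable.read(config.methylation_b, config.condition_b,
                                       config.methylation_dialect)
        expr = ExpressionTable.read(config.expression, config.condition_a,
                                    config.condition_b)
        reps = {}
        for mark, conds in config.peaks.items():
            for cond, files in conds.items():
                reps[(mark, cond)] = [
                    PeakSet.read_bed(f, mark, cond, f"rep{i + 1}")
                    for i, f in enumerate(files)
                ]

    with _stage("compartment_medians"):
        regions = sample_random_regions(
            sizes, config.n_random_regions, config.random_region_length,
            seed=config.seed,
        )
        med = compartment_medians(
            meth_a, meth_b, ann, regions, config.min_coverage,
            config.promoter_upstream, config.promoter_downstream,
        )
        manifest["methylation_medians_percent"] = {
            cond: {k: _round(100 * v, 4) for k, v in comp.items()}
            for cond, comp in med.items()
        }
        pa, pb = med[config.condition_a], med[config.condition_b]
        manifest["methylation_reduction_percent"] = {
            k: _round(100 * (1 - pb[k] / pa[k]), 4) for k in pa
        }

    with _stage("promoter_methylation_state"):
        windows = list(
            ann.promoter_windows(config.promoter_upstream,
                                 config.promoter_downstream).values()
        )
        counts = {}
        prom_tables = {}
        for table in (meth_a, meth_b):
            agg = aggregate_region_methylation(table, windows, config.min_coverage)
            labels = [
                classify_promoter_methylation(v, config.high_meth_threshold)
                for v in agg["mean_meth"]
            ]
            prom_tables[table.condition] = agg
            counts[table.condition] = {
                s: labels.count(s) for s in ("high", "low", "missing")
            }
        manifest["promoter_methylation_counts"] = counts

    with _stage("expression_classes"):
        class_table = build_gene_class_table(
            expr, low_cut=config.low_expression_cut,
            high_cut=config.high_expression_cut,
            p_cut=config.p_cut, fc_cut=config.fc_cut,
        )
        class_table.to_csv(outdir / "gene_classes.tsv", sep="\t",
                           float_format="%.6g")
        manifest["gene_class_counts"] = {
            c: int((class_table["class"] == c).sum())
            for c in ("de_repressed", "up", "down", "unchanged", "not_expressed")
        }
        derepressed = sorted(class_table.index[class_table["class"] == "de_repressed"])
        up_genes = sorted(class_table.index[class_table["class"] == "up"])
        down_genes = sorted(class_table.index[class_table["class"] == "down"])

    with _stage("tumor_suppressors"):
        if config.tsg:
            tsg = read_tsg_list(config.tsg)
            manifest["tsg_overlap"] = {
                "de_repressed": len(annotate_tsg(derepressed, tsg)),
                "up": len(annotate_tsg(up_genes, tsg)),
            }

    with _stage("promoter_h3k4me3"):
        if ("H3K4me3", config.condition_a) in reps:
            cons_a = consensus_peaks(*reps[("H3K4me3", config.condition_a)])
            cons_b = consensus_peaks(*reps[("H3K4me3", config.condition_b)])
            prox_a, _ = split_by_tss_proximity(cons_a, ann, config.proximal_window)
            prox_b, _ = split_by_tss_proximity(cons_b, ann, config.proximal_window)
            ca, ua, ub, _m, cb = compare_peak_intervals(
                prox_a.intervals, prox_b.intervals
            )
            common_peaks = prox_a.subset(ca)
            new_peaks = prox_b.subset(ub)
            manifest["promoter_h3k4me3"] = {
                "proximal_a": len(prox_a), "proximal_b": len(prox_b),
                "common_a": len(ca), "common_b": cb,
                "unique_a": len(ua), "unique_b": len(ub),
            }
            part = integrate.derepressed_h3k4me3_overlap(
                derepressed, new_peaks, common_peaks, ann, config.proximal_window
            )
            manifest["derepressed_h3k4me3"] = {k: len(v) for k, v in part.items()}
            alt_table, alt = integrate.alternative_promoter_scan(
                part["neither"], new_peaks, ann, config.near
            )
            alt_table.to_csv(outdir / "alternative_promoter_distances.tsv", sep="\t")
            manifest["alternative_promoter"] = {
                "n_candidates": len(part["neither"]),
                "n_within_near": int(alt["n_within"]),
                "median_distance": _round(alt["median_distance"], 1),
            }

    with _stage("enhancers"):
        comparison = None
        if ("H3K27ac", config.condition_a) in reps:
            econs_a = consensus_peaks(*reps[("H3K27ac", config.condition_a)])
            econs_b = consensus_peaks(*reps[("H3K27ac", config.condition_b)])
            enh_a = define_enhancers(econs_a, ann, config.proximal_window)
            enh_b = define_enhancers(econs_b, ann, config.proximal_window)
            comparison = compare_enhancers(enh_a, enh_b)
            annotate_comparison_compartments(comparison, ann)
            manifest["enhancer_venn"] = comparison.counts()
            manifest["enhancer_compartments"] = {
                cat: {
                    lab: comparison.compartments[cat].count(lab)
                    for lab in ("intergenic", "intronic", "exonic")
                }
                for cat in comparison.compartments
            }
            emeth = enhancer_parental_methylation(comparison, meth_a,
                                                  config.min_coverage)
            emeth.to_csv(outdir / "enhancer_comparison.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest["enhancer_parental_meth_median_percent"] = {
                cat: _round(100 * float(np.nanmedian(vals)), 4) if len(vals) else None
                for cat, vals in (
                    (c, np.array(comparison.parental_meth[c], dtype=float))
                    for c in comparison.parental_meth
                )
            }
            if ("H3K4me1", config.condition_a) in reps and comparison.unique_b:
                k4me1 = consensus_peaks(*reps[("H3K4me1", config.condition_a)])
                manifest["poised_fraction"] = _round(
                    poised_fraction(comparison.unique_b, k4me1), 6
                )

    with _stage("enhancer_gene_distances"):
        if comparison is not None:
            dist_summaries = {}
            for name, gene_set in (("up", up_genes), ("down", down_genes)):
                table, summary = integrate.gene_enhancer_distances(
                    gene_set, comparison, ann, config.near
                )
                table.to_csv(outdir / f"enhancer_distances_{name}.tsv", sep="\t")
                dist_summaries[name] = {
                    cat: {"frac_within": _round(s["frac_within"], 6),
                          "median_distance": _round(s["median_distance"], 1)}
                    for cat, s in summary.items()
                }
            manifest["enhancer_distances"] = dist_summaries

    with _stage("intragenic_enhancers"):
        if comparison is not None:
            intra_summaries = {}
            for name, gene_set in (("up", up_genes), ("down", down_genes)):
                counts = integrate.count_intragenic_enhancers(gene_set, comparison, ann)
                counts.to_csv(outdir / f"intragenic_enhancers_{name}.tsv", sep="\t")
                intra_summaries[name] = {
                    "genes_with_unique_b": int((counts["unique_b_total"] > 0).sum()),
                    "genes_with_unique_a": int((counts["unique_a_total"] > 0).sum()),
                    "genes_spreading": int(counts["spreading"].sum()),
                    "unique_b_total": int(counts["unique_b_total"].sum()),
                    "unique_b_intronic": int(counts["unique_b_intronic"].sum()),
                    "unique_b_exonic": int(counts["unique_b_exonic"].sum()),
                    "histogram_unique_b": {
                        str(k): v for k, v in integrate.intragenic_histogram(
                            counts["unique_b_total"]).items()
                    },
                }
            manifest["intragenic_enhancers"] = intra_summaries

    with _stage("promoter_features"):
        if config.cgi:
            cgi = _read_bed_intervals(config.cgi)
            feat = {}
            for name, gene_set in (("de_repressed", derepressed), ("up", up_genes),
                                   ("down", down_genes)):
                if not gene_set:
                    feat[name] = {"frac_cgi": None, "mean_cgi_length": None}
                    continue
                table, mean_len = integrate.promoter_cgi_classification(
                    gene_set, cgi, ann
                )
                feat[name] = {
                    "frac_cgi": _round(float(table["cgi_promoter"].mean()), 6),
                    "mean_cgi_length": _round(mean_len, 1),
                }
            manifest["cgi_promoters"] = feat
        if config.promoter_fasta:
            seqs = _read_fasta(config.promoter_fasta)
            feat = {}
            for name, gene_set in (("de_repressed", derepressed), ("up", up_genes),
                                   ("down", down_genes)):
                hits = [
                    integrate.tata_scan(seqs[g], config.tata_motif,
                                        config.tata_max_mismatch)[0]
                    for g in gene_set if g in seqs
                ]
                feat[name] = _round(float(np.mean(hits)), 6) if hits else None
            manifest["tata_promoters"] = feat

    with _stage("methylation_profiles"):
        anchors = [
            (ann.genes[g].chrom, ann.genes[g].tss, ann.genes[g].strand)
            for g in derepressed
        ]
        if anchors:
            prof_a = methylation_profile(meth_a, anchors, config.profile_flank,
                                         config.profile_bin)
            prof_b = methylation_profile(meth_b, anchors, config.profile_flank,
                                         config.profile_bin)
            prof = prof_a.rename(columns={"mean_meth": "mean_meth_a",
                                          "n_pairs": "n_pairs_a"})
            prof["mean_meth_b"] = prof_b["mean_meth"]
            prof["n_pairs_b"] = prof_b["n_pairs"]
            prof.to_csv(outdir / "derepressed_tss_profile.tsv", sep="\t",
                        index=False, float_format="%.6g")

    with _stage("write_manifest"):
        med_tbl = pd.DataFrame(
            [
                (cond, comp, v)
                for cond, comps in manifest["methylation_medians_percent"].items()
                for comp, v in comps.items()
            ],
            columns=["condition", "compartment", "median_percent"],
        )
        med_tbl.to_csv(outdir / "compartment_medians.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest


def _read_bed_intervals(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "expected >= 3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as err:
                raise ParseError(path, lineno, str(err))
    return out


def validate_bundle(config: RunConfig) -> dict[str, str]:
    """Run every format validator without analysing; returns per-input status
    ('ok' or the error message)."""
    report: dict[str, str] = {}

    def _try(key, fn):
        try:
            fn()
            report[key] = "ok"
        except Exception as err:  # report, do not abort
            report[key] = f"error: {err}"

    _try("chrom_sizes", lambda: read_chrom_sizes(config.chrom_sizes))
    sizes = None
    try:
        sizes = read_chrom_sizes(config.chrom_sizes)
    except Exception:
        pass
    if sizes is not None:
        _try("annotation", lambda: read_annotation(config.annotation, sizes))
    _try("methylation_a", lambda: MethylationTable.read(
        config.methylation_a, config.condition_a, config.methylation_dialect))
    _try("methylation_b", lambda: MethylationTable.read(
        config.methylation_b, config.condition_b, config.methylation_dialect))
    _try("expression", lambda: ExpressionTable.read(
        config.expression, config.condition_a, config.condition_b))
    for mark, conds in config.peaks.items():
        for cond, files in conds.items():
            for i, f in enumerate(files):
                _try(f"peaks.{mark}.{cond}.rep{i + 1}",
                     lambda f=f, mark=mark, cond=cond, i=i: PeakSet.read_bed(
                         f, mark, cond, f"rep{i + 1}"))
    if config.cgi:
        _try("cgi", lambda: _read_bed_intervals(config.cgi))
    if config.tsg:
        _try("tsg", lambda: read_tsg_list(config.tsg))
    if config.promoter_fasta:
        _try("promoter_fasta", lambda: _read_fasta(config.promoter_fasta))
    return report
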