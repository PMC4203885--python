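#!/usr/bin/env python
"""The differential enhancer landscape and its relation to up-regulated genes.

Defines enhancers as replicate-consensus H3K27ac peaks more than 2 kb from
every TSS, compares the two conditions (common / condition-unique),
annotates genomic compartments, measures parental methylation of each
enhancer class, the fraction of new enhancers pre-marked by parental
H3K4me1 (poised), TSS-to-nearest-enhancer distances for up- and
down-regulated genes, and intragenic new-enhancer counts ("spreading").
Writes the per-figure tables under results/tables/.
"""

import argparse
from pathlib import Path

import numpy as np

from demethylome.expression import ExpressionTable, build_gene_class_table
from demethylome.integrate import count_intragenic_enhancers, gene_enhancer_distances
from demethylome.intervals import read_annotation, read_chrom_sizes
from demethylome.methylome import MethylationTable
from demethylome.peaks import (
    PeakSet,
    annotate_comparison_compartments,
    compare_enhancers,
    consensus_peaks,
    define_enhancers,
    enhancer_parental_methylation,
    poised_fraction,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sizes = read_chrom_sizes(args.bundle / "chrom_sizes.tsv")
    ann = read_annotation(args.bundle / "annotation.gtf", sizes)

    enh = {}
    for cond in ("parental", "demethylated"):
        reps = [PeakSet.read_bed(args.bundle / "peaks" / f"h3k27ac_{cond}_rep{r}.bed",
                                 "H3K27ac", cond, f"rep{r}") for r in (1, 2)]
        enh[cond] = define_enhancers(consensus_peaks(*reps), ann, 2000)
    cmp = compare_enhancers(enh["parental"], enh["demethylated"])
    annotate_comparison_compartments(cmp, ann)
    c = cmp.counts()
    print(f"enhancers (distal H3K27ac): parental {c['total_a']}, "
          f"demethylated {c['total_b']}; common {c['common_a']}, "
          f"parental-unique {c['unique_a']}, new in demethylated {c['unique_b']}")
    for cat in ("common", "unique_a", "unique_b"):
        labs = cmp.compartments[cat]
        print(f"  {cat}: " + ", ".join(
            f"{labs.count(k)} {k}" for k in ("intergenic", "intronic", "exonic")))

    parental = MethylationTable.read(args.bundle / "methylation_parental.tsv",
                                     "parental", "percent")
    emeth = enhancer_parental_methylation(cmp, parental)
    emeth.to_csv(args.outdir / "enhancer_comparison.tsv", sep="\t", index=False,
                 float_format="%.6g")
    for cat in ("common", "unique_a", "unique_b"):
        med = np.nanmedian(np.array(cmp.parental_meth[cat], dtype=float))
        print(f"  parental methylation median, {cat}: {100 * med:.1f}%")

    k4me1 = consensus_peaks(*[
        PeakSet.read_bed(args.bundle / "peaks" / f"h3k4me1_parental_rep{r}.bed",
                         "H3K4me1", "parental", f"rep{r}") for r in (1, 2)])
    frac = poised_fraction(cmp.unique_b, k4me1)
    print(f"poised: {frac * 100:.0f}% of the {len(cmp.unique_b)} new enhancers "
          f"carried parental H3K4me1")

    expr = ExpressionTable.read(args.bundle / "expression.tsv",
                                "parental", "demethylated")
    classes = build_gene_class_table(expr)
    for name in ("up", "down"):
        genes = sorted(classes.index[classes["class"] == name])
        table, summary = gene_enhancer_distances(genes, cmp, ann, 20_000)
        table.to_csv(args.outdir / f"enhancer_distances_{name}.tsv", sep="\t")
        s_new, s_lost = summary["unique_b"], summary["unique_a"]
        print(f"{name}-regulated genes ({len(genes)}): "
              f"{100 * s_new['frac_within']:.0f}% within 20 kb of a new "
              f"enhancer (median {s_new['median_distance'] / 1000:.0f} kb), "
              f"{100 * s_lost['frac_within']:.0f}% within 20 kb of a lost one "
              f"(median {s_lost['median_distance'] / 1000:.0f} kb)")
        counts = count_intragenic_enhancers(genes, cmp, ann)
        counts.to_csv(args.outdir / f"intragenic_enhancers_{name}.tsv", sep="\t")
        with_new = int((counts["unique_b_total"] > 0).sum())
        spreading = int(counts["spreading"].sum())
        intronic = int(counts["unique_b_intronic"].sum())
        exonic = int(counts["unique_b_exonic"].sum())
        print(f"  intragenic new enhancers: {with_new} genes host "
              f"{intronic + exonic} ({intronic} intronic, {exonic} exonic); "
              f"{spreading} genes host more than one (spreading)")


if __name__ == "__main__":
    main()
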