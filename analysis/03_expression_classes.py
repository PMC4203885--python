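#!/usr/bin/env python
"""Classify genes by their expression response to demethylation.

Applies the de-repression rule (log2 parental < 1.5 and log2 demethylated
> 2.5 on mean log2(normalized+1)) and the differential rule (P < 0.05, fold
change > 1.2) to the replicate expression table, then characterizes each
class: tumor-suppressor overlap, CpG-island promoters (with mean island
length) and TATA-box promoters. Writes results/tables/gene_classes.tsv and
promoter_features.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from demethylome.expression import (
    ExpressionTable,
    annotate_tsg,
    build_gene_class_table,
    read_tsg_list,
)
from demethylome.integrate import promoter_cgi_classification, tata_scan
from demethylome.intervals import read_annotation, read_chrom_sizes
from demethylome.pipeline import _read_bed_intervals, _read_fasta


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    expr = ExpressionTable.read(args.bundle / "expression.tsv",
                                "parental", "demethylated")
    classes = build_gene_class_table(expr)
    classes.to_csv(args.outdir / "gene_classes.tsv", sep="\t", float_format="%.6g")

    counts = classes["class"].value_counts().to_dict()
    print("gene classes:", {k: counts.get(k, 0) for k in
                            ("de_repressed", "up", "down", "unchanged",
                             "not_expressed")})

    by_class = {
        name: sorted(classes.index[classes["class"] == name])
        for name in ("de_repressed", "up", "down")
    }

    tsg = read_tsg_list(args.bundle / "tsg.tsv")
    for name, genes in by_class.items():
        hits = annotate_tsg(genes, tsg)
        print(f"  {name}: {len(genes)} genes, {len(hits)} in the "
              f"tumor-suppressor list")

    sizes = read_chrom_sizes(args.bundle / "chrom_sizes.tsv")
    ann = read_annotation(args.bundle / "annotation.gtf", sizes)
    cgi = _read_bed_intervals(args.bundle / "cgi.bed")
    seqs = _read_fasta(args.bundle / "promoters.fasta")

    rows = []
    for name, genes in by_class.items():
        table, mean_len = promoter_cgi_classification(genes, cgi, ann)
        frac_cgi = table["cgi_promoter"].mean()
        frac_tata = pd.Series(
            [tata_scan(seqs[g])[0] for g in genes if g in seqs]).mean()
        rows.append((name, len(genes), round(100 * frac_cgi, 1),
                     round(mean_len, 0), round(100 * frac_tata, 1)))
        print(f"  {name}: {100 * frac_cgi:.0f}% CGI promoters "
              f"(mean island {mean_len:.0f} bp), {100 * frac_tata:.0f}% with a "
              f"TATA box in -40..-20")
    pd.DataFrame(rows, columns=["class", "n_genes", "pct_cgi_promoters",
                                "mean_cgi_length_bp", "pct_tata_promoters"]) \
        .to_csv(args.outdir / "promoter_features.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir / 'gene_classes.tsv'} and promoter_features.tsv")


if __name__ == "__main__":
    main()
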