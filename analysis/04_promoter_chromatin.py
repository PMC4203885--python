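#!/usr/bin/env python
"""Promoter chromatin state of de-repressed genes.

Builds replicate-consensus promoter-proximal H3K4me3 peak sets for both
conditions, partitions de-repressed genes into those that gained a new
promoter peak / were already in a common peak / neither, and scans the
"neither" group for the nearest newly acquired H3K4me3 site (a candidate
alternative promoter). Writes results/tables/derepressed_h3k4me3.tsv and
alternative_promoter_distances.tsv.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from demethylome.expression import ExpressionTable, build_gene_class_table
from demethylome.integrate import (
    alternative_promoter_scan,
    derepressed_h3k4me3_overlap,
)
from demethylome.intervals import read_annotation, read_chrom_sizes
from demethylome.peaks import (
    PeakSet,
    compare_peak_intervals,
    consensus_peaks,
    split_by_tss_proximity,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sizes = read_chrom_sizes(args.bundle / "chrom_sizes.tsv")
    ann = read_annotation(args.bundle / "annotation.gtf", sizes)
    expr = ExpressionTable.read(args.bundle / "expression.tsv",
                                "parental", "demethylated")
    classes = build_gene_class_table(expr)
    derepressed = sorted(classes.index[classes["class"] == "de_repressed"])

    cons = {}
    for cond in ("parental", "demethylated"):
        reps = [PeakSet.read_bed(args.bundle / "peaks" / f"h3k4me3_{cond}_rep{r}.bed",
                                 "H3K4me3", cond, f"rep{r}") for r in (1, 2)]
        cons[cond], _ = split_by_tss_proximity(consensus_peaks(*reps), ann, 2000)
    ca, ua, ub, _m, cb = compare_peak_intervals(
        cons["parental"].intervals, cons["demethylated"].intervals)
    print(f"promoter-proximal H3K4me3 consensus peaks: "
          f"parental {len(cons['parental'])}, demethylated "
          f"{len(cons['demethylated'])} ({len(ub)} newly acquired)")

    common = cons["parental"].subset(ca)
    new = cons["demethylated"].subset(ub)
    part = derepressed_h3k4me3_overlap(derepressed, new, common, ann, 2000)
    print(f"of {len(derepressed)} de-repressed genes: "
          f"{len(part['gained_new'])} gained a new promoter H3K4me3 peak, "
          f"{len(part['in_common'])} already sat in a common peak, "
          f"{len(part['neither'])} had neither")

    rows = [(g, status) for status, genes in part.items() for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "h3k4me3_status"]) \
        .to_csv(args.outdir / "derepressed_h3k4me3.tsv", sep="\t", index=False)

    table, summary = alternative_promoter_scan(part["neither"], new, ann, 20_000)
    table.to_csv(args.outdir / "alternative_promoter_distances.tsv", sep="\t")
    med = summary["median_distance"]
    med_txt = "undefined" if math.isnan(med) else f"{med / 1000:.0f} kb"
    print(f"alternative-promoter scan over the {len(part['neither'])} "
          f"'neither' genes: {summary['n_within']:.0f} have a new H3K4me3 "
          f"site within 20 kb; median distance {med_txt}")


if __name__ == "__main__":
    main()
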