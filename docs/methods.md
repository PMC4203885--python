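# Methods

## The analytic model

The package compares two conditions of the same genome — a *parental*
epigenome and a *demethylated* derivative — across four data modalities and
a fixed set of decision rules:

**Methylation.** Input is one call per CpG: a methylated fraction in [0, 1]
and a read coverage. Only CpGs with coverage ≥ `min_coverage` (default 3)
enter any aggregate. A region's methylation is the *unweighted* mean of its
qualifying CpG fractions; a coverage-weighted mean is available behind a
flag but is not the default, because the ratio-averaging convention treats
every CpG as one observation regardless of depth. Regions with no
qualifying CpG are missing and are excluded (never imputed) from medians.
Promoters are strand-oriented windows of `upstream + downstream + 1` bp
around the TSS (default −100..+700, an 801-bp window including the TSS
base; the inclusive convention is a package decision, configurable).
A promoter is *highly methylated* when its mean strictly exceeds 50%.
TSS-anchored profiles average all (anchor, CpG) pairs into 100-bp bins over
±2,500 bp, orienting offsets by the anchor strand.

**Chromatin.** Peaks arrive already called, two replicates per
mark/condition. Consensus keeps every replicate-1 peak that overlaps ≥ 1 bp
of a replicate-2 peak, retaining replicate-1 coordinates (simplest rule that
preserves peak identity; an intersection mode exists). Peaks are
promoter-proximal when they overlap ±2 kb of any TSS (both boundary bases
included), distal otherwise; *enhancers are distal H3K27ac consensus
peaks*. Two enhancer sets are compared by ≥ 1 bp overlap: an A-enhancer is
common iff it overlaps a B-enhancer, symmetrically for B. Because overlap
can be many-to-one the two sides' common counts may differ; both are
reported, with A's coordinates carrying the common set. Genomic compartment
(intergenic / intronic / exonic) is assigned by peak *midpoint* with
exon > intron precedence, which gives every peak exactly one label.

**Expression.** Normalized linear values per replicate per condition.
Per-condition summary is the mean of log₂(x + 1) across replicates (the
pseudocount is a package decision, configurable). *De-repressed*: log₂
parental < 1.5 AND log₂ demethylated > 2.5, strict on both sides.
Remaining genes are *up*/*down* when P < 0.05 and the linear
fold change (ratio of per-condition means of linear values) exceeds 1.2 in
the corresponding direction; genes with zero mean expression in both
conditions are *not expressed*; everything else is *unchanged*.
Precedence: not-expressed → de-repressed → differential. Without external
p-values a two-sided Welch t-test on log₂(x + 1) replicate values is used —
an explicit stand-in for a dedicated differential-expression model, and the
reason callers reproducing published gene lists should pass their own
p-values. Zero-variance degeneracies are pinned (identical groups p = 1,
distinct constants p = 0).

**Integration.** All coordinates are 0-based half-open; overlap means ≥ 1
shared base; distances from a point to an interval are 0 inside, else the
gap to the closest covered base; inter-chromosome distances are an
*unreachable* sentinel excluded from medians; nearest ties break
deterministically by (start, end, insertion order). "Within 20 kb" is
inclusive. Intragenic enhancer assignment uses the enhancer midpoint inside
the half-open gene span. The TATA scan matches the degenerate motif TATAWAW
(W = A/T) with ≤ 1 mismatch, sense strand only, with the motif start offset
in [−40, −20] relative to a TSS that is the last base of the supplied
sequence; an N in the sequence never matches.

## The synthetic epigenome generator

The generator's defaults are the study conditions: every downstream test
and the acceptance script run against them unchanged.

**Scale.** 2 chromosomes × 15 Mb, 2,000 genes with log-uniform spans of
3–12 kb, ≥ 3 kb intergenic gaps, ~240,000 CpGs at 0.0075 CpG/bp with
CpG-island enrichment (0.018 CpG/bp inside islands). Three scale choices
are deliberate desk-scale compromises rather than genome mimicry:
(1) 15 Mb chromosomes keep the genic share of a random 10-kb window near
38% — with denser gene packing the gene-body residual alone would push the
random-region demethylated median above its 9% target; (2) the 3-kb minimum
gene span keeps the −100..+700 promoter window below ~15% of a gene's CpGs,
without which short genes could not reach high body-methylation targets;
(3) the ≥ 3 kb gap guarantees ≥ 2.5 kb TSS spacing, so a promoter peak can
never fall inside a neighbouring gene's ±2 kb window and planted chromatin
states are recovered exactly.

**Promoter methylation.** Per-promoter levels come from a two-beta mixture.
Each component beta is parameterized by its *median* at concentration 4
(low mode 0.03, high mode 0.90), and the high-mode weight is solved in
closed form from the component CDFs so the mixture median equals the 0.30
target. Levels are drawn by *stratified mid-quantile sampling* (the i-th of
n values is the ((i+0.5)/n)-quantile), not iid: a sharply bimodal mixture
has little density at its median, so an iid sample median at n = 2,000
would wander by several percentage points and the generator could not
reproducibly present the calibrated conditions. The high mode is carried by
the de-repressed genes plus a silent-gene pool whose size follows from the
calibrated weight (~46% of promoters highly methylated).

**Gene bodies and background.** Background methylation lives on 5-kb blocks
whose levels are stratified draws from a beta with median 0.84
(concentration 30). Gene bodies get per-gene targets from the same
distribution, assigned *assortatively*: because the unmethylated promoter
window and any hypomethylated active enhancer inside a gene put a ceiling
on its achievable span mean, targets are matched rank-for-rank to those
ceilings, and the free body CpGs receive the level that makes the
CpG-weighted span mean hit the target exactly. Random assignment would clip
at the ceiling and bias the body median downward. Per-CpG values add
N(0, 0.04) noise, clipped to [0, 1].

**The demethylated condition** is parental × a per-compartment residual
factor plus N(0, 0.003) noise. The promoter factor is the ratio of the
configured target (0.005, under the < 1% bound) to the realized parental
promoter median; the body factor is solved by bisection so the realized
per-gene body-mean median equals 0.13; the background factor is solved over
an internal 1,000-region random-window sample so the random-region median
equals 0.09 — random windows mix genic and intergenic CpGs, so the
background factor cannot be read off a single compartment. Before noise the
derived value never exceeds the parental one.

**Chromatin.** Active-in-parental enhancers (common + parental-unique) are
written as hypomethylated islands (beta median 0.08); new
(demethylated-unique) enhancers stay at the local methylated level — the
planted version of "new enhancers were methylated before demethylation".
40% of up-regulated genes host 1–5 planted intragenic new enhancers (59% of
hosts more than one, emulating spreading; 8% of planted slots are covered
by an exon). 47% of all new enhancers receive a parental H3K4me1 peak
(poised). Promoter H3K4me3/H3K27ac/RNAPII peaks mark expressed genes; 40%
of de-repressed genes gain a new promoter H3K4me3 peak in the demethylated
condition and 13% of the non-gainers sit in a common peak. Replicate 2 of
every peak set is replicate 1 jittered by ≤ 50 bp plus replicate-private
noise peaks, so the both-replicate consensus rule does real filtering.

**Expression.** Three replicates per condition; per-gene log₂ baselines by
class (de-repressed: parental U(0.3, 1.35), demethylated U(2.7, 5.5);
up/down: fold changes of 0.7–2.0 log₂ units off a U(2, 7) baseline;
unchanged: ±0.08; silent: exact zeros) with N(0, 0.1) replicate noise on
the log₂ scale. Effect sizes are set so rule-based class recovery is ≥ 95%
but not 100% — the misclassification margin is part of what the tests
exercise. CpG-island fractions per class are 0.58 / 0.75 / 0.83 (plus 0.70
for the remainder), island lengths ~N(1000, 150) bp trimmed so no island
covers a foreign TSS; TATA fractions are 0.10 / 0.10 / 0.07; promoter
sequences for non-TATA genes are rejection-sampled to contain no qualifying
motif, so planted sequence labels are exact.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: read-level error and mapping bias, repeat
structure and copy-number variation, chromosome-scale methylation domains,
isoform diversity (one transcript model per gene), peak-calling noise
beyond replicate jitter, and any coupling between methylation and
expression beyond the planted class structure. The generator demonstrates
that the *operations* implement their stated rules, not that the rules are
biologically optimal.

## Numerical choices

Region aggregation uses prefix sums over coverage-filtered CpGs (exact, no
binning). Nearest-feature queries compute exact point-to-interval distances
with lexicographic tie-breaks; the test suite checks them against naive
O(n·m) re-implementations on ≥ 100 random instances per operation. Beta
medians are inverted with Brent's method to 1e-10; the two residual-factor
bisections stop at 1e-6. Manifests are JSON with sorted keys and rounded
floats, making simulate + analyze byte-reproducible for a fixed seed. The
analysis samples its random regions from the run seed; the generator's
internal calibration regions use a separate derived stream so calibration
and measurement never share randomness.

## Known limitations

* The built-in Welch test is underpowered at 2 replicates and is not a
  negative-binomial count model; supply external p-values for real data.
* Enhancer–gene linking is proximity-only (nearest TSS distance); no
  chromatin-loop information is used.
* The common-enhancer count is side-dependent when overlaps are
  many-to-one; both counts are reported rather than resolved.
* Compartment medians at desk scale carry ~±0.5 percentage point sampling
  noise from coverage filtering and region sampling; tolerances in the
  tests (±2 points) reflect that.
* The TATA scan is sense-strand only by default (a reverse-strand scan is a
  one-line wrapper away, but the default mirrors the promoter-FASTA
  convention in which the TSS is the last base).
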