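# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); UCSC-style 1-based
inputs are converted on read. Reads are single-coordinate tags (the 5'
mapping position) and a tag belongs to an interval iff its coordinate lies
in `[start, end)`. Point assignment, rather than fractional overlap, makes
counting over any disjoint genome tiling conserve the library total
exactly — an invariant the test suite checks. Genomes are tiled into
fixed-width bins (1 kb for focality and spreading statistics, 500 bp for
aggregate profiles, 10/100 kb available for coarse tracks); the last bin of
a chromosome may be short, and RPKM uses the true bin width.

Promoters are 5 kb intervals centered on each unique TSS, irrespective of
strand (the TSS of a minus-strand transcript is its larger genomic
coordinate); identical TSSs are deduplicated. Genic regions take, per gene,
the transcript span maximizing |TES − TSS|, ties resolved to the lower
start coordinate. Blacklist filtering removes any region with ≥ 1 bp of
overlap — the conservative any-overlap reading.

## Spike-in normalization

The Rx ratio divides the target/spike-in mapped-read odds of the ChIP
sample by the same odds of its input. Because only ratios enter the
formula, tag collections carry just the two totals; unmapped reads are out
of scope, so the two fractions sum to one in practice. The pseudocount
(`c = 1` raw read) is added to raw counts before any scaling, never to
scaled values, and the Rx factor multiplies the ChIP term only — inputs are
never Rx-scaled, consistent with the normalization equations, which apply
Rx to the target sample alone. `input_normalize_with_rx` is algebraically
`input_normalize + log2(Rx)` and the implementation preserves that identity
to machine precision.

## Difference-plot categorization

Per-region processed counts are `Rx * (count + c) / total`; with two
wild-type replicates the x coordinate averages the two log-ratios against
their inputs and the y coordinate subtracts the mean log WT signal from the
log K27M signal. The pseudocount convention is reused here because regions
with zero counts must have finite logarithms.

Categories are conjunctions of strict half-plane bounds, shipped as presets
(BT245-CGI, DIPGXIII-CGI, BT245-promoter) and overridable from YAML.
Evaluation order is fixed — Gained, Absent, Lost, Retained, first match
wins — because the DIPGXIII Gained and Retained bounds overlap and need a
deterministic precedence. The BT245 CGI regions are pairwise disjoint
(verified by grid scan in the tests). Points matching no region are labelled
Unclassified rather than forced into a class: the thresholds are not
exhaustive.

## Spreading statistics

The top-percent score selects `ceil(pct/100 * N)` bins (never empty), ties
broken by genomic order under a stable sort. Spread-correlation windows
sort 1 kb input-normalized bins by the K27M H3K27me2 value, descending, and
split the ranking into 1000 contiguous groups whose sizes differ by at most
one; window 1 is the most enriched. Aggregate profiles sample the track at
bin centers offset from each anchor midpoint and discard out-of-bounds
offsets from the means; the region-scaled variant (for PMDs) keeps flanks in
absolute bp and resamples the domain body onto a fixed number of bins.
Signal matrices impute missing values as 0 and cluster rows with standard
squared-error k-means (k = 3 by default, fixed seed, 10 restarts); rows are
ordered by cluster mean then row mean, the conventional heatmap layout.

## PMD calling

CpGs with coverage below 5, at known SNPs, or inside blacklist regions are
removed first. Windows of 10 kb stepped by 10 kb seed a candidate when
their unweighted mean CpG methylated fraction is strictly below 0.70 — a
window at exactly the threshold does not seed, which fixes the boundary the
acceptance script locates empirically. Candidates are extended rightward
only; seeds inside an already-called candidate are skipped, overlapping
candidates are merged, and merged regions strictly longer than 1 Mb are
reported. Mean methylation is the unweighted mean over CpGs, not
coverage-weighted.

Two extension rules are provided. The default (`window_mean`) grows the
candidate while each added 10 kb increment is itself sub-threshold;
CpG-free windows are neutral — they neither extend nor stop the run, so
gaps are bridged. This is equivalent to joining consecutive sub-threshold
tiles and recovers planted domain boundaries within one window width. The
alternative (`region_mean`) grows the candidate while the running mean of
the whole region stays sub-threshold, excluding the terminating increment.
Its right boundary depends on how quickly flanking high-methylation CpGs
dilute the running mean: a 1.5 Mb domain at 50% methylation flanked by 85%
extends roughly `L * (0.70 − 0.50)/(0.85 − 0.70) ≈ 2 Mb` past the true
edge before the mean reaches threshold. Because a domain boundary should
not depend on megabases of unrelated downstream sequence, `window_mean` is
the default; `region_mean` is retained because it is the literal
running-mean reading of the procedure and still guarantees that every
reported region has sub-threshold mean.

## Expression summaries

DE labels use strict thresholds (log2FC > 1 and padj < 0.05 for Up, the
mirrored bounds for Down); records lacking padj are labelled NS with a
warning. Deciles are defined over *all* genes' parental expression — not DE
genes only — and DE genes are then binned; ties at a boundary go to the
lower decile. Any monotone transform of the expression values (raw
normalized counts, rlog) yields identical deciles, so the choice of scale
is immaterial. The viability percentage uses the oxidized Alamar-blue
extinction coefficients O1 = 80586 (570 nm) and O2 = 117216 (600 nm) and is
invariant under common scaling of all four absorbances.

## Synthetic data: what it emulates

The generator is a pure function of a seeded configuration; regenerating
with the same seed is bit-identical, and every sample draws from its own
deterministic RNG stream so samples can be generated independently or as a
set.

Defaults describe a desk-scale study: a 2 × 5 Mb genome, 200 non-overlapping
CGIs with log-normal widths (median ≈ 1.2 kb), of which the widest 20% are
nucleation sites (DNA methylation ≈ 0.05 vs ≈ 0.65 elsewhere; SUZ12 peaks
coincide with them), 200 000 expected reads per sample and a 5% spike-in
fraction. Rate maps are piecewise constant: enrichment 30× background
(chosen so that, from the rate map alone, a majority — about 58% — of K27M
H3K27me3 tags fall inside nucleation CGIs ± the 4 kb peak width). Wild-type
H3K27me3 occupies nucleation CGIs ± 100 kb plus the planted PMDs; K27M
H3K27me3 only nucleation CGIs ± 4 kb; K27M H3K27me2 exactly the wild-type
me3 footprint; wild-type me2 its complement; SUZ12 sits at nucleation CGIs
with broader flanks in the K27M regime. Counts are Poisson per 100 bp
generation bin with tags placed uniformly within the bin; overdispersion,
fragment-length structure and mappability variation are deliberately not
modelled, so passing tests demonstrate correctness of the statistics, not
robustness to the full noise structure of real libraries.

Global abundance differences between conditions (me3: 0.2, me2: 0.7,
matching the several-fold global me3 depletion the K27M regime emulates)
are implemented by scaling target-genome rates at a fixed spike-in rate —
exactly how a global loss manifests in ChIP-Rx — so the expected spike
fraction of a depleted sample rises above the configured base fraction, and
the Rx ratio of the two conditions estimates the configured abundance
ratio (recovered within 5% at default depth).

The methylome places CpGs ~1 per 100 bp (exponential spacings), coverage
Poisson(30) with 5% of sites downgraded to Poisson(2) to exercise the
coverage filter, and Beta-distributed methylated fractions around 0.85
outside planted PMDs and around each PMD's configured mean inside (two
planted domains: 1.5 Mb at 0.50 and 1.2 Mb at 0.55). The expression table
plants 102 upregulated and 12 downregulated genes among 2000, upregulation
drawn preferentially from low-expression ranks (~e³-fold weighting), with
effects well separated from the classification thresholds so the planted
sets are recoverable exactly.

## Problem sizes

All defaults are desk-scale by design: the 10 Mb genome yields 10 000 1 kb
bins (the spread-correlation windows therefore hold 10 bins each), each
ChIP sample carries ~2 × 10⁵ reads, the methylome ~10⁵ CpGs and the DE
table 2000 genes. A full dataset generates in well under a second and the
complete analysis, including the randomized oracle comparisons, runs in a
few seconds.

## Known limitations

- The simulator's piecewise-constant rate maps produce sharper domain
  edges than real chromatin; boundary-precision results on synthetic data
  are upper bounds on real-data performance.
- Spike-in reads are tallied, never placed on an exogenous genome; spike-in
  quality and cross-genome mapping ambiguity are out of scope.
- Peak calling, read alignment and DE model fitting are consumed as inputs
  (BED / count tables), not reimplemented.
- The `region_mean` PMD extension rule is sensitive to chromosome-end
  effects by construction (the candidate may run to the last CpG window).
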