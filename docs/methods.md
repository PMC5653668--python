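# Methods

This note records the models implemented by `lesionevo`, the parameters
that matter, what the synthetic cohorts do and do not emulate, and the
choices made where the design was genuinely open.

## Scope and assumptions

The package analyzes clonal evolution across several microdissected lesions
of one patient that share a single founding lineage: a ubiquitous,
homozygous TP53 mutation (wild-type allele lost) is assumed present in every
tumor sample, and most copy-number change is assumed to predate most point
mutations, so mutations carry multiplicity m = 1 unless stated. Intra-lesion
heterogeneity beyond clonal clusters is out of scope: each sample is treated
as one (possibly impure) clone drawn from the patient's clone tree. Read
alignment, base-quality modeling, and GC/repeat/capture bias correction of
bin counts are assumed done upstream.

## Variant screen

Discovery stringency (per sample): altered fraction > 10% of distinct
reads, ≥ 5 altered reads, coverage at the base at least the sample's TP53
coverage, and coverage > 20% of the sample's mean. "Overall sequence
coverage" is interpreted as the sample's mean distinct coverage across
assayed bases — the natural reference point, though other summaries
(median, targeted-panel mean) would differ little. One passing sample makes
a patient-level candidate; presence elsewhere then needs only ≥ 2 distinct
altered reads *and* ≥ 1% of reads. Requiring both reconciles the two
detection statements (a read-count floor and a VAF floor): at 200× they
coincide, at higher depth the VAF floor dominates. Context filters remove
candidates inside homopolymer runs of ≥ 5 identical bases (indels
leftmost-aligned, so the run is tested at the variant's entry point) and
candidates averaging < 50× across samples. Alignment-uniqueness screening
(BLAT-style) is exposed as a pluggable predicate on (chrom, pos, context)
rather than implemented; no bundled aligner dependency is warranted for the
package's scope.

## Allelic imbalance

MAF uses loci at ≥ 10× (default `snp_min_coverage`). The LOH test is
signed — normal MAF minus tumor MAF > 0.10 — because a genuine gain cannot
push MAF above 0.5; an absolute test would double the false-positive
surface for no sensitivity gain. Confidence tiers compare a segment's MAF
with the sample's minimum MAF over ≥ 10 Mb segments (the cleanest
attainable LOH level, itself a purity proxy): within 0.1 high, 0.1–0.2
intermediate, > 0.2 low.

Patient-level harmonization takes the union of all samples' breakpoints per
chromosome, recomputes per-sample MAF/LOH on the atomic intervals, merges
adjacent intervals whose calls agree everywhere with per-sample MAF
differences ≤ 0.05 and boundary gaps ≤ 5 Mb, then filters (≥ 20 SNPs in
every sample, ≥ 10 Mb, high-confidence LOH somewhere, ≥ 0.1 MAF gap between
carriers and non-carriers). Merging before filtering keeps genuinely shared
segments that breakpoint jitter would otherwise fragment below the size
floor; with clean segmentations the order is immaterial.

The pooled low-input path is for samples whose covered-SNP count falls
below 20% of the patient median (`low_input_fraction`): patient segments
are defined from the other samples, each SNP's minor allele is fixed by
majority vote over well-covered samples (ties broken by pooled read
counts), and the segment MAF is Σ minor reads / Σ coverage, which removes
the per-locus variance that dooms 3–5× data. LOH requires the pooled MAF
to sit ≥ 0.1 below the normal's.

## Segmentation engine

Both MAF series and log-ratio profiles use recursive binary segmentation:
the best split maximizes a pooled-variance z statistic (computed for all
splits via cumulative sums), accepted when it beats a within-segment
permutation null (α = 0.01, 1000 permutations by default, 300 in the
pipeline; seeded, with early exit once non-significance is certain).
Minimum segment size 5 SNPs / 3 bins. Segmentation never crosses
chromosome boundaries. An exhaustive least-squares single-changepoint fit
serves as the independent oracle in tests.

## Copy number

Anchors are allelically balanced regions; their observed log ratios are
grouped by single-linkage within 0.30 log2 units (half the spacing between
adjacent even copy states at high purity), and only the level covering the
most genome is kept when several appear. δ is solved in closed form at
anchor CN 2; the profile is implausible when any CN 0 segment reaches
≥ 25 Mb or ≥ 80% of a chromosome arm (arms approximated as half
chromosomes; the size cut operationalizes "chromosome-arm-scale"), in which
case anchors are re-fixed at CN 4. Integer assignment is the argmin of
|R_obs − R_model| over CN 0..8; exact midpoint ties resolve to the lower
copy number (less complex genome). `max_cn` = 8 suffices because solutions
are deliberately biased toward low-integer genomes. Manual anchor override
is available for cohorts where no chromosome is balanced in all samples.

## Cellularity and clustering

The cellularity grid is 0..1 in steps of 0.01 (101 points). The CI is a
likelihood-ratio interval at the χ²₁ 95% cutoff, chosen because it degrades
gracefully at the C = 0 and C = 1 boundaries where a Wald interval fails.
Cluster cellularity pools member read counts in a joint likelihood (one
shared C, each member at its own expected VAF given its local copy number);
pooling counts rather than averaging per-mutation MLEs avoids the boundary
bias of averaging clipped estimates. Mutations in unresolved copy-number
segments default to CN 2 with a warning. Samples with TP53-estimated purity
below 0.5 are routed to structure-only analysis (LOH, copy number) and
excluded from clustering and tree inference, since cellularity estimates
at low purity are dominated by purity error.

Clustering is greedy agglomeration of exactly matching presence patterns
(patterns ordered by descending support). An optional tolerance mode for
ambiguous samples exists at the presence-matrix level by adjusting the
thresholds; exact matching is the default because the generator — like the
intended data — produces well-separated patterns at ≥ 100×.

## Phylogeny

The precedence matrix allows ancestor → descendant when the ancestor's
cellularity MLE is ≥ the descendant's − 0.05 in every retained sample; the
0.05 default reflects the cellularity noise scale at ~100× with ~10
mutations per cluster. Trees are rooted at germline with the ubiquitous
(TP53) cluster as the root's only child; remaining clusters are enumerated
exhaustively via Prüfer sequences up to 8 clusters, beyond which a seeded
hill-climb with restarts takes over (the same hill-climb doubles as an
independent search route in tests).

Fitness is "satisfied precedence constraints plus cellularity-sum
consistency", graded by violation magnitude: each ancestor/descendant pair
contributes 1 minus its summed per-sample precedence violation beyond
tolerance, and each node is charged the amount by which its children's
cellularity sum exceeds its own. Binary ±1 scoring was rejected: a single
noise-scale (~0.03) violation then outweighs tree structure and flips
otherwise-recovered topologies, whereas graded penalties let hard
violations (a private cluster forced above a shared one, ~1.0) dominate
while noise-scale ones merely break ties. All co-optimal trees are
returned, ordered lexicographically by parent map for reproducibility.

Unmatched LOH feature groups are placed post hoc on the deepest edge whose
subtree sample set equals the group's carriers; groups with no consistent
edge are reported as homoplasy candidates rather than forced. The
maximum-parsimony oracle enumerates rooted binary sample trees (≤ 8
samples), scores binary presence characters by Fitch counting with the
germline root constrained all-absent, and returns all minimum-score trees;
the two analyses are "concordant" when every parsimony clade is nested in
or disjoint from every clone-subtree sample set.

## Timing

The posterior over the founder-age ratio is Beta(a + n_j, b + n_k − n_j)
by conjugacy. Alteration counts n include mutation-cluster members and LOH
feature groups on the path (a flag restricts to sequence-only for
sensitivity analysis). The default prior Beta(34, 1.6) encodes one prior
patient with 34 shared and 1.6 additional alterations (ratio mean 0.95);
configured alternatives are (17, 0.8), (68, 3.2) — same mean at half and
double weight — and the flat (1, 1). HPD intervals minimize interval width
over the left-tail mass using the analytic quantile function (bounded
scalar minimization; the width is unimodal in the tail mass for a unimodal
beta); a dense quantile scan is the independent oracle in tests, and both
"HPD" and "confidence interval" labels are used interchangeably in output.
Three-lesion chains draw 10⁵ seeded Monte Carlo samples from the two
component posteriors and multiply them, integrating out the intermediate
founder time; the empirical HPD is the narrowest order-statistic window.

A note on calibration: the frequentist coverage of the 90% HPD is nominal
(~0.89 measured over simulated linear accrual at truth ratio 0.8,
n_k = 60) under the flat prior, but ~0.42 under the default informative
prior — not an interval defect but ordinary prior bias when the truth sits
deep in the prior tail. The calibration benchmark therefore uses the flat
prior; inferences under the informative prior should be read as Bayesian
summaries, with the prior-sensitivity table showing how conclusions move.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 3–10
lesions per patient on one clone tree rooted at germline; a ubiquitous
TP53-like mutation inside copy-neutral LOH whose VAF equals purity;
cluster-structured mutations (default 10 per cluster) on tree edges;
chromosome-scale LOH events per edge, copy-neutral by default with a
single-copy-deletion mode; per-sample purity drawn from 0.3–0.9; ~10⁴
heterozygous SNPs at ~100× distinct coverage (negative-binomial per locus,
dispersion 20); and a low-input mode that binomially thins one sample's
reads. Every subclone receives at least one sample so presence patterns are
distinguishable — the regime the source design targets. Founder ages are
proportional to path alteration counts, matching the timing model's
constant-rate assumption. The TP53 locus depth is pinned at the sample
mean coverage: its relative capture efficiency is a fixed assay property,
and because the discovery filter is calibrated against it, resampling it
from the dispersed per-locus distribution makes whole patients' candidate
yields bimodal.

Not emulated: sequencing error and mapping artifacts, FASTQ/BAM-level
detail, subclonal (fractional) copy number, overlapping or nested LOH
events, mutation loss other than annotation, and platform-specific
coverage structure. Passing tests therefore demonstrate correct recovery
of the generative model's structure at realistic noise levels, not
robustness to alignment artifacts or to violations of the clonal-sample
assumption.

## Problem sizes and determinism

Validation benchmarks run at desk scale: six 100 Mb chromosomes with 20
SNPs per 10 Mb for LOH (50 seeds), 120 anchor bins at Poisson depth ~500
for bias recovery, 4-cluster/5-sample patients for tree recovery and
parsimony concordance (50 seeds), 100 random 5-cluster instances for
search-route agreement, 1000 random instances for the cellularity grid,
and 200 replicates for timing calibration. These sizes were chosen so each
benchmark's sampling error is well inside its acceptance margin. All
stochastic call sites take an explicit seed; a pipeline run with the same
config and seed is byte-identical, including file artifacts.

## Known limitations

Coordinates are 0-based half-open internally and 1-based inclusive at file
interfaces (except BED). Chromosome X carries no special haploid logic
(female-genome cohort). The harmonization `n_snps` per marker is the
minimum across samples (conservative). The manual edge-split adjustment for
multi-subclone lesions is a config directive, not automated. Exhaustive
parsimony is limited to 8 samples; larger patients must rely on the
cellularity-based search alone.
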