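# lesionevo

Multi-lesion tumor evolution analysis for microdissected cancer precursor
studies: from per-sample sequencing read counts of related lesions (p53
signatures, serous tubal intraepithelial carcinomas, fallopian-tube/ovarian
carcinomas, metastases) to LOH segments, integer copy number, mutation
cellularities, a subclonal phylogeny, and a chronological estimate of the
interval between precursor and carcinoma founder cells.

It is written for analysts of multi-region tumor sequencing who have, per
patient, (i) germline-heterozygous SNP read counts in tumor and normal,
(ii) candidate somatic mutations with per-sample distinct coverage and
altered-read counts, (iii) binned tumor/normal read counts, and (iv) the
patient's age at diagnosis. A first-class synthetic-cohort generator
produces ground-truthed patients with the same statistical structure, so
every stage is testable without access to controlled patient data.

## The models

**Allelic imbalance.** At a germline heterozygous SNP, the minor allele
frequency is MAF = min(ref, alt)/(ref + alt): 0.5 when balanced, suppressed
under loss of heterozygosity. Per-sample MAF series (loci at ≥ 10×) are
segmented by recursive binary segmentation with a permutation stopping rule;
a segment is LOH when the normal-minus-tumor MAF difference exceeds 0.10.
Each sample's minimum segment MAF over ≥ 10 Mb segments acts as a purity
proxy and grades LOH confidence (high/intermediate/low). Sample segments
are intersected into patient-level markers (≥ 20 SNPs, ≥ 10 Mb,
high-confidence LOH in ≥ 1 sample, ≥ 0.1 MAF separation between carriers
and non-carriers, 5 Mb merge window). Low-input samples are genotyped per
marker by pooling minor-allele reads across all its SNPs, the minor allele
fixed by majority vote over the well-covered samples.

**Copy number.** With purity α, tumor copy number CN_T and normal CN_N, the
expected binned log ratio is

    R = log2((α·CN_T + (1 − α)·CN_N)/2) − δ

where δ is a genome-wide bias left over after library-size normalization.
Regions of complete allelic balance can only hold an even number of copies;
fixing them at CN 2 solves for δ, and each segment takes the integer CN_T
whose predicted R is nearest. If that profile implies chromosome-scale
homozygous deletions, the anchors are re-fixed at CN 4 and re-solved.

**Cellularity and phylogeny.** Sample purity is the variant read fraction
of the ubiquitous TP53 mutation (wild-type allele lost). A mutation carried
by a fraction C of cancer cells at multiplicity m has expected VAF

    V_exp = m·α·C / (α·CN_T + (1 − α)·CN_N)

and the observed altered-read count is binomial at V_exp; profiling the
likelihood over C = 0, 0.01, …, 1 gives the MLE and a likelihood-ratio CI.
Mutations are clustered by identical presence patterns (≥ 2% VAF, ≥ 2
mutant reads), LOH markers with identical patterns form feature groups, and
rooted clone trees over the clusters are scored by the lineage precedence
rule — an ancestor's cellularity must be ≥ its descendant's in every sample
— with exhaustive search at per-patient cluster counts and an exhaustive
Fitch maximum-parsimony oracle as a cross-check.

**Timing.** On a linear path, the number of the later lesion's n_k
alterations already present in the earlier lesion (n_j) is
Binomial(n_k, t_j/t_k) under constant mutation rate, where t_j/t_k is the
founder-age ratio. With a Beta(a, b) prior the posterior is
Beta(a + n_j, b + n_k − n_j); the default prior Beta(34, 1.6) centers the
ratio at 0.95. Point estimates are posterior means with 90% HPD intervals;
three-lesion chains multiply two independent ratio posteriors by Monte
Carlo.

## Worked example

```
lesionevo simulate --out demo/patient --samples 4 --clusters 3 \
    --snps 4000 --purity-min 0.55 --seed 11
lesionevo run-all --in demo/patient --out demo/results --seed 11
```

prints

```
## Sample purities
  S0: 0.69
  S1: 0.81
  S2: 0.60
  S3: 0.62

## Alteration categories per sample
sample  ubiquitous  shared_subset  private
    S0          10              0        0
    S1          10              0        6
    S2          10              0        7
    S3          10              0        0

## Patient-level LOH markers: 3

## Clone tree (1 co-optimal)
(('cluster_C1|G0@S2','cluster_C2|G1@S1')'cluster_C0|G2@S0+S3')germline;

## Lesion timing
earlier_node later_node earlier_samples later_samples  n_early  n_late  t_late  ratio_mean  elapsed_years  elapsed_lo  elapsed_hi
          C0         C1           S0+S3            S2       11      19    60.0    0.824176      10.549451    5.529522   15.427950
          C0         C2           S0+S3            S1       11      18    60.0    0.839552       9.626866    4.756160   14.349098
```

Reading this: all four lesions share 10 ubiquitous alterations (the TP53
cluster C0 plus the clonal LOH group G2 sit on the root edge), samples S1
and S2 each carry a private subclone, and the three patient-level LOH
markers were matched to mutation clusters by their presence patterns. For
each ancestor/descendant pair of sampled nodes the timing table gives the
posterior mean founder-age ratio and the elapsed years with its 90%
interval: here roughly a decade between the shared S0+S3 clone's founder
cell and each later subclone, dating the later lesions at age 60. The same
library surface is importable directly (`lesionevo.analyze_patient`,
`lesionevo.simulate_patient`, module-level functions per stage), and all
artifacts (VCF, SEG, TSV, newick, JSON) are written next to the report.

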