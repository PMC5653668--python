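"""End-to-end orchestration of the multi-lesion evolution analysis.

Stage order: variant screen -> allelic imbalance -> copy number -> purity and
cellularity -> clone-tree inference -> lesion timing.  Samples below the
purity floor are routed to structure-only analysis (LOH, copy number) and
excluded from mutation clustering; samples with drastically reduced SNP
coverage (p53 signatures) are excluded from patient-segment definition and
genotyped by the pooled low-input procedure instead.

`analyze_patient` is the in-memory entry point; `run_pipeline` wraps it with
file I/O for a patient directory written by the `simulate` stage or by any
producer of the same formats.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellularity as cel
from . import copynumber as cn
from . import io as lio
from . import loh, phylogeny, timing, variants
from .trees import GERMLINE, CloneTree

log = logging.getLogger("lesionevo")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, at their standard defaults."""

    # variant screen
    candidate_vaf_min: float = 0.10
    candidate_min_alt: int = 5
    candidate_coverage_ratio: float = 0.20
    presence_min_alt: int = 2
    presence_vaf_floor: float = 0.01
    min_avg_coverage: float = 50.0
    # allelic imbalance
    loh_threshold: float = 0.10
    snp_min_coverage: int = 10
    segment_min_snps: int = 20
    segment_min_length_mb: float = 10.0
    merge_window_mb: float = 5.0
    merge_maf_tol: float = 0.05
    low_input_fraction: float = 0.2   # covered-SNP fraction below which a
                                      # sample is treated as low-input
    # clonality
    clustering_vaf_min: float = 0.02
    clustering_min_alt: int = 2
    purity_floor: float = 0.50
    # phylogeny
    precedence_tolerance: float = 0.05
    # timing
    prior: tuple[float, float] = timing.DEFAULT_PRIOR
    hpd_level: float = 0.90
    # misc
    tp53_id: str = "TP53_like"
    segmentation_n_perm: int = 300
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior"] = list(d["prior"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "prior" in d:
            d["prior"] = tuple(d["prior"])
        return cls(**d)


@dataclass
class PatientReport:
    """Artifacts of one pipeline run."""

    config: PipelineConfig
    purities: dict[str, float]
    candidates: pd.DataFrame
    presence: variants.PresenceMatrix | None
    sample_segments: dict[str, pd.DataFrame]
    patient_segments: pd.DataFrame
    pooled_low_input: dict[str, pd.DataFrame]
    cn_solutions: dict[str, cn.CnSolution]
    clusters: list[cel.MutationCluster]
    feature_groups: list[cel.LohFeatureGroup]
    trees: list[CloneTree]
    unplaced_groups: list[cel.LohFeatureGroup]
    timing_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def analyze_patient(
    mutation_counts: pd.DataFrame,
    snp_counts: pd.DataFrame,
    config: PipelineConfig | None = None,
    bins: dict[str, pd.DataFrame] | None = None,
    patient_age: float | None = None,
    normal_sample: str = "normal",
) -> PatientReport:
    """Run the full analysis for one patient's lesions."""
    config = config or PipelineConfig()
    warnings_: list[str] = []
    samples = sorted(
        set(snp_counts["sample"]) | set(mutation_counts.get("sample", ()))
        - {normal_sample}
    )
    samples = [s for s in samples if s != normal_sample]

    # --- purity from the ubiquitous TP53 mutation
    tp53 = mutation_counts[
        mutation_counts["mutation_id"] == config.tp53_id
    ].set_index("sample")
    purities: dict[str, float] = {}
    for s in samples:
        if s in tp53.index and int(tp53.loc[s, "distinct_coverage"]) > 0:
            purities[s] = cel.estimate_purity_tp53(
                int(tp53.loc[s, "altered_reads"]),
                int(tp53.loc[s, "distinct_coverage"]),
            )
        else:
            warnings_.append(f"no TP53 coverage in {s}; purity undefined")

    # --- variant screen
    if len(mutation_counts):
        mean_cov = (
            mutation_counts[mutation_counts["sample"] != normal_sample]
            .groupby("sample")["distinct_coverage"].mean().to_dict()
        )
        tp53_cov = {
            s: int(tp53.loc[s, "distinct_coverage"]) if s in tp53.index else 0
            for s in samples
        }
        candidates = variants.call_candidates(
            mutation_counts, tp53_cov, mean_cov,
            vaf_min=config.candidate_vaf_min,
            min_altered_reads=config.candidate_min_alt,
            coverage_ratio_min=config.candidate_coverage_ratio,
        )
        candidates = variants.apply_context_filters(
            candidates, min_avg_coverage=config.min_avg_coverage
        )
        presence = variants.propagate_presence(
            candidates, mutation_counts,
            min_altered_reads=config.presence_min_alt,
            vaf_min=config.presence_vaf_floor,
        )
    else:
        warnings_.append("empty mutation table; mutation stages skipped")
        candidates, presence = mutation_counts, None

    # --- allelic imbalance
    covered = {
        s: int(
            (
                snp_counts[snp_counts["sample"] == s][["ref_count", "alt_count"]]
                .sum(axis=1) >= config.snp_min_coverage
            ).sum()
        )
        for s in samples
    }
    median_cov = float(np.median(list(covered.values()))) if covered else 0.0
    full_samples = [
        s for s in samples
        if median_cov == 0 or covered[s] >= config.low_input_fraction * median_cov
    ]
    low_input_samples = [s for s in samples if s not in full_samples]

    maf = {s: loh.compute_maf(snp_counts, s, config.snp_min_coverage)
           for s in full_samples}
    normal_maf = loh.compute_maf(snp_counts, normal_sample, config.snp_min_coverage)
    sample_segments: dict[str, pd.DataFrame] = {}
    proxies: dict[str, float] = {}
    for s in full_samples:
        segs = loh.segment_maf(
            maf[s], n_perm=config.segmentation_n_perm, seed=config.seed
        )
        sample_segments[s], proxies[s] = loh.call_loh(
            segs, normal_maf, threshold=config.loh_threshold
        )
    if len(full_samples) >= 2:
        patient_segments = loh.harmonize_patient_segments(
            sample_segments, maf, normal_maf, proxies,
            threshold=config.loh_threshold,
            min_snps=config.segment_min_snps,
            min_length_mb=config.segment_min_length_mb,
            merge_window_mb=config.merge_window_mb,
            merge_maf_tol=config.merge_maf_tol,
        )
    else:
        warnings_.append("fewer than 2 full-coverage samples; no patient segments")
        patient_segments = pd.DataFrame()

    pooled = {}
    for s in low_input_samples:
        if len(patient_segments):
            pooled[s] = loh.pooled_loh_low_input(
                patient_segments, snp_counts, s, full_samples,
                normal_sample=normal_sample,
                min_vote_coverage=config.snp_min_coverage,
                margin=config.loh_threshold,
            )

    # --- copy number
    cn_solutions: dict[str, cn.CnSolution] = {}
    genome = None
    if bins:
        any_bins = next(iter(bins.values()))
        genome = any_bins.groupby("chrom")["end"].max().to_dict()
        balanced = _balanced_regions(patient_segments, full_samples, genome)
        for s, b in bins.items():
            if s not in purities:
                continue
            profile = cn.build_log_ratio(
                b, seed=config.seed, n_perm=config.segmentation_n_perm
            )
            try:
                cn_solutions[s] = cn.solve_profile(
                    profile, balanced, purities[s], genome=genome
                )
            except ValueError as exc:
                warnings_.append(f"copy number unresolved in {s}: {exc}")

    # --- clustering and feature groups
    clonal_samples = [
        s for s in samples
        if purities.get(s, 0.0) >= config.purity_floor
    ]
    excluded = sorted(set(samples) - set(clonal_samples))
    if excluded:
        warnings_.append(
            f"samples below purity floor, structure-only analysis: {excluded}"
        )
    clusters: list[cel.MutationCluster] = []
    groups: list[cel.LohFeatureGroup] = []
    if presence is not None and clonal_samples:
        cluster_presence = cel.build_presence(
            mutation_counts[
                mutation_counts["mutation_id"].isin(candidates["mutation_id"])
            ],
            vaf_min=config.clustering_vaf_min,
            min_altered_reads=config.clustering_min_alt,
        )
        cn_by_mut = _cn_by_mutation(candidates, cn_solutions)
        clusters = cel.cluster_mutations(
            cluster_presence, mutation_counts, purities,
            cn_by_mutation=cn_by_mut, min_purity=config.purity_floor,
        )
        if len(patient_segments):
            seg_samples = [s for s in full_samples if s in clonal_samples]
            groups = cel.group_loh_features(patient_segments, clusters, seg_samples)

    # --- tree
    trees, unplaced = [], []
    if clusters:
        ubiq = _ubiquitous_cluster(clusters, config.tp53_id)
        if ubiq is None:
            warnings_.append("no ubiquitous cluster; tree inference skipped")
        else:
            pm = phylogeny.precedence_matrix(
                clusters, tolerance=config.precedence_tolerance
            )
            trees = phylogeny.search_trees(
                pm, clusters, ubiq, seed=config.seed
            )
            placed = []
            for t in trees:
                pt, un = phylogeny.place_loh_features(t, groups)
                placed.append(pt)
            trees = placed
            unplaced = un if trees else []

    # --- timing
    timing_table = pd.DataFrame()
    if trees and patient_age is not None:
        timing_table = timeline_table(
            trees[0], clusters, config, patient_age
        )

    return PatientReport(
        config=config, purities=purities, candidates=candidates,
        presence=presence, sample_segments=sample_segments,
        patient_segments=patient_segments, pooled_low_input=pooled,
        cn_solutions=cn_solutions, clusters=clusters, feature_groups=groups,
        trees=trees, unplaced_groups=unplaced, timing_table=timing_table,
        warnings=warnings_,
    )


def _balanced_regions(patient_segments, samples, genome) -> pd.DataFrame:
    """Whole chromosomes with no LOH call in any full-coverage sample."""
    loh_chroms = set()
    for seg in patient_segments.itertuples() if len(patient_segments) else ():
        if any(getattr(seg, f"loh_{s}", False) for s in samples):
            loh_chroms.add(seg.chrom)
    rows = [
        {"chrom": c, "start": 0, "end": int(end)}
        for c, end in genome.items()
        if c not in loh_chroms
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _cn_by_mutation(candidates, cn_solutions) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    if not cn_solutions:
        return out
    meta = candidates.drop_duplicates("mutation_id")
    for m in meta.itertuples():
        per_sample = {}
        for s, sol in cn_solutions.items():
            segs = sol.segments
            hit = segs[
                (segs["chrom"] == m.chrom)
                & (segs["start"] < m.pos)
                & (m.pos <= segs["end"])
            ]
            if len(hit):
                per_sample[s] = int(hit["cn_t"].iloc[0])
        out[m.mutation_id] = per_sample
    return out


def _ubiquitous_cluster(clusters, tp53_id) -> str | None:
    for cl in clusters:
        if tp53_id in cl.members and all(cl.pattern):
            return cl.cluster_id
    for cl in clusters:
        if all(cl.pattern):
            return cl.cluster_id
    return None


def _alteration_count(tree: CloneTree, clusters, node) -> int:
    """Sequence plus structural alterations on the path germline -> node."""
    sizes = {cl.cluster_id: len(cl.members) for cl in clusters}
    n = 0
    for c in tree.path_from_root(node):
        n += sizes.get(c, 0) + len(tree.loh_groups.get(c, []))
    return n


def timeline_table(
    tree: CloneTree,
    clusters,
    config: PipelineConfig,
    patient_age: float,
) -> pd.DataFrame:
    """Founder-age intervals for every ancestor/descendant sampled-node pair.

    For each adjacent pair of sampled nodes on a root-to-leaf path, the
    earlier node's alteration count n_j against the later node's n_k yields
    the beta posterior on the founder-age ratio; the later lesion is dated
    at the patient's age at diagnosis.
    """
    sampled = [n for n in [GERMLINE, *tree.parent] if tree.sample_labels.get(n)]
    rows = []
    for node in sampled:
        if node == GERMLINE:
            continue
        # nearest sampled ancestor
        anc = tree.parent[node]
        while anc != GERMLINE and not tree.sample_labels.get(anc):
            anc = tree.parent[anc]
        if anc == GERMLINE:
            continue
        n_j = _alteration_count(tree, clusters, anc)
        n_k = _alteration_count(tree, clusters, node)
        inp = timing.TimingInput(
            n_early=n_j, n_late=n_k, t_late=patient_age,
            prior_a=config.prior[0], prior_b=config.prior[1],
        )
        post = timing.posterior_ratio(inp, hpd_level=config.hpd_level)
        summ = timing.lesion_interval(post, patient_age)
        rows.append(
            {
                "earlier_node": str(anc),
                "later_node": str(node),
                "earlier_samples": "+".join(tree.sample_labels.get(anc, [])),
                "later_samples": "+".join(tree.sample_labels.get(node, [])),
                "n_early": n_j,
                "n_late": n_k,
                "t_late": patient_age,
                "ratio_mean": summ.ratio_mean,
                "elapsed_years": summ.elapsed_mean,
                "elapsed_lo": summ.elapsed_hpd[0],
                "elapsed_hi": summ.elapsed_hpd[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def alteration_categories(presence: variants.PresenceMatrix) -> pd.DataFrame:
    """Per-sample counts of ubiquitous / shared-subset / private alterations."""
    m = presence.matrix
    n_samples = m.shape[1]
    n_present = m.sum(axis=1)
    category = pd.Series(
        np.select(
            [n_present == n_samples, n_present > 1],
            ["ubiquitous", "shared_subset"],
            default="private",
        ),
        index=m.index,
    )
    rows = []
    for s in m.columns:
        present = m[s]
        counts = category[present].value_counts()
        rows.append(
            {
                "sample": s,
                "ubiquitous": int(counts.get("ubiquitous", 0)),
                "shared_subset": int(counts.get("shared_subset", 0)),
                "private": int(counts.get("private", 0)),
            }
        )
    return pd.DataFrame(rows)


def render_report(report: PatientReport) -> str:
    """Human-readable summary: alteration matrix, tree, timing."""
    lines = ["# lesionevo patient report", ""]
    lines.append("## Sample purities")
    for s, a in sorted(report.purities.items()):
        lines.append(f"  {s}: {a:.2f}")
    if report.presence is not None and len(report.presence.matrix):
        lines.append("")
        lines.append("## Alteration categories per sample")
        lines.append(alteration_categories(report.presence).to_string(index=False))
    if len(report.patient_segments):
        lines.append("")
        lines.append(f"## Patient-level LOH markers: {len(report.patient_segments)}")
    if report.trees:
        lines.append("")
        lines.append(f"## Clone tree ({len(report.trees)} co-optimal)")
        lines.append(report.trees[0].to_newick())
    if len(report.timing_table):
        lines.append("")
        lines.append("## Lesion timing")
        lines.append(report.timing_table.to_string(index=False))
    if report.warnings:
        lines.append("")
        lines.append("## Warnings")
        lines.extend(f"  - {w}" for w in report.warnings)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file-level entry points


def write_patient_inputs(patient, outdir: str | Path, bins_delta: float = 0.0):
    """Write a synthetic patient as the pipeline's input file set."""
    from . import synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = dict(patient.config.genome_model)
    lio.write_snp_counts(patient.snp_counts, outdir / "snp_counts.tsv")
    lio.write_mutations_vcf(
        patient.mutation_counts, outdir / "mutations.vcf", genome
    )
    for i, s in enumerate(patient.tumor_samples):
        b = synthetic.simulate_bin_counts(
            patient, s, delta=bins_delta, seed=patient.config.seed + 1000 + i
        )
        b.to_csv(outdir / f"bins_{s}.tsv", sep="\t", index=False)
    (outdir / "truth_tree.nwk").write_text(patient.truth_tree.to_newick() + "\n")
    lio.write_json(
        {
            "sample_purities": patient.sample_purities,
            "ages": patient.ages,
            "patient_age": patient.config.patient_age,
            "truth_clusters": patient.truth_clusters,
            "seed": patient.config.seed,
        },
        outdir / "truth.json",
    )
    truth_segs = pd.DataFrame([dataclasses.asdict(t) for t in patient.truth_segments])
    truth_segs.drop(columns=["samples"]).assign(
        samples=[",".join(t.samples) for t in patient.truth_segments]
    ).to_csv(outdir / "truth_segments.seg", sep="\t", index=False)


def run_pipeline(
    indir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> PatientReport:
    """Read a patient directory, run every stage, write all artifacts."""
    indir, outdir = Path(indir), Path(outdir)
    config = config or PipelineConfig()
    outdir.mkdir(parents=True, exist_ok=True)

    snp_counts = lio.read_snp_counts(indir / "snp_counts.tsv")
    mutation_counts = lio.read_mutations_vcf(indir / "mutations.vcf")
    bins = {
        p.stem.removeprefix("bins_"): pd.read_csv(p, sep="\t", dtype={"chrom": str})
        for p in sorted(indir.glob("bins_*.tsv"))
    }
    patient_age = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        patient_age = lio.read_json(truth_path).get("patient_age")

    report = analyze_patient(
        mutation_counts, snp_counts, config=config, bins=bins or None,
        patient_age=patient_age,
    )

    lio.write_yaml(config.to_dict(), outdir / "config.yaml")
    genome = (
        {c: int(l) for c, l in pd.concat(bins.values())
         .groupby("chrom")["end"].max().items()}
        if bins
        else snp_counts.groupby("chrom")["pos"].max().astype(int).to_dict()
    )
    if len(report.candidates):
        lio.write_mutations_vcf(
            report.candidates, outdir / "candidates.vcf", genome
        )
    if report.presence is not None:
        report.presence.matrix.to_csv(outdir / "presence.tsv", sep="\t")
    for s, segs in report.sample_segments.items():
        lio.write_seg(segs, s, outdir / f"segments_{s}.seg")
    if len(report.patient_segments):
        lio.write_patient_segments(
            report.patient_segments, outdir / "patient_segments.tsv"
        )
    for s, df in report.pooled_low_input.items():
        df.to_csv(outdir / f"pooled_loh_{s}.tsv", sep="\t", index=False)
    for s, sol in report.cn_solutions.items():
        lio.write_seg(sol.segments, s, outdir / f"cn_{s}.seg", mean_col="cn_t")
        lio.write_json(sol.report(), outdir / f"cn_report_{s}.json")
    if report.clusters:
        cel.cluster_table(report.clusters).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
    if report.trees:
        (outdir / "tree.nwk").write_text(report.trees[0].to_newick() + "\n")
        (outdir / "tree.json").write_text(report.trees[0].to_json() + "\n")
    if len(report.timing_table):
        report.timing_table.to_csv(outdir / "timing.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(render_report(report))
    return report
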