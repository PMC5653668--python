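"""Ground-truthed synthetic multi-lesion patients.

Emulates the data structure of a multi-region study of serous ovarian
carcinogenesis: several microdissected lesions per patient (p53 signature,
STIC, fallopian-tube/ovarian carcinoma, metastases) share one clone tree
rooted at the germline.  Every tumor sample carries a ubiquitous TP53-like
mutation rendered homozygous by copy-neutral LOH, so its variant allele
fraction encodes sample purity.  Somatic mutations come in clusters tied to
tree edges, chromosome-scale LOH events sit on edges, and observed read
counts are binomial draws from the expected allele fractions implied by the
tree, per-sample purity, and local copy number.

A low-input mode thins a sample's coverage below the analysis threshold to
emulate the few hundred cells of a p53 signature.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import GERMLINE, CloneTree

#: Approximate female genome, lengths in bp (Mb resolution).
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{name}", mb * 1_000_000)
    for name, mb in [
        (1, 249), (2, 243), (3, 198), (4, 191), (5, 181), (6, 171),
        (7, 159), (8, 146), (9, 141), (10, 136), (11, 135), (12, 134),
        (13, 115), (14, 107), (15, 103), (16, 90), (17, 81), (18, 78),
        (19, 59), (20, 63), (21, 48), (22, 51), ("X", 155),
    ]
)

#: Chromosomes assigned whole-chromosome LOH events by default, cluster by
#: cluster.  The first (TP53-bearing chr17) always goes to the ubiquitous
#: cluster and is always copy-neutral, mirroring loss of the TP53 wild-type
#: allele with retained total copy number.
DEFAULT_LOH_CHROMS: tuple[str, ...] = (
    "chr17", "chr13", "chr5", "chr6", "chr16", "chr18", "chr22", "chr1",
)

COPY_NEUTRAL = "copy_neutral"
DELETION = "deletion"

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LohEvent:
    """A clonal LOH event attached to a clone-tree edge."""

    chrom: str
    start: int
    end: int
    cluster: int
    mode: str = COPY_NEUTRAL

    @property
    def cn_t(self) -> int:
        return 2 if self.mode == COPY_NEUTRAL else 1


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic patient.

    Defaults follow the cohort the generator emulates: 3-10 lesions per
    patient, purities 0.3-0.9, ~10^4 exome heterozygous SNPs at ~100x
    distinct coverage, cluster-structured mutations on a shared clone tree.
    """

    n_samples: int = 5
    n_clusters: int = 4
    tree_topology: tuple[tuple[object, int], ...] | None = None
    purity_range: tuple[float, float] = (0.3, 0.9)
    n_snps: int = 10_000
    mean_distinct_coverage: float = 100.0
    coverage_dispersion: float = 20.0
    n_mutations_per_cluster: int = 10
    loh_segments: tuple[LohEvent, ...] | None = None
    loh_mode: str = COPY_NEUTRAL
    genome_model: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    patient_age: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"purity_range must lie in (0, 1], got {self.purity_range}")
        if self.n_clusters < 1:
            raise ValueError("need at least one mutation cluster")
        if self.n_samples < self.n_clusters:
            raise ValueError(
                "need n_samples >= n_clusters so every subclone is sampled"
            )
        if self.loh_mode not in (COPY_NEUTRAL, DELETION):
            raise ValueError(f"unknown loh_mode {self.loh_mode!r}")
        lengths = dict(self.genome_model)
        for ev in self.loh_segments or ():
            if ev.chrom not in lengths:
                raise ValueError(f"LOH segment on unknown chromosome {ev.chrom}")
            if not (0 <= ev.start < ev.end <= lengths[ev.chrom]):
                raise ValueError(f"LOH segment out of bounds: {ev}")
            if not (0 <= ev.cluster < self.n_clusters):
                raise ValueError(f"LOH segment on unknown cluster {ev.cluster}")


@dataclass(frozen=True)
class TruthSegment:
    """Ground-truth LOH interval with true tumor copy number."""

    chrom: str
    start: int
    end: int
    cluster: int
    mode: str
    cn_t: int
    samples: tuple[str, ...]


@dataclass
class SyntheticPatient:
    """One simulated patient with full ground truth retained."""

    config: CohortConfig
    truth_tree: CloneTree
    sample_purities: dict[str, float]
    sample_nodes: dict[str, int]
    snp_counts: pd.DataFrame
    mutation_counts: pd.DataFrame
    truth_segments: list[TruthSegment]
    ages: dict[str, float]
    normal_sample: str = "normal"
    truth_clusters: dict[str, int] = field(default_factory=dict)

    @property
    def tumor_samples(self) -> list[str]:
        return sorted(self.sample_purities)

    def truth_presence(self) -> pd.DataFrame:
        """Mutations x samples boolean matrix implied by the truth tree."""
        samples = self.tumor_samples
        pres = self.truth_tree.cluster_presence(samples)
        rows = {
            mut: list(pres[cluster])
            for mut, cluster in self.truth_clusters.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=samples
        ).sort_index()


# ---------------------------------------------------------------------------


def simulate_read_counts(
    expected_vaf: float,
    coverage: float,
    seed: int | np.random.Generator = 0,
    dispersion: float = 20.0,
) -> tuple[int, int]:
    """Draw (alt reads, depth) for one locus.

    Depth is negative-binomial around ``coverage`` with the given
    overdispersion (variance mu + mu^2/dispersion); alt reads are binomial
    at ``expected_vaf`` given the depth.
    """
    if not 0 <= expected_vaf <= 1:
        raise ValueError("expected_vaf must be in [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = _draw_depth(rng, coverage, dispersion, size=None)
    alt = int(rng.binomial(depth, expected_vaf)) if depth else 0
    return alt, int(depth)


def _draw_depth(rng, mean, dispersion, size):
    if mean == 0:
        return 0 if size is None else np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _default_topology(n_clusters: int, rng: np.random.Generator) -> dict[int, object]:
    """Random growing tree over clusters; cluster 0 is the ubiquitous root child."""
    parent: dict[int, object] = {0: GERMLINE}
    for c in range(1, n_clusters):
        parent[c] = int(rng.integers(0, c))
    return parent


def _default_loh_segments(config: CohortConfig) -> tuple[LohEvent, ...]:
    lengths = dict(config.genome_model)
    events = []
    for cluster in range(config.n_clusters):
        chrom = DEFAULT_LOH_CHROMS[cluster % len(DEFAULT_LOH_CHROMS)]
        mode = COPY_NEUTRAL if cluster == 0 else config.loh_mode
        events.append(LohEvent(chrom, 0, lengths[chrom], cluster, mode))
    return tuple(events)


def _snp_alt_fraction(alpha: float, event: LohEvent | None, keep_alt: bool) -> float:
    """Expected alt-read fraction at a germline het SNP in one tumor sample."""
    if event is None:
        return 0.5
    if event.mode == COPY_NEUTRAL:
        # tumor cells carry two copies of the kept allele
        return (1 + alpha) / 2 if keep_alt else (1 - alpha) / 2
    # single-copy deletion: tumor carries one copy of the kept allele
    return (alpha * keep_alt + (1 - alpha)) / (2 - alpha)


def simulate_patient(config: CohortConfig) -> SyntheticPatient:
    """Generate one patient; all randomness flows from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- clone tree and sample attachment
    if config.tree_topology is not None:
        parent = {int(c): p for c, p in config.tree_topology}
        if sorted(parent) != list(range(config.n_clusters)):
            raise ValueError("tree_topology must cover clusters 0..n_clusters-1")
    else:
        parent = _default_topology(config.n_clusters, rng)
    samples = [f"S{i}" for i in range(config.n_samples)]
    # one sample per subclone guarantees distinguishable presence patterns;
    # extra samples land on random subclones
    sample_nodes = {samples[i]: i for i in range(config.n_clusters)}
    for s in samples[config.n_clusters:]:
        sample_nodes[s] = int(rng.integers(0, config.n_clusters))
    labels: dict[object, list[str]] = {}
    for s, node in sample_nodes.items():
        labels.setdefault(node, []).append(s)
    tree = CloneTree(parent=dict(parent), sample_labels=labels)

    lo, hi = config.purity_range
    purities = {s: float(rng.uniform(lo, hi)) for s in samples}

    events = (
        tuple(config.loh_segments)
        if config.loh_segments is not None
        else _default_loh_segments(config)
    )
    # overlapping clonal events are out of scope for the generator
    by_chrom: dict[str, list[LohEvent]] = {}
    for ev in events:
        for other in by_chrom.get(ev.chrom, []):
            if ev.start < other.end and other.start < ev.end:
                raise ValueError(f"overlapping LOH events on {ev.chrom}")
        by_chrom.setdefault(ev.chrom, []).append(ev)

    presence = tree.cluster_presence(samples)  # cluster -> tuple[bool]
    truth_segments = [
        TruthSegment(
            ev.chrom, ev.start, ev.end, ev.cluster, ev.mode, ev.cn_t,
            samples=tuple(s for s, p in zip(samples, presence[ev.cluster]) if p),
        )
        for ev in events
    ]

    snp_counts = _simulate_snps(config, rng, samples, purities, by_chrom, presence)
    mutation_counts, truth_clusters = _simulate_mutations(
        config, rng, samples, purities, presence, by_chrom
    )
    ages = _founder_ages(config, tree, sample_nodes, truth_clusters, events)

    return SyntheticPatient(
        config=config,
        truth_tree=tree,
        sample_purities=purities,
        sample_nodes=sample_nodes,
        snp_counts=snp_counts,
        mutation_counts=mutation_counts,
        truth_segments=truth_segments,
        ages=ages,
        truth_clusters=truth_clusters,
    )


def _simulate_snps(config, rng, samples, purities, by_chrom, presence):
    lengths = dict(config.genome_model)
    total = sum(lengths.values())
    chroms, positions = [], []
    for chrom, length in config.genome_model:
        n = int(round(config.n_snps * length / total))
        pos = np.sort(rng.integers(1, length, size=n))
        chroms.extend([chrom] * n)
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    n_snps = len(pos_all)
    chrom_all = np.array(chroms)

    # which clonal event covers each SNP, and which haplotype it keeps
    event_idx = np.full(n_snps, -1)
    all_events = [ev for evs in by_chrom.values() for ev in evs]
    for i, ev in enumerate(all_events):
        mask = (chrom_all == ev.chrom) & (pos_all > ev.start) & (pos_all <= ev.end)
        event_idx[mask] = i
    keep_alt = rng.random(n_snps) < 0.5  # kept haplotype, shared across samples

    frames = []
    for s in [*samples, "normal"]:
        depth = _draw_depth(
            rng, config.mean_distinct_coverage, config.coverage_dispersion, n_snps
        )
        if s == "normal":
            f = np.full(n_snps, 0.5)
        else:
            alpha = purities[s]
            f = np.full(n_snps, 0.5)
            for i, ev in enumerate(all_events):
                if not presence[ev.cluster][samples.index(s)]:
                    continue
                mask = event_idx == i
                f[mask] = np.where(
                    keep_alt[mask],
                    _snp_alt_fraction(alpha, ev, True),
                    _snp_alt_fraction(alpha, ev, False),
                )
        alt = rng.binomial(depth, f)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom_all,
                    "pos": pos_all,
                    "sample": s,
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _random_context(rng, k: int = 5) -> str:
    """Flanking bases around a mutation, guaranteed homopolymer-free center."""
    while True:
        ctx = "".join(rng.choice(BASES, size=2 * k + 1))
        if not _has_homopolymer(ctx, 5):
            return ctx


def _has_homopolymer(ctx: str, min_run: int) -> bool:
    run, best = 1, 1
    for a, b in zip(ctx, ctx[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best >= min_run


def _simulate_mutations(config, rng, samples, purities, presence, by_chrom):
    lengths = dict(config.genome_model)

    def covered_event(chrom, pos):
        for ev in by_chrom.get(chrom, []):
            if ev.start < pos <= ev.end:
                return ev
        return None

    rows = []
    truth_clusters: dict[str, int] = {}

    def add_mutation(mut_id, chrom, pos, cluster, multiplicity, cn_t,
                     fixed_depth=None):
        ref, alt_base = rng.choice(BASES, size=2, replace=False)
        ctx = _random_context(rng)
        truth_clusters[mut_id] = cluster
        for s in [*samples, "normal"]:
            if s == "normal":
                vaf = 0.0
            else:
                alpha = purities[s]
                cellularity = float(presence[cluster][samples.index(s)])
                vaf = multiplicity * alpha * cellularity / (
                    alpha * cn_t + (1 - alpha) * 2
                )
            if fixed_depth is not None:
                depth = fixed_depth
                alt_reads = int(rng.binomial(depth, vaf)) if depth else 0
            else:
                alt_reads, depth = simulate_read_counts(
                    vaf, config.mean_distinct_coverage, rng,
                    config.coverage_dispersion,
                )
            rows.append(
                {
                    "mutation_id": mut_id,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": str(ref),
                    "alt": str(alt_base),
                    "context": ctx,
                    "sample": s,
                    "distinct_coverage": depth,
                    "altered_reads": alt_reads,
                }
            )

    # ubiquitous TP53-like mutation inside the copy-neutral LOH on the root
    # edge: both tumor copies mutated, so expected VAF equals purity.  Its
    # depth is pinned at the sample-typical coverage: the locus's relative
    # capture efficiency is a fixed assay property, and the discovery filter
    # is calibrated against it, so resampling it from the dispersed per-locus
    # depth distribution would make whole patients' candidate yields bimodal.
    tp53_depth = int(round(config.mean_distinct_coverage))
    root_events = [
        e for evs in by_chrom.values() for e in evs
        if e.cluster == 0 and e.mode == COPY_NEUTRAL
    ]
    if root_events:
        ev = root_events[0]
        pos = int(rng.integers(ev.start + 1, ev.end))
        add_mutation("TP53_like", ev.chrom, pos, 0, multiplicity=2, cn_t=2,
                     fixed_depth=tp53_depth)
    else:
        # no copy-neutral root event: fall back to a single mutated copy
        chrom = next(iter(lengths))
        pos = int(rng.integers(1, lengths[chrom]))
        ev = covered_event(chrom, pos)
        add_mutation(
            "TP53_like", chrom, pos, 0,
            multiplicity=1, cn_t=ev.cn_t if ev else 2,
            fixed_depth=tp53_depth,
        )

    # cluster passengers on diploid loci (outside all LOH events)
    chrom_names = [c for c, _ in config.genome_model]
    for cluster in range(config.n_clusters):
        for j in range(config.n_mutations_per_cluster):
            while True:
                chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                pos = int(rng.integers(1, lengths[chrom]))
                if covered_event(chrom, pos) is None:
                    break
            add_mutation(f"M{cluster}_{j}", chrom, pos, cluster, 1, 2)

    return pd.DataFrame(rows), truth_clusters


def _founder_ages(config, tree, sample_nodes, truth_clusters, events):
    """Founder age per lesion: alterations accrue linearly in time, so a
    lesion's founder age is proportional to the alteration count on its path."""
    per_cluster: dict[int, int] = {}
    for cluster in truth_clusters.values():
        per_cluster[cluster] = per_cluster.get(cluster, 0) + 1
    for ev in events:
        per_cluster[ev.cluster] = per_cluster.get(ev.cluster, 0) + 1
    path_counts = {
        s: sum(per_cluster.get(c, 0) for c in tree.path_from_root(node))
        for s, node in sample_nodes.items()
    }
    latest = max(path_counts.values()) or 1
    return {
        s: config.patient_age * n / latest for s, n in path_counts.items()
    }


def simulate_bin_counts(
    patient: SyntheticPatient,
    sample: str,
    bin_size: int = 3_000_000,
    mean_normal_count: int = 500,
    delta: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned tumor/normal read counts consistent with the truth CN profile.

    Bin counts are Poisson; the tumor mean follows the mixture model
    (alpha * CN_T + (1 - alpha) * 2) / 2 times 2**-delta, where ``delta``
    injects a known genome-wide library-size bias for the normalization
    solver to recover.  Counts are assumed upstream-bias-corrected (GC,
    capture), so no other distortion is simulated.
    """
    rng = np.random.default_rng(seed)
    alpha = patient.sample_purities[sample]
    rows = []
    for chrom, length in patient.config.genome_model:
        starts = np.arange(0, length, bin_size)
        for start in starts:
            end = min(start + bin_size, length)
            mid = (start + end) // 2
            cn_t = 2
            for seg in patient.truth_segments:
                if (
                    seg.chrom == chrom
                    and seg.start <= mid < seg.end
                    and sample in seg.samples
                ):
                    cn_t = seg.cn_t
                    break
            normal = rng.poisson(mean_normal_count)
            mix = (alpha * cn_t + (1 - alpha) * 2) / 2.0
            tumor = rng.poisson(mean_normal_count * mix * 2.0 ** (-delta))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "tumor_count": int(tumor),
                    "normal_count": int(normal),
                }
            )
    return pd.DataFrame(rows)


def degrade_to_low_input(
    patient: SyntheticPatient,
    sample_id: str,
    keep_fraction: float,
    seed: int = 0,
) -> SyntheticPatient:
    """Thin one sample's reads to emulate a low-input p53 signature.

    Every read survives independently with probability ``keep_fraction``, so
    per-locus counts stay binomial with the same expected allele fraction but
    most SNPs drop below the 10x analysis threshold at small fractions.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if sample_id not in patient.sample_purities:
        raise KeyError(f"unknown sample {sample_id!r}")
    if keep_fraction == 1:
        return patient
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(patient)

    snp = out.snp_counts
    mask = snp["sample"] == sample_id
    for col in ("ref_count", "alt_count"):
        snp.loc[mask, col] = rng.binomial(snp.loc[mask, col], keep_fraction)

    mut = out.mutation_counts
    mask = mut["sample"] == sample_id
    alt = rng.binomial(mut.loc[mask, "altered_reads"], keep_fraction)
    wild = rng.binomial(
        mut.loc[mask, "distinct_coverage"] - mut.loc[mask, "altered_reads"],
        keep_fraction,
    )
    mut.loc[mask, "altered_reads"] = alt
    mut.loc[mask, "distinct_coverage"] = alt + wild
    out.config = replace(out.config, seed=out.config.seed)
    return out
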