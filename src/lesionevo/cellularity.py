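"""Purity, mutation cellularity, and presence-pattern clustering.

Sample purity comes straight from the ubiquitous TP53 mutation: with the
wild-type allele lost, every cancer cell contributes only mutant copies at
the locus, so the TP53 variant read fraction equals the fraction of
neoplastic cells.  Per-mutation cellularity C (cancer cell fraction) follows
from the expected variant allele fraction

    V_exp = m * alpha * C / (alpha * CN_T + (1 - alpha) * CN_N)

with multiplicity m = 1: observed alt reads are binomial at V_exp, and the
likelihood is profiled over a 101-point grid C = 0, 0.01, ..., 1 for the MLE
and a likelihood-ratio confidence interval.  Mutations are clustered by
identical presence/absence patterns across samples (presence: >= 2% allele
frequency and >= 2 distinct mutant reads), and chromosome-scale LOH markers
with identical patterns form feature groups, matched to mutation clusters
when the patterns coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants import NORMAL_SAMPLE, PresenceMatrix, propagate_presence

CELLULARITY_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

#: Likelihood-ratio drop for a 95% CI: chi2(1) quantile / 2.
_LR_CUTOFF = stats.chi2.ppf(0.95, df=1) / 2.0


def estimate_purity_tp53(tp53_alt: int, tp53_depth: int) -> float:
    """Sample purity as the TP53 variant read fraction.

    Valid when the TP53 wild-type allele is lost, so tumor cells carry only
    mutant copies.  Zero depth leaves purity undefined; zero alt reads flag
    a sample without tumor content.
    """
    if tp53_depth <= 0:
        raise ValueError("TP53 depth is zero; purity undefined for this sample")
    return tp53_alt / tp53_depth


@dataclass(frozen=True)
class CellularityEstimate:
    """Grid likelihood profile of one mutation's cancer cell fraction."""

    grid: np.ndarray
    loglik: np.ndarray
    mle: float
    ci: tuple[float, float]

    def __post_init__(self):
        assert self.ci[0] <= self.mle <= self.ci[1]


def expected_vaf(
    c: np.ndarray, alpha: float, cn_t: int, cn_n: int = 2, m: int = 1
) -> np.ndarray:
    return m * alpha * np.asarray(c) / (alpha * cn_t + (1 - alpha) * cn_n)


def mutation_cellularity(
    alt: int,
    depth: int,
    alpha: float,
    cn_t: int,
    cn_n: int = 2,
    m: int = 1,
) -> CellularityEstimate:
    """Grid-likelihood cellularity estimate for one mutation in one sample."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    v = expected_vaf(CELLULARITY_GRID, alpha, cn_t, cn_n, m)
    if v[-1] > 1:
        raise ValueError(
            f"V_exp(C=1) = {v[-1]:.3f} > 1; multiplicity/copy-number inputs "
            "are inconsistent"
        )
    loglik = stats.binom.logpmf(alt, depth, v)
    # V_exp = 0 at C = 0 gives -inf when alt > 0; that is a valid zero
    i = int(np.argmax(loglik))
    inside = loglik >= loglik[i] - _LR_CUTOFF
    ci = (float(CELLULARITY_GRID[inside].min()), float(CELLULARITY_GRID[inside].max()))
    return CellularityEstimate(
        grid=CELLULARITY_GRID, loglik=loglik, mle=float(CELLULARITY_GRID[i]), ci=ci
    )


def pooled_cellularity(
    alts: np.ndarray,
    depths: np.ndarray,
    alpha: float,
    cn_ts: np.ndarray,
    cn_n: int = 2,
    m: int = 1,
) -> CellularityEstimate:
    """Joint grid likelihood over a cluster's member mutations in one sample.

    Members share one cellularity; read counts are summed in the likelihood
    (independent binomials at each member's own expected VAF).
    """
    v = np.stack(
        [expected_vaf(CELLULARITY_GRID, alpha, cn_t, cn_n, m) for cn_t in cn_ts]
    )
    loglik = stats.binom.logpmf(
        np.asarray(alts)[:, None], np.asarray(depths)[:, None], v
    ).sum(axis=0)
    i = int(np.argmax(loglik))
    inside = loglik >= loglik[i] - _LR_CUTOFF
    ci = (float(CELLULARITY_GRID[inside].min()), float(CELLULARITY_GRID[inside].max()))
    return CellularityEstimate(
        grid=CELLULARITY_GRID, loglik=loglik, mle=float(CELLULARITY_GRID[i]), ci=ci
    )


@dataclass
class MutationCluster:
    """Mutations sharing one presence/absence pattern across samples."""

    cluster_id: str
    members: list[str]
    pattern: tuple[bool, ...]
    samples: list[str]
    #: per-sample pooled cellularity estimates, filled by estimate step
    cellularity: dict[str, CellularityEstimate] = field(default_factory=dict)

    @property
    def n_samples_present(self) -> int:
        return sum(self.pattern)

    def mle_vector(self) -> np.ndarray:
        return np.array([self.cellularity[s].mle for s in self.samples])


def build_presence(
    table: pd.DataFrame,
    vaf_min: float = 0.02,
    min_altered_reads: int = 2,
) -> PresenceMatrix:
    """Presence matrix at clustering stringency (2% VAF, 2 mutant reads)."""
    return propagate_presence(
        table, table, min_altered_reads=min_altered_reads, vaf_min=vaf_min
    )


def cluster_mutations(
    presence: PresenceMatrix,
    table: pd.DataFrame,
    purities: dict[str, float],
    cn_by_mutation: dict[str, dict[str, int]] | None = None,
    min_purity: float = 0.5,
) -> list[MutationCluster]:
    """Greedy agglomeration of identical presence patterns into clusters.

    Patterns (restricted to samples with purity >= ``min_purity``) are sorted
    by descending mutation support and exact matches merge.  Cluster
    cellularity per sample is estimated from the pooled member read counts.
    ``cn_by_mutation[mut][sample]`` supplies tumor copy number at each
    mutation; unresolved loci default to CN 2.
    """
    samples = [
        s for s in presence.samples
        if purities.get(s, 0.0) >= min_purity and s != NORMAL_SAMPLE
    ]
    if presence.matrix.empty or not samples:
        return []
    sub = presence.matrix[samples]

    by_pattern: dict[tuple[bool, ...], list[str]] = {}
    for mut_id, row in sub.iterrows():
        pat = tuple(bool(v) for v in row)
        if not any(pat):
            continue
        by_pattern.setdefault(pat, []).append(mut_id)

    ordered = sorted(
        by_pattern.items(), key=lambda kv: (-len(kv[1]), kv[0]), reverse=False
    )
    counts = table.set_index(["mutation_id", "sample"])

    clusters = []
    for i, (pat, members) in enumerate(ordered):
        cl = MutationCluster(
            cluster_id=f"C{i}", members=sorted(members), pattern=pat, samples=samples
        )
        for s in samples:
            alts, depths, cns = [], [], []
            for mut in cl.members:
                row = counts.loc[(mut, s)]
                alts.append(int(row["altered_reads"]))
                depths.append(int(row["distinct_coverage"]))
                cns.append(
                    (cn_by_mutation or {}).get(mut, {}).get(s, 2)
                )
            cl.cellularity[s] = pooled_cellularity(
                np.array(alts), np.array(depths), purities[s], np.array(cns)
            )
        clusters.append(cl)
    return clusters


@dataclass
class LohFeatureGroup:
    """Patient-level LOH markers sharing one presence pattern."""

    group_id: str
    members: list[str]          # marker ids
    pattern: tuple[bool, ...]
    samples: list[str]
    matched_cluster: str | None = None


def group_loh_features(
    patient_segments: pd.DataFrame,
    clusters: list[MutationCluster],
    samples: list[str],
) -> list[LohFeatureGroup]:
    """Group LOH markers by identical presence pattern and match clusters.

    A group whose pattern equals a mutation cluster's pattern is bound to
    that cluster (they are taken to have arisen together); unmatched groups
    are flagged for post-hoc placement on the tree.
    """
    by_pattern: dict[tuple[bool, ...], list[str]] = {}
    for seg in patient_segments.itertuples():
        pat = tuple(bool(getattr(seg, f"loh_{s}")) for s in samples)
        if not any(pat):
            continue
        by_pattern.setdefault(pat, []).append(seg.marker_id)

    cluster_patterns = {cl.pattern: cl.cluster_id for cl in clusters}
    groups = []
    for i, (pat, members) in enumerate(sorted(by_pattern.items(), key=str)):
        groups.append(
            LohFeatureGroup(
                group_id=f"G{i}",
                members=sorted(members),
                pattern=pat,
                samples=list(samples),
                matched_cluster=cluster_patterns.get(pat),
            )
        )
    return groups


def cluster_table(clusters: list[MutationCluster]) -> pd.DataFrame:
    """Flat per-(cluster, sample) table of cellularity estimates."""
    rows = []
    for cl in clusters:
        for s in cl.samples:
            est = cl.cellularity[s]
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "n_members": len(cl.members),
                    "sample": s,
                    "present": cl.pattern[cl.samples.index(s)],
                    "cellularity_mle": est.mle,
                    "ci_low": est.ci[0],
                    "ci_high": est.ci[1],
                }
            )
    return pd.DataFrame(rows)
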