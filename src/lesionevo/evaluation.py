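"""Self-validation benchmarks on synthetic cohorts.

Each function regenerates ground-truthed data, runs the corresponding
analysis stage, and reports a recovery metric.  All randomness is controlled
by an explicit seed, and problem sizes default to the generator's study
conditions scaled to a handful of lesions per patient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cellularity as cel
from . import copynumber as cn
from . import loh, phylogeny
from .segmentation import segment_series
from .synthetic import CohortConfig, LohEvent, simulate_patient
from .timing import beta_hpd
from .trees import GERMLINE

BENCH_GENOME = tuple((f"chr{i}", 100_000_000) for i in range(1, 7))


def _bench_config(seed: int, **overrides) -> CohortConfig:
    """Six 100 Mb chromosomes, 20 SNPs per 10 Mb, one LOH event per cluster."""
    defaults = dict(
        n_samples=3,
        n_clusters=3,
        n_snps=1200,
        purity_range=(0.5, 0.9),
        genome_model=BENCH_GENOME,
        loh_segments=(
            LohEvent("chr1", 0, 100_000_000, 0),
            LohEvent("chr2", 0, 100_000_000, 1),
            LohEvent("chr3", 0, 100_000_000, 2),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def _interval_overlap(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(
        max(0, min(hi, b) - max(lo, a)) for a, b in intervals
    )


def loh_benchmark(n_seeds: int = 50, seed: int = 0, n_perm: int = 300) -> dict:
    """Base-pair-weighted LOH sensitivity and false-positive rate.

    Patients have purity >= 0.5, >= 20 SNPs per 10 Mb at ~100x, and three
    whole-chromosome LOH events on known tree edges; three chromosomes stay
    balanced.  Sensitivity pools truth-LOH base pairs recovered by called-LOH
    segments across samples and seeds; the false-positive rate pools
    balanced base pairs wrongly called.
    """
    truth_bp = called_truth_bp = balanced_bp = called_balanced_bp = 0
    for i in range(n_seeds):
        patient = simulate_patient(_bench_config(seed + 1000 * i))
        genome = dict(patient.config.genome_model)
        normal_maf = loh.compute_maf(patient.snp_counts, "normal")
        for s in patient.tumor_samples:
            maf = loh.compute_maf(patient.snp_counts, s)
            segs = loh.segment_maf(maf, n_perm=n_perm, seed=seed)
            segs, _ = loh.call_loh(segs, normal_maf)
            called = [
                (r.start, r.end) for r in segs.itertuples() if r.loh
            ]
            for chrom, length in genome.items():
                analyzed = maf[maf.chrom == chrom]
                if analyzed.empty:
                    continue
                lo, hi = int(analyzed.pos.min()) - 1, int(analyzed.pos.max())
                called_here = [
                    (r.start, r.end) for r in segs.itertuples()
                    if r.loh and r.chrom == chrom
                ]
                has_truth = any(
                    t.chrom == chrom and s in t.samples
                    for t in patient.truth_segments
                )
                span = hi - lo
                if has_truth:
                    truth_bp += span
                    called_truth_bp += _interval_overlap(called_here, lo, hi)
                else:
                    balanced_bp += span
                    called_balanced_bp += _interval_overlap(called_here, lo, hi)
    return {
        "sensitivity": called_truth_bp / truth_bp,
        "false_positive_rate": called_balanced_bp / balanced_bp,
    }


def delta_recovery_benchmark(
    deltas: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    seed: int = 0,
    alpha: float = 0.8,
    bins_per_chrom: int = 60,
    mean_count: int = 500,
) -> dict:
    """Inject known genome-wide biases and re-solve them from anchors.

    Four chromosomes (two balanced at CN 2, one CN 1, one CN 3), Poisson bin
    counts at ~500 reads (log-ratio noise sigma ~ 0.09), 120 anchor bins.
    Reports the worst absolute delta error and whether noise-free profiles
    recover every integer copy state exactly.
    """
    rng = np.random.default_rng(seed)
    cn_map = {"chr1": 2, "chr2": 2, "chr3": 1, "chr4": 3}
    genome = {c: bins_per_chrom * 1_000_000 for c in cn_map}
    balanced = pd.DataFrame(
        [{"chrom": c, "start": 0, "end": genome[c]} for c in ("chr1", "chr2")]
    )
    max_err = 0.0
    exact_integers = True
    for delta in deltas:
        for noisy in (True, False):
            rows = []
            for chrom, cnv in cn_map.items():
                ratio = (alpha * cnv + (1 - alpha) * 2) / 2 * 2.0 ** (-delta)
                for b in range(bins_per_chrom):
                    n = rng.poisson(mean_count) if noisy else mean_count
                    t = rng.poisson(ratio * mean_count) if noisy else ratio * mean_count
                    rows.append(
                        {"chrom": chrom, "start": b * 1_000_000,
                         "end": (b + 1) * 1_000_000,
                         "tumor_count": t, "normal_count": n}
                    )
            prof = cn.build_log_ratio(
                pd.DataFrame(rows), seed=seed, n_perm=300, center=False
            )
            sol = cn.solve_profile(prof, balanced, alpha, genome=genome)
            if noisy:
                max_err = max(max_err, abs(sol.delta - delta))
            else:
                got = dict(zip(sol.segments.chrom, sol.segments.cn_t))
                exact_integers &= got == cn_map
    return {"max_delta_error": max_err, "noise_free_cn_exact": exact_integers}


def cellularity_grid_benchmark(n_instances: int = 1000, seed: int = 0) -> dict:
    """Worst deviation of the grid MLE from the closed-form estimate."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        alpha = rng.uniform(0.3, 1.0)
        cn_t = int(rng.integers(1, 5))
        depth = int(rng.integers(30, 300))
        v = alpha * rng.uniform(0, 1) / (alpha * cn_t + (1 - alpha) * 2)
        alt = int(rng.binomial(depth, v))
        est = cel.mutation_cellularity(alt, depth, alpha, cn_t)
        closed = min(
            1.0, alt * (alpha * cn_t + (1 - alpha) * 2) / (depth * alpha)
        )
        worst = max(worst, abs(est.mle - closed))
    return {"max_grid_deviation": worst}


def cluster_cellularity_benchmark(n_seeds: int = 20, seed: int = 0) -> dict:
    """RMSE of pooled cluster cellularity vs truth at ~100x, purity >= 0.5."""
    sq = []
    for i in range(n_seeds):
        patient = simulate_patient(
            CohortConfig(
                n_samples=5, n_clusters=4, n_snps=200,
                n_mutations_per_cluster=12, purity_range=(0.5, 0.9),
                seed=seed + 1000 * i,
            )
        )
        pres = cel.build_presence(patient.mutation_counts)
        clusters = cel.cluster_mutations(
            pres, patient.mutation_counts, patient.sample_purities
        )
        truth_patterns = {
            tuple(v): k
            for k, v in patient.truth_tree.cluster_presence(
                patient.tumor_samples
            ).items()
        }
        for cl in clusters:
            if cl.pattern in truth_patterns:
                truth = np.array([float(b) for b in cl.pattern])
                sq.extend((cl.mle_vector() - truth) ** 2)
    return {"rmse": float(np.sqrt(np.mean(sq)))}


def recover_topology(seed: int, topology=None, n_samples: int = 5) -> bool:
    """One tree-recovery trial: estimated purities, presence clustering,
    exhaustive search; True iff the unique co-optimal tree is the truth."""
    patient = simulate_patient(
        CohortConfig(
            n_samples=n_samples, n_clusters=4, n_snps=200,
            purity_range=(0.6, 0.9), tree_topology=topology, seed=seed,
        )
    )
    tp53 = patient.mutation_counts.query(
        "mutation_id == 'TP53_like' and sample != 'normal'"
    ).set_index("sample")
    purities = {
        s: cel.estimate_purity_tp53(
            int(r["altered_reads"]), int(r["distinct_coverage"])
        )
        for s, r in tp53.iterrows()
    }
    pres = cel.build_presence(patient.mutation_counts)
    clusters = cel.cluster_mutations(pres, patient.mutation_counts, purities)
    ubiq = [c.cluster_id for c in clusters if all(c.pattern)]
    if len(clusters) != 4 or not ubiq:
        return False
    matrix = phylogeny.precedence_matrix(clusters)
    trees = phylogeny.search_trees(matrix, clusters, ubiq[0])
    if len(trees) != 1:
        return False
    patmap = {
        tuple(v): k
        for k, v in patient.truth_tree.cluster_presence(
            patient.tumor_samples
        ).items()
    }
    rec = {c.cluster_id: patmap.get(c.pattern) for c in clusters}
    if any(v is None for v in rec.values()):
        return False
    inferred = {
        rec[c]: (rec[p] if p != GERMLINE else GERMLINE)
        for c, p in trees[0].parent.items()
    }
    return inferred == patient.truth_tree.parent


def tree_recovery_benchmark(n_seeds: int = 50, seed: int = 0) -> dict:
    hits = sum(recover_topology(seed + 1000 * i) for i in range(n_seeds))
    return {"recovery_rate": hits / n_seeds}


def search_agreement_benchmark(n_instances: int = 100, seed: int = 0) -> dict:
    """Exhaustive vs hill-climb co-optimal sets on 5-cluster instances."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        clusters = _random_cluster_instance(rng, n_clusters=5, n_samples=5)
        matrix = phylogeny.precedence_matrix(clusters)
        exhaustive = phylogeny.search_trees(
            matrix, clusters, clusters[0].cluster_id
        )
        heuristic = phylogeny.search_trees(
            matrix, clusters, clusters[0].cluster_id,
            max_exhaustive=0, seed=int(rng.integers(2**31)), n_restarts=60,
        )
        agree += {frozenset(t.parent.items()) for t in exhaustive} == {
            frozenset(t.parent.items()) for t in heuristic
        }
    return {"agreement_rate": agree / n_instances}


def _random_cluster_instance(rng, n_clusters, n_samples):
    parent = {0: GERMLINE}
    for c in range(1, n_clusters):
        parent[c] = int(rng.integers(0, c))
    clusters = []
    for c in range(n_clusters):
        below = {c}
        changed = True
        while changed:
            changed = False
            for k, p in parent.items():
                if p in below and k not in below:
                    below.add(k)
                    changed = True
        mles = [
            min(1.0, max(0.0, float(s in below) + rng.normal(0, 0.02)))
            for s in range(n_samples)
        ]
        cl = cel.MutationCluster(
            cluster_id=f"C{c}", members=[f"C{c}_m"],
            pattern=tuple(s in below for s in range(n_samples)),
            samples=[f"S{i}" for i in range(n_samples)],
        )
        for s, m in zip(cl.samples, mles):
            cl.cellularity[s] = cel.CellularityEstimate(
                grid=cel.CELLULARITY_GRID, loglik=np.zeros(101),
                mle=float(m), ci=(float(m), float(m)),
            )
        clusters.append(cl)
    return clusters


def parsimony_concordance_benchmark(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of synthetic matrices where the cellularity-based tree is
    hierarchy-compatible with an exhaustive maximum-parsimony sample tree."""
    hits = trials = 0
    for i in range(n_seeds):
        patient = simulate_patient(
            CohortConfig(
                n_samples=5, n_clusters=4, n_snps=200,
                purity_range=(0.6, 0.9), seed=seed + 1000 * i,
            )
        )
        pres = cel.build_presence(patient.mutation_counts)
        clusters = cel.cluster_mutations(
            pres, patient.mutation_counts, patient.sample_purities
        )
        ubiq = [c.cluster_id for c in clusters if all(c.pattern)]
        if not ubiq:
            continue
        matrix = phylogeny.precedence_matrix(clusters)
        clone_tree = phylogeny.search_trees(matrix, clusters, ubiq[0])[0]
        pars = phylogeny.parsimony_oracle(pres.matrix)
        trials += 1
        hits += any(
            phylogeny.clone_tree_compatible(clone_tree, t) for t in pars
        )
    return {"concordance": hits / trials, "n": trials}


def timing_calibration_benchmark(
    n_replicates: int = 200,
    truth_ratio: float = 0.8,
    n_late: int = 60,
    prior: tuple[float, float] = (1.0, 1.0),
    level: float = 0.90,
    seed: int = 0,
) -> dict:
    """Frequentist coverage of the HPD under simulated linear accrual.

    The flat prior is used so the interval's frequentist behavior is
    measured rather than prior informativeness; see the methods note.
    """
    rng = np.random.default_rng(seed)
    a, b = prior
    hits = 0
    for _ in range(n_replicates):
        n_early = int(rng.binomial(n_late, truth_ratio))
        lo, hi = beta_hpd(a + n_early, b + (n_late - n_early), level)
        hits += lo <= truth_ratio <= hi
    return {"coverage": hits / n_replicates}
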