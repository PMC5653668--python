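"""Somatic-mutation candidate screening across a patient's lesions.

The cascade mirrors a stringent multi-region exome filter: a candidate must,
in at least one sample, be altered in more than 10% of distinct reads with at
least 5 altered reads, at a base covered at least as deeply as the patient's
TP53 alteration, and at more than 20% of that sample's mean coverage.  Once a
candidate is identified anywhere, far weaker evidence (two distinct altered
reads, at least 1% of reads) suffices to call it present in the patient's
other samples.  Context filters then drop homopolymer-tract artifacts and
low-coverage candidates; a pluggable hook accepts any additional uniqueness
screen on (chrom, pos, context).

Mutation tables are long-form DataFrames with one row per (mutation, sample):
columns mutation_id, chrom, pos, ref, alt, context, sample, distinct_coverage,
altered_reads.  The matched normal sample, if present, is ignored by the
per-sample rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

NORMAL_SAMPLE = "normal"

MUTATION_COLUMNS = [
    "mutation_id", "chrom", "pos", "ref", "alt", "context",
    "sample", "distinct_coverage", "altered_reads",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean mutations x samples matrix plus the thresholds that built it."""

    matrix: pd.DataFrame
    vaf_min: float
    min_altered_reads: int

    @property
    def mutations(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def pattern(self, mutation_id: str) -> tuple[bool, ...]:
        return tuple(bool(v) for v in self.matrix.loc[mutation_id])


def _tumor(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["sample"] != NORMAL_SAMPLE]


def call_candidates(
    table: pd.DataFrame,
    tp53_coverage: dict[str, float],
    mean_coverage: dict[str, float],
    vaf_min: float = 0.10,
    min_altered_reads: int = 5,
    coverage_ratio_min: float = 0.20,
) -> pd.DataFrame:
    """Identify candidate somatic mutations at discovery stringency.

    A mutation is retained if, in at least one tumor sample, all of:
    altered fraction > ``vaf_min`` of distinct reads; altered reads
    >= ``min_altered_reads``; distinct coverage at the base at least as high
    as that sample's TP53 alteration coverage; and distinct coverage more
    than ``coverage_ratio_min`` of the sample's mean coverage.

    Returns the table restricted to retained mutations (all samples' rows).
    """
    tumor = _tumor(table)
    missing = set(tumor["sample"]) - set(tp53_coverage) - {NORMAL_SAMPLE}
    missing |= set(tumor["sample"]) - set(mean_coverage) - {NORMAL_SAMPLE}
    if missing:
        raise ValueError(f"missing per-sample coverage for {sorted(missing)}")

    depth = tumor["distinct_coverage"].to_numpy(dtype=float)
    alt = tumor["altered_reads"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    tp53 = tumor["sample"].map(tp53_coverage).to_numpy(dtype=float)
    mean = tumor["sample"].map(mean_coverage).to_numpy(dtype=float)
    ok = (
        (frac > vaf_min)
        & (alt >= min_altered_reads)
        & (depth >= tp53)
        & (depth / mean > coverage_ratio_min)
    )
    keep = set(tumor.loc[ok, "mutation_id"])
    return table[table["mutation_id"].isin(keep)].reset_index(drop=True)


def propagate_presence(
    candidates: pd.DataFrame,
    table: pd.DataFrame,
    min_altered_reads: int = 2,
    vaf_min: float = 0.01,
) -> PresenceMatrix:
    """Cross-sample presence of identified candidates at detection stringency.

    Presence in a sample requires at least ``min_altered_reads`` distinct
    altered reads and an altered fraction of at least ``vaf_min`` — the
    detection floor of alterations in >= 1% of reads.
    """
    cand_ids = set(candidates["mutation_id"])
    if not cand_ids <= set(table["mutation_id"]):
        raise ValueError("candidates must be a subset of the full table")
    tumor = _tumor(table[table["mutation_id"].isin(cand_ids)]).copy()
    depth = tumor["distinct_coverage"].to_numpy(dtype=float)
    alt = tumor["altered_reads"].to_numpy(dtype=float)
    frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    tumor["present"] = (alt >= min_altered_reads) & (frac >= vaf_min)
    matrix = (
        tumor.pivot_table(
            index="mutation_id", columns="sample", values="present",
            aggfunc="any", fill_value=False,
        )
        .astype(bool)
        .sort_index()
    )
    matrix.columns.name = None
    return PresenceMatrix(
        matrix=matrix, vaf_min=vaf_min, min_altered_reads=min_altered_reads
    )


def in_homopolymer(context: str, min_run: int = 5) -> bool:
    """True if the center base of ``context`` sits in a run of >= min_run
    identical reference bases (indels are assumed leftmost-aligned, so the
    center position is the run entry point)."""
    if len(context) < 2 * min_run + 1 or len(context) % 2 == 0:
        raise ValueError(
            f"context must cover >= {min_run} bases each side of the variant"
        )
    center = len(context) // 2
    run_start = center
    while run_start > 0 and context[run_start - 1] == context[center]:
        run_start -= 1
    run_end = center
    while run_end + 1 < len(context) and context[run_end + 1] == context[center]:
        run_end += 1
    return run_end - run_start + 1 >= min_run


def apply_context_filters(
    candidates: pd.DataFrame,
    min_avg_coverage: float = 50.0,
    min_homopolymer_run: int = 5,
    uniqueness_hook: Callable[[str, int, str], bool] | None = None,
) -> pd.DataFrame:
    """Drop artifact-prone candidates after discovery.

    Removes candidates whose variant base lies in a homopolymer tract of
    ``min_homopolymer_run`` or more identical bases, and candidates whose
    across-sample average distinct coverage is below ``min_avg_coverage``.
    ``uniqueness_hook(chrom, pos, context) -> bool`` (True = keep) stands in
    for an alignment-uniqueness screen such as BLAT.
    """
    meta = candidates.drop_duplicates("mutation_id").set_index("mutation_id")
    avg_cov = _tumor(candidates).groupby("mutation_id")["distinct_coverage"].mean()

    keep = []
    for mut_id, row in meta.iterrows():
        if in_homopolymer(row["context"], min_homopolymer_run):
            continue
        if avg_cov.get(mut_id, 0.0) < min_avg_coverage:
            continue
        if uniqueness_hook is not None and not uniqueness_hook(
            row["chrom"], int(row["pos"]), row["context"]
        ):
            continue
        keep.append(mut_id)
    return candidates[candidates["mutation_id"].isin(keep)].reset_index(drop=True)


def screen(
    table: pd.DataFrame,
    tp53_coverage: dict[str, float],
    mean_coverage: dict[str, float],
    uniqueness_hook: Callable[[str, int, str], bool] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, PresenceMatrix]:
    """Full cascade: discovery, context filters, presence propagation."""
    cands = call_candidates(table, tp53_coverage, mean_coverage, **kwargs)
    cands = apply_context_filters(cands, uniqueness_hook=uniqueness_hook)
    return cands, propagate_presence(cands, table)
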