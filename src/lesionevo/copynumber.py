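"""Integer copy number from tumor/normal read-count log ratios.

Median-centering binned log ratios assumes a median ploidy of two, which
fails in genomes with pervasive aneuploidy; the residual genome-wide shift
delta is instead solved from anchor regions of complete allelic balance,
which can only hold an even number of copies.  With purity alpha and normal
copy number CN_N, the expected log ratio of a segment at tumor copy number
CN_T is

    R = log2((alpha * CN_T + (1 - alpha) * CN_N) / 2) - delta

Anchors are first fixed at CN 2; if the resulting profile implies
chromosome-scale homozygous deletions the anchors are re-fixed at CN 4 and
the profile re-solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import segment_series

MB = 1_000_000


@dataclass
class LogRatioProfile:
    """Binned log2 ratios plus their piecewise-constant segmentation."""

    bins: pd.DataFrame       # chrom, start, end, log2_ratio
    segments: pd.DataFrame   # chrom, start, end, n_bins, log2_ratio


@dataclass
class CnSolution:
    """Integer profile with the solved bias and the anchoring decisions."""

    delta: float
    alpha: float
    anchor_cn: int
    anchors: pd.DataFrame
    segments: pd.DataFrame   # chrom, start, end, log2_ratio, cn_t
    plausible: bool

    def report(self) -> dict:
        return {
            "delta": self.delta,
            "alpha": self.alpha,
            "anchor_cn": self.anchor_cn,
            "plausible": self.plausible,
            "anchors": self.anchors.to_dict(orient="records"),
        }


def build_log_ratio(
    bins: pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_size: int = 3,
    center: bool = True,
) -> LogRatioProfile:
    """Log2 tumor/normal ratio per bin, median-centered, then segmented.

    ``bins`` needs chrom, start, end, tumor_count, normal_count with
    bias-corrected counts; bins with zero normal count are masked.
    ``center=False`` skips the median-ploidy-2 centering so a known injected
    bias is carried through to the solver untouched.  Segmentation uses the
    same engine as the allelic-imbalance analysis and never crosses
    chromosome boundaries.
    """
    df = bins.copy()
    df = df[df["normal_count"] > 0].reset_index(drop=True)
    ratio = df["tumor_count"] / df["normal_count"]
    with np.errstate(divide="ignore"):
        r = np.log2(ratio.to_numpy(dtype=float))
    if center:
        r = r - np.median(r[np.isfinite(r)])
    df["log2_ratio"] = r
    df = df[np.isfinite(df["log2_ratio"])].reset_index(drop=True)

    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        for seg in segment_series(
            grp["log2_ratio"].to_numpy(), alpha=alpha, n_perm=n_perm,
            min_size=min_size, seed=seed,
        ):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(grp["start"].iloc[seg.start]),
                    "end": int(grp["end"].iloc[seg.end - 1]),
                    "n_bins": seg.n,
                    "log2_ratio": seg.mean,
                }
            )
    return LogRatioProfile(bins=df, segments=pd.DataFrame(rows))


def select_anchor_regions(
    segments: pd.DataFrame,
    balanced_regions: pd.DataFrame,
    level_tolerance: float = 0.30,
) -> pd.DataFrame:
    """Anchor segments: allelically balanced and at one common ratio level.

    ``balanced_regions`` (chrom, start, end) are intervals without allelic
    imbalance in any sample (or a manual override).  Segments overlapping
    them are grouped into ratio levels within ``level_tolerance`` log2 units;
    when several levels appear (e.g. two balanced regions ~0.6 apart, one
    even copy state above the other), only the level covering the most
    genome is kept.
    """
    hits = []
    for seg in segments.itertuples():
        for reg in balanced_regions.itertuples():
            if seg.chrom == reg.chrom and seg.start < reg.end and reg.start < seg.end:
                hits.append(seg._asdict())
                break
    anchors = pd.DataFrame(hits)
    if anchors.empty:
        raise ValueError(
            "no balanced anchor region found; supply a manual override"
        )
    anchors = anchors.sort_values("log2_ratio").reset_index(drop=True)
    # single-linkage grouping of ratio levels
    level_ids, level = [], 0
    prev = None
    for r in anchors["log2_ratio"]:
        if prev is not None and r - prev > level_tolerance:
            level += 1
        level_ids.append(level)
        prev = r
    anchors["level"] = level_ids
    anchors["length"] = anchors["end"] - anchors["start"]
    best = anchors.groupby("level")["length"].sum().idxmax()
    return anchors[anchors["level"] == best].drop(columns=["level", "length"])


def solve_bias(
    anchor_r: float, alpha: float, anchor_cn: int = 2, cn_normal: int = 2
) -> float:
    """Solve the genome-wide bias delta given the anchors' copy state."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(
        np.log2((alpha * anchor_cn + (1 - alpha) * cn_normal) / 2.0) - anchor_r
    )


def expected_log_ratio(
    cn_t: np.ndarray, alpha: float, delta: float, cn_normal: int = 2
) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2((alpha * np.asarray(cn_t) + (1 - alpha) * cn_normal) / 2.0) - delta


def assign_integer_cn(
    segments: pd.DataFrame,
    alpha: float,
    delta: float,
    cn_normal: int = 2,
    max_cn: int = 8,
) -> pd.DataFrame:
    """Nearest-integer copy state per segment under the solved bias.

    CN_T minimizes |R_observed - R_expected(CN)| over 0..max_cn; exact
    midpoint ties resolve toward the lower copy number (the less complex
    genome).
    """
    grid = np.arange(0, max_cn + 1)
    expect = expected_log_ratio(grid, alpha, delta, cn_normal)
    out = segments.copy()
    resid = np.abs(out["log2_ratio"].to_numpy()[:, None] - expect[None, :])
    out["cn_t"] = grid[np.argmin(resid, axis=1)]  # argmin takes first=lowest on ties
    return out


def _implausible(
    segments: pd.DataFrame,
    genome: dict[str, int] | None,
    min_del_mb: float = 25.0,
    arm_fraction: float = 0.80,
) -> bool:
    """Chromosome(-arm)-scale homozygous deletion test.

    A CN 0 segment of >= ``min_del_mb`` megabases, or covering >=
    ``arm_fraction`` of its chromosome when lengths are known, marks the
    solution implausible.
    """
    zero = segments[segments["cn_t"] == 0]
    for seg in zero.itertuples():
        length = seg.end - seg.start
        if length >= min_del_mb * MB:
            return True
        if genome and seg.chrom in genome:
            if length >= arm_fraction * genome[seg.chrom] / 2:
                return True
    return False


def solve_profile(
    profile: LogRatioProfile,
    balanced_regions: pd.DataFrame,
    alpha: float,
    cn_normal: int = 2,
    max_cn: int = 8,
    genome: dict[str, int] | None = None,
) -> CnSolution:
    """Full solve: anchors, bias at CN 2, plausibility, CN-4 fallback.

    Raises if neither anchor level yields a plausible profile, reporting
    both candidate deltas in the error message.
    """
    anchors = select_anchor_regions(profile.segments, balanced_regions)
    anchor_r = float(
        np.average(anchors["log2_ratio"], weights=anchors["n_bins"])
    )
    attempts = {}
    for anchor_cn in (2, 4):
        delta = solve_bias(anchor_r, alpha, anchor_cn, cn_normal)
        segs = assign_integer_cn(profile.segments, alpha, delta, cn_normal, max_cn)
        plausible = not _implausible(segs, genome)
        attempts[anchor_cn] = (delta, segs, plausible)
        if plausible:
            return CnSolution(
                delta=delta, alpha=alpha, anchor_cn=anchor_cn, anchors=anchors,
                segments=segs, plausible=True,
            )
    raise ValueError(
        "no plausible integer profile at anchor CN 2 or 4; candidate deltas: "
        + ", ".join(f"CN{cn}: {d:.4f}" for cn, (d, _, _) in attempts.items())
    )
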