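"""Loss-of-heterozygosity analysis from germline heterozygous SNP counts.

Per sample: minor-allele frequencies (MAF) at covered germline het SNPs are
segmented into piecewise-constant runs, segments are called LOH when the
tumor MAF falls at least 0.10 below the matched normal, and each LOH segment
gets a confidence tier against the sample's purity proxy (its minimum MAF
over segments of at least 10 Mb — the cleanest attainable LOH level).

Per patient: sample-level segments are intersected into patient-level
segments honoring variable breakpoints, filtered for marker support, size,
confidence, and MAF separation between carrier and non-carrier samples, and
over-segmented neighbours are merged back.

Low-input samples (p53 signatures) with too few covered SNPs are genotyped
per patient segment by pooling minor-allele reads across all the segment's
SNPs, with each SNP's minor allele fixed by majority vote over the
well-covered samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .segmentation import segment_series

MB = 1_000_000

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_snps", "maf_tumor", "maf_normal",
                   "loh", "confidence"]


def compute_maf(
    snp_counts: pd.DataFrame, sample: str, min_coverage: int = 10
) -> pd.DataFrame:
    """Per-SNP minor allele frequency for one sample.

    MAF = min(ref, alt) / (ref + alt) at loci with depth >= ``min_coverage``;
    under-covered loci are excluded.  Returns chrom, pos, ref_count,
    alt_count, maf sorted by genomic position.
    """
    df = snp_counts[snp_counts["sample"] == sample].copy()
    depth = df["ref_count"] + df["alt_count"]
    df = df[depth >= min_coverage]
    if df.empty:
        warnings.warn(f"sample {sample!r} has no SNPs at >= {min_coverage}x")
        return pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count", "maf"])
    depth = df["ref_count"] + df["alt_count"]
    df["maf"] = np.minimum(df["ref_count"], df["alt_count"]) / depth
    return (
        df[["chrom", "pos", "ref_count", "alt_count", "maf"]]
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )


def segment_maf(
    maf_series: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment per-SNP MAFs into piecewise-constant runs per chromosome.

    Returns chrom, start, end (bp, 0-based half-open, spanning the member
    SNPs), n_snps, maf_tumor.  Segmentation never crosses chromosome
    boundaries and is deterministic for a fixed seed.
    """
    rows = []
    for chrom, grp in maf_series.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        for seg in segment_series(
            grp["maf"].to_numpy(), alpha=alpha, n_perm=n_perm,
            min_size=min_size, seed=seed,
        ):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[seg.start]) - 1,
                    "end": int(pos[seg.end - 1]),
                    "n_snps": seg.n,
                    "maf_tumor": seg.mean,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "maf_tumor"])


def _interval_maf(maf_df: pd.DataFrame, chrom: str, start: int, end: int):
    """Mean MAF and SNP count of one 0-based half-open interval."""
    sel = maf_df[
        (maf_df["chrom"] == chrom) & (maf_df["pos"] > start) & (maf_df["pos"] <= end)
    ]
    return (float(sel["maf"].mean()) if len(sel) else np.nan), len(sel)


def call_loh(
    segments: pd.DataFrame,
    normal_maf: pd.DataFrame,
    threshold: float = 0.10,
    min_proxy_mb: float = 10.0,
) -> tuple[pd.DataFrame, float]:
    """Label segments as LOH and grade confidence against the purity proxy.

    A segment is LOH when normal MAF minus tumor MAF exceeds ``threshold``
    (signed: only suppressed tumor MAF counts).  The purity proxy is the
    minimum tumor MAF over segments of at least ``min_proxy_mb`` megabases;
    LOH confidence is high when the segment MAF is within 0.1 of that
    minimum, intermediate within 0.1-0.2, low beyond 0.2.

    Returns (segments with maf_normal/loh/confidence columns, purity proxy).
    """
    out = segments.copy()
    out["maf_normal"] = [
        _interval_maf(normal_maf, r.chrom, r.start, r.end)[0]
        for r in out.itertuples()
    ]
    out["loh"] = (out["maf_normal"] - out["maf_tumor"]) > threshold

    big = out[(out["end"] - out["start"]) >= min_proxy_mb * MB]
    if big.empty:
        warnings.warn("no segment >= 10 Mb; purity proxy undefined")
        proxy = np.nan
    else:
        proxy = float(big["maf_tumor"].min())

    def grade(row):
        if not row.loh or np.isnan(proxy):
            return None
        excess = row.maf_tumor - proxy
        if excess <= 0.1:
            return "high"
        if excess <= 0.2:
            return "intermediate"
        return "low"

    out["confidence"] = [grade(r) for r in out.itertuples()]
    return out, proxy


def analyze_sample(
    snp_counts: pd.DataFrame,
    sample: str,
    normal_sample: str = "normal",
    min_coverage: int = 10,
    threshold: float = 0.10,
    seed: int = 0,
    **segment_kwargs,
) -> tuple[pd.DataFrame, float]:
    """MAF computation, segmentation, and LOH calling for one sample."""
    tumor_maf = compute_maf(snp_counts, sample, min_coverage)
    normal_maf = compute_maf(snp_counts, normal_sample, min_coverage)
    segs = segment_maf(tumor_maf, seed=seed, **segment_kwargs)
    return call_loh(segs, normal_maf, threshold=threshold)


def harmonize_patient_segments(
    sample_segments: dict[str, pd.DataFrame],
    sample_maf: dict[str, pd.DataFrame],
    normal_maf: pd.DataFrame,
    purity_proxy: dict[str, float],
    threshold: float = 0.10,
    min_snps: int = 20,
    min_length_mb: float = 10.0,
    merge_window_mb: float = 5.0,
    merge_maf_tol: float = 0.05,
    min_maf_gap: float = 0.10,
) -> pd.DataFrame:
    """Intersect sample-level segments into patient-level LOH markers.

    Per chromosome, the union of all samples' breakpoints defines atomic
    intervals; per-sample MAF and LOH are recomputed on each.  Adjacent
    intervals with identical LOH calls, per-sample MAF differences at most
    ``merge_maf_tol``, and boundary gaps within ``merge_window_mb`` are
    merged to undo over-segmentation.  Kept markers must span at least
    ``min_snps`` SNPs in every sample and ``min_length_mb`` megabases, show
    high-confidence LOH in at least one sample, and separate carrier from
    non-carrier samples by at least ``min_maf_gap`` in MAF.

    Returns one row per marker with per-sample ``maf_<s>``, ``loh_<s>`` and
    ``conf_<s>`` columns.
    """
    if len(sample_segments) < 2:
        raise ValueError("patient-level harmonization needs >= 2 tumor samples")
    samples = sorted(sample_segments)
    rows = []
    chroms = sorted(
        {c for segs in sample_segments.values() for c in segs["chrom"]}, key=str
    )
    for chrom in chroms:
        cuts = sorted(
            {
                int(b)
                for s in samples
                for b in sample_segments[s]
                .loc[sample_segments[s]["chrom"] == chrom, ["start", "end"]]
                .to_numpy()
                .ravel()
            }
        )
        atoms = [
            _atom_row(chrom, lo, hi, samples, sample_maf, normal_maf,
                      purity_proxy, threshold)
            for lo, hi in zip(cuts, cuts[1:])
        ]
        atoms = [a for a in atoms if a is not None]
        rows.extend(_merge_atoms(atoms, samples, merge_window_mb, merge_maf_tol))

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    keep = (
        (out["n_snps"] >= min_snps)
        & ((out["end"] - out["start"]) >= min_length_mb * MB)
        & out.apply(lambda r: _marker_ok(r, samples, min_maf_gap), axis=1)
    )
    out = out[keep].reset_index(drop=True)
    out.insert(0, "marker_id", [f"L{i}" for i in range(len(out))])
    return out


def _atom_row(chrom, lo, hi, samples, sample_maf, normal_maf, proxy, threshold):
    maf_n, n_norm = _interval_maf(normal_maf, chrom, lo, hi)
    if n_norm == 0:
        return None
    row = {"chrom": chrom, "start": lo, "end": hi, "maf_normal": maf_n}
    n_min = np.inf
    for s in samples:
        maf_t, n = _interval_maf(sample_maf[s], chrom, lo, hi)
        n_min = min(n_min, n)
        loh = bool((maf_n - maf_t) > threshold) if not np.isnan(maf_t) else False
        row[f"maf_{s}"] = maf_t
        row[f"loh_{s}"] = loh
        row[f"conf_{s}"] = _confidence(maf_t, proxy.get(s)) if loh else None
    row["n_snps"] = 0 if not np.isfinite(n_min) else int(n_min)
    return row


def _confidence(maf_t: float, proxy: float | None) -> str | None:
    if proxy is None or np.isnan(proxy):
        return None
    excess = maf_t - proxy
    if excess <= 0.1:
        return "high"
    if excess <= 0.2:
        return "intermediate"
    return "low"


def _merge_atoms(atoms, samples, merge_window_mb, merge_maf_tol):
    merged = []
    for atom in atoms:
        if merged and _mergeable(merged[-1], atom, samples,
                                 merge_window_mb, merge_maf_tol):
            merged[-1] = _merge_pair(merged[-1], atom, samples)
        else:
            merged.append(dict(atom))
    return merged


def _mergeable(a, b, samples, window_mb, maf_tol):
    if b["start"] - a["end"] > window_mb * MB:
        return False
    for s in samples:
        if a[f"loh_{s}"] != b[f"loh_{s}"]:
            return False
        ma, mb_ = a[f"maf_{s}"], b[f"maf_{s}"]
        if np.isnan(ma) or np.isnan(mb_) or abs(ma - mb_) > maf_tol:
            return False
    return True


def _merge_pair(a, b, samples):
    wa, wb = max(a["n_snps"], 1), max(b["n_snps"], 1)
    out = dict(a)
    out["end"] = b["end"]
    out["n_snps"] = a["n_snps"] + b["n_snps"]
    for col in [f"maf_{s}" for s in samples] + ["maf_normal"]:
        out[col] = (a[col] * wa + b[col] * wb) / (wa + wb)
    for s in samples:
        # identical calls were a merge precondition; keep the better tier
        tiers = {None: 3, "low": 2, "intermediate": 1, "high": 0}
        out[f"conf_{s}"] = min(
            (a[f"conf_{s}"], b[f"conf_{s}"]), key=lambda t: tiers[t]
        )
    return out


def _marker_ok(row, samples, min_maf_gap) -> bool:
    carriers = [s for s in samples if row[f"loh_{s}"]]
    others = [s for s in samples if not row[f"loh_{s}"]]
    if not any(row[f"conf_{s}"] == "high" for s in carriers):
        return False
    if carriers and others:
        gap = min(row[f"maf_{s}"] for s in others) - max(
            row[f"maf_{s}"] for s in carriers
        )
        if gap < min_maf_gap:
            return False
    return True


def pooled_loh_low_input(
    patient_segments: pd.DataFrame,
    snp_counts: pd.DataFrame,
    low_input_sample: str,
    voting_samples: list[str],
    normal_sample: str = "normal",
    min_vote_coverage: int = 10,
    margin: float = 0.10,
) -> pd.DataFrame:
    """Pooled LOH calls for a low-input sample on predefined patient segments.

    Each SNP's minor allele (ref or alt) is fixed by majority vote over the
    well-covered ``voting_samples`` (ties broken by pooled read counts).  The
    segment MAF of the low-input sample is then the sum of its minor-allele
    reads over all the segment's SNPs divided by the summed coverage, which
    sidesteps the per-SNP variance of very low coverage.  A segment is LOH
    when that pooled MAF sits at least ``margin`` below the normal's pooled
    MAF; segments with zero covered SNPs are flagged undefined.
    """
    by_sample = {
        s: snp_counts[snp_counts["sample"] == s].set_index(["chrom", "pos"])
        for s in [low_input_sample, normal_sample, *voting_samples]
    }
    rows = []
    for seg in patient_segments.itertuples():
        norm = by_sample[normal_sample]
        loci = norm[
            (norm.index.get_level_values("chrom") == seg.chrom)
            & (norm.index.get_level_values("pos") > seg.start)
            & (norm.index.get_level_values("pos") <= seg.end)
        ].index
        minor_reads = total = 0
        norm_minor = norm_total = 0
        for locus in loci:
            minor = _vote_minor_allele(locus, by_sample, voting_samples,
                                       min_vote_coverage)
            if minor is None:
                continue
            low = by_sample[low_input_sample]
            if locus in low.index:
                r = low.loc[locus]
                minor_reads += int(r[f"{minor}_count"])
                total += int(r["ref_count"] + r["alt_count"])
            r = norm.loc[locus]
            norm_minor += int(r[f"{minor}_count"])
            norm_total += int(r["ref_count"] + r["alt_count"])
        maf = minor_reads / total if total else np.nan
        maf_norm = norm_minor / norm_total if norm_total else np.nan
        rows.append(
            {
                "marker_id": getattr(seg, "marker_id", None),
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "pooled_maf": maf,
                "pooled_maf_normal": maf_norm,
                "loh": bool(maf_norm - maf >= margin) if total else None,
                "defined": bool(total),
            }
        )
    return pd.DataFrame(rows)


def _vote_minor_allele(locus, by_sample, voting_samples, min_cov) -> str | None:
    votes = {"ref": 0, "alt": 0}
    pooled = {"ref": 0, "alt": 0}
    for s in voting_samples:
        df = by_sample[s]
        if locus not in df.index:
            continue
        r = df.loc[locus]
        ref, alt = int(r["ref_count"]), int(r["alt_count"])
        if ref + alt < min_cov:
            continue
        pooled["ref"] += ref
        pooled["alt"] += alt
        if ref != alt:
            votes["ref" if ref < alt else "alt"] += 1
    if votes["ref"] == votes["alt"] == 0 and pooled["ref"] == pooled["alt"] == 0:
        return None
    if votes["ref"] != votes["alt"]:
        return "ref" if votes["ref"] > votes["alt"] else "alt"
    return "ref" if pooled["ref"] <= pooled["alt"] else "alt"
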