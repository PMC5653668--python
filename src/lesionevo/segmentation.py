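"""Piecewise-constant segmentation of ordered genomic signals.

Recursive binary segmentation in the style of circular binary segmentation:
each candidate split maximizes the two-sample t-like statistic between the
flanks, and is accepted only if it beats the null distribution obtained by
permuting the values within the segment.  Segmentation never crosses
chromosome boundaries; callers run one chromosome at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Segment:
    """Half-open index range [start, end) with its mean signal."""

    start: int
    end: int
    mean: float

    @property
    def n(self) -> int:
        return self.end - self.start


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best internal split of x maximizing |mean difference| scaled by size.

    Returns (split index, statistic); statistic is the absolute two-sample
    z-score assuming common variance, computed for every split via cumsums.
    """
    n = len(x)
    if n < 2 * min_size:
        return -1, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    k = np.arange(min_size, n - min_size + 1)  # split positions
    left_mean = cs[k - 1] / k
    right_mean = (total - cs[k - 1]) / (n - k)
    sd = np.std(x)
    if sd == 0:
        return -1, 0.0
    stat = np.abs(left_mean - right_mean) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    i = int(np.argmax(stat))
    return int(k[i]), float(stat[i])


def _split_significant(
    x: np.ndarray,
    stat: float,
    rng: np.random.Generator,
    alpha: float,
    n_perm: int,
    min_size: int,
) -> bool:
    """Permutation test: does the observed split statistic beat chance?"""
    exceed = 0
    allowed = int(alpha * n_perm)
    for _ in range(n_perm):
        perm = rng.permutation(x)
        _, s = _best_split(perm, min_size)
        if s >= stat:
            exceed += 1
            if exceed > allowed:  # early exit: already non-significant
                return False
    return exceed <= allowed


def segment_series(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_size: int = 3,
    seed: int = 0,
) -> list[Segment]:
    """Segment a 1-D series into piecewise-constant runs.

    Parameters
    ----------
    values
        Signal ordered by genomic position (one chromosome).
    alpha
        Significance level of the permutation stopping rule.
    n_perm
        Permutations per tested split.
    min_size
        Minimum points per segment.
    seed
        Seeds the permutation RNG; fixed seed gives identical segmentations.
    """
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[Segment] = []

    def recurse(lo: int, hi: int) -> None:
        sub = x[lo:hi]
        split, stat = _best_split(sub, min_size)
        if split > 0 and _split_significant(sub, stat, rng, alpha, n_perm, min_size):
            recurse(lo, lo + split)
            recurse(lo + split, hi)
        else:
            out.append(Segment(lo, hi, float(sub.mean())))

    if len(x):
        recurse(0, len(x))
    return out


def best_single_changepoint(values: np.ndarray) -> int:
    """Exhaustive least-squares location of one changepoint (test oracle).

    Minimizes within-segment sum of squares over all splits; independent of
    the recursive engine above.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    best_k, best_cost = -1, np.inf
    for k in range(1, n):
        l, r = x[:k], x[k:]
        cost = ((l - l.mean()) ** 2).sum() + ((r - r.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_k = cost, k
    return best_k
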