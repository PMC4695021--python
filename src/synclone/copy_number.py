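"""Read-depth copy number: GC correction, log2 ratios, CBS segmentation.

Input is a binned depth table (chrom, start, end, gc, depth_tumor,
depth_normal).  Depths are GC-corrected per sample by median-ratio
stratification, library-size normalized, log2-transformed, and segmented per
chromosome with circular binary segmentation (CBS): recursively find the arc
of the circularized signal maximizing a mean-difference t-like statistic
between arc and complement, accept the split when a permutation p-value falls
below alpha, and recurse.  Segments are called gain / neutral / loss by
log2-ratio thresholds; neutral segments feed the clonal-architecture stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit


@dataclass
class CopySegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_bins: int
    call: str = "neutral"


REQUIRED_COLUMNS = ("chrom", "start", "end", "gc", "depth_tumor", "depth_normal")


def _check_bins(bins: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in bins.columns]
    if missing:
        raise ValueError(f"depth table is missing columns: {missing}")


def gc_correct(bins: pd.DataFrame, stratum_width: float = 0.02, min_bins: int = 20) -> pd.DataFrame:
    """Median-ratio GC correction of both depth columns.

    Bins are stratified into GC windows of ``stratum_width``; each sample's
    depths are divided by (stratum median / global median).  Strata with
    fewer than ``min_bins`` bins inherit the correction factor of the nearest
    populated stratum, so sparse GC extremes are not over-fit.
    """
    _check_bins(bins)
    if ((bins["gc"] < 0) | (bins["gc"] > 1)).any():
        raise ValueError("gc must lie in [0, 1]")
    out = bins.copy()
    strata = np.floor(bins["gc"].to_numpy() / stratum_width).astype(int)
    unique = np.unique(strata)
    counts = {s: int((strata == s).sum()) for s in unique}
    populated = [s for s in unique if counts[s] >= min_bins]
    if not populated:
        populated = list(unique)  # degenerate: every stratum is sparse
    for col in ("depth_tumor", "depth_normal"):
        depth = bins[col].to_numpy(dtype=float)
        global_median = np.median(depth)
        factors = {}
        for s in populated:
            med = np.median(depth[strata == s])
            factors[s] = med / global_median if global_median > 0 and med > 0 else 1.0
        per_bin = np.array(
            [factors[min(populated, key=lambda p: abs(p - s))] for s in strata]
        )
        out[col] = depth / per_bin
    return out


def normalize_and_ratio(
    bins: pd.DataFrame, min_normal_depth: float = 10.0, normalize: bool = True
) -> pd.DataFrame:
    """Library-size normalization and per-bin log2 tumor/normal ratio.

    Bins with normal depth below ``min_normal_depth`` are masked
    (``masked`` column) and excluded from normalization and segmentation.
    Tumor depths are scaled so the unmasked totals match, then
    ``log2((tumor + 0.5) / (normal + 0.5))``.
    """
    _check_bins(bins)
    out = bins.copy()
    out["masked"] = out["depth_normal"] < min_normal_depth
    unmasked = ~out["masked"]
    for chrom, grp in out.groupby("chrom", sort=False):
        if grp["masked"].all():
            import warnings

            warnings.warn(f"all bins masked on {chrom}")
    scale = 1.0
    if normalize:
        tumor_total = out.loc[unmasked, "depth_tumor"].sum()
        normal_total = out.loc[unmasked, "depth_normal"].sum()
        if tumor_total > 0:
            scale = normal_total / tumor_total
    out["log2ratio"] = np.log2(
        (out["depth_tumor"] * scale + 0.5) / (out["depth_normal"] + 0.5)
    )
    return out


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _max_arc_stat(x: np.ndarray, min_width: int):
    """Max |t-like statistic| over all arcs [i, j) of the circularized series.

    The statistic for an arc of length k is
    ``(mean_arc - mean_complement) * sqrt(k * (n - k) / n)``.  Only
    non-wrapping arcs are enumerated: a wrapping arc equals the complement of
    a non-wrapping one and has the same absolute statistic.  Returns
    (max |stat|, i, j).
    """
    n = x.size
    c = np.empty(n + 1)
    c[0] = 0.0
    for t in range(n):
        c[t + 1] = c[t] + x[t]
    total = c[n]
    best = -1.0
    bi, bj = 0, n
    for k in range(min_width, n - min_width + 1):
        w = np.sqrt(k * (n - k) / n)
        for i in range(0, n - k + 1):
            arc = c[i + k] - c[i]
            stat = abs((arc / k - (total - arc) / (n - k)) * w)
            if stat > best:
                best = stat
                bi, bj = i, i + k
    return best, bi, bj


@njit(cache=True)
def _max_stat_only(x: np.ndarray, min_width: int) -> float:
    s, _, _ = _max_arc_stat(x, min_width)
    return s


def _split_significant(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
):
    """Permutation test for the best arc of one segment.

    Sequential early stopping: once the exceedance count is already above
    ``alpha * n_perm`` the split cannot be significant and remaining
    permutations are skipped (the decision equals the full-run decision).
    Returns (significant, i, j).
    """
    n = x.size
    if n < 2 * min_width or np.ptp(x) == 0.0:
        return False, 0, n
    observed, i, j = _max_arc_stat(x, min_width)
    if observed <= 0.0:
        return False, 0, n
    threshold = alpha * n_perm
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        if _max_stat_only(perm, min_width) >= observed:
            exceed += 1
            if exceed > threshold:
                return False, 0, n
    return True, i, j


def cbs_segment(
    values: Sequence[float],
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: Optional[int] = None,
) -> list:
    """Breakpoint indices from recursive circular binary segmentation.

    Returns sorted interior breakpoints b (0 < b < n): bins [0, b1), [b1, b2),
    ... form the segments.  Constant input yields no breakpoints.  The best
    circular arc contributes up to two breakpoints per accepted split; both
    resulting parts must have at least ``min_width`` bins.  Deterministic
    under ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if x.size == 0:
        return []
    rng = np.random.default_rng(seed)
    breakpoints: list = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        significant, i, j = _split_significant(seg, alpha, n_perm, min_width, rng)
        if not significant:
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        breakpoints.extend(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(breakpoints)


def call_segments(
    segments: Sequence[CopySegment],
    gain_threshold: float = 0.25,
    loss_threshold: float = -0.25,
) -> list:
    """Assign gain / neutral / loss calls by mean log2 ratio (in place)."""
    if not (gain_threshold > 0 > loss_threshold):
        raise ValueError("thresholds must satisfy gain > 0 > loss")
    for seg in segments:
        if seg.mean_log2 >= gain_threshold:
            seg.call = "gain"
        elif seg.mean_log2 <= loss_threshold:
            seg.call = "loss"
        else:
            seg.call = "neutral"
    return list(segments)


def segment_profile(
    bins: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: Optional[int] = None,
    gain_threshold: float = 0.25,
    loss_threshold: float = -0.25,
) -> list:
    """Segment a log2-ratio depth table per chromosome and call the segments.

    ``bins`` must carry ``log2ratio`` (see :func:`normalize_and_ratio`);
    masked bins are excluded.  Per chromosome the returned segments are
    ordered, non-overlapping, and tile the unmasked binned extent, with
    ``n_bins`` summing to the number of unmasked bins.
    """
    if "log2ratio" not in bins.columns:
        raise ValueError("run normalize_and_ratio first (log2ratio column missing)")
    work = bins if "masked" in bins.columns else bins.assign(masked=False)
    segments: list = []
    for chrom, grp in work.groupby("chrom", sort=False):
        grp = grp[~grp["masked"]]
        if len(grp) == 0:
            continue
        values = grp["log2ratio"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bps = cbs_segment(values, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)
        edges = [0] + bps + [len(values)]
        for lo, hi in zip(edges[:-1], edges[1:]):
            segments.append(
                CopySegment(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_log2=float(values[lo:hi].mean()),
                    n_bins=hi - lo,
                )
            )
    return call_segments(segments, gain_threshold, loss_threshold)


def read_depth_tsv(path) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_bins(bins)
    return bins


def write_segments_tsv(segments: Sequence[CopySegment], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "mean_log2": s.mean_log2,
                "n_bins": s.n_bins,
                "call": s.call,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)
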