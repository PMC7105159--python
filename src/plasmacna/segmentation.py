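"""Segmentation of per-bin log2 profiles into constant-mean segments.

Circular-binary-segmentation style changepoint search: within each
chromosome the candidate is the contiguous sub-segment maximizing the
two-sample t-statistic between the segment and its complement (interior
candidates place two breakpoints at once, which keeps a gain and a loss on
one chromosome from cancelling in a single split); the candidate is accepted
when a seeded permutation test rejects the constant-mean null, and the
procedure recurses into the resulting pieces.  Accepted splits are undone
when adjacent segment means are closer than the noise supports.  The
permutation stream is derived deterministically from the seed and the node's
bin interval, so a fixed input and seed always yield the same segmentation
and lowering ``alpha`` can only prune, never add, accepted splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .layout import GenomeLayout


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    z: Optional[float] = None  # filled by reference_panel.region_zscore downstream


def _candidate_pairs(n: int, min_seg_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with a segment [i, j) and complement both >= min_seg_bins."""
    i_idx, j_idx = np.triu_indices(n + 1, k=min_seg_bins)
    keep = (j_idx - i_idx) <= n - min_seg_bins
    return i_idx[keep], j_idx[keep]


def _max_boxcar_t(
    x: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray
) -> tuple[float, int, int]:
    """Max two-sample t of any candidate segment vs its complement."""
    n = len(x)
    s = np.concatenate(([0.0], np.cumsum(x)))
    q = np.concatenate(([0.0], np.cumsum(x * x)))
    length = (j_idx - i_idx).astype(float)
    comp = n - length
    sum_in = s[j_idx] - s[i_idx]
    m_in = sum_in / length
    m_out = (s[n] - sum_in) / comp
    ss_in = np.maximum((q[j_idx] - q[i_idx]) - length * m_in**2, 0.0)
    ss_out = np.maximum((q[n] - (q[j_idx] - q[i_idx])) - comp * m_out**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (ss_in + ss_out) / (n - 2)
        t = np.abs(m_in - m_out) / np.sqrt(pooled * (1 / length + 1 / comp))
    t = np.where(np.isnan(t), 0.0, t)
    t = np.where(np.isinf(t), 1e12, t)
    best = int(np.argmax(t))
    return float(t[best]), int(i_idx[best]), int(j_idx[best])


def _node_accepted(
    x: np.ndarray, t_obs: float, i_idx: np.ndarray, j_idx: np.ndarray,
    alpha: float, n_perm: int, rng: np.random.Generator,
) -> bool:
    """Permutation test with early rejection once acceptance is impossible."""
    if t_obs <= 0:
        return False
    max_exceed = int(np.floor(alpha * (n_perm + 1))) - 1  # accept iff exceed <= this
    if max_exceed < 0:
        return False
    exceed = 0
    for _ in range(n_perm):
        t_perm, _, _ = _max_boxcar_t(rng.permutation(x), i_idx, j_idx)
        if t_perm >= t_obs:
            exceed += 1
            if exceed > max_exceed:
                return False
    return True


def _recurse(
    x: np.ndarray, lo: int, alpha: float, min_seg_bins: int, n_perm: int,
    seed: int, chrom_idx: int, depth: int, max_depth: int, breaks: list[int],
) -> None:
    n = len(x)
    if depth >= max_depth or n < 2 * min_seg_bins:
        return
    i_idx, j_idx = _candidate_pairs(n, min_seg_bins)
    t_obs, bi, bj = _max_boxcar_t(x, i_idx, j_idx)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, chrom_idx, lo, lo + n])
    )
    if not _node_accepted(x, t_obs, i_idx, j_idx, alpha, n_perm, rng):
        return
    cuts = [c for c in (bi, bj) if 0 < c < n]
    for c in cuts:
        breaks.append(lo + c)
    for a, b in zip([0, *cuts], [*cuts, n]):
        _recurse(x[a:b], lo + a, alpha, min_seg_bins, n_perm, seed, chrom_idx,
                 depth + 1, max_depth, breaks)


def segment_profile(
    log2: np.ndarray,
    layout: GenomeLayout,
    mask: Optional[np.ndarray] = None,
    alpha: float = 0.01,
    min_seg_bins: int = 3,
    n_perm: int = 200,
    merge_tol: float = 0.05,
    undo_sd: float = 3.0,
    max_depth: int = 20,
    seed: int = 0,
) -> list[Segment]:
    """Partition a per-bin log2 profile into constant-mean segments.

    Masked bins are excluded from every statistic; each chromosome's segments
    are contiguous over its unmasked bins and jointly cover them all.
    Segment coordinates span from the first to the last covered bin.

    Accepted breakpoints are undone when the adjacent segment means differ by
    less than ``merge_tol`` log2 units or by less than ``undo_sd`` noise
    standard errors (noise estimated robustly from first differences), the
    undo-splits rule of classic circular binary segmentation.
    """
    log2 = np.asarray(log2, dtype=float)
    if mask is None:
        mask = np.isfinite(log2)
    bins = layout.bins()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    segments: list[Segment] = []
    for chrom_idx, (chrom, sl) in enumerate(layout.chrom_bin_slices().items()):
        idx = np.arange(sl.start, sl.stop)[mask[sl]]
        if idx.size == 0:
            continue
        x = log2[idx]
        breaks: list[int] = []
        _recurse(x, 0, alpha, min_seg_bins, n_perm, seed, chrom_idx, 0, max_depth, breaks)
        bounds = [0] + sorted(breaks) + [len(x)]
        # robust per-chromosome noise level from first differences
        noise = 0.0
        if len(x) > 1:
            noise = float(np.median(np.abs(np.diff(x)))) / (np.sqrt(2) * 0.6745)
        # undo splits whose segment means are closer than the noise allows
        pieces = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        merged: list[tuple[int, int]] = []
        for lo, hi in pieces:
            if merged:
                plo, phi = merged[-1]
                n1, n2 = phi - plo, hi - lo
                gap = abs(x[plo:phi].mean() - x[lo:hi].mean())
                sd_gap = undo_sd * noise * np.sqrt(1 / n1 + 1 / n2)
                if gap < max(merge_tol, sd_gap):
                    merged[-1] = (plo, hi)
                    continue
            merged.append((lo, hi))
        for lo, hi in merged:
            seg_idx = idx[lo:hi]
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(starts[seg_idx[0]]),
                    end=int(ends[seg_idx[-1]]),
                    n_bins=int(hi - lo),
                    mean_log2=float(x[lo:hi].mean()),
                )
            )
    return segments


def exhaustive_breakpoint_oracle(
    x: Sequence[float], k_breaks: int, min_seg_bins: int = 1
) -> tuple[tuple[int, ...], float]:
    """Globally optimal breakpoints by enumeration (test oracle, <= 30 bins).

    Returns ``(breakpoints, rss)`` minimizing the residual sum of squares over
    all placements of exactly ``k_breaks`` breakpoints (prefix lengths).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n > 30:
        raise ValueError("oracle is for instances of <= 30 bins")
    if k_breaks > 2:
        raise ValueError("oracle supports at most 2 breakpoints")

    def rss(lo: int, hi: int) -> float:
        seg = x[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum())

    if k_breaks == 0:
        return (), rss(0, n)
    best: tuple[float, tuple[int, ...]] = (np.inf, ())
    positions = range(min_seg_bins, n - min_seg_bins + 1)
    for combo in combinations(positions, k_breaks):
        bounds = (0, *combo, n)
        if any(b - a < min_seg_bins for a, b in zip(bounds, bounds[1:])):
            continue
        total = sum(rss(a, b) for a, b in zip(bounds, bounds[1:]))
        if total < best[0] - 1e-12:
            best = (total, combo)
    return best[1], best[0]


def segments_to_bed(segments: Sequence[Segment], path: str | Path) -> None:
    """Write segments as BED-style TSV with mean_log2 and z extra columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_bins\tmean_log2\tz\n")
        for s in segments:
            z = "" if s.z is None else f"{s.z:.6g}"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_bins}\t{s.mean_log2:.17g}\t{z}\n")


def read_segments_bed(path: str | Path) -> list[Segment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, n_bins, mean_log2, z = (line.rstrip("\n").split("\t") + [""])[:6]
            segments.append(
                Segment(chrom, int(start), int(end), int(n_bins), float(mean_log2),
                        float(z) if z else None)
            )
    return segments
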