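"""Per-bin count profiles: counting, masking, GC correction, normalization.

A :class:`BinProfile` carries one sample's per-bin fragment counts through the
chain raw counts -> GC-corrected counts -> panel-normalized log2 ratios.  The
chain is invariant to uniform rescaling of one sample's counts (sequencing
depth), which is what makes profiles comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, TYPE_CHECKING

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .layout import GenomeLayout

if TYPE_CHECKING:  # pragma: no cover
    from .panel import ReferencePanel

GC_RANGE = (0.3, 0.7)


@dataclass
class BinProfile:
    """One sample's per-bin vectors on a shared :class:`GenomeLayout` grid.

    ``corrected`` and ``log2_ratio`` are ``None`` until the corresponding
    stage has run.  ``mask`` flags usable bins; every statistic downstream
    ignores masked-out bins.
    """

    sample_id: str
    layout: GenomeLayout
    raw_counts: np.ndarray
    gc: np.ndarray
    corrected: Optional[np.ndarray] = None
    log2_ratio: Optional[np.ndarray] = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.layout.n_bins
        self.raw_counts = np.asarray(self.raw_counts)
        self.gc = np.asarray(self.gc, dtype=float)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("raw_counts", "gc", "corrected", "log2_ratio", "mask"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, layout has {n} bins")
        if np.any(self.raw_counts < 0):
            raise ValueError("raw counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = self.layout.bins()
        df["count"] = self.raw_counts
        df["gc"] = self.gc
        df["mask"] = self.mask.astype(int)
        if self.corrected is not None:
            df["corrected"] = self.corrected
        if self.log2_ratio is not None:
            df["log2_ratio"] = self.log2_ratio
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path, layout: GenomeLayout, sample_id: str | None = None) -> BinProfile:
    """Read a bin-profile TSV (chrom, start, end, count, gc[, ...]) on ``layout``."""
    df = pd.read_csv(path, sep="\t")
    bins = layout.bins()
    if len(df) != len(bins) or not (
        (df["chrom"].to_numpy() == bins["chrom"].to_numpy()).all()
        and (df["start"].to_numpy() == bins["start"].to_numpy()).all()
    ):
        raise ValueError(f"{path}: bin grid does not match the supplied layout")
    return BinProfile(
        sample_id=sample_id or Path(path).stem,
        layout=layout,
        raw_counts=df["count"].to_numpy(),
        gc=df["gc"].to_numpy(dtype=float),
        corrected=df["corrected"].to_numpy(dtype=float) if "corrected" in df else None,
        log2_ratio=df["log2_ratio"].to_numpy(dtype=float) if "log2_ratio" in df else None,
        mask=df["mask"].to_numpy(dtype=bool) if "mask" in df else None,
    )


def make_bins(layout: GenomeLayout) -> pd.DataFrame:
    """Ordered half-open bin table tiling the layout (chromosome-major)."""
    return layout.bins()


def count_fragments(
    fragments: Iterable[tuple[str, int, int]], layout: GenomeLayout
) -> tuple[np.ndarray, int]:
    """Assign each fragment to exactly one bin by its midpoint.

    Midpoints use integer division, so a midpoint landing exactly on a bin
    boundary belongs to the right-hand bin (half-open convention).  Fragments
    on unknown chromosomes are skipped and counted; malformed intervals
    (``end <= start``) raise a record-level warning and are skipped.

    Returns ``(counts, n_skipped)``.
    """
    counts = np.zeros(layout.n_bins, dtype=np.int64)
    slices = layout.chrom_bin_slices()
    lengths = layout.lengths
    skipped = 0
    for chrom, start, end in fragments:
        if end <= start:
            warnings.warn(f"malformed interval {chrom}:{start}-{end} skipped", stacklevel=2)
            skipped += 1
            continue
        sl = slices.get(chrom)
        if sl is None:
            skipped += 1
            continue
        mid = (start + end) // 2
        if mid < 0 or mid >= lengths[chrom]:
            skipped += 1
            continue
        counts[sl.start + mid // layout.bin_size] += 1
    return counts, skipped


def mask_bins(
    profile: BinProfile,
    donor_counts: Optional[np.ndarray] = None,
    gc_range: tuple[float, float] = GC_RANGE,
) -> BinProfile:
    """Mask bins with extreme GC or (given a donor count matrix) zero median.

    The rule set is idempotent: re-applying it to an already-masked profile
    leaves the mask unchanged.  The existing mask is AND-combined, so a bin
    masked upstream never comes back.
    """
    ok = (profile.gc >= gc_range[0]) & (profile.gc <= gc_range[1])
    if donor_counts is not None:
        donor_counts = np.atleast_2d(np.asarray(donor_counts))
        ok &= np.median(donor_counts, axis=0) > 0
    profile.mask = profile.mask & ok
    return profile


def _gc_fit(raw: np.ndarray, gc: np.ndarray, lowess_frac: float) -> np.ndarray:
    """Expected count as a smooth function of GC, evaluated per bin."""
    if len(raw) >= 200:
        span = gc.max() - gc.min()
        fit = lowess(raw, gc, frac=lowess_frac, delta=0.01 * span, return_sorted=False)
        if np.all(fit > 0):
            return fit
    # decile-median fallback for tiny inputs or degenerate smooths
    deciles = np.quantile(gc, np.linspace(0, 1, 11))
    deciles[0] -= 1e-9
    idx = np.clip(np.searchsorted(deciles, gc, side="left") - 1, 0, 9)
    med = np.array([np.median(raw[idx == k]) if np.any(idx == k) else np.median(raw) for k in range(10)])
    fit = med[idx].astype(float)
    fit[fit <= 0] = max(np.median(raw), 1.0)
    return fit


def gc_correct(profile: BinProfile, lowess_frac: float = 0.3, min_unmasked: int = 50) -> BinProfile:
    """Divide counts by a smooth GC trend, preserving the mean count.

    The trend is a lowess fit of count on GC over unmasked bins (median ratio
    per GC decile when fewer than 200 bins are available).  Corrected counts
    are rescaled so that their unmasked mean equals the raw unmasked mean,
    which makes the correction scale-equivariant: doubling the raw counts
    doubles the corrected counts.
    """
    m = profile.mask
    if int(m.sum()) < min_unmasked:
        raise ValueError(f"only {int(m.sum())} unmasked bins; need >= {min_unmasked}")
    raw = profile.raw_counts.astype(float)
    fit = np.ones_like(raw)
    fit[m] = _gc_fit(raw[m], profile.gc[m], lowess_frac)
    corrected = raw / fit
    scale = raw[m].mean() / corrected[m].mean() if corrected[m].mean() > 0 else 1.0
    profile.corrected = corrected * scale
    return profile


def to_log2_ratio(profile: BinProfile, panel: "ReferencePanel") -> BinProfile:
    """Per-bin log2 of the sample's bin fraction over the panel median fraction.

    Bin fractions (bin count / total unmasked count) make the value invariant
    to the sample's total depth.  A pseudo-count of half the smallest positive
    panel median fraction guards log2 against zero bins at shallow coverage.
    Masked bins get NaN.
    """
    if panel.layout != profile.layout:
        raise ValueError("profile and panel are on different bin grids")
    if profile.corrected is None:
        gc_correct(profile)
    m = profile.mask & panel.mask
    frac = np.full(profile.layout.n_bins, np.nan)
    total = profile.corrected[m].sum()
    if total <= 0:
        raise ValueError("sample has no usable signal in unmasked bins")
    frac[m] = profile.corrected[m] / total
    pc = panel.pseudo_count
    l2 = np.full(profile.layout.n_bins, np.nan)
    l2[m] = np.log2((frac[m] + pc) / (panel.median_fraction[m] + pc))
    profile.log2_ratio = l2
    profile.mask = m
    return profile
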