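"""Healthy-donor reference panel: the null model for plasma Z-scores.

The panel summarizes a set of healthy-donor cfDNA profiles on one bin grid:
the per-bin median fraction (the normalization target), per-bin mean and SD of
donor log2 ratios (for bin-level Z), and the full donor-by-bin log2 matrix.
The matrix is retained because the *segmented* Z-score of a region is defined
by donor projection: the sample's region-mean log2 is standardized against
the distribution of the same region-mean across the donors themselves.  That
construction absorbs inter-bin correlation that a naive SD/sqrt(n) would
ignore.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .profiles import BinProfile, gc_correct, mask_bins, GC_RANGE

PANEL_FORMAT_VERSION = 1


class RegionZ(NamedTuple):
    """Segmented Z of one region: NaN z with n_bins=0 means unevaluable."""

    z: float
    n_bins: int
    sample_mean: float


@dataclass
class ReferencePanel:
    layout: GenomeLayout
    donor_ids: list[str]
    mask: np.ndarray                 # usable bins (GC range + positive median count)
    median_fraction: np.ndarray      # per-bin median donor fraction
    mean_log2: np.ndarray            # per-bin mean of donor log2 ratios
    sd_log2: np.ndarray              # per-bin SD, floored
    donor_log2: np.ndarray           # n_donors x n_bins
    sd_floor: float
    pseudo_count: float

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    def grid_hash(self) -> str:
        key = repr((self.layout.chromosomes, self.layout.bin_size)).encode()
        return hashlib.sha1(key).hexdigest()[:12]


def build_panel(
    donor_profiles: Sequence[BinProfile],
    sd_floor_quantile: float = 0.05,
    gc_range: tuple[float, float] = GC_RANGE,
) -> ReferencePanel:
    """Build the null model from >= 2 healthy-donor profiles on one grid.

    Steps: shared mask (GC window plus zero-median-count exclusion), per-donor
    GC correction, per-bin median fraction, then each donor's log2 ratio
    against that median and its per-bin mean/SD.  SDs are floored at the
    ``sd_floor_quantile`` quantile of all positive bin SDs so that degenerate
    bins (e.g. identical donors) cannot produce infinite Z-scores.
    """
    if len(donor_profiles) < 2:
        raise ValueError("a reference panel needs at least 2 donors")
    layout = donor_profiles[0].layout
    if any(p.layout != layout for p in donor_profiles):
        raise ValueError("all donor profiles must share one bin grid")

    # work on copies: building a panel must not mutate the donor profiles
    counts = np.vstack([p.raw_counts for p in donor_profiles])
    donors = []
    for p in donor_profiles:
        q = BinProfile(
            p.sample_id, p.layout, p.raw_counts, p.gc,
            corrected=None if p.corrected is None else np.array(p.corrected),
            mask=np.array(p.mask),
        )
        mask_bins(q, donor_counts=counts, gc_range=gc_range)
        if q.corrected is None:
            gc_correct(q)
        donors.append(q)
    mask = np.logical_and.reduce([p.mask for p in donors])

    fracs = np.vstack([p.corrected / p.corrected[mask].sum() for p in donors])
    median_fraction = np.full(layout.n_bins, np.nan)
    median_fraction[mask] = np.median(fracs[:, mask], axis=0)
    if not np.any(median_fraction[mask] > 0):
        raise ValueError("panel median fraction is zero everywhere")
    # half the smallest representable positive bin fraction (one fragment)
    # across donors: guards log2 against zero-count bins while staying far
    # below any real bin fraction, so log2 ratios are not attenuated
    totals = [p.raw_counts[mask].sum() for p in donors]
    pseudo_count = 0.5 * min(1.0 / t for t in totals if t > 0)

    donor_log2 = np.full((len(donor_profiles), layout.n_bins), np.nan)
    donor_log2[:, mask] = np.log2(
        (fracs[:, mask] + pseudo_count) / (median_fraction[mask] + pseudo_count)
    )

    mean_log2 = np.full(layout.n_bins, np.nan)
    sd_log2 = np.full(layout.n_bins, np.nan)
    mean_log2[mask] = donor_log2[:, mask].mean(axis=0)
    sd_log2[mask] = donor_log2[:, mask].std(axis=0, ddof=1)
    pos_sd = sd_log2[mask][sd_log2[mask] > 0]
    sd_floor = float(np.quantile(pos_sd, sd_floor_quantile)) if pos_sd.size else 1e-6
    sd_log2[mask] = np.maximum(sd_log2[mask], sd_floor)

    return ReferencePanel(
        layout=layout,
        donor_ids=[p.sample_id for p in donor_profiles],
        mask=mask,
        median_fraction=median_fraction,
        mean_log2=mean_log2,
        sd_log2=sd_log2,
        donor_log2=donor_log2,
        sd_floor=sd_floor,
        pseudo_count=pseudo_count,
    )


def bin_zscores(profile: BinProfile, panel: ReferencePanel) -> np.ndarray:
    """Per-bin Z = (log2 - panel mean) / panel SD on unmasked bins, else NaN."""
    from .profiles import to_log2_ratio

    if profile.log2_ratio is None:
        to_log2_ratio(profile, panel)
    z = np.full(panel.layout.n_bins, np.nan)
    m = profile.mask & panel.mask
    z[m] = (profile.log2_ratio[m] - panel.mean_log2[m]) / panel.sd_log2[m]
    return z


def region_zscore(
    profile: BinProfile, panel: ReferencePanel, chrom: str, start: int, end: int
) -> RegionZ:
    """Segmented Z-score of an arbitrary region by donor projection.

    The sample's mean log2 over the region's unmasked bins is standardized
    against the same region-mean computed for every panel donor; the donor SD
    is floored at ``sd_floor / sqrt(n_bins)`` (the bin-level floor scaled to a
    region mean).  A region with no unmasked bins is unevaluable and returns
    ``RegionZ(nan, 0, nan)`` — deliberately distinct from Z = 0.
    """
    from .profiles import to_log2_ratio

    if profile.log2_ratio is None:
        to_log2_ratio(profile, panel)
    idx = panel.layout.region_bin_indices(chrom, start, end)
    if idx.size == 0:
        return RegionZ(float("nan"), 0, float("nan"))
    m = profile.mask[idx] & panel.mask[idx]
    idx = idx[m]
    if idx.size == 0:
        return RegionZ(float("nan"), 0, float("nan"))
    sample_mean = float(profile.log2_ratio[idx].mean())
    donor_means = panel.donor_log2[:, idx].mean(axis=1)
    sd = float(donor_means.std(ddof=1))
    sd = max(sd, panel.sd_floor / np.sqrt(idx.size))
    z = (sample_mean - float(donor_means.mean())) / sd
    return RegionZ(float(z), int(idx.size), sample_mean)


def save_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Serialize the panel as one TSV bundle with a metadata header."""
    path = Path(path)
    chrom_spec = ",".join(f"{c}:{l}" for c, l in panel.layout.chromosomes)
    header = [
        f"#plasmacna_panel_version={PANEL_FORMAT_VERSION}",
        f"#grid_hash={panel.grid_hash()}",
        f"#bin_size={panel.layout.bin_size}",
        f"#chromosomes={chrom_spec}",
        f"#n_donors={panel.n_donors}",
        f"#donor_ids={','.join(panel.donor_ids)}",
        f"#sd_floor={float(panel.sd_floor)!r}",
        f"#pseudo_count={float(panel.pseudo_count)!r}",
    ]
    df = panel.layout.bins()
    df["mask"] = panel.mask.astype(int)
    df["median_fraction"] = panel.median_fraction
    df["mean_log2"] = panel.mean_log2
    df["sd_log2"] = panel.sd_log2
    for i, donor in enumerate(panel.donor_ids):
        df[f"donor_log2__{donor}"] = panel.donor_log2[i]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def load_panel(path: str | Path) -> ReferencePanel:
    """Load a panel saved by :func:`save_panel`; statistics round-trip exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
    version = meta.get("plasmacna_panel_version")
    if version != str(PANEL_FORMAT_VERSION):
        raise ValueError(
            f"{path}: panel format version {version!r} unsupported "
            f"(expected {PANEL_FORMAT_VERSION})"
        )
    chroms = tuple(
        (name, int(length))
        for name, _, length in (c.partition(":") for c in meta["chromosomes"].split(","))
    )
    layout = GenomeLayout(chromosomes=chroms, bin_size=int(meta["bin_size"]))
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    donor_ids = meta["donor_ids"].split(",")
    donor_log2 = np.vstack([df[f"donor_log2__{d}"].to_numpy() for d in donor_ids])
    panel = ReferencePanel(
        layout=layout,
        donor_ids=donor_ids,
        mask=df["mask"].to_numpy(dtype=bool),
        median_fraction=df["median_fraction"].to_numpy(),
        mean_log2=df["mean_log2"].to_numpy(),
        sd_log2=df["sd_log2"].to_numpy(),
        donor_log2=donor_log2,
        sd_floor=float(meta["sd_floor"]),
        pseudo_count=float(meta["pseudo_count"]),
    )
    if meta.get("grid_hash") and panel.grid_hash() != meta["grid_hash"]:
        raise ValueError(f"{path}: grid hash mismatch")
    return panel
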