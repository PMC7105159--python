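"""Genome layout and the shared fixed-width bin grid.

Every stage of the pipeline — simulation, counting, normalization,
segmentation, detection — operates on the same tiling of the genome into
fixed-width, half-open ``[start, end)`` bins, chromosome-major.  The default
layout is the 22 human autosomes at megabase resolution: the donor reference
panel is male while the patients are female, so sex chromosomes are excluded
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# hg38 autosome lengths rounded up to whole Mb; ~2.9 Gb total.
_AUTOSOME_MB = {
    "chr1": 249, "chr2": 243, "chr3": 199, "chr4": 191, "chr5": 182,
    "chr6": 171, "chr7": 160, "chr8": 146, "chr9": 139, "chr10": 134,
    "chr11": 136, "chr12": 134, "chr13": 115, "chr14": 108, "chr15": 102,
    "chr16": 91, "chr17": 84, "chr18": 81, "chr19": 59, "chr20": 65,
    "chr21": 47, "chr22": 51,
}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes plus a fixed bin width.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Lengths must be positive.
    bin_size
        Bin width in bp.  Each chromosome is tiled with half-open bins
        ``[k*bin_size, (k+1)*bin_size)``; the final bin is truncated at the
        chromosome end.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def n_bins_of(self, chrom: str) -> int:
        length = self.lengths[chrom]
        return -(-length // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chrom_names)

    def bins(self) -> pd.DataFrame:
        """Bin table (chrom, start, end), chromosome-major, position-minor."""
        rows = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        out = pd.concat(rows, ignore_index=True)
        return out

    def chrom_bin_slices(self) -> dict[str, slice]:
        """Map chromosome name -> slice of its rows in the global bin index."""
        slices: dict[str, slice] = {}
        offset = 0
        for chrom in self.chrom_names:
            n = self.n_bins_of(chrom)
            slices[chrom] = slice(offset, offset + n)
            offset += n
        return slices

    def region_bin_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping the half-open region."""
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            return np.empty(0, dtype=np.int64)
        sl = self.chrom_bin_slices()[chrom]
        first = max(0, start // self.bin_size)
        last = min(self.n_bins_of(chrom), -(-end // self.bin_size))
        return np.arange(sl.start + first, sl.start + last, dtype=np.int64)


def default_layout(bin_size: int = 1_000_000) -> GenomeLayout:
    """The 22 human autosomes (whole-Mb lengths) at the given bin width."""
    chroms = tuple((name, mb * 1_000_000) for name, mb in _AUTOSOME_MB.items())
    return GenomeLayout(chromosomes=chroms, bin_size=bin_size)


def toy_layout(n_chroms: int = 2, chrom_length: int = 50_000_000,
               bin_size: int = 1_000_000) -> GenomeLayout:
    """Small uniform layout for tests and examples."""
    chroms = tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms))
    return GenomeLayout(chromosomes=chroms, bin_size=bin_size)
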