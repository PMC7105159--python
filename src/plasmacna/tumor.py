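"""Tumor CNA calling from array-like per-bin log2 profiles.

The study design is tumor-informed: plasma is interrogated only at regions
known to be altered in the patient's own tumor, so the tumor profile (an
SNP-array-style per-bin log2 ratio track) must first be reduced to discrete
gain/loss calls.  Pre-called regions can also be supplied directly as BED,
bypassing this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .segmentation import Segment, segment_profile

GAIN = "gain"
LOSS = "loss"


@dataclass
class CnaCall:
    """One tumor copy-number alteration: a region, its direction, its level."""

    chrom: str
    start: int
    end: int
    type: str                  # "gain" | "loss"
    tumor_log2: float

    def __post_init__(self) -> None:
        if self.type not in (GAIN, LOSS):
            raise ValueError(f"CNA type must be 'gain' or 'loss', got {self.type!r}")
        if self.end <= self.start:
            raise ValueError(f"empty CNA region {self.chrom}:{self.start}-{self.end}")
        if self.type == GAIN and self.tumor_log2 <= 0:
            raise ValueError("gain requires tumor_log2 > 0")
        if self.type == LOSS and self.tumor_log2 >= 0:
            raise ValueError("loss requires tumor_log2 < 0")

    @property
    def length(self) -> int:
        return self.end - self.start


def call_tumor_cnas(
    tumor_log2: np.ndarray,
    layout: GenomeLayout,
    mask: Optional[np.ndarray] = None,
    gain_thresh: float = 0.2,
    loss_thresh: float = -0.2,
    min_seg_bins: int = 3,
    alpha: float = 0.01,
    merge_tol: float = 0.05,
    seed: int = 0,
) -> list[CnaCall]:
    """Segment a tumor log2 profile and call gains/losses by mean threshold.

    Segments with mean >= ``gain_thresh`` become gains, <= ``loss_thresh``
    losses; copy-neutral segments are dropped and adjacent same-type calls
    are merged.  The defaults (+/-0.2) correspond to single-copy events in a
    diploid tumor at moderate purity.
    """
    if gain_thresh <= 0 or loss_thresh >= 0:
        raise ValueError("gain_thresh must be > 0 and loss_thresh < 0")
    segments = segment_profile(
        tumor_log2, layout, mask=mask, alpha=alpha, min_seg_bins=min_seg_bins,
        merge_tol=merge_tol, seed=seed,
    )
    calls: list[CnaCall] = []
    for seg in segments:
        if seg.mean_log2 >= gain_thresh:
            kind = GAIN
        elif seg.mean_log2 <= loss_thresh:
            kind = LOSS
        else:
            continue
        prev = calls[-1] if calls else None
        if prev is not None and prev.chrom == seg.chrom and prev.type == kind and prev.end >= seg.start:
            # merge adjacent same-type calls, length-weighting the level
            w1, w2 = prev.length, seg.end - seg.start
            merged_log2 = (prev.tumor_log2 * w1 + seg.mean_log2 * w2) / (w1 + w2)
            calls[-1] = CnaCall(prev.chrom, prev.start, seg.end, kind, merged_log2)
        else:
            calls.append(CnaCall(seg.chrom, seg.start, seg.end, kind, seg.mean_log2))
    return calls


def write_cna_bed(calls: Sequence[CnaCall], path: str | Path) -> None:
    """BED (0-based half-open): chrom, start, end, type, round(1000*|log2|), tumor_log2."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tscore\ttumor_log2\n")
        for c in calls:
            score = int(round(1000 * abs(c.tumor_log2)))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{score}\t{c.tumor_log2:.17g}\n")


def read_cna_bed(path: str | Path, coordinate_system: str = "0-based") -> list[CnaCall]:
    """Read CNA calls from BED; only the 0-based half-open dialect is accepted."""
    if coordinate_system != "0-based":
        raise ValueError(
            f"coordinate_system {coordinate_system!r} not supported: convert to "
            "0-based half-open BED before loading"
        )
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(fields)}")
            chrom, start, end, kind, _score, tumor_log2 = fields[:6]
            if kind not in (GAIN, LOSS):
                raise ValueError(f"{path}:{ln}: unknown CNA type {kind!r}")
            calls.append(CnaCall(chrom, int(start), int(end), kind, float(tumor_log2)))
    return calls


def summarize_cna_burden(
    calls_by_patient: Mapping[str, Sequence[CnaCall]]
) -> dict:
    """Per-patient CNA counts plus median and range over CNA-positive patients.

    Patients with zero calls are reported in ``counts`` but — matching how
    array studies quote per-tumor burden — excluded from the median/range,
    which describe the tumors in which CNAs were found at all.
    """
    counts = {pid: len(calls) for pid, calls in calls_by_patient.items()}
    positive = [n for n in counts.values() if n > 0]
    summary = {
        "counts": counts,
        "n_patients": len(counts),
        "n_with_cnas": len(positive),
        "total_cnas": int(sum(counts.values())),
        "median": float(np.median(positive)) if positive else None,
        "range": (int(min(positive)), int(max(positive))) if positive else None,
    }
    return summary
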