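"""Tumor-informed ctDNA detection: the pipeline's core statistic.

Each CNA called in a patient's tumor is evaluated in the matched plasma
sample: the segmented Z-score is computed over the CNA's own genomic
footprint, the direction of the plasma signal must agree with the tumor call
(gain up, loss down), and the region counts as detected when additionally
|Z| exceeds the cutoff (default 1.5).  A patient is ctDNA-positive when any
tumor CNA is detected.  Healthy donors screened against the same query
regions give the specificity of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import statsmodels.api as sm
from scipy import stats

from .layout import GenomeLayout
from .panel import ReferencePanel, build_panel, region_zscore
from .profiles import BinProfile, to_log2_ratio
from .segmentation import Segment
from .tumor import CnaCall, GAIN


@dataclass
class DetectionRecord:
    """Evaluation of one tumor CNA in the matched plasma sample."""

    patient_id: str
    cna: CnaCall
    plasma_z: float
    plasma_mean_log2: float
    n_bins: int
    direction_match: bool
    detected: bool
    evaluable: bool = True


@dataclass
class GenomeAlteredSummary:
    patient_id: str
    pct_genome_altered: float
    n_detected: int


def intersect_regions(
    cnas: Sequence[CnaCall], segments: Sequence[Segment]
) -> pd.DataFrame:
    """Any-overlap intersection of tumor CNAs with plasma segments.

    One row per (CNA, overlapping segment) pair with the overlap length in bp
    and the fraction of the CNA covered; deterministic ordering by CNA index
    then segment start.  Disjoint inputs give an empty frame.
    """
    cols = [
        "cna_index", "chrom", "cna_start", "cna_end", "cna_type",
        "seg_start", "seg_end", "seg_mean_log2", "overlap_bp", "overlap_fraction",
    ]
    if not cnas or not segments:
        return pd.DataFrame(columns=cols)
    a = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [c.chrom for c in cnas],
                "Start": [c.start for c in cnas],
                "End": [c.end for c in cnas],
                "cna_index": range(len(cnas)),
                "cna_type": [c.type for c in cnas],
            }
        )
    )
    b = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [s.chrom for s in segments],
                "Start": [s.start for s in segments],
                "End": [s.end for s in segments],
                "seg_mean_log2": [s.mean_log2 for s in segments],
            }
        )
    )
    joined = a.join(b).df
    if joined.empty:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(
        {
            "cna_index": joined["cna_index"],
            "chrom": joined["Chromosome"].astype(str),
            "cna_start": joined["Start"],
            "cna_end": joined["End"],
            "cna_type": joined["cna_type"],
            "seg_start": joined["Start_b"],
            "seg_end": joined["End_b"],
            "seg_mean_log2": joined["seg_mean_log2"],
        }
    )
    out["overlap_bp"] = np.minimum(out["cna_end"], out["seg_end"]) - np.maximum(
        out["cna_start"], out["seg_start"]
    )
    out["overlap_fraction"] = out["overlap_bp"] / (out["cna_end"] - out["cna_start"])
    return out.sort_values(["cna_index", "seg_start"], ignore_index=True)[cols]


def evaluate_cna_in_plasma(
    cna: CnaCall,
    plasma: BinProfile,
    panel: ReferencePanel,
    z_cut: float = 1.5,
    patient_id: Optional[str] = None,
) -> DetectionRecord:
    """Score one tumor CNA region in plasma.

    The segmented Z is taken over the CNA's own footprint; the direction
    match requires the plasma region mean log2 to carry the sign of the
    tumor call; detection additionally requires |Z| > ``z_cut``.  A region
    with no unmasked bins yields an unevaluable record (never a detection).
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    rz = region_zscore(plasma, panel, cna.chrom, cna.start, cna.end)
    if rz.n_bins == 0:
        return DetectionRecord(
            patient_id or plasma.sample_id, cna, float("nan"), float("nan"), 0,
            direction_match=False, detected=False, evaluable=False,
        )
    direction = rz.sample_mean > 0 if cna.type == GAIN else rz.sample_mean < 0
    detected = bool(direction and abs(rz.z) > z_cut)
    return DetectionRecord(
        patient_id or plasma.sample_id, cna, rz.z, rz.sample_mean, rz.n_bins,
        direction_match=bool(direction), detected=detected,
    )


def detect_patient(
    cnas: Sequence[CnaCall],
    plasma: BinProfile,
    panel: ReferencePanel,
    z_cut: float = 1.5,
    patient_id: Optional[str] = None,
) -> tuple[list[DetectionRecord], bool]:
    """Evaluate every tumor CNA; the patient is ctDNA-positive if any is detected.

    A tumor with no CNAs yields no records and a negative flag — the method
    is blind to such tumors by construction.  Unevaluable regions are counted
    via a warning and excluded from summaries.
    """
    records = [
        evaluate_cna_in_plasma(c, plasma, panel, z_cut=z_cut, patient_id=patient_id)
        for c in cnas
    ]
    n_bad = sum(not r.evaluable for r in records)
    if n_bad:
        warnings.warn(f"{n_bad} CNA region(s) had no unmasked bins and were not evaluable",
                      stacklevel=2)
    return records, any(r.detected for r in records)


def percent_genome_altered(
    records: Sequence[DetectionRecord], layout: GenomeLayout
) -> GenomeAlteredSummary:
    """Percent of the genome covered by the union of detected regions."""
    detected = [r for r in records if r.detected]
    pid = records[0].patient_id if records else ""
    if not detected:
        return GenomeAlteredSummary(pid, 0.0, 0)
    g = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [r.cna.chrom for r in detected],
                "Start": [r.cna.start for r in detected],
                "End": [r.cna.end for r in detected],
            }
        )
    ).merge()
    union = int((g.df["End"] - g.df["Start"]).sum())
    return GenomeAlteredSummary(pid, 100.0 * union / layout.total_length, len(detected))


def donor_specificity(
    donor_profiles: Sequence[BinProfile],
    query_regions: Sequence[CnaCall],
    panel: Optional[ReferencePanel] = None,
    z_cut: float = 1.5,
    leave_one_out: bool = True,
    require_direction: bool = True,
) -> tuple[int, int, float]:
    """Fraction of healthy donors in which no query region is called detected.

    A donor is a false positive if ANY query region is detected in its
    profile (direction-matched when ``require_direction``, |Z| > ``z_cut``).
    Donors that are members of the supplied panel are screened against a
    panel rebuilt without them when ``leave_one_out`` is set, so a donor is
    never compared against a null that contains itself.  With no query
    regions every donor is trivially negative.  Returns
    ``(true_negatives, n_donors, specificity)``.
    """
    n_true_neg = 0
    panel_ids = set(panel.donor_ids) if panel is not None else set()
    for donor in donor_profiles:
        if panel is None or (leave_one_out and donor.sample_id in panel_ids):
            others = [p for p in donor_profiles if p.sample_id != donor.sample_id]
            donor_panel = build_panel(others)
        else:
            donor_panel = panel
        fresh = BinProfile(donor.sample_id, donor.layout, donor.raw_counts, donor.gc)
        hit = False
        for region in query_regions:
            rec = evaluate_cna_in_plasma(region, fresh, donor_panel, z_cut=z_cut)
            if not rec.evaluable:
                continue
            if require_direction:
                hit = rec.detected
            else:
                hit = abs(rec.plasma_z) > z_cut
            if hit:
                break
        n_true_neg += not hit
    n = len(donor_profiles)
    return n_true_neg, n, (n_true_neg / n if n else 1.0)


def tumor_plasma_agreement(records: Sequence[DetectionRecord]) -> dict:
    """OLS fit of plasma segmented Z on tumor log2 across evaluated CNAs.

    Returns slope, intercept, r_squared, p_value (two-sided, zero slope) and
    n.  Degenerate two-point fits are flagged with a warning (R^2 is 1 by
    construction).
    """
    pts = [(r.cna.tumor_log2, r.plasma_z) for r in records if r.evaluable and np.isfinite(r.plasma_z)]
    if len(pts) < 2:
        raise ValueError("need at least 2 evaluable records for a regression")
    if len(pts) == 2:
        warnings.warn("regression on 2 points is degenerate (R^2 = 1)", stacklevel=2)
    x, y = np.array(pts).T
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.pvalues[1]) if len(pts) > 2 else float("nan"),
        "n": len(pts),
    }


def analytic_null_specificity(n_regions: int, n_donors: int, z_cut: float = 1.5) -> float:
    """Expected specificity for ideal null donors screened on independent regions.

    Under calibration, a null donor's region Z against an ``n_donors`` panel
    is Student-t with ``n_donors - 1`` df scaled by sqrt(1 + 1/n_donors); a
    direction-matched detection at ``z_cut`` is the one-sided tail, and the
    donor stays negative only if all ``n_regions`` independent regions do.
    """
    scale = np.sqrt(1.0 + 1.0 / n_donors)
    tail = float(stats.t.sf(z_cut / scale, df=n_donors - 1))
    return (1.0 - tail) ** n_regions
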