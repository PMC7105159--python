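"""Synthetic cohort generator: every input the pipeline consumes, simulated.

The generator emulates the study conditions of a tumor-informed plasma CNA
screen for uterine leiomyoma (LM): shallow (~0.1x) whole-genome cfDNA
sequencing summarized as per-megabase fragment counts (desk scale: mean 30
fragments per 1 Mb bin), SNP-array-like tumor log2 profiles carrying 0-20
mostly single-copy CNAs per tumor, plasma samples that are an admixture of
healthy cfDNA and a small tumor-derived fraction, a 25-donor healthy
reference panel, and a clinical table with the LM/LMS lactate-dehydrogenase
and age distributions (group means 191/288 U/L and 48/54 years).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout, default_layout
from .profiles import BinProfile
from .tumor import CnaCall, GAIN, LOSS

# Desk-scale defaults shared by donor and plasma count simulation.
MEAN_DEPTH = 30.0            # expected fragments per bin
GC_BIAS_AMPLITUDE = 0.3      # relative height of the unimodal GC bias curve
DISPERSION = 0.001           # NB dispersion alpha: var = mu + alpha*mu^2


@dataclass(frozen=True)
class TruthCna:
    """A ground-truth tumor CNA with its integer copy number."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError("truth CNA copy number must be >= 0 and != 2")
        if self.end <= self.start:
            raise ValueError("empty truth region")

    @property
    def type(self) -> str:
        return GAIN if self.copy_number > 2 else LOSS

    @property
    def expected_log2(self) -> float:
        if self.copy_number == 0:
            return float("-inf")
        return float(np.log2(self.copy_number / 2))

    def to_cna_call(self) -> CnaCall:
        return CnaCall(self.chrom, self.start, self.end, self.type, self.expected_log2)


@dataclass(frozen=True)
class SimTruth:
    """The unobserved tumor state behind one simulated patient."""

    tumor_cnas: tuple[TruthCna, ...]
    tumor_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        regions = sorted(self.tumor_cnas, key=lambda c: (c.chrom, c.start))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("truth CNA regions must not overlap")


def simulate_gc_track(layout: GenomeLayout, seed: int, smooth_window: int = 15) -> np.ndarray:
    """Spatially autocorrelated per-bin GC fractions in [0.3, 0.7].

    A per-chromosome Gaussian random walk is smoothed by a moving average,
    standardized genome-wide, and squashed through tanh into the GC window.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    for chrom in layout.chrom_names:
        n = layout.n_bins_of(chrom)
        walk = np.cumsum(rng.normal(size=n + smooth_window))
        kernel = np.ones(smooth_window) / smooth_window
        pieces.append(np.convolve(walk, kernel, mode="valid")[:n])
    track = np.concatenate(pieces)
    track = (track - track.mean()) / max(track.std(), 1e-12)
    return 0.5 + 0.2 * np.tanh(0.8 * track)


def _gc_bias_curve(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth unimodal multiplicative bias, peaked near GC 0.45, mean 1."""
    raw = 1.0 + amplitude * (1.0 - ((gc - 0.45) / 0.3) ** 2)
    raw = np.maximum(raw, 0.05)
    return raw / raw.mean()


def _draw_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _expected_counts(
    layout: GenomeLayout,
    gc_track: np.ndarray,
    mean_depth: float,
    gc_bias_amplitude: float,
    truth: SimTruth | None,
    tumor_fraction: float,
) -> np.ndarray:
    mean = mean_depth * _gc_bias_curve(np.asarray(gc_track, dtype=float), gc_bias_amplitude)
    if truth is not None and tumor_fraction > 0:
        for cna in truth.tumor_cnas:
            idx = layout.region_bin_indices(cna.chrom, cna.start, cna.end)
            mean[idx] *= 1.0 + tumor_fraction * (cna.copy_number / 2.0 - 1.0)
    return mean


def simulate_donor_counts(
    layout: GenomeLayout,
    gc_track: np.ndarray,
    seed: int,
    mean_depth: float = MEAN_DEPTH,
    gc_bias_amplitude: float = GC_BIAS_AMPLITUDE,
    dispersion: float = DISPERSION,
    sample_id: str = "donor",
) -> BinProfile:
    """Healthy-donor per-bin fragment counts with GC bias and overdispersion.

    Counts are negative binomial with mean ``mean_depth * g(gc)`` where ``g``
    is a smooth unimodal curve normalized to mean 1 (so ``mean_depth`` is the
    genome-average depth at any bias amplitude); ``dispersion=0`` gives the
    Poisson limit.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    mean = _expected_counts(layout, gc_track, mean_depth, gc_bias_amplitude, None, 0.0)
    rng = np.random.default_rng(seed)
    counts = _draw_counts(mean, dispersion, rng)
    return BinProfile(sample_id=sample_id, layout=layout, raw_counts=counts, gc=np.asarray(gc_track))


def simulate_plasma_counts(
    layout: GenomeLayout,
    gc_track: np.ndarray,
    truth: SimTruth,
    seed: int,
    tumor_fraction: float | None = None,
    mean_depth: float = MEAN_DEPTH,
    gc_bias_amplitude: float = GC_BIAS_AMPLITUDE,
    dispersion: float = DISPERSION,
    sample_id: str = "plasma",
) -> BinProfile:
    """Patient plasma counts: healthy baseline plus a tumor-derived admixture.

    Inside each truth CNA the expected count is scaled by
    ``1 + tf * (copy/2 - 1)``; at ``tumor_fraction=0`` the draw reproduces
    :func:`simulate_donor_counts` exactly (same seed, identical counts).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    tf = truth.tumor_fraction if tumor_fraction is None else tumor_fraction
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    mean = _expected_counts(layout, gc_track, mean_depth, gc_bias_amplitude, truth, tf)
    rng = np.random.default_rng(seed)
    counts = _draw_counts(mean, dispersion, rng)
    return BinProfile(sample_id=sample_id, layout=layout, raw_counts=counts, gc=np.asarray(gc_track))


def simulate_tumor_truth(
    layout: GenomeLayout,
    n_cnas: int,
    seed: int,
    size_range: tuple[int, int] = (5_000_000, 100_000_000),
    copy_numbers: tuple[int, ...] = (1, 3),
    tumor_fraction: float = 0.1,
    max_tries: int = 1000,
) -> SimTruth:
    """Place ``n_cnas`` non-overlapping bin-aligned CNA regions at random.

    Copy numbers are drawn uniformly from ``copy_numbers`` (default single
    copy loss/gain, the typical LM event); region sizes are uniform over
    ``size_range`` rounded to whole bins.  ``n_cnas=0`` models the CNA-free
    tumors.  Raises if the requested regions cannot be placed without overlap.
    """
    if n_cnas < 0:
        raise ValueError("n_cnas must be >= 0")
    rng = np.random.default_rng(seed)
    bs = layout.bin_size
    chrom_names = layout.chrom_names
    lengths = layout.lengths
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    placed: list[TruthCna] = []
    tries = 0
    while len(placed) < n_cnas:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cnas} non-overlapping regions in {max_tries} tries"
            )
        tries += 1
        chrom = str(rng.choice(chrom_names, p=weights))
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = max(bs, (size // bs) * bs)
        if size >= lengths[chrom]:
            continue
        start = int(rng.integers(0, (lengths[chrom] - size) // bs + 1)) * bs
        end = start + size
        if any(c.chrom == chrom and start < c.end and c.start < end for c in placed):
            continue
        cn = int(rng.choice(copy_numbers))
        placed.append(TruthCna(chrom, start, end, cn))
    placed.sort(key=lambda c: (chrom_names.index(c.chrom), c.start))
    return SimTruth(tumor_cnas=tuple(placed), tumor_fraction=tumor_fraction, seed=seed)


def simulate_array_profile(
    truth: SimTruth, layout: GenomeLayout, seed: int, noise_sd: float = 0.1
) -> np.ndarray:
    """SNP-array-like tumor log2 track: log2(copy/2) in truth regions plus noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    log2 = np.zeros(layout.n_bins)
    for cna in truth.tumor_cnas:
        idx = layout.region_bin_indices(cna.chrom, cna.start, cna.end)
        log2[idx] = cna.expected_log2
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=layout.n_bins)
    return log2


def truth_to_bed(truth: SimTruth, path) -> None:
    """Write truth CNAs as 6-column BED: name=gain|loss, score=copy number."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c in truth.tumor_cnas:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{c.copy_number}\t.\n")


# Clinical distributions: group means from the LM/LMS comparison; the spreads
# are chosen so that two-group Welch tests on typical draws land near the
# reported significance levels (see the methods note).
LDH_MEANS = (191.0, 288.0)
LDH_SDS = (60.0, 120.0)
AGE_MEANS = (48.0, 54.0)
AGE_SDS = (9.0, 9.0)


def simulate_clinical_cohort(
    seed: int,
    n_lm: int = 9,
    n_lms: int = 8,
    ldh_means: tuple[float, float] = LDH_MEANS,
    ldh_sds: tuple[float, float] = LDH_SDS,
    age_means: tuple[float, float] = AGE_MEANS,
    age_sds: tuple[float, float] = AGE_SDS,
) -> pd.DataFrame:
    """Clinical table (patient_id, diagnosis, ldh, age), Gaussians truncated at 0."""
    if n_lm < 0 or n_lms < 0:
        raise ValueError("group sizes must be >= 0")
    if any(s < 0 for s in (*ldh_sds, *age_sds)):
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / sd  # truncate at zero
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    rows = []
    for label, n, lm, ls, am, asd, prefix in (
        ("LM", n_lm, ldh_means[0], ldh_sds[0], age_means[0], age_sds[0], "LM"),
        ("LMS", n_lms, ldh_means[1], ldh_sds[1], age_means[1], age_sds[1], "LMS"),
    ):
        ldh = draw(n, lm, ls)
        age = draw(n, am, asd)
        for i in range(n):
            rows.append((f"{prefix}-{i + 1:02d}", label, float(ldh[i]), float(age[i])))
    return pd.DataFrame(rows, columns=["patient_id", "diagnosis", "ldh", "age"])


# The study conditions: 12 patients with benign uterine smooth-muscle tumors,
# 8 of whose tumors carry CNAs (33 total; median 1, range 1-20), screened
# against a 25-donor healthy reference panel.
STUDY_CNA_COUNTS = (1, 1, 1, 1, 1, 2, 6, 20, 0, 0, 0, 0)


@dataclass
class StudyPatient:
    patient_id: str
    truth: SimTruth
    tumor_log2: np.ndarray
    plasma: BinProfile


@dataclass
class StudyCohort:
    layout: GenomeLayout
    gc_track: np.ndarray
    donors: list[BinProfile]
    patients: list[StudyPatient]
    clinical: pd.DataFrame


def simulate_study_cohort(
    seed: int,
    layout: GenomeLayout | None = None,
    n_donors: int = 25,
    cna_counts: tuple[int, ...] = STUDY_CNA_COUNTS,
    array_noise_sd: float = 0.1,
) -> StudyCohort:
    """One full synthetic study: donors, tumors, plasma, clinical table.

    Tumor fractions for CNA-positive patients are drawn log-uniformly over
    [0.02, 0.3] — low-burden disease where detection is genuinely borderline.
    CNA-free tumors get tumor fraction 0 (nothing to shed that the assay
    could see).  Everything derives deterministically from ``seed``.
    """
    layout = layout or default_layout()
    gc = simulate_gc_track(layout, seed=seed)
    donors = [
        simulate_donor_counts(layout, gc, seed=seed * 1_000 + d + 1,
                              sample_id=f"donor-{d + 1:02d}")
        for d in range(n_donors)
    ]
    rng = np.random.default_rng(seed + 99)
    patients = []
    for i, n_cnas in enumerate(cna_counts, start=1):
        tf = float(10 ** rng.uniform(-1.7, np.log10(0.3))) if n_cnas > 0 else 0.0
        truth = simulate_tumor_truth(
            layout, n_cnas, seed=seed * 2_000 + i, tumor_fraction=tf)
        tumor_log2 = simulate_array_profile(
            truth, layout, seed=seed * 3_000 + i, noise_sd=array_noise_sd)
        plasma = simulate_plasma_counts(
            layout, gc, truth, seed=seed * 4_000 + i, sample_id=f"LM-{i:02d}")
        patients.append(StudyPatient(f"LM-{i:02d}", truth, tumor_log2, plasma))
    clinical = simulate_clinical_cohort(seed=seed + 7)
    return StudyCohort(layout, gc, donors, patients, clinical)


def simulate_mutation_table(seed: int, n_patients: int = 36) -> pd.DataFrame:
    """Exome-style mutation table for a 36-patient tumor cohort.

    14 patients carry a deleterious MED12 exon-2 mutation and 2 a deleterious
    ACLY mutation (the study's recurrence structure); a sprinkling of
    patient-private deleterious mutations and benign polymorphisms in other
    genes provides realistic background that the tally must ignore.
    """
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:02d}" for i in range(n_patients)]
    order = rng.permutation(n_patients)
    med12 = [ids[k] for k in order[:14]]
    acly = [ids[k] for k in order[14:16]]
    rows = [(p, "MED12", True) for p in med12]
    rows += [(p, "ACLY", True) for p in acly]
    background = ["TTN", "MUC16", "OBSCN", "FLG", "SYNE1", "USH2A"]
    for gene, p_idx in zip(background, rng.permutation(n_patients)[:len(background)]):
        rows.append((ids[p_idx], gene, bool(rng.random() < 0.5)))
    df = pd.DataFrame(rows, columns=["patient_id", "gene", "deleterious"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
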