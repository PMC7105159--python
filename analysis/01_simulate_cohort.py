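"""Generate the synthetic study cohort and write it to disk.

Simulates the full input set of a tumor-informed plasma CNA screen: a
25-donor healthy cfDNA reference panel, 12 patients with benign uterine
smooth-muscle tumors (8 tumors carrying 33 CNAs between them — counts
1,1,1,1,1,2,6,20 — and 4 CNA-free), matched SNP-array-style tumor log2
profiles and shallow-WGS plasma bin counts, and a clinical table with the
LM/LMS LDH and age distributions.

Bulky per-sample tables go to scratch/cohort/ (regenerable from the seed);
small summary tables go to results/.
"""

import argparse
import json
from pathlib import Path

from plasmacna import synthetic
from plasmacna.tumor import summarize_cna_burden

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    study = synthetic.simulate_study_cohort(args.seed)
    layout = study.layout

    args.outdir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    bins = layout.bins()
    bins["gc"] = study.gc_track
    bins.to_csv(args.outdir / "gc_track.tsv", sep="\t", index=False)
    for prof in study.donors:
        prof.write_tsv(args.outdir / f"{prof.sample_id}.tsv")
    for pat in study.patients:
        synthetic.truth_to_bed(pat.truth, args.outdir / f"{pat.patient_id}.truth.bed")
        t = layout.bins()
        t["log2"] = pat.tumor_log2
        t.to_csv(args.outdir / f"{pat.patient_id}.tumor_log2.tsv", sep="\t", index=False)
        pat.plasma.write_tsv(args.outdir / f"{pat.patient_id}.plasma.tsv")
    study.clinical.to_csv(results / "clinical.tsv", sep="\t", index=False)

    truth_calls = {
        p.patient_id: [c.to_cna_call() for c in p.truth.tumor_cnas] for p in study.patients
    }
    burden = summarize_cna_burden(truth_calls)
    mean_depth = sum(p.raw_counts.mean() for p in study.donors) / len(study.donors)
    summary = {
        "seed": args.seed,
        "n_donors": len(study.donors),
        "n_patients": len(study.patients),
        "n_bins": layout.n_bins,
        "bin_size": layout.bin_size,
        "mean_fragments_per_bin": round(mean_depth, 2),
        "tumor_cna_burden": {
            "total": burden["total_cnas"],
            "patients_with_cnas": burden["n_with_cnas"],
            "median": burden["median"],
            "range": burden["range"],
        },
        "tumor_fractions": {
            p.patient_id: round(p.truth.tumor_fraction, 4) for p in study.patients
        },
    }
    (results / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"Simulated cohort (seed {args.seed}):")
    print(f"  {len(study.donors)} healthy donors, {layout.n_bins} bins of "
          f"{layout.bin_size // 1_000_000} Mb, mean {mean_depth:.1f} fragments/bin")
    print(f"  {burden['total_cnas']} tumor CNAs across {burden['n_with_cnas']} of "
          f"{len(study.patients)} patients (median {burden['median']}, "
          f"range {burden['range']})")
    print(f"  per-sample tables -> {args.outdir}")
    print(f"  summaries -> {results}")


if __name__ == "__main__":
    main()
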