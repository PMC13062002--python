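#!/usr/bin/env python
"""Simulate a twelve-exposure study against one shared disease outcome.

Emulates the published analysis shape — many exposure GWAS (metabolic and
inflammatory traits at the published effect magnitudes, plus deliberate
nulls) paired with a single case-control outcome GWAS — writing the same
tab-delimited summary-statistic dialect the pipeline reads, a per-variant
truth table, and a ready-to-run pipeline configuration.

Each exposure gets its own block of variant ids inside the shared outcome
file, mimicking non-overlapping published instrument lists.
"""

import argparse
from pathlib import Path

import yaml

from mrkit.io import write_summary_stats
from mrkit.synthetic import SyntheticScenario, generate

ROOT = Path(__file__).resolve().parents[1]

#: label -> true causal effect (log-odds per exposure unit); magnitudes
#: follow the published IVW estimates for the corresponding trait class.
EXPOSURES = {
    "glucose_ukb_like": -0.722,
    "glucose_magic_like": -0.843,
    "atopy_combined_like": 0.610,
    "nonasthma_allergy_like": 0.518,
    "eosinophil_like": 0.353,
    "asthma_like": 0.263,
    "childhood_asthma_like": 0.042,
    "adult_asthma_like": 0.014,
    "rheumatoid_arthritis_like": 0.104,
    "crohns_like": 0.077,
    "ulcerative_colitis_like": 0.015,
    "null_trait": 0.0,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-instruments", type=int, default=40)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "sim_study")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    outcome_records = []
    truth_frames = []
    exposure_entries = []
    for k, (label, theta) in enumerate(EXPOSURES.items()):
        scenario = SyntheticScenario(
            n_instruments=args.n_instruments,
            theta_true=theta,
            gamma_mean=0.08,
            gamma_sd=0.02,
            palindromic_fraction=0.1,
            swap_fraction=0.3,
            seed=args.seed * 1000 + k,
        )
        exposure, outcome, truth = generate(scenario)
        for rec_e, rec_o in zip(exposure, outcome):
            rec_e.variant_id = f"{k:02d}_{rec_e.variant_id}"
            rec_o.variant_id = f"{k:02d}_{rec_o.variant_id}"
        truth["variant_id"] = [f"{k:02d}_{v}" for v in truth["variant_id"]]
        truth.insert(0, "exposure", label)
        truth.insert(1, "theta_true", theta)
        path = args.out / f"{label}.tsv"
        write_summary_stats(exposure, path)
        outcome_records.extend(outcome)
        truth_frames.append(truth)
        exposure_entries.append({"path": str(path), "label": label})
        print(f"  {label:28s} theta={theta:+.3f}  -> {path.name}")

    outcome_path = args.out / "keratoconus_like_outcome.tsv"
    write_summary_stats(outcome_records, outcome_path)

    import pandas as pd

    truth_path = args.out / "truth.tsv"
    pd.concat(truth_frames).to_csv(truth_path, sep="\t", index=False)

    config = {
        "outcome": {"path": str(outcome_path), "label": "keratoconus_like"},
        "exposures": exposure_entries,
        "seed": args.seed,
        "n_boot": 2000,
        "output_dir": str(ROOT / "results" / "mr_report"),
    }
    config_path = args.out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    print(f"wrote {outcome_path}, {truth_path} and {config_path}")


if __name__ == "__main__":
    main()
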