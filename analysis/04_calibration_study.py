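#!/usr/bin/env python
"""Estimator calibration under known truth: bias, coverage, test size.

Replicates strong-instrument scenarios at the published effect magnitudes
(glucose-scale -0.72, null, asthma-scale 0.26, atopy-scale 0.61) and
tabulates, per estimator, mean bias, empirical vs estimated SE, RMSE and
95% CI coverage, plus the Egger intercept test's rejection rate under the
no-pleiotropy null and under directional pleiotropy.

Expected finding: IVW and the simple median are unbiased to within
Monte-Carlo error with ~95% coverage; MR-Egger shows its known mild
regression dilution but near-nominal coverage; the intercept test holds
its ~5% size under the null and gains power under directional pleiotropy.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrkit.synthetic import evaluate, strong_instrument_scenario

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=500)
    args = parser.parse_args()

    frames = []
    for slug, theta in [("glucose-scale", -0.722), ("null", 0.0),
                        ("asthma-scale", 0.263), ("atopy-scale", 0.610)]:
        scenario = strong_instrument_scenario(theta, seed=args.seed)
        metrics = evaluate(args.replicates, scenario, n_boot=200)
        metrics.insert(0, "scenario", slug)
        metrics.insert(1, "theta_true", theta)
        frames.append(metrics)

    for mode, kwargs in [
        ("null (no pleiotropy)", {}),
        ("directional pleiotropy",
         {"pleiotropy_mode": "directional", "alpha_mean": 0.02,
          "alpha_sd": 0.005}),
    ]:
        scenario = strong_instrument_scenario(0.263, seed=args.seed + 1, **kwargs)
        metrics = evaluate(args.replicates, scenario, methods=("egger",), n_boot=100)
        metrics.insert(0, "scenario", f"egger intercept test, {mode}")
        metrics.insert(1, "theta_true", 0.263)
        frames.append(metrics)

    table = pd.concat(frames, ignore_index=True)
    out_path = ROOT / "results" / "calibration.tsv"
    out_path.parent.mkdir(exist_ok=True)
    table.to_csv(out_path, sep="\t", index=False, float_format="%.6g")

    with pd.option_context("display.width", 160, "display.max_columns", 20):
        print(table[["scenario", "method", "mean_bias", "bias_mc_se",
                     "empirical_se", "mean_est_se", "coverage",
                     "intercept_rejection_rate"]].round(4).to_string(index=False))
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
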