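#!/usr/bin/env python
"""Regenerate the published keratoconus odds ratios from their log-odds inputs.

The published results tables report, per exposure and MR method, the
estimate on the log-odds scale and its SE.  This driver pushes every pair
through the package's reporting transforms and writes the resulting OR,
95% CI and p-value table, printing the headline rows.

Finding: all five headline OR (95% CI) values — glucose 0.49 (0.33-0.72)
and 0.43 (0.29-0.64), combined atopy 1.84 (1.52-2.22), non-asthma allergy
1.68 (1.44-1.95), eosinophil count 1.42 (1.21-1.68) — are recovered after
2-dp rounding, and the twelve-test Bonferroni threshold is 0.0042.
"""

from pathlib import Path

from mrkit.reference import PUBLISHED_N_TESTS, published_or_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = published_or_table(confidence=0.95)
    out_path = OUT / "published_or_ci.tsv"
    table.to_csv(out_path, sep="\t", index=False, float_format="%.6g")

    ivw = table[table.method == "IVW"]
    print("IVW odds ratios regenerated from published (ln(OR), SE) pairs:")
    for row in ivw.itertuples():
        print(
            f"  {row.exposure:32s} [{row.source:15s}] "
            f"OR={row._6:.2f} (95% CI {row.ci_low:.2f}-{row.ci_high:.2f}) "
            f"p={row.pvalue:.2E}"
        )
    print(f"\nBonferroni threshold for {PUBLISHED_N_TESTS} IVW tests: "
          f"{0.05 / PUBLISHED_N_TESTS:.4f}")
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
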