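#!/usr/bin/env python
"""Quantify internal consistency and test-retest reliability.

Split-half (change-point-level, Spearman-Brown corrected) reliability of
the CP-aligned median learning rate and confidence, ICC(2,1) between the
two sessions for the same measures and for the regression coefficients,
and the reliability-vs-number-of-change-points curve for confidence.
"""

import argparse

import pandas as pd

from predinf import pipeline, psychometrics
from predinf.behaviour import align_to_cps
from predinf.io import read_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results/pipeline")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--skip-coefficients", action="store_true",
                    help="skip the slow regression-coefficient block")
    args = ap.parse_args()

    table = pipeline.stage_psychometrics(
        args.out_dir, seed=args.seed, coefficients=not args.skip_coefficients
    )
    raw = table[table["measure"].isin(["lr", "confidence"])]
    print("Reliability of CP-aligned median measures:")
    with pd.option_context("display.float_format", "{:.3f}".format):
        print(raw.pivot_table(index=["measure", "phase"], columns="estimator",
                              values="estimate").round(3).to_string())

    normative = read_table(f"{args.out_dir}/normative.csv")
    sess1 = normative[normative["session"] == 1]

    def conf_stable(sub):
        even = align_to_cps(sub, "confidence", cp_half="even").set_index("participant_id")
        odd = align_to_cps(sub, "confidence", cp_half="odd").set_index("participant_id")
        return psychometrics.split_half_scores(even["off_0"], odd["off_0"])

    curve = psychometrics.reliability_vs_ncps(
        sess1, conf_stable, cp_range=range(6, 25, 3)
    )
    curve.to_csv(f"{args.out_dir}/reliability_vs_ncps.csv", index=False)
    print("\nSplit-half reliability of CP-trial confidence vs number of CPs used:")
    print(curve[["n_cps", "estimate", "category"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
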