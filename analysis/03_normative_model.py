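#!/usr/bin/env python
"""Run the reduced Bayesian learner on every participant's trial stream.

Conditioned on each participant's own prediction errors, the learner
yields trial-wise change-point probability (CPP), relative uncertainty
(RU) and its own normative learning rate. The script reports the
co-linearity between CPP and |PE| that is inherent to this task's fixed
hazard rate and outcome noise.
"""

import argparse

import numpy as np

from predinf import pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results/pipeline")
    ap.add_argument("--mode", default="conditioned_on_participant",
                    choices=["normative", "conditioned_on_participant"])
    args = ap.parse_args()

    normative = pipeline.stage_normative(args.out_dir, mode=args.mode)
    for sess, g in normative.groupby("session"):
        r = np.corrcoef(g["cpp"], g["pe"].abs())[0, 1]
        print(f"Session {sess}: corr(CPP, |PE|) = {r:.3f} "
              f"(CPP mean {g['cpp'].mean():.3f}, RU mean {g['ru'].mean():.3f})")
    print("\nStrong CPP-|PE| co-linearity is expected: with a fixed hazard "
          "rate and outcome SD, surprise is almost a deterministic function "
          "of the error magnitude.")


if __name__ == "__main__":
    main()
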