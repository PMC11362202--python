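#!/usr/bin/env python
"""Derive the behavioural measures and apply the data-quality screens.

Computes per-trial prediction error, action-update and learning rate,
applies the confidence-scale exclusion criteria and the pooled
99th-percentile learning-rate trim, and summarises how the learning rate
and confidence move around change-points (the task's behavioural
signature).
"""

import argparse

import pandas as pd

from predinf import behaviour, pipeline
from predinf.io import read_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results/pipeline")
    args = ap.parse_args()

    derived = pipeline.stage_derive(args.out_dir)
    ledger = read_table(f"{args.out_dir}/ledger.csv")
    print("Exclusion ledger:")
    print(ledger.to_string(index=False))

    for sess, g in derived.groupby("session"):
        aligned = behaviour.align_to_cps(g, "lr", stat="median")
        group = aligned[[behaviour._off_col(o) for o in behaviour.OFFSETS]].median()
        res = behaviour.cp_effect_test(aligned)
        print(f"\nSession {sess}: group-median learning rate by CP offset")
        print(group.round(3).to_string())
        print(f"CP vs post-CP adaptation: mean diff {res.mean:.3f}, "
              f"Welch t({res.df:.1f}) = {res.t:.2f}, p = {res.p:.2g}")
        conf = behaviour.align_to_cps(g, "confidence", stat="median")
        cg = conf[[behaviour._off_col(o) for o in behaviour.OFFSETS]].mean()
        print(f"Confidence dip after CP: {cg['off_-1']:.1f} (pre) -> "
              f"{cg['off_+1']:.1f} (post) -> {cg['off_+4']:.1f} (recovered)")


if __name__ == "__main__":
    main()
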