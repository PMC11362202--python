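#!/usr/bin/env python
"""Render the final plain-text report of every pipeline table."""

import argparse

from predinf import pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results/pipeline")
    args = ap.parse_args()
    print(pipeline.stage_report(args.out_dir))


if __name__ == "__main__":
    main()
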