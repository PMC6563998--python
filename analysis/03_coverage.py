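"""Gap analysis: how much of each species' climate space the reserves cover,
and how much is lost inside them between periods.

Writes the per-group coverage and loss tables and richness maps, and prints
the group means (+/- sample sd, in percent).

Usage: python analysis/03_coverage.py [--outdir results/run]
"""

import argparse
import logging

from islereserve.pipeline import load_bundle, load_consensus, stage_coverage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)

    bundle = load_bundle(f"{args.outdir}/bundle")
    consensus = load_consensus(args.outdir)
    tables, _rich = stage_coverage(consensus, bundle, args.outdir)

    print("share of suitable climate space inside current reserves (% +/- sd):")
    print(tables["coverage"].round(1).to_string(index=False))
    print("\nloss of suitable climate space inside reserves, baseline -> future:")
    print(tables["loss"].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
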