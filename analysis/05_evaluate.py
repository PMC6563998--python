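"""Score the current reserves: efficiency ratios against the quasi-optimal
networks and null-model significance of per-species coverage.

Re-runs the optimization stage (deterministic for a given seed), writes
efficiency.csv and null_comparison.csv, and prints both tables.

Usage: python analysis/05_evaluate.py [--seed 1] [--outdir results/run]
"""

import argparse
import logging

from islereserve.pipeline import (
    load_bundle,
    load_config,
    load_consensus,
    stage_evaluate,
    stage_optimize,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--config", default=None)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)

    cfg = load_config(args.config)
    bundle = load_bundle(f"{args.outdir}/bundle")
    consensus = load_consensus(args.outdir)
    runs = stage_optimize(consensus, bundle, cfg, args.seed, args.outdir)
    eff_df, null_df = stage_evaluate(runs, bundle, cfg, args.seed, args.outdir)

    print("reserve efficiency (1 = current reserves match the quasi-optimum):")
    print(eff_df.round(3).to_string(index=False))
    print("\nspecies coverage vs random reserves of equal size:")
    print(null_df.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
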