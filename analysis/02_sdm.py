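"""Fit per-species ensembles and project consensus maps for both periods.

Samples occurrences from the simulated baseline ranges, evaluates the two
reference suitability models over ten 80/20 splits with the True Skill
Statistic, filters members with mean TSS < 0, and writes per-species
majority-consensus rasters plus the evaluation table.

Usage: python analysis/02_sdm.py [--seed 1] [--outdir results/run]
"""

import argparse
import logging

import pandas as pd

from islereserve.pipeline import load_bundle, load_config, stage_sdm


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--config", default=None)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)

    cfg = load_config(args.config)
    bundle = load_bundle(f"{args.outdir}/bundle")
    consensus, eval_df = stage_sdm(bundle, cfg, args.seed, args.outdir)

    print(f"modelled {len(consensus)} of {len(bundle.species)} species")
    summary = (
        eval_df.groupby("model")["tss"].agg(["mean", "min", "max"]).round(3)
        if not eval_df.empty
        else pd.DataFrame()
    )
    print("TSS by member model across species and splits:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
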