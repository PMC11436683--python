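#!/usr/bin/env python
"""Which uncertainties drive which outcomes: extra-trees feature scoring.

Reads the stored ensemble (run 02_ensemble.py first, or this script draws a
fresh one), fits extremely-randomised-trees regressions of each outcome on
the sampled parameters, and writes the normalised importance matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from mesofishery import build_space, feature_scores, lhs_sample, run_ensemble
from mesofishery.config import stage_seed

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    OUT.mkdir(exist_ok=True)
    samples_csv = OUT / "samples.csv"
    if samples_csv.exists():
        samples = pd.read_csv(samples_csv, index_col="run").iloc[:args.n]
        ens = pd.read_csv(OUT / "outcomes_open.csv", index_col="run").iloc[:args.n]
    else:
        sm = lhs_sample(build_space(), args.n, stage_seed(args.seed, "sampling"))
        samples, ens = sm.values, run_ensemble(sm)

    fs = feature_scores(samples, ens, seed=stage_seed(args.seed, "trees"))
    fs.to_csv(OUT / "feature_scores.csv", index_label="outcome")

    print(f"Extra-trees feature scores over {len(samples)} runs:")
    for outcome in fs.index:
        top = fs.loc[outcome].sort_values(ascending=False)[:3]
        drivers = ", ".join(f"{p} ({v:.2f})" for p, v in top.items())
        print(f"  {outcome:28s} <- {drivers}")


if __name__ == "__main__":
    main()
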