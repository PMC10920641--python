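"""Reduce synchrony matrices to the 25-feature dyad table.

Each synchrony matrix collapses to seven order-free summary statistics
(min, max, mean, median, SD, skew, kurtosis); with the four movement
quantities this gives 25 behavioral features per dyad. Age and diagnostic
label ride along as metadata — age is regressed out inside CV folds, never
used as a feature.

Writes features.csv under the run directory.
"""

import argparse

import pandas as pd

from dyadsync.pipeline import RunConfig, run


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--outdir", default="results/run")
    parser.add_argument("--features", choices=["mea", "mea+demo"], default="mea")
    args = parser.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed, fps=29.95,
                    feature_mode=args.features)
    out = run("featurize", cfg)
    table = pd.read_csv(out / "features.csv", index_col="dyad_id")
    n_feat = table.shape[1] - 2  # label + age are metadata
    print(f"feature table: {table.shape[0]} dyads x {n_feat} features")
    print(table.filter(like="body_sync").describe().loc[["mean", "std"]].round(3))


if __name__ == "__main__":
    main()
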