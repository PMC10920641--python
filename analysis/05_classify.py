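"""Nested cross-validated linear SVM classification of dyad type.

Runs the repeated nested stratified CV (here 10 outer folds x 3
repetitions, 10 inner folds, the 11-point C grid) with all preprocessing
fit in-fold, pools each dyad's held-out decision scores by their median,
and reports confusion-derived metrics. Optionally runs the
label-permutation significance test.

Writes pooled_scores.csv, metrics.json and the model store under the run
directory.
"""

import argparse
import json

from dyadsync.pipeline import RunConfig, run


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--outdir", default="results/run")
    parser.add_argument("--labeling", choices=["asd-cc", "ndd-cc"],
                        default="asd-cc")
    parser.add_argument("--permutations", type=int, default=0,
                        help="label-permutation test size (0 skips it)")
    args = parser.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed, fps=29.95,
                    outer_folds=10, outer_perms=3, inner_folds=10,
                    labeling=args.labeling, permutations=args.permutations)
    out = run("classify", cfg)
    m = json.loads((out / "metrics.json").read_text())["metrics"]
    print(f"confusion tn/tp/fn/fp = {m['tn']}/{m['tp']}/{m['fn']}/{m['fp']}")
    print(f"BAC = {m['bac']:.1%}  sensitivity = {m['sensitivity']:.1%}  "
          f"specificity = {m['specificity']:.1%}  AUC = {m['auc']:.2f}")
    if "permutation_p" in m:
        print(f"permutation test p = {m['permutation_p']:.3f}")


if __name__ == "__main__":
    main()
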