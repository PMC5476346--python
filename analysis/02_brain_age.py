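"""Train the brain-age model and predict the test cohort.

Fits the linear-kernel Gaussian-process age regression on the training
kernel, reports 10-fold cross-validated accuracy (Pearson r, R^2, MAE,
RMSE) with a label-permutation p-value, then applies the full trained
model to the DS/control cross-kernel to produce brain-predicted ages
and brain-PAD scores.

Run after 01:  python analysis/02_brain_age.py [--seed 42] [--out results/run]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from neurochron.brainage import permutation_test
from neurochron.config import RunConfig
from neurochron.io import read_kernel
from neurochron.pipeline import run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--n-perm", type=int, default=199,
                    help="label permutations for the significance test")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    cfg.simulation.seed = args.seed
    run_pipeline(cfg, args.out, stages=["train", "predict"])

    acc = json.loads((args.out / "accuracy.json").read_text())
    print("10-fold cross-validated accuracy on the training set:")
    print(f"  r = {acc['pearson_r']:.3f}, R^2 = {acc['r_squared']:.3f}, "
          f"MAE = {acc['mae_years']:.2f} y, RMSE = {acc['rmse_years']:.2f} y")

    K, ids = read_kernel(args.out / "kernel_train.csv")
    ages = pd.read_csv(args.out / "cohort.csv").set_index(
        "subject_id").loc[ids, "age_years"].to_numpy()
    perm = permutation_test(K, ages, n_perm=args.n_perm, k=cfg.folds,
                            seed=args.seed, optimize=False,
                            hypers=(1.0, float(np.var(ages))))
    print(f"  permutation test (n = {args.n_perm}): p = {perm['p_value']:.4f}")

    preds = pd.read_csv(args.out / "predictions.csv")
    coh = pd.read_csv(args.out / "cohort.csv")
    m = preds.merge(coh[["subject_id", "group"]], on="subject_id")
    for grp in ("DS", "control"):
        pad = m.loc[m["group"] == grp, "brain_pad"]
        print(f"  mean brain-PAD {grp}: {pad.mean():+.2f} y "
              f"(SD {pad.std():.2f})")


if __name__ == "__main__":
    main()
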