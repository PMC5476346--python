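"""Classify PiB status and regional amyloid abnormality.

From the fitted subject x ROI BP_ND table: computes striatal BP_ND per
subject, splits the cohort at one SD of the bimodal striatal
distribution from zero, flags regions >= 2 SD above the PiB-negative
mean, counts abnormal regions (0-30) and averages cortical BP_ND.

Run after 03:  python analysis/04_amyloid_status.py [--seed 42] [--out results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from neurochron.config import RunConfig
from neurochron.pipeline import run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    cfg.simulation.seed = args.seed
    run_pipeline(cfg, args.out, stages=["amyloid"])

    prof = pd.read_csv(args.out / "profiles.csv")
    pos = prof[prof["pib_status"] == "positive"]
    print(f"PiB-positive: {len(pos)} / {len(prof)} DS subjects")
    print(f"  mean cortical BP_ND in positives: "
          f"{pos['mean_cortical_bpnd'].mean():.2f} "
          f"(SD {pos['mean_cortical_bpnd'].std():.2f})")
    print(f"  median abnormal-ROI count in positives: "
          f"{pos['abnormal_count'].median():.0f} "
          f"(range {pos['abnormal_count'].min():.0f}-"
          f"{pos['abnormal_count'].max():.0f} of 30)")
    truth = pd.read_csv(args.out / "cohort.csv").set_index("subject_id")
    m = prof.set_index("subject_id").join(truth["pib_positive_true"])
    agree = ((m["pib_status"] == "positive")
             == m["pib_positive_true"].astype(bool)).mean()
    print(f"  agreement with generating labels: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
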