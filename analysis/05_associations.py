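"""Fit the cohort association models.

Merges demographics, brain-PAD predictions, volume summaries and
amyloid profiles, then fits the full model battery: the group effect on
brain-PAD and ICV, logistic prediction of PiB status, linear models of
amyloid burden, the CAMCOG ~ brain-PAD x PiB interaction, the ordinal
CAMDEX model, and the supporting correlations and t-tests.

Run after 04:  python analysis/05_associations.py [--seed 42] [--out results/run]
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
    run_pipeline(cfg, args.out, stages=["stats"])

    res = pd.read_csv(args.out / "stats_results.csv")

    def show(model, term, label):
        row = res[(res["model_name"] == model) & (res["term"] == term)]
        if row.empty:
            return
        r = row.iloc[0]
        print(f"  {label}: b = {r['estimate']:.3g} (SE {r['se']:.3g}, "
              f"p = {r['p']:.3g})")

    print("headline models (full table in stats_results.csv):")
    show("brainpad_group", "group_ds", "brain-PAD ~ group (DS effect, years)")
    show("icv_group", "group_ds", "ICV ~ group (litres)")
    show("pib_status_logistic", "brain_pad", "PiB+ ~ brain-PAD (log-odds/yr)")
    show("mean_cortical_bpnd_linear", "brain_pad",
         "mean cortical BP_ND ~ brain-PAD")
    show("abnormal_count_linear", "brain_pad", "abnormal ROIs ~ brain-PAD")
    show("camcog_interaction", "brain_pad_x_pib",
         "CAMCOG ~ brain-PAD x PiB interaction")
    show("camdex_ordinal", "brain_pad", "CAMDEX ~ brain-PAD (ordinal)")
    print(f"full report: {args.out / 'report.md'}")


if __name__ == "__main__":
    main()
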