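"""End-to-end orchestration: simulate -> features -> brain age -> PET -> stats.

Each stage writes its outputs under the run directory and later stages
read them back from disk, so any stage can be re-run alone against the
cached outputs of earlier stages.  Every run writes ``run_metadata.json``
stamped with the config hash, the seed and per-stage parameters.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import amyloid as amy
from . import brainage, features, io, kinetics
from .config import RunConfig
from .synthetic import generate_cohort

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("neurochron")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    data = generate_cohort(cfg.simulation)
    io.write_cohort(data.cohort, out / "cohort.csv")
    tac_dir = out / "tacs"
    tac_dir.mkdir(exist_ok=True)
    for sid, table in data.tacs.items():
        io.write_tacs(table, tac_dir / f"{sid}.tsv")
    if data.regional_truth is not None:
        data.regional_truth.rename_axis("subject_id").to_csv(
            out / "bpnd_true.csv")
    cfg.to_yaml(out / "config.yaml")
    state["cohort"] = data.cohort
    state["maps"] = data.maps
    state["schedule"] = data.schedule


def _load_cohort(out: Path, state: dict) -> pd.DataFrame:
    if "cohort" not in state:
        state["cohort"] = io.read_cohort(out / "cohort.csv")
    return state["cohort"]


def _stage_features(cfg: RunConfig, out: Path, state: dict) -> None:
    cohort = _load_cohort(out, state)
    maps = state.get("maps")
    if maps is None:
        raise FileNotFoundError("tissue maps not available; run simulate first")
    ids = list(cohort["subject_id"])
    vecs = {sid: features.vectorize(maps[sid], cfg.fwhm_mm) for sid in ids}
    vols = pd.DataFrame([{
        "subject_id": sid,
        **{f"{k}": v for k, v in vars(features.summary_volumes(maps[sid])).items()},
    } for sid in ids])
    vols.to_csv(out / "volumes.csv", index=False)

    train_ids = list(cohort.loc[cohort["group"] == "train", "subject_id"])
    test_ids = list(cohort.loc[cohort["group"] != "train", "subject_id"])
    ktrain = features.linear_kernel([vecs[s] for s in train_ids], train_ids)
    kcross = features.cross_kernel([vecs[s] for s in train_ids],
                                   [vecs[s] for s in test_ids])
    io.write_kernel(ktrain.values, train_ids, out / "kernel_train.csv")
    pd.DataFrame(kcross, index=test_ids, columns=train_ids).to_csv(
        out / "kernel_cross.csv")
    state.update(ktrain=ktrain, kcross=kcross, train_ids=train_ids,
                 test_ids=test_ids, volumes=vols)


def _load_kernels(out: Path, state: dict) -> None:
    if "ktrain" not in state:
        values, ids = io.read_kernel(out / "kernel_train.csv")
        state["ktrain"] = features.KernelMatrix(values, ids)
        state["train_ids"] = ids
    if "kcross" not in state:
        df = pd.read_csv(out / "kernel_cross.csv", index_col=0)
        state["kcross"] = df.to_numpy(float)
        state["test_ids"] = [str(i) for i in df.index]


def _stage_train(cfg: RunConfig, out: Path, state: dict) -> None:
    cohort = _load_cohort(out, state)
    _load_kernels(out, state)
    ages = cohort.set_index("subject_id").loc[state["train_ids"], "age_years"]
    cv = brainage.crossval_predict(state["ktrain"], ages.to_numpy(),
                                   k=cfg.folds, seed=cfg.seed)
    cv["subject_id"] = state["train_ids"]
    cv.to_csv(out / "cv_predictions.csv", index=False)
    report = brainage.performance(cv["age_years"], cv["brain_predicted_age"])
    acc = vars(report).copy()
    if cfg.run_permutation:
        perm = brainage.permutation_test(state["ktrain"], ages.to_numpy(),
                                         n_perm=cfg.n_perm, k=cfg.folds,
                                         seed=cfg.seed)
        acc["permutation_p"] = perm["p_value"]
    with open(out / "accuracy.json", "w") as fh:
        json.dump(acc, fh, indent=2)
    model = brainage.fit_gpr(state["ktrain"], ages.to_numpy())
    with open(out / "model.json", "w") as fh:
        json.dump({
            "dual_weights": model.dual_weights.tolist(),
            "train_mean_age": model.train_mean_age,
            "signal_var": model.signal_var,
            "noise_var": model.noise_var,
            "kernel_norm": model.kernel_norm,
            "train_ids": model.train_ids,
        }, fh)
    state["model"] = model


def _load_model(out: Path, state: dict) -> brainage.GPRModel:
    if "model" not in state:
        with open(out / "model.json") as fh:
            d = json.load(fh)
        state["model"] = brainage.GPRModel(
            np.asarray(d["dual_weights"]), d["train_mean_age"],
            d["signal_var"], d["noise_var"], d["kernel_norm"], d["train_ids"])
    return state["model"]


def _stage_predict(cfg: RunConfig, out: Path, state: dict) -> None:
    cohort = _load_cohort(out, state)
    _load_kernels(out, state)
    model = _load_model(out, state)
    ages = cohort.set_index("subject_id").loc[state["test_ids"], "age_years"]
    preds = brainage.predict(model, state["kcross"],
                             subject_ids=state["test_ids"],
                             ages=ages.to_numpy())
    preds.to_csv(out / "predictions.csv", index=False)
    state["predictions"] = preds


def _stage_kinetics(cfg: RunConfig, out: Path, state: dict) -> None:
    tac_dir = out / "tacs"
    grid = np.geomspace(cfg.theta3_lo_per_min, cfg.theta3_hi_per_min,
                        cfg.theta3_n)
    rows = []
    for path in sorted(tac_dir.glob("*.tsv")):
        sched, rois = io.read_tacs(path)
        ref = kinetics.TAC(sched, rois["superior_cerebellum"].to_numpy(float),
                           roi_id="superior_cerebellum")
        row = {"subject_id": path.stem}
        for roi in rois.columns:
            if roi == "superior_cerebellum":
                continue
            tac = kinetics.TAC(sched, rois[roi].to_numpy(float), roi_id=roi)
            fit = kinetics.srtm_basis_fit(tac, ref, grid,
                                          fine_dt_s=cfg.simulation.fine_dt_s)
            row[roi] = fit.bpnd
        rows.append(row)
    bpnd = pd.DataFrame(rows).set_index("subject_id")
    bpnd.to_csv(out / "bpnd.csv")
    state["bpnd"] = bpnd


def _stage_amyloid(cfg: RunConfig, out: Path, state: dict) -> None:
    if "bpnd" not in state:
        state["bpnd"] = pd.read_csv(out / "bpnd.csv", index_col=0)
    profiles = amy.build_profiles(state["bpnd"], sd_mode=cfg.sd_mode,
                                  fixed_sd=cfg.fixed_sd)
    profiles.to_csv(out / "profiles.csv", index=False)
    profiles.attrs["flags"].to_csv(out / "abnormal_flags.csv")
    state["profiles"] = profiles


def _stage_stats(cfg: RunConfig, out: Path, state: dict) -> None:
    from .stats import run_cohort_models

    cohort = _load_cohort(out, state)
    if "predictions" not in state:
        state["predictions"] = pd.read_csv(out / "predictions.csv",
                                           dtype={"subject_id": str})
    if "profiles" not in state:
        state["profiles"] = pd.read_csv(out / "profiles.csv",
                                        dtype={"subject_id": str})
    if "volumes" not in state:
        state["volumes"] = pd.read_csv(out / "volumes.csv",
                                       dtype={"subject_id": str})
    merged = (cohort.merge(state["predictions"].drop(columns=["age_years"]),
                           on="subject_id", how="inner")
              .merge(state["volumes"], on="subject_id", how="left")
              .merge(state["profiles"], on="subject_id", how="left"))
    merged.to_csv(out / "merged.csv", index=False)
    models = run_cohort_models(merged)
    tidy = pd.concat([m.tidy() for m in models], ignore_index=True)
    tidy.to_csv(out / "stats_results.csv", index=False)
    lines = ["# Cohort model results", ""]
    for m in models:
        lines.append(f"## {m.model_name} (n = {m.n}, {m.statistic_kind}-statistics)")
        lines.append(m.terms.to_string(index=False))
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    state["stats"] = models


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "train": _stage_train,
    "predict": _stage_predict,
    "kinetics": _stage_kinetics,
    "amyloid": _stage_amyloid,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig, out_dir, stages=None) -> Path:
    """Run the configured stages, writing all outputs under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    stages = list(stages or config.stages)
    meta = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    for name in stages:
        func = _STAGE_FUNCS.get(name)
        if func is None:
            raise PipelineError(f"unknown stage '{name}'")
        log.info("stage %s starting", name)
        try:
            func(config, out, state)
        except Exception as exc:            # noqa: BLE001 - re-raised with stage
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        meta["stages"][name] = {"status": "ok"}
        log.info("stage %s done", name)
    meta["parameters"] = config.to_dict()
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return out
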