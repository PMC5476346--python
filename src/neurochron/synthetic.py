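"""Synthetic cohorts with the statistical structure the analysis assumes.

Real study data (MRI tissue maps, dynamic PiB PET, cognition) are not
redistributable, so every downstream stage is exercised on a generated
cohort that emulates three structural facts:

1. **Tissue maps age.**  A subject's GM probability map declines
   linearly with an *effective age* (chronological age plus a
   group-level offset for Down syndrome plus a per-subject brain-age
   deviation), over a fixed smooth spatial pattern; WM declines at half
   the rate; CSF takes up the remainder.
2. **Striatal amyloid is bimodal.**  PiB-negative subjects draw striatal
   BP_ND from a tight component around zero, PiB-positive subjects from
   an elevated component; dynamic TACs are generated from the SRTM
   forward model with known R1/k2/BP_ND per region, so kinetic fits have
   a ground truth.
3. **Cognition couples to brain-PAD only under amyloid.**  CAMCOG falls
   with the true brain-age deviation in PiB-positive subjects only
   (an interaction), plus noise.

All draws are deterministic given the configured seed; per-subject
streams are sub-seeded as ``seed + subject index`` in a fixed order so
adding subjects never perturbs earlier subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import TissueMaps
from .kinetics import FrameSchedule, TAC, standard_schedule, frame_average, srtm_forward

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "CohortData",
    "generate_cohort",
    "simulate_tissue_maps",
    "gamma_variate",
    "simulate_reference_tac",
    "simulate_target_tac",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the cohort being emulated: 46 DS and 30 control test
    subjects, a lifespan training set, a DS effective-age offset near the
    reported adjusted group effect, and a bimodal striatal BP_ND mixture
    with a positive fraction of 19/46.
    """

    n_train: int = 300
    n_ds: int = 46
    n_control: int = 30
    age_range_train: tuple[float, float] = (18.0, 90.0)
    age_range_test: tuple[float, float] = (28.0, 65.0)
    group_offset_years: float = 8.0
    pad_sd_years: float = 7.0          # per-subject brain-age deviation SD
    grid_dims: tuple[int, int, int] = (12, 14, 12)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    atrophy_rate: float = 0.003        # GM probability lost per effective year
    feature_noise_sd: float = 0.02
    tac_noise_cv: float = 0.05
    bpnd_neg_mean: float = 0.0
    bpnd_neg_sd: float = 0.05
    bpnd_pos_mean: float = 0.5
    bpnd_pos_sd: float = 0.12
    pib_pos_fraction: float = 19.0 / 46.0
    camcog_baseline: float = 85.0
    camcog_interaction_slope: float = 1.75   # CAMCOG points per brain-PAD year
    camcog_noise_sd: float = 7.0
    peak_time_s: float = 300.0
    ref_scale: float = 1.0
    r1_mean: float = 0.9
    k2_per_min: float = 0.15
    fine_dt_s: float = 1.0
    seed: int = 42

    def validate(self) -> None:
        for name in ("n_train", "n_ds", "n_control"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("age_range_train", "age_range_test"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be a non-degenerate interval")
        if any(d < 4 for d in self.grid_dims):
            raise ConfigError("grid_dims must be >= 4 per axis")
        if not 0 <= self.pib_pos_fraction <= 1:
            raise ConfigError("pib_pos_fraction must be in [0, 1]")
        if self.atrophy_rate < 0:
            raise ConfigError("atrophy_rate must be >= 0")
        max_age = max(self.age_range_train[1],
                      self.age_range_test[1] + self.group_offset_years)
        if self.atrophy_rate * max_age >= 1:
            raise ConfigError("atrophy_rate x max effective age must be < 1")
        for name in ("feature_noise_sd", "tac_noise_cv", "pad_sd_years",
                     "bpnd_neg_sd", "bpnd_pos_sd", "camcog_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.peak_time_s <= 0:
            raise ConfigError("peak_time_s must be > 0")
        if self.k2_per_min <= 0:
            raise ConfigError("k2_per_min must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# fixed smooth spatial fields, deterministic functions of the grid only
def _spatial_fields(grid_dims, voxel_size_mm):
    axes = [np.linspace(-1.0, 1.0, n) for n in grid_dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = gx**2 + gy**2 + gz**2
    g0 = 0.45 + 0.25 * np.exp(-r2 / 0.8)               # baseline GM field
    w0 = 0.20 + 0.20 * np.exp(-((r2 - 0.5) ** 2) / 0.3)  # WM shell
    pattern = 0.5 + 0.5 * np.cos(np.pi * gx / 2) * np.cos(np.pi * gy / 2)
    pattern_wm = 0.5 * pattern
    return g0, w0, pattern, pattern_wm


def simulate_tissue_maps(age_effective: float, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         csf_scale: float = 1.0) -> TissueMaps:
    """Tissue maps for one subject at a given effective age.

    ``GM(v) = clip(g0(v) - atrophy_rate * age * pattern(v) + eps_v, 0, 1)``
    over fixed smooth fields ``g0`` and ``pattern``; WM declines at half
    the rate over its own pattern; CSF is the remainder so the three
    probabilities sum to one wherever GM + WM <= 1.

    ``csf_scale`` shrinks only the CSF compartment (leaving a fraction of
    each voxel unassigned), which is how the generator emulates
    between-subject intracranial-volume differences without touching the
    GM/WM features the age model sees.
    """
    config.validate()
    if not 0 < csf_scale <= 1:
        raise ConfigError("csf_scale must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g0, w0, pattern, pattern_wm = _spatial_fields(config.grid_dims,
                                                  config.voxel_size_mm)
    sd = config.feature_noise_sd
    eps_g = rng.normal(0.0, sd, size=config.grid_dims) if sd > 0 else 0.0
    eps_w = rng.normal(0.0, sd, size=config.grid_dims) if sd > 0 else 0.0
    gm = np.clip(g0 - config.atrophy_rate * age_effective * pattern + eps_g,
                 0.0, 1.0)
    wm = np.clip(w0 - 0.5 * config.atrophy_rate * age_effective * pattern_wm
                 + eps_w, 0.0, 1.0)
    wm = np.minimum(wm, 1.0 - gm)
    csf = np.clip(1.0 - gm - wm, 0.0, 1.0) * csf_scale
    return TissueMaps(gm, wm, csf, config.voxel_size_mm)


def gamma_variate(times_s: np.ndarray, peak_time_s: float,
                  scale: float = 1.0) -> np.ndarray:
    """Shape-2 gamma-variate bolus curve, peaking at ``scale`` at the peak time."""
    if peak_time_s <= 0:
        raise ValueError("peak_time_s must be > 0")
    t = np.asarray(times_s, dtype=float)
    return scale * (t / peak_time_s) * np.exp(1.0 - t / peak_time_s)


def simulate_reference_tac(schedule: FrameSchedule, peak_time_s: float = 300.0,
                           scale: float = 1.0,
                           fine_dt_s: float = 1.0) -> tuple[TAC, np.ndarray, np.ndarray]:
    """Noiseless reference-region TAC from an analytic gamma-variate curve.

    Returns ``(tac, fine_times, fine_values)``; the fine-grid curve is
    what the SRTM forward model convolves against.
    """
    fine_t = schedule.fine_times(fine_dt_s)
    fine_v = gamma_variate(fine_t, peak_time_s, scale)
    framed = frame_average(fine_v, fine_t, schedule)
    return TAC(schedule, framed, roi_id="reference"), fine_t, fine_v


def simulate_target_tac(ref_fine: np.ndarray, fine_times: np.ndarray,
                        r1: float, k2_per_min: float, bpnd: float,
                        schedule: FrameSchedule, noise_cv: float = 0.0,
                        rng: np.random.Generator | None = None,
                        roi_id: str = "roi") -> TAC:
    """Frame-averaged SRTM forward curve with optional Gaussian frame noise.

    Per-frame noise SD is ``noise_cv * value / sqrt(duration / max duration)``,
    so short early frames are noisier, as in real framed PET.
    """
    if bpnd < 0:
        raise ValueError("bpnd must be >= 0")
    fine_ct = srtm_forward(r1, k2_per_min, bpnd, ref_fine, fine_times)
    framed = frame_average(fine_ct, fine_times, schedule)
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        rel_dur = schedule.duration_s / schedule.duration_s.max()
        sd = noise_cv * np.abs(framed) / np.sqrt(rel_dur)
        framed = framed + rng.normal(0.0, 1.0, size=framed.size) * sd
    return TAC(schedule, framed, roi_id=roi_id)


@dataclass
class CohortData:
    """Everything :func:`generate_cohort` produces."""

    cohort: pd.DataFrame
    maps: dict = field(default_factory=dict)        # subject_id -> TissueMaps
    tacs: dict = field(default_factory=dict)        # subject_id -> TAC table
    regional_truth: pd.DataFrame | None = None      # subject x ROI true BP_ND
    schedule: FrameSchedule | None = None
    config: SimulationConfig | None = None


def _draw_subject_row(idx: int, group: str, config: SimulationConfig,
                      catalog_rois: list[tuple[str, str]]) -> dict:
    """One subject's demographic/cognitive/amyloid draw (fixed order)."""
    rng = np.random.default_rng(config.seed + idx)
    row: dict = {"subject_id": f"sub-{idx:04d}", "group": group}
    row["sex"] = "male" if rng.random() < 0.5 else "female"
    pad_dev = rng.normal(0.0, config.pad_sd_years)

    if group == "train":
        row["age_years"] = rng.uniform(*config.age_range_train)
        row["brain_pad_true"] = pad_dev
        row["pib_positive_true"] = np.nan
        row["camdex_class"] = None
        row["camcog"] = np.nan
        row["apoe_e4_carrier"] = None
    elif group == "control":
        row["age_years"] = rng.uniform(*config.age_range_test)
        row["brain_pad_true"] = pad_dev
        row["pib_positive_true"] = np.nan
        row["camdex_class"] = None
        row["camcog"] = np.nan
        row["apoe_e4_carrier"] = None
    else:  # DS
        pib_pos = rng.random() < config.pib_pos_fraction
        lo, hi = config.age_range_test
        mid = 0.5 * (lo + hi)
        # PiB-positive DS subjects are older, as amyloid accrues with age
        row["age_years"] = rng.uniform(mid - 4, hi) if pib_pos else rng.uniform(lo, mid + 4)
        row["brain_pad_true"] = config.group_offset_years + pad_dev
        row["pib_positive_true"] = bool(pib_pos)
        if pib_pos:
            camdex_p = [0.37, 0.26, 0.37]
        else:
            camdex_p = [0.89, 0.04, 0.07]
        row["camdex_class"] = rng.choice(
            ["stable", "declining", "dementia"], p=camdex_p)
        camcog = (config.camcog_baseline
                  - config.camcog_interaction_slope * row["brain_pad_true"]
                  * (1.0 if pib_pos else 0.0)
                  + rng.normal(0.0, config.camcog_noise_sd))
        # a few DS participants cannot complete the assessment (~3/46)
        if rng.random() < 3.0 / 46.0:
            row["camcog"] = np.nan
        else:
            row["camcog"] = float(np.clip(camcog, 0.0, 107.0))
        row["apoe_e4_carrier"] = "yes" if rng.random() < 0.28 else "no"
    row["effective_age_years"] = row["age_years"] + row["brain_pad_true"]

    # amyloid ground truth per ROI
    if group == "DS":
        if row["pib_positive_true"]:
            striatal = rng.normal(config.bpnd_pos_mean, config.bpnd_pos_sd)
            cortical_mean = max(rng.normal(0.36, 0.22), 0.05)
        else:
            striatal = rng.normal(config.bpnd_neg_mean, config.bpnd_neg_sd)
            cortical_mean = 0.0
        regional = {}
        for roi, roi_class in catalog_rois:
            # PiB-negative non-striatal regions carry bounded, U-shaped
            # trace noise (either at the detection floor or a small bounded
            # trace): true negatives then sit inside any 2-SD abnormality
            # cut, as observed empirically in PiB-negative cohorts, which
            # unbounded Gaussian noise cannot guarantee
            if roi_class == "reference":
                regional[roi] = 0.0
            elif roi_class == "striatal":
                regional[roi] = striatal + rng.normal(0.0, 0.03)
            elif roi_class == "cortical":
                regional[roi] = (cortical_mean + rng.normal(0.0, 0.05)
                                 if row["pib_positive_true"]
                                 else 0.03 * rng.beta(0.3, 0.3))
            else:  # other_subcortical
                regional[roi] = (0.5 * cortical_mean + rng.normal(0.0, 0.05)
                                 if row["pib_positive_true"]
                                 else 0.03 * rng.beta(0.3, 0.3))
        row["striatal_bpnd_true"] = striatal
        row["_regional"] = {k: max(v, 0.0) for k, v in regional.items()}
    else:
        row["striatal_bpnd_true"] = np.nan
        row["_regional"] = None
    # SRTM kinetics truth
    row["_r1"] = max(rng.normal(config.r1_mean, 0.05), 0.5)
    row["_k2"] = max(rng.normal(config.k2_per_min, 0.01), 0.05)
    # head size: DS intracranial volume is reduced (emulated through the
    # CSF compartment only, so GM/WM age features are unaffected)
    if group == "DS":
        row["_csf_scale"] = float(np.clip(rng.normal(0.35, 0.06), 0.05, 1.0))
    else:
        row["_csf_scale"] = float(np.clip(rng.normal(0.95, 0.04), 0.05, 1.0))
    return row


def generate_cohort(config: SimulationConfig | None = None,
                    include_maps: bool = True,
                    include_tacs: bool = True) -> CohortData:
    """Generate a full synthetic cohort.

    Subjects are drawn in the fixed order train, DS, control, each from
    its own ``seed + index`` stream.  DS subjects get effective age
    ``age + group_offset + pad deviation``; PiB-positive DS subjects draw
    striatal BP_ND from the positive mixture component; CAMCOG declines
    with the true brain-age deviation only in PiB-positive subjects.
    Tissue maps (all subjects) and per-ROI dynamic TACs (DS subjects) are
    attached unless switched off for speed.
    """
    from .amyloid import default_catalog

    config = config or SimulationConfig()
    config.validate()
    catalog = default_catalog()
    catalog_rois = list(zip(catalog.table["roi_id"], catalog.table["roi_class"]))

    groups = (["train"] * config.n_train + ["DS"] * config.n_ds
              + ["control"] * config.n_control)
    rows = [_draw_subject_row(i, g, config, catalog_rois)
            for i, g in enumerate(groups)]

    schedule = standard_schedule()
    maps: dict = {}
    tacs: dict = {}
    regional_rows = {}
    if include_tacs:
        _, fine_t, ref_fine = simulate_reference_tac(
            schedule, config.peak_time_s, config.ref_scale, config.fine_dt_s)
    for i, row in enumerate(rows):
        sid = row["subject_id"]
        # map / TAC noise drawn from a dedicated offset stream so the
        # demographic draws above stay stable if stages are toggled
        if include_maps:
            rng_m = np.random.default_rng(config.seed + 100_000 + i)
            maps[sid] = simulate_tissue_maps(row["effective_age_years"],
                                             config, rng_m,
                                             csf_scale=row["_csf_scale"])
        if include_tacs and row["_regional"] is not None:
            rng_t = np.random.default_rng(config.seed + 200_000 + i)
            frames = {"frame_start_s": schedule.start_s,
                      "frame_duration_s": schedule.duration_s}
            for roi, true_bp in row["_regional"].items():
                if roi == "superior_cerebellum":
                    tac = simulate_target_tac(ref_fine, fine_t, 1.0,
                                              row["_k2"], 0.0, schedule,
                                              config.tac_noise_cv, rng_t, roi)
                else:
                    tac = simulate_target_tac(ref_fine, fine_t, row["_r1"],
                                              row["_k2"], true_bp, schedule,
                                              config.tac_noise_cv, rng_t, roi)
                frames[roi] = tac.activity
            tacs[sid] = pd.DataFrame(frames)
        if row["_regional"] is not None:
            regional_rows[sid] = row["_regional"]

    cohort = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")}
                           for r in rows])
    regional_truth = (pd.DataFrame.from_dict(regional_rows, orient="index")
                      if regional_rows else None)
    return CohortData(cohort=cohort, maps=maps, tacs=tacs,
                      regional_truth=regional_truth, schedule=schedule,
                      config=config)
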