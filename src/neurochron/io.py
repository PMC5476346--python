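"""File I/O: cohort CSV, NIfTI volumes, TAC TSV and kernel CSV.

Conventions: UTF-8 comma-separated CSV with a header row and empty
strings for missing values; voxel indices 0-based; NIfTI-1 volumes with
the voxel size on the affine diagonal; TAC TSV columns are
``frame_start_s``, ``frame_duration_s`` then one column per ROI id.
"""

from __future__ import annotations


import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import FrameSchedule

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_volume",
    "write_volume",
    "read_tacs",
    "write_tacs",
    "read_kernel",
    "write_kernel",
]

MANDATORY_COHORT_COLUMNS = ["subject_id", "age_years", "sex", "group"]
_SEX_LEVELS = {"male", "female"}
_GROUP_LEVELS = {"DS", "control", "train"}
_CAMDEX_LEVELS = {"stable", "declining", "dementia"}
_APOE_LEVELS = {"yes", "no"}


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Mandatory columns: subject_id, age_years, sex, group; optional:
    camdex_class, camcog, apoe_e4 / apoe_e4_carrier.  Non-numeric ages
    and unknown categorical levels are rejected with the offending row
    named (1-based data rows, excluding the header).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory column(s): {missing}")
    if "apoe_e4" in df.columns and "apoe_e4_carrier" not in df.columns:
        df = df.rename(columns={"apoe_e4": "apoe_e4_carrier"})
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    bad = df.index[ages.isna() & df["age_years"].notna()]
    if len(bad):
        raise ValueError(
            f"non-numeric age_years at data row {int(bad[0]) + 1}: "
            f"{df.loc[bad[0], 'age_years']!r}")
    df["age_years"] = ages
    for col, levels in (("sex", _SEX_LEVELS), ("group", _GROUP_LEVELS),
                        ("camdex_class", _CAMDEX_LEVELS),
                        ("apoe_e4_carrier", _APOE_LEVELS)):
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        vals = vals[vals.astype(str).str.len() > 0]
        unknown = set(vals) - levels
        if unknown:
            raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")
    if "camcog" in df.columns:
        df["camcog"] = pd.to_numeric(df["camcog"], errors="coerce")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(data: np.ndarray, path, voxel_size_mm=(1.5, 1.5, 1.5)) -> None:
    """Write a 3D/4D array as NIfTI-1 float32."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def read_volume(path, expect_ndim: int | None = None):
    """Read a NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ValueError(f"{path}: expected {expect_ndim}-D volume, "
                         f"got {data.ndim}-D")
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel


def write_tacs(tac_table: pd.DataFrame, path) -> None:
    """Write a per-ROI TAC table as TSV."""
    tac_table.to_csv(path, sep="\t", index=False)


def read_tacs(path) -> tuple[FrameSchedule, pd.DataFrame]:
    """Read a TAC TSV; returns the schedule and the per-ROI activity table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"TAC file missing column {col}")
    sched = FrameSchedule(df["frame_start_s"].to_numpy(float),
                          df["frame_duration_s"].to_numpy(float))
    rois = df.drop(columns=["frame_start_s", "frame_duration_s"])
    return sched, rois


def write_kernel(values: np.ndarray, subject_ids, path) -> None:
    pd.DataFrame(values, index=subject_ids, columns=subject_ids).to_csv(path)


def read_kernel(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]
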