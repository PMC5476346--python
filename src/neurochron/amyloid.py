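"""PiB-positivity classification and regional amyloid abnormality.

Striatal (caudate + putamen) PiB BP_ND is bimodal in Down syndrome:
a tight amyloid-negative component around zero and an elevated positive
component.  A subject is PiB-negative when their striatal BP_ND lies
less than one standard deviation from zero and PiB-positive at or above
that threshold; regional BP_ND is then called abnormal when it lies at
least two standard deviations above the PiB-negative group mean for that
region, abnormal regions are counted per subject (0-30 over the default
catalogue), and the mean BP_ND over cortical regions summarises global
amyloid load.

Which distribution's standard deviation anchors the positivity
threshold is configurable (see :func:`classify_pib_status`).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "RoiCatalog",
    "PiBProfile",
    "default_catalog",
    "striatal_bpnd",
    "classify_pib_status",
    "regional_abnormality",
    "summarize_profile",
    "build_profiles",
]

_SIGMA_FLOOR = 1e-6

# 30 non-reference ROIs: 22 cortical, 4 striatal, 4 other subcortical,
# plus the cerebellar reference region. Editable: any 30-ROI catalogue
# with the same class column can be slotted in via RoiCatalog.from_csv.
_DEFAULT_CATALOG_CSV = """roi_id,roi_class
frontal_l,cortical
frontal_r,cortical
orbitofrontal_l,cortical
orbitofrontal_r,cortical
sensorimotor_l,cortical
sensorimotor_r,cortical
parietal_l,cortical
parietal_r,cortical
precuneus_l,cortical
precuneus_r,cortical
occipital_l,cortical
occipital_r,cortical
temporal_l,cortical
temporal_r,cortical
entorhinal_l,cortical
entorhinal_r,cortical
insula_l,cortical
insula_r,cortical
cingulate_ant_l,cortical
cingulate_ant_r,cortical
cingulate_post_l,cortical
cingulate_post_r,cortical
caudate_l,striatal
caudate_r,striatal
putamen_l,striatal
putamen_r,striatal
thalamus_l,other_subcortical
thalamus_r,other_subcortical
hippocampus_l,other_subcortical
hippocampus_r,other_subcortical
superior_cerebellum,reference
"""


@dataclass
class RoiCatalog:
    """ROI list with classes cortical / striatal / other_subcortical / reference."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"roi_id", "roi_class"}
        if not required.issubset(self.table.columns):
            raise ValueError("catalog needs roi_id and roi_class columns")
        bad = set(self.table["roi_class"]) - {
            "cortical", "striatal", "other_subcortical", "reference"}
        if bad:
            raise ValueError(f"unknown roi_class values: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path) -> "RoiCatalog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def rois(self, roi_class: str | None = None) -> list[str]:
        t = self.table
        if roi_class is not None:
            t = t[t["roi_class"] == roi_class]
        return list(t["roi_id"])

    @property
    def non_reference(self) -> list[str]:
        return list(self.table.loc[self.table["roi_class"] != "reference", "roi_id"])

    @property
    def striatal(self) -> list[str]:
        return self.rois("striatal")

    @property
    def cortical(self) -> list[str]:
        return self.rois("cortical")


def default_catalog() -> RoiCatalog:
    """The default 30-ROI catalogue (plus the cerebellar reference)."""
    return RoiCatalog(pd.read_csv(StringIO(_DEFAULT_CATALOG_CSV)))


@dataclass
class PiBProfile:
    """Per-subject amyloid profile."""

    subject_id: str
    regional_bpnd: dict
    striatal_bpnd: float
    status: str                      # "positive" | "negative"
    abnormal_rois: set
    abnormal_count: int
    mean_cortical_bpnd: float

    def __post_init__(self):
        if self.abnormal_count != len(self.abnormal_rois):
            raise ValueError("abnormal_count must equal |abnormal_rois|")
        if self.status not in ("positive", "negative"):
            raise ValueError("status must be 'positive' or 'negative'")


def striatal_bpnd(regional: dict | pd.Series, catalog: RoiCatalog) -> float:
    """Unweighted mean BP_ND over the striatal ROIs (caudate and putamen)."""
    missing = [r for r in catalog.striatal if r not in regional]
    if missing:
        raise ValueError(f"missing striatal ROI(s): {missing}")
    return float(np.mean([regional[r] for r in catalog.striatal]))


def classify_pib_status(striatal_values: np.ndarray, sd_mode: str = "cohort",
                        fixed_sd: float | None = None,
                        max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Classify each subject PiB-positive/negative from striatal BP_ND.

    A subject is positive iff their striatal BP_ND >= sigma0 ("one SD from
    zero"; the boundary value is positive).  sigma0 is, by ``sd_mode``:

    - ``"cohort"`` (default): the sample SD of the full bimodal striatal
      distribution.  With a tight negative mode at zero and a clearly
      elevated positive mode, this lands the cut between the modes.
    - ``"iterative"``: start from the cohort SD, then repeatedly
      re-estimate sigma0 as the root mean square about zero of the
      currently-negative subjects until the labels stop changing.  Note
      that truncating at the threshold biases this RMS low, so the fixed
      point settles inside the negative component's upper tail; the
      cohort mode is the safer default (see the methods note).
    - ``"fixed"``: use the supplied ``fixed_sd``.

    Returns (boolean positive flags, sigma0).  sigma0 is floored at 1e-6
    so an all-zero cohort degenerates to all-negative rather than 0/0.
    """
    v = np.asarray(striatal_values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    if sd_mode == "fixed":
        if fixed_sd is None:
            raise ValueError("sd_mode='fixed' requires fixed_sd")
        sigma = max(float(fixed_sd), _SIGMA_FLOOR)
        return v >= sigma, sigma
    sigma = max(float(np.std(v, ddof=1)), _SIGMA_FLOOR)
    if sd_mode == "cohort":
        return v >= sigma, sigma
    if sd_mode != "iterative":
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    positive = v >= sigma
    for _ in range(max_iter):
        neg = v[~positive]
        if neg.size == 0:
            raise ValueError(
                "degenerate split: every subject positive; use sd_mode='fixed'")
        sigma = max(float(np.sqrt(np.mean(neg**2))), _SIGMA_FLOOR)
        new_positive = v >= sigma
        if np.array_equal(new_positive, positive):
            return positive, sigma
        positive = new_positive
    raise ValueError("iterative SD estimate did not converge; use sd_mode='fixed'")


def regional_abnormality(bpnd_table: pd.DataFrame,
                         positive: np.ndarray) -> pd.DataFrame:
    """Flag abnormal regional BP_ND against the PiB-negative group.

    For each ROI (column), the mean and SD are taken over PiB-negative
    subjects; subject i is abnormal in that ROI iff their value is at
    least 2 SDs above the negative-group mean (boundary inclusive).  With
    a degenerate SD of zero the rule reduces to ``value >= mean``, so
    exact equality still counts as abnormal.
    """
    positive = np.asarray(positive, dtype=bool)
    if positive.shape[0] != len(bpnd_table):
        raise ValueError("status length must match the BP_ND table")
    neg = bpnd_table.loc[~positive]
    if len(neg) < 2:
        raise ValueError("need at least 2 PiB-negative subjects")
    mu = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1)
    return bpnd_table.ge(mu + 2.0 * sd, axis=1)


def summarize_profile(flags: pd.Series, regional: pd.Series,
                      catalog: RoiCatalog, subject_id: str,
                      status: str, striatal: float) -> PiBProfile:
    """Complete one subject's profile: abnormal-ROI count and cortical mean."""
    rois = catalog.non_reference
    abnormal = {r for r in rois if bool(flags.get(r, False))}
    cortical = [regional[r] for r in catalog.cortical]
    return PiBProfile(
        subject_id=subject_id,
        regional_bpnd=dict(regional),
        striatal_bpnd=float(striatal),
        status=status,
        abnormal_rois=abnormal,
        abnormal_count=len(abnormal),
        mean_cortical_bpnd=float(np.mean(cortical)),
    )


def build_profiles(bpnd_table: pd.DataFrame, catalog: RoiCatalog | None = None,
                   sd_mode: str = "cohort",
                   fixed_sd: float | None = None) -> pd.DataFrame:
    """Full amyloid pipeline over a (subject x ROI) BP_ND table.

    Returns a per-subject table with striatal BP_ND, PiB status, abnormal
    ROI count over the 30-ROI catalogue and mean cortical BP_ND; the
    estimated sigma0 is stored in ``result.attrs['sigma0']`` and the
    per-ROI flags in ``result.attrs['flags']``.
    """
    catalog = catalog or default_catalog()
    striatal = bpnd_table[catalog.striatal].mean(axis=1)
    positive, sigma0 = classify_pib_status(striatal.to_numpy(), sd_mode=sd_mode,
                                           fixed_sd=fixed_sd)
    flags = regional_abnormality(bpnd_table[catalog.non_reference], positive)
    out = pd.DataFrame({
        "subject_id": bpnd_table.index,
        "striatal_bpnd": striatal.to_numpy(),
        "pib_status": np.where(positive, "positive", "negative"),
        "abnormal_count": flags.sum(axis=1).to_numpy(),
        "mean_cortical_bpnd": bpnd_table[catalog.cortical].mean(axis=1).to_numpy(),
    })
    out.attrs["sigma0"] = sigma0
    out.attrs["flags"] = flags
    out.attrs["sd_mode"] = sd_mode
    return out
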