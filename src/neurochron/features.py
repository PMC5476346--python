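"""Voxelwise tissue maps to feature vectors, kernels and volume summaries.

A subject's spatially normalised grey-matter (GM) and white-matter (WM)
probability maps are smoothed, flattened in a fixed raster order and
concatenated into one feature vector ``x_i``; the similarity of two
subjects is the plain dot product ``x_i . x_j``, giving an N x N linear
kernel matrix for kernel regression.  Summary tissue volumes (GM, WM,
CSF and their sum, the intracranial volume) are probability sums scaled
by the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TissueMaps",
    "KernelMatrix",
    "VolumeSummary",
    "FWHM_TO_SIGMA",
    "smooth_volume",
    "vectorize",
    "linear_kernel",
    "cross_kernel",
    "summary_volumes",
]

#: sigma = FWHM / (2 * sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TissueMaps:
    """GM/WM/CSF probability volumes for one subject in a common space."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    space_tag: str = "synthetic-template"

    def __post_init__(self):
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("gm, wm and csf must share a shape")
        for name, vol in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if vol.min() < -1e-12 or vol.max() > 1.0 + 1e-12:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")


@dataclass
class KernelMatrix:
    """Pairwise dot-product similarity with the subject order that defines it."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("kernel must be square")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match the kernel")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10 * max(
            1.0, np.max(np.abs(self.values))
        ):
            raise ValueError("kernel must be symmetric")


@dataclass(frozen=True)
class VolumeSummary:
    """Tissue volumes in litres; ICV is their sum."""

    gm_l: float
    wm_l: float
    csf_l: float
    icv_l: float


def smooth_volume(vol: np.ndarray, fwhm_mm: float,
                  voxel_size_mm=(1.5, 1.5, 1.5)) -> np.ndarray:
    """Separable Gaussian smoothing with zero-padded boundaries.

    ``fwhm_mm = 0`` is the identity.  Interior mass is conserved (a delta
    away from the boundary smooths to a kernel summing to one).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (vol.ndim,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    return gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0,
                           truncate=6.0)


def vectorize(maps: TissueMaps, fwhm_mm: float = 4.0) -> np.ndarray:
    """Smooth GM and WM and concatenate them into one feature vector.

    Raster order is fixed: axis 0 varies fastest (Fortran order), GM
    voxels first then WM.  Any consistent order is equivalent since only
    dot products of identically ordered vectors are ever used.
    """
    gm = smooth_volume(maps.gm, fwhm_mm, maps.voxel_size_mm)
    wm = smooth_volume(maps.wm, fwhm_mm, maps.voxel_size_mm)
    return np.concatenate([gm.ravel(order="F"), wm.ravel(order="F")])


def _stack(vectors) -> np.ndarray:
    vecs = [np.asarray(v, dtype=float).ravel() for v in vectors]
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValueError("feature vectors must all have the same length")
    return np.vstack(vecs)


def linear_kernel(vectors, subject_ids: list[str] | None = None) -> KernelMatrix:
    """N x N matrix of pairwise dot products of the feature vectors."""
    x = _stack(vectors)
    k = x @ x.T
    k = 0.5 * (k + k.T)  # remove float asymmetry
    return KernelMatrix(k, subject_ids or [])


def cross_kernel(train_vectors, test_vectors) -> np.ndarray:
    """(n_test, n_train) dot products between test and training vectors."""
    xtr = _stack(train_vectors)
    xte = _stack(test_vectors)
    if xtr.shape[1] != xte.shape[1]:
        raise ValueError("train and test feature lengths differ")
    return xte @ xtr.T


def summary_volumes(maps: TissueMaps) -> VolumeSummary:
    """GM/WM/CSF volumes in litres: probability sums x voxel volume."""
    voxel_mm3 = float(np.prod(maps.voxel_size_mm))
    mm3_per_l = 1e6
    gm = float(maps.gm.sum()) * voxel_mm3 / mm3_per_l
    wm = float(maps.wm.sum()) * voxel_mm3 / mm3_per_l
    csf = float(maps.csf.sum()) * voxel_mm3 / mm3_per_l
    return VolumeSummary(gm, wm, csf, gm + wm + csf)
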