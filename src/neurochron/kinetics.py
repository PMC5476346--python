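"""Reference-tissue kinetic modelling of dynamic PET.

Implements time-activity-curve (TAC) handling for a framed dynamic
acquisition, partial-volume-corrected ROI TAC extraction, the simplified
reference tissue model (SRTM) forward operator, and the basis-function
SRTM fit used to estimate the nondisplaceable binding potential BP_ND.

The SRTM relates a target-region curve :math:`C_T` to a reference-region
curve :math:`C_R` (a region assumed devoid of specific binding) through

.. math::

    C_T(t) = R_1 C_R(t) + (k_2 - R_1 k_{2a}) \\, C_R(t) \\otimes e^{-k_{2a} t},

with :math:`k_{2a} = k_2 / (1 + BP_{ND})`.  The basis-function scheme
grids the only nonlinear rate (:math:`k_{2a}`, called ``theta3`` here),
precomputes the convolution basis for each grid value, solves the two
remaining coefficients by weighted linear least squares, and keeps the
grid point with the smallest weighted residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "FrameSchedule",
    "TAC",
    "SRTMFit",
    "standard_schedule",
    "frame_average",
    "convolve_exp",
    "srtm_forward",
    "srtm_basis_fit",
    "default_theta3_grid",
    "extract_roi_tac",
    "extract_reference_tac",
]

_SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition, in seconds.

    Frames are half-open intervals ``[start, start + duration)`` that must
    tile the acquisition contiguously from time zero.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if start[0] != 0:
            raise ValueError("first frame must start at 0 s")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1])

    def fine_times(self, dt_s: float = 1.0) -> np.ndarray:
        """Uniform fine grid from 0 to the end of the last frame (inclusive)."""
        n = int(round(self.total_duration_s / dt_s))
        return np.linspace(0.0, n * dt_s, n + 1)


def standard_schedule() -> FrameSchedule:
    """The 58-frame, 90-minute PiB acquisition schedule.

    18 x 5 s, 6 x 15 s, 10 x 30 s, 7 x 60 s, 4 x 150 s and 13 x 300 s.
    """
    blocks = [(18, 5.0), (6, 15.0), (10, 30.0), (7, 60.0), (4, 150.0), (13, 300.0)]
    dur = np.concatenate([np.full(n, d) for n, d in blocks])
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


@dataclass
class TAC:
    """Per-frame activity of one region, with its schedule and fit weights."""

    schedule: FrameSchedule
    activity: np.ndarray
    weights: np.ndarray | None = None
    roi_id: str = ""

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must match schedule")
        if self.weights is None:
            # duration weighting: longer frames carry lower variance
            self.weights = self.schedule.duration_s.copy()
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.activity.shape:
            raise ValueError("weights length must match schedule")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


def frame_average(fine_values: np.ndarray, fine_times: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval.

    The frame value is the trapezoidal integral of the curve over
    ``[start, start + duration]`` divided by the duration, so a constant
    curve frame-averages to itself and the scheme converges at second
    order as the fine grid is refined.
    """
    fine_values = np.asarray(fine_values, dtype=float)
    fine_times = np.asarray(fine_times, dtype=float)
    dt = np.diff(fine_times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("fine grid must be uniform")
    if fine_times[-1] < schedule.total_duration_s - 1e-9:
        raise ValueError("fine grid does not cover the schedule")
    # cumulative trapezoid integral, interpolated at frame boundaries
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (fine_values[1:] + fine_values[:-1]) * dt)])
    i0 = np.interp(schedule.start_s, fine_times, cum)
    i1 = np.interp(schedule.end_s, fine_times, cum)
    return (i1 - i0) / schedule.duration_s


def convolve_exp(values: np.ndarray, times: np.ndarray, rate_per_s: float) -> np.ndarray:
    """Trapezoidal convolution of a fine-grid curve with ``exp(-rate * t)``.

    Returns the curve :math:`y(t) = \\int_0^t f(s) e^{-k (t - s)} ds`
    evaluated on the same uniform grid.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("fine grid must be uniform")
    h = float(dt[0])
    kern = np.exp(-rate_per_s * times)
    full = fftconvolve(values, kern)[: values.size]
    # trapezoid end corrections: half-weight the first and last samples
    out = h * (full - 0.5 * values[0] * kern - 0.5 * values * kern[0])
    out[0] = 0.0
    return out


def srtm_forward(r1: float, k2_per_min: float, bpnd: float,
                 ref_fine: np.ndarray, fine_times_s: np.ndarray) -> np.ndarray:
    """SRTM forward model: fine-grid target curve from a fine reference curve."""
    if bpnd < 0:
        raise ValueError("bpnd must be >= 0")
    if k2_per_min <= 0:
        raise ValueError("k2_per_min must be > 0")
    if r1 < 0:
        raise ValueError("r1 must be >= 0")
    k2a_s = k2_per_min / (1.0 + bpnd) / _SEC_PER_MIN
    theta2_s = (k2_per_min - r1 * k2_per_min / (1.0 + bpnd)) / _SEC_PER_MIN
    ref_fine = np.asarray(ref_fine, dtype=float)
    return r1 * ref_fine + theta2_s * convolve_exp(ref_fine, fine_times_s, k2a_s)


def default_theta3_grid(n: int = 64, lo_per_min: float = 0.006,
                        hi_per_min: float = 0.6) -> np.ndarray:
    """Logarithmically spaced k2a basis grid (1/min), standard for PiB."""
    return np.geomspace(lo_per_min, hi_per_min, n)


@dataclass
class SRTMFit:
    """Basis-function SRTM parameter estimates for one region."""

    r1: float
    k2_per_min: float
    k2a_per_min: float
    bpnd: float
    theta2_per_min: float
    wrss: float
    grid_index: int
    negative_bpnd: bool = False
    wrss_grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if abs(self.bpnd - (self.k2_per_min / self.k2a_per_min - 1.0)) > 1e-10 * max(
            1.0, abs(self.bpnd)
        ):
            raise ValueError("inconsistent bpnd / k2 / k2a")


def _fine_reference(reference: TAC, fine_times: np.ndarray) -> np.ndarray:
    """Piecewise-linear reference curve through (0, 0) and the frame midpoints."""
    mids = np.concatenate([[0.0], reference.schedule.mid_s])
    vals = np.concatenate([[0.0], reference.activity])
    return np.interp(fine_times, mids, vals)


def srtm_basis_fit(target: TAC, reference: TAC,
                   theta3_grid: np.ndarray | None = None,
                   fine_dt_s: float = 1.0,
                   ref_fine: np.ndarray | None = None) -> SRTMFit:
    """Fit the SRTM to a target TAC by the basis-function method.

    For each ``theta3`` (candidate k2a) on the grid, the basis
    ``B = C_R (x) exp(-theta3 t)`` is computed on a fine uniform grid and
    frame-averaged; ``(theta1, theta2)`` are then solved by weighted linear
    least squares of the target frames on ``[C_R frames, B frames]`` and the
    grid point minimising the weighted residual sum of squares is kept.
    Reported parameters: ``R1 = theta1``, ``k2 = theta2 + theta1 * theta3``,
    ``k2a = theta3``, ``BP_ND = k2 / k2a - 1``.

    The fine reference curve is, by default, the measured reference frames
    linearly interpolated through their midpoints (anchored at the origin);
    a caller holding a noiseless fine curve may pass it via ``ref_fine``.
    A negative fitted BP_ND is allowed but flagged.
    """
    if target.schedule.n_frames != reference.schedule.n_frames or not np.allclose(
        target.schedule.start_s, reference.schedule.start_s
    ):
        raise ValueError("target and reference must share a schedule")
    if theta3_grid is None:
        theta3_grid = default_theta3_grid()
    theta3_grid = np.asarray(theta3_grid, dtype=float)
    if theta3_grid.size < 2 or np.any(np.diff(theta3_grid) <= 0):
        raise ValueError("theta3 grid must be ascending with at least 2 points")

    sched = target.schedule
    fine_t = sched.fine_times(fine_dt_s)
    if ref_fine is None:
        ref_fine = _fine_reference(reference, fine_t)
    else:
        ref_fine = np.asarray(ref_fine, dtype=float)
        if ref_fine.shape != fine_t.shape:
            raise ValueError("ref_fine must match the fine grid of the schedule")

    cr_framed = reference.activity
    y = target.activity
    w = target.weights
    sw = np.sqrt(w)

    best = None
    wrss_grid = np.empty(theta3_grid.size)
    for idx, th3 in enumerate(theta3_grid):
        basis = convolve_exp(ref_fine, fine_t, th3 / _SEC_PER_MIN)
        b_framed = frame_average(basis, fine_t, sched)
        design = np.column_stack([cr_framed, b_framed])
        a = design * sw[:, None]
        rank = np.linalg.matrix_rank(a)
        if rank < 2:
            wrss_grid[idx] = np.inf
            continue
        coef, _, _, _ = np.linalg.lstsq(a, y * sw, rcond=None)
        resid = y - design @ coef
        wrss = float(np.sum(w * resid**2))
        wrss_grid[idx] = wrss
        if best is None or wrss < best[0]:
            best = (wrss, idx, coef)
    if best is None:
        raise ValueError("design rank-deficient at every theta3 grid point")

    wrss, idx, (theta1, theta2_s) = best
    theta2 = theta2_s * _SEC_PER_MIN  # fitted against a per-second basis integral
    th3 = theta3_grid[idx]
    k2 = theta2 + theta1 * th3
    bpnd = k2 / th3 - 1.0
    return SRTMFit(
        r1=float(theta1),
        k2_per_min=float(k2),
        k2a_per_min=float(th3),
        bpnd=float(bpnd),
        theta2_per_min=float(theta2),
        wrss=wrss,
        grid_index=int(idx),
        negative_bpnd=bool(bpnd < 0),
        wrss_grid=wrss_grid,
    )


def _extract(pet_4d: np.ndarray, mask: np.ndarray, gm_prob: np.ndarray,
             csf_prob: np.ndarray, gm_thresh: float, schedule: FrameSchedule,
             roi_id: str, csf_cap: float) -> tuple[TAC, int]:
    pet_4d = np.asarray(pet_4d, dtype=float)
    if pet_4d.ndim != 4 or pet_4d.shape[3] != schedule.n_frames:
        raise ValueError("PET 4th dimension must match the frame schedule")
    mask = np.asarray(mask, dtype=bool)
    include = mask & (np.asarray(gm_prob) >= gm_thresh)
    capped = include & (np.asarray(csf_prob) > csf_cap)
    n_capped = int(np.count_nonzero(capped))
    include &= ~capped
    if not include.any():
        raise ValueError(f"ROI '{roi_id}': no voxels survive the GM threshold")
    voxel_tacs = pet_4d[include]                      # (n_vox, n_frames)
    corr = 1.0 - np.asarray(csf_prob, dtype=float)[include]
    voxel_tacs = voxel_tacs / corr[:, None]
    return TAC(schedule, voxel_tacs.mean(axis=0), roi_id=roi_id), n_capped


def extract_roi_tac(pet_4d: np.ndarray, roi_mask: np.ndarray, gm_prob: np.ndarray,
                    csf_prob: np.ndarray, schedule: FrameSchedule,
                    gm_thresh: float = 0.65, roi_id: str = "roi",
                    csf_cap: float = 0.95) -> TAC:
    """Extract a partial-volume-corrected ROI TAC.

    Voxels in the ROI with GM probability >= ``gm_thresh`` are kept; each
    voxel's TAC is divided by ``1 - CSF probability`` at that voxel before
    unweighted averaging.  Voxels with CSF probability above ``csf_cap``
    are excluded rather than divided (division by near-zero amplifies
    noise).  Default fit weights are the frame durations.
    """
    tac, _ = _extract(pet_4d, roi_mask, gm_prob, csf_prob, gm_thresh, schedule,
                      roi_id, csf_cap)
    return tac


def extract_reference_tac(pet_4d: np.ndarray, cerebellum_mask: np.ndarray,
                          gm_prob: np.ndarray, csf_prob: np.ndarray,
                          schedule: FrameSchedule, gm_thresh: float = 0.90,
                          roi_id: str = "reference",
                          csf_cap: float = 0.95) -> TAC:
    """Extract the reference-region TAC (superior cerebellum, GM >= 0.90)."""
    tac, _ = _extract(pet_4d, cerebellum_mask, gm_prob, csf_prob, gm_thresh,
                      schedule, roi_id, csf_cap)
    return tac
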