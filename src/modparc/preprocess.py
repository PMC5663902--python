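"""Per-run preprocessing chain for resting-state runs.

Fixed stage order: drop initial volumes -> band-pass (0.01-0.10 Hz) ->
nuisance regression (6 motion parameters + 3 white-matter and 3 CSF
principal components) -> spatial smoothing (FWHM 4 mm) -> motion/variance
censoring (FD > 0.5 mm or DVARS > 0.5%), with subject-level quality control
discarding runs with more than 30% (rest) or 20% (task) of frames censored.

FD and DVARS are computed on the unfiltered post-drop data: censoring
targets raw motion artifacts, not their filtered residue.  FD follows the
Power convention -- the sum of absolute backward differences of the six
parameters, with rotations converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sp_signal

from .core import MotionTrace, TimeSeriesVolume

__all__ = [
    "CensorReport",
    "drop_initial_volumes",
    "bandpass_filter",
    "nuisance_regression",
    "smooth_gaussian",
    "compute_fd",
    "compute_dvars",
    "make_censor_mask",
    "apply_censoring",
    "qc_subject",
    "preprocess_run",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
HEAD_RADIUS_MM = 50.0


@dataclass
class CensorReport:
    fd: np.ndarray  # mm per frame
    dvars: np.ndarray  # percent per frame
    censored: np.ndarray  # bool per frame

    @property
    def fraction_censored(self) -> float:
        return float(np.mean(self.censored))

    def save(self, path) -> None:
        """One-column 0/1 censor file: 1 = retained, 0 = censored."""
        np.savetxt(path, (~self.censored).astype(int), fmt="%d")


def drop_initial_volumes(run: TimeSeriesVolume, n: int = 4, motion: MotionTrace = None):
    """Remove the first ``n`` equilibration frames (and paired motion rows)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= run.n_frames:
        raise ValueError(f"cannot drop {n} of {run.n_frames} frames")
    out = TimeSeriesVolume(
        run.data[..., n:], run.voxel_size, run.tr, run.frame_mask[n:]
    )
    if motion is None:
        return out
    if motion.n_frames != run.n_frames:
        raise ValueError("motion rows must match the run's frame count")
    return out, MotionTrace(motion.params[n:])


def bandpass_filter(
    run: TimeSeriesVolume, low: float = 0.01, high: float = 0.10, order: int = 2
) -> TimeSeriesVolume:
    """Zero-phase Butterworth band-pass along time; removes the mean (0 Hz)."""
    nyq = 0.5 / run.tr
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq:.3f} Hz")
    b, a = sp_signal.butter(order, [low / nyq, high / nyq], btype="bandpass")
    data = run.data - run.data.mean(axis=3, keepdims=True)
    data = sp_signal.filtfilt(b, a, data, axis=3)
    data -= data.mean(axis=3, keepdims=True)
    return TimeSeriesVolume(data, run.voxel_size, run.tr, run.frame_mask.copy())


def _principal_components(ts: np.ndarray, n_pcs: int) -> np.ndarray:
    """First ``n_pcs`` temporal PCs (columns, standardized) of (V, T) data."""
    x = ts - ts.mean(axis=1, keepdims=True)
    # time-courses are the right singular vectors of the voxel-by-time matrix
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > 1e-10 * max(s.max(initial=0.0), 1.0)  # drop null components
    pcs = vt[keep][:n_pcs].T
    if pcs.shape[1] == 0:
        return np.empty((ts.shape[1], 0))
    sd = pcs.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pcs / sd


def nuisance_regression(
    run: TimeSeriesVolume,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_pcs: int = 3,
) -> TimeSeriesVolume:
    """Voxelwise residual of regression on motion and WM/CSF components.

    Design: intercept, the 6 realignment parameters, and the first
    ``n_pcs`` principal components of the WM voxel signals and of the CSF
    voxel signals (separate PCAs, 2*n_pcs component columns).  Collinear
    columns are dropped with a logged warning.
    """
    t = run.n_frames
    if motion.n_frames != t:
        raise ValueError("motion trace length mismatch")
    if n_pcs >= t:
        raise ValueError("n_pcs must be smaller than the frame count")
    flat = run.data.reshape(-1, t)
    cols = [np.ones((t, 1)), motion.params - motion.params.mean(axis=0)]
    for mask, name in ((wm_mask, "WM"), (csf_mask, "CSF")):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        cols.append(_principal_components(flat[mask.ravel()], n_pcs))
    x = np.hstack(cols)
    # drop collinear columns via pivoted QR
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        import scipy.linalg as sla

        _, _, piv = sla.qr(x, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        log.warning(
            "nuisance design rank-deficient: dropping %d collinear column(s)",
            x.shape[1] - rank,
        )
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    resid = flat - (x @ beta).T
    return TimeSeriesVolume(
        resid.reshape(run.data.shape), run.voxel_size, run.tr, run.frame_mask.copy()
    )


def smooth_gaussian(data, voxel_size: float = None, fwhm: float = 4.0):
    """Spatial Gaussian smoothing (per frame for 4D input), reflect boundary.

    Accepts a TimeSeriesVolume or a bare 3D array (then ``voxel_size`` is
    required).  ``fwhm`` is in mm; sigma = fwhm / (2 sqrt(2 ln 2)) voxels
    after conversion.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(data, TimeSeriesVolume):
        if fwhm == 0:
            return data.copy()
        sigma = fwhm * FWHM_TO_SIGMA / data.voxel_size
        out = ndimage.gaussian_filter(
            data.data, sigma=(sigma, sigma, sigma, 0), mode="reflect"
        )
        return TimeSeriesVolume(out, data.voxel_size, data.tr, data.frame_mask.copy())
    arr = np.asarray(data, dtype=float)
    if fwhm == 0:
        return arr.copy()
    if voxel_size is None:
        raise ValueError("voxel_size required for bare arrays")
    sigma = fwhm * FWHM_TO_SIGMA / voxel_size
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect")


def compute_fd(motion: MotionTrace, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences, mm."""
    d = np.abs(np.diff(motion.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_dvars(run: TimeSeriesVolume, brain_mask: np.ndarray) -> np.ndarray:
    """RMS frame-to-frame signal change over the mask, percent of the
    whole-mask temporal-mean signal; DVARS[0] = 0."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    ts = run.data[mask]  # (V, T)
    mean_signal = float(ts.mean())
    if abs(mean_signal) < 1e-12:
        raise ValueError("zero mean signal: percent DVARS undefined")
    d = np.diff(ts, axis=1)
    rms = np.sqrt((d**2).mean(axis=0))
    return np.concatenate([[0.0], 100.0 * rms / abs(mean_signal)])


def make_censor_mask(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
) -> CensorReport:
    """Frame censored iff FD or DVARS *exceeds* its threshold (strict >)."""
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have equal length")
    censored = (fd > fd_thresh) | (dvars > dvars_thresh)
    return CensorReport(fd, dvars, censored)


def apply_censoring(run: TimeSeriesVolume, report: CensorReport) -> TimeSeriesVolume:
    if report.censored.shape != (run.n_frames,):
        raise ValueError("censor report length mismatch")
    out = run.copy()
    out.frame_mask &= ~report.censored
    return out


def qc_subject(reports, modality: str = "rest") -> bool:
    """True (keep) unless any run exceeds the censoring budget:
    30% for rest, 20% for task (strict 'more than')."""
    limits = {"rest": 0.30, "task": 0.20}
    if modality not in limits:
        raise ValueError("modality must be 'rest' or 'task'")
    if len(reports) == 0:
        raise ValueError("need at least one censor report")
    return all(r.fraction_censored <= limits[modality] for r in reports)


def preprocess_run(
    run: TimeSeriesVolume,
    motion: MotionTrace,
    brain_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_drop: int = 4,
    low: float = 0.01,
    high: float = 0.10,
    n_pcs: int = 3,
    fwhm: float = 4.0,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
):
    """Full chain on one run; returns (TimeSeriesVolume, CensorReport).

    FD/DVARS are measured on the post-drop, pre-filter data; the censor
    mask is applied to the filtered, regressed and smoothed output.
    """
    run2, motion2 = drop_initial_volumes(run, n_drop, motion)
    fd = compute_fd(motion2)
    dvars = compute_dvars(run2, brain_mask)
    report = make_censor_mask(fd, dvars, fd_thresh, dvars_thresh)
    out = bandpass_filter(run2, low, high)
    out = nuisance_regression(out, motion2, wm_mask, csf_mask, n_pcs)
    out = smooth_gaussian(out, fwhm=fwhm)
    out = apply_censoring(out, report)
    log.info(
        "preprocessed run: %d frames, %.1f%% censored",
        out.n_frames,
        100 * report.fraction_censored,
    )
    return out, report
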