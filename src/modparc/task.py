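"""Block-design task GLM in percent-signal-change units.

A minimal fixed-effects GLM for a two-condition (face/shape) block design:
canonical double-gamma HRF regressors, per-run intercept and linear drift,
six motion regressors of no interest, frame censoring on the Euclidean norm
of the motion-parameter derivative, and voxelwise scaling to percent signal
change so the face-shape contrast beta is directly interpretable as a
percentage of baseline signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import FCMap, MotionTrace, TimeSeriesVolume

__all__ = [
    "TaskDesign",
    "hcp_emotion_design",
    "canonical_hrf",
    "build_condition_regressors",
    "build_design",
    "save_task_timing",
    "motion_enorm",
    "glm_percent_signal",
    "roi_mean_beta",
    "bold_fc_correlation",
]

HEAD_RADIUS_MM = 50.0


@dataclass
class TaskDesign:
    """Condition timing for one run (seconds)."""

    onsets: dict  # condition -> list of block onsets, s
    durations: dict  # condition -> list of block durations, s
    tr: float
    n_frames: int
    cue_onsets: list = field(default_factory=list)
    # canonical double-gamma parameters: response peak, undershoot peak (s),
    # undershoot ratio
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 1.0 / 6.0

    @property
    def condition_names(self):
        return sorted(self.onsets)

    def validate(self) -> None:
        dur_total = self.n_frames * self.tr
        events = []
        for cond in self.condition_names:
            ons, durs = self.onsets[cond], self.durations[cond]
            if len(ons) != len(durs):
                raise ValueError(f"onsets/durations length mismatch for {cond}")
            for o, d in zip(ons, durs):
                if o < 0 or d < 0 or o > dur_total:
                    raise ValueError("events must lie within the run duration")
                events.append((o, o + d, cond))
        events.sort()
        for (s0, e0, c0), (s1, e1, c1) in zip(events, events[1:]):
            if s1 < e0 - 1e-9 and c0 != c1:
                raise ValueError(
                    f"blocks of conditions {c0!r} and {c1!r} overlap in time"
                )

    def last_event_end(self) -> float:
        return max(
            (o + d for c in self.onsets for o, d in zip(self.onsets[c], self.durations[c])),
            default=0.0,
        )


def save_task_timing(design: TaskDesign, path) -> None:
    """Write condition timing as TSV (onset, duration, condition)."""
    import pandas as pd

    rows = [
        {"onset": o, "duration": d, "condition": c}
        for c in design.condition_names
        for o, d in zip(design.onsets[c], design.durations[c])
    ]
    pd.DataFrame(rows).sort_values("onset").to_csv(path, sep="\t", index=False)


def hcp_emotion_design(tr: float = 0.72, n_frames: int = 176) -> TaskDesign:
    """Default face/shape matching block design.

    Six blocks (3 face, 3 shape, interleaved, face first).  Each block:
    3 s task cue then 6 trials of 2 s with 1 s inter-trial interval (18 s
    of active task).  The trailing fixation period is not modeled.
    """
    block_len = 3.0 + 6 * (2.0 + 1.0)  # cue + trials
    onsets = {"face": [], "shape": []}
    durations = {"face": [], "shape": []}
    cues = []
    for k in range(6):
        start = k * block_len
        cond = "face" if k % 2 == 0 else "shape"
        cues.append(start)
        onsets[cond].append(start + 3.0)  # active period follows the cue
        durations[cond].append(18.0)
    d = TaskDesign(onsets, durations, tr, n_frames, cue_onsets=cues)
    d.validate()
    return d


def canonical_hrf(t: np.ndarray, peak=6.0, undershoot=16.0, ratio=1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF, unit peak, evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak) - ratio * stats.gamma.pdf(t, undershoot)
    m = h.max()
    return h / m if m > 0 else h


def build_condition_regressors(design: TaskDesign, oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcars, sampled at frame times; unit peak per column."""
    design.validate()
    t_hi = design.n_frames * design.tr
    dt = design.tr / oversample
    n_hi = int(np.ceil(t_hi / dt)) + 1
    grid = np.arange(n_hi) * dt
    hrf = canonical_hrf(
        np.arange(0, 32.0, dt), design.hrf_peak, design.hrf_undershoot, design.hrf_ratio
    )
    cols = []
    for cond in design.condition_names:
        box = np.zeros(n_hi)
        for o, d in zip(design.onsets[cond], design.durations[cond]):
            box[(grid >= o) & (grid < o + d)] = 1.0
        reg = np.convolve(box, hrf)[:n_hi]
        frame_times = np.arange(design.n_frames) * design.tr
        reg = np.interp(frame_times, grid, reg)
        m = np.abs(reg).max()
        cols.append(reg / m if m > 0 else reg)
    return np.column_stack(cols)


def build_design(design: TaskDesign, motion: MotionTrace = None) -> tuple:
    """Design matrix (frames x regressors) and column names.

    Columns: one HRF-convolved regressor per condition, intercept, linear
    drift, and the six motion parameters when supplied.
    """
    cond = build_condition_regressors(design)
    names = list(design.condition_names)
    n = design.n_frames
    cols = [cond, np.ones((n, 1)), np.linspace(-1, 1, n)[:, None]]
    names += ["intercept", "drift"]
    if motion is not None:
        if motion.n_frames != n:
            raise ValueError("motion trace length must match n_frames")
        mp = motion.params - motion.params.mean(axis=0, keepdims=True)
        cols.append(mp)
        names += [f"motion{i}" for i in range(6)]
    return np.hstack(cols), names


def motion_enorm(motion: MotionTrace, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Euclidean norm of the frame-to-frame parameter derivative (mm).

    Rotations are converted to arc length on a ``head_radius`` sphere; the
    first frame has norm 0 by convention.
    """
    d = np.diff(motion.params, axis=0)
    d[:, 3:] *= head_radius
    e = np.sqrt((d**2).sum(axis=1))
    return np.concatenate([[0.0], e])


def glm_percent_signal(
    runs,
    motions,
    design: TaskDesign,
    brain_mask: np.ndarray,
    enorm_thresh: float = 0.3,
) -> np.ndarray:
    """Fixed-effects face-shape contrast in percent signal change.

    Each run is scaled voxelwise to ``100 * signal / temporal mean``, frames
    with motion-derivative Euclidean norm above ``enorm_thresh`` mm are
    censored, runs are concatenated with run-specific intercept and drift
    columns, and the contrast is estimated by ordinary least squares.
    Returns the 3D contrast beta map (0 outside the brain mask).
    """
    if len(runs) != len(motions):
        raise ValueError("one motion trace per run required")
    mask_flat = np.flatnonzero(np.asarray(brain_mask).ravel())
    ys, xs = [], []
    n_shared = None
    for run, motion in zip(runs, motions):
        x, names = build_design(design, motion)
        keep = (motion_enorm(motion) <= enorm_thresh) & run.frame_mask
        flat = run.data.reshape(-1, run.n_frames)[mask_flat]
        mean = flat.mean(axis=1, keepdims=True)
        bad = np.abs(mean[:, 0]) < 1e-12
        mean[bad] = 1.0
        psc = 100.0 * flat / mean
        psc[bad] = 0.0
        ys.append(psc[:, keep])
        xs.append(x[keep])
        if keep.sum() < 2 * x.shape[1]:
            raise ValueError("too few retained frames for the design")
        n_shared = len(design.condition_names)
    n_cond = n_shared
    y = np.concatenate(ys, axis=1)
    # block-diagonal nuisance columns, shared condition columns (fixed effects)
    total = sum(x.shape[0] for x in xs)
    n_nuis = xs[0].shape[1] - n_cond
    x_full = np.zeros((total, n_cond + n_nuis * len(runs)))
    row = 0
    for i, x in enumerate(xs):
        r = x.shape[0]
        x_full[row : row + r, :n_cond] = x[:, :n_cond]
        x_full[row : row + r, n_cond + i * n_nuis : n_cond + (i + 1) * n_nuis] = x[
            :, n_cond:
        ]
        row += r
    if total < x_full.shape[1]:
        raise ValueError("too few retained frames for the design")
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        raise ValueError("rank-deficient task design matrix")
    beta, *_ = np.linalg.lstsq(x_full, y.T, rcond=None)
    names_c = sorted(design.onsets)
    contrast = beta[names_c.index("face")] - beta[names_c.index("shape")]
    out = np.zeros(brain_mask.size)
    out[mask_flat] = contrast
    return out.reshape(brain_mask.shape)


def roi_mean_beta(beta_map: np.ndarray, labels_volume: np.ndarray, module_id: int) -> float:
    """Mean contrast beta over one module of the parcellation."""
    sel = labels_volume == module_id
    if not sel.any():
        raise ValueError(f"module {module_id} is empty")
    return float(beta_map[sel].mean())


def positive_significant_mean(fc: FCMap, brain_mask: np.ndarray, alpha: float = 0.05):
    """Mean of Fisher-z values that are positive and individually significant.

    Significance is the subject-level two-sided r-to-t test at the map's own
    degrees of freedom.  Returns (mean, flagged) where flagged is True when
    no voxel qualifies (mean reported as 0).
    """
    df = fc.df
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    r_crit = t_crit / np.sqrt(t_crit**2 + df)
    z_crit = np.arctanh(r_crit)
    vals = fc.z[brain_mask]
    sel = vals > z_crit
    if not sel.any():
        return 0.0, True
    return float(vals[sel].mean()), False


def bold_fc_correlation(betas, fc_maps, brain_mask, alpha: float = 0.05):
    """Across-subject correlation of ROI task activation with the mean
    positive-significant connectivity of the same seed.

    Parameters
    ----------
    betas : sequence of float
        Per-subject ROI mean contrast betas (percent signal change).
    fc_maps : sequence of FCMap
        Per-subject connectivity maps for the matching seed module.

    Returns
    -------
    (r, p, n, flags) with ``flags`` naming degenerate subjects (no
    significant positive voxels) or a degenerate correlation (constant
    input, reported as r=0, p=1).
    """
    if len(betas) != len(fc_maps):
        raise ValueError("betas and fc_maps must cover the same subjects")
    n = len(betas)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    summaries = np.empty(n)
    flags = []
    for i, fc in enumerate(fc_maps):
        summaries[i], flagged = positive_significant_mean(fc, brain_mask, alpha)
        if flagged:
            flags.append(f"subject {i}: no significant positive voxels")
    betas = np.asarray(betas, dtype=float)
    if np.std(betas) == 0 or np.std(summaries) == 0:
        return 0.0, 1.0, n, flags + ["degenerate: constant input"]
    r, p = stats.pearsonr(betas, summaries)
    return float(r), float(p), n, flags
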