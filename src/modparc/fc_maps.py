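"""Seed-based partial-correlation functional connectivity maps.

Each parcellation module serves as a seed: its mean signal is correlated
with every brain voxel after regressing the mean signals of the *other*
seed modules out of both sides (textbook partial correlation).  Maps are
Fisher r-to-z transformed and averaged across runs per subject
(transform-then-average).  For test-retest analyses, each run's retained
frames are split into four contiguous equal subseries ("sessions").
"""

from __future__ import annotations

import logging

import numpy as np

from .core import FCMap, TimeSeriesVolume

__all__ = [
    "seed_mean_signal",
    "partial_corr_map",
    "fisher_z",
    "run_fc_map",
    "subject_fc",
    "split_subseries",
]

log = logging.getLogger(__name__)


def seed_mean_signal(
    run: TimeSeriesVolume, labels_volume: np.ndarray, seed_id: int
) -> np.ndarray:
    """Mean over seed voxels of the retained-frame signals."""
    sel = np.asarray(labels_volume) == seed_id
    if not sel.any():
        raise ValueError(f"seed {seed_id} is empty")
    return run.data[sel][:, run.retained_indices()].mean(axis=0)


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residual of y (rows = series) on [intercept, covariates]."""
    t = y.shape[-1]
    x = np.ones((t, 1))
    if covariates is not None and covariates.size:
        x = np.hstack([x, covariates.T])
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ beta).T


def partial_corr_map(
    run: TimeSeriesVolume,
    labels_volume: np.ndarray,
    seed_id: int,
    other_seed_ids=(),
    brain_mask: np.ndarray = None,
) -> tuple:
    """Per-voxel partial correlation of the seed with the brain.

    Both the seed mean signal and every voxel signal are residualized on
    [intercept + mean signals of the other seeds]; the map holds the
    Pearson correlation of the residuals.  Zero-variance voxels get r = 0.
    Returns (r_map 3D, df) with df = retained frames - covariates - 2.
    """
    seed = seed_mean_signal(run, labels_volume, seed_id)
    others = []
    for sid in other_seed_ids:
        if sid == seed_id:
            raise ValueError("seed cannot be its own covariate")
        others.append(seed_mean_signal(run, labels_volume, sid))
    cov = np.asarray(others) if others else None
    if cov is not None and len(others) > 1:
        c = np.corrcoef(cov)
        cond = np.linalg.cond(c)
        if cond > 1e6:
            raise ValueError(
                f"collinear seed covariate signals (condition number {cond:.2e})"
            )
    if brain_mask is None:
        brain_mask = np.ones(run.shape, dtype=bool)
    mask = np.asarray(brain_mask, dtype=bool)
    vox = run.data[mask][:, run.retained_indices()]
    seed_r = _residualize(seed[None, :], cov)[0]
    vox_r = _residualize(vox, cov)
    seed_r = seed_r - seed_r.mean()
    vox_r = vox_r - vox_r.mean(axis=1, keepdims=True)
    seed_norm = np.linalg.norm(seed_r)
    if seed_norm == 0:
        raise ValueError("seed residual has zero variance")
    vox_norm = np.linalg.norm(vox_r, axis=1)
    # voxels fully explained by the covariates (residual at machine noise)
    # are reported as r = 0 rather than correlating numerical noise
    orig = vox - vox.mean(axis=1, keepdims=True)
    orig_norm = np.linalg.norm(orig, axis=1)
    ok = vox_norm > 1e-8 * np.maximum(orig_norm, 1e-300)
    r = np.zeros(vox.shape[0])
    r[ok] = (vox_r[ok] @ seed_r) / (vox_norm[ok] * seed_norm)
    np.clip(r, -1.0, 1.0, out=r)
    r_map = np.zeros(run.shape)
    r_map[mask] = r
    n_cov = 0 if cov is None else cov.shape[0]
    df = run.n_retained - n_cov - 2
    return r_map, df


def fisher_z(r) -> np.ndarray:
    """Fisher r-to-z: z = atanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        log.warning("clipping |r| >= 1 before Fisher transform")
        r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    return np.arctanh(r)


def run_fc_map(
    run, labels_volume, seed_id, other_seed_ids=(), brain_mask=None
) -> tuple:
    """Fisher-z map and df for a single run."""
    r_map, df = partial_corr_map(run, labels_volume, seed_id, other_seed_ids, brain_mask)
    return fisher_z(r_map), df


def subject_fc(
    runs,
    labels_volume: np.ndarray,
    seed_id: int,
    other_seed_ids=(),
    brain_mask: np.ndarray = None,
    subject_id: int = 0,
    session_id: int = 0,
) -> FCMap:
    """Per-run z maps averaged elementwise; df accumulates across runs."""
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    z_sum = None
    df_total = 0.0
    for run in runs:
        z, df = run_fc_map(run, labels_volume, seed_id, other_seed_ids, brain_mask)
        z_sum = z if z_sum is None else z_sum + z
        df_total += df
    return FCMap(z_sum / len(runs), df_total, seed_id, subject_id, session_id)


def split_subseries(run: TimeSeriesVolume, k: int = 4):
    """Split retained frames into k contiguous equal segments.

    Remainder frames are dropped from the end; censoring is applied before
    splitting, so each segment contains retained frames only.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    retained = run.retained_indices()
    seg = retained.size // k
    if seg < 10:
        raise ValueError(f"too few retained frames ({retained.size}) for k={k}")
    out = []
    for j in range(k):
        idx = retained[j * seg : (j + 1) * seg]
        out.append(
            TimeSeriesVolume(run.data[..., idx], run.voxel_size, run.tr)
        )
    return out
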