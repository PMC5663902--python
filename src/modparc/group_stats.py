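"""Voxelwise group inference on connectivity maps.

One-sample t maps, seed-contrast maps, a balanced two-way repeated-measures
ANOVA (session x seed with subject as random blocking factor), ICC(3,1)
test-retest reliability, and Monte-Carlo cluster-extent correction in the
AlphaSim tradition: the null distribution of the maximum supra-threshold
cluster size is simulated from smoothed Gaussian noise fields at an assumed
smoothness (a conservative fixed 10 mm FWHM by default), and observed
clusters smaller than the (1 - alpha) quantile are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import StatMap
from .preprocess import smooth_gaussian

__all__ = [
    "one_sample_t_map",
    "seed_contrast_map",
    "rm_anova_map",
    "icc31_map",
    "ClusterNull",
    "mc_cluster_threshold",
    "extract_clusters",
]

log = logging.getLogger(__name__)

T_CAP = 1e4  # documented ceiling replacing infinite t at zero variance

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _stack(maps) -> np.ndarray:
    arrs = [m.z if hasattr(m, "z") else np.asarray(m) for m in maps]
    return np.stack(arrs, axis=0).astype(float)


def one_sample_t_map(z_maps) -> StatMap:
    """Voxelwise one-sample t against 0 across subjects (df = n - 1).

    Zero-variance voxels get t = 0 (pure-zero input) or a capped +-T_CAP
    (identical nonzero input) and are flagged for mask-out.
    """
    data = _stack(z_maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    flagged = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[flagged & (mean == 0)] = 0.0
    t[flagged & (mean != 0)] = np.sign(mean[flagged & (mean != 0)]) * T_CAP
    np.clip(t, -T_CAP, T_CAP, out=t)
    return StatMap(t, "t", (n - 1,), "one-sample", flagged)


def seed_contrast_map(z_maps_by_seed: dict, contrast) -> StatMap:
    """Within-subject seed contrast followed by a one-sample t.

    ``contrast`` is either ``("one_vs_rest", seed)`` or
    ``("pairwise", seed_a, seed_b)``.  ``z_maps_by_seed`` maps seed id to a
    subject-ordered list of maps; subject order must match across seeds.
    """
    lengths = {len(v) for v in z_maps_by_seed.values()}
    if len(lengths) != 1:
        raise ValueError("subject sets mismatch across seeds")
    kind = contrast[0]
    if kind == "one_vs_rest":
        seed = contrast[1]
        others = [s for s in z_maps_by_seed if s != seed]
        if not others:
            raise ValueError("one-vs-rest needs at least two seeds")
        a = _stack(z_maps_by_seed[seed])
        b = np.mean([_stack(z_maps_by_seed[s]) for s in others], axis=0)
        label = f"seed{seed} > rest"
    elif kind == "pairwise":
        _, sa, sb = contrast
        a = _stack(z_maps_by_seed[sa])
        b = _stack(z_maps_by_seed[sb])
        label = f"seed{sa} > seed{sb}"
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    out = one_sample_t_map(list(a - b))
    out.contrast_label = label
    return out


def rm_anova_map(data: np.ndarray) -> dict:
    """Balanced two-way repeated-measures ANOVA per voxel.

    ``data`` has shape (n_subjects, n_sessions, n_seeds, ...voxels...).
    Subjects are a random blocking factor; each fixed effect is tested
    against its own subject-interaction mean square:
    F(seed) ~ F(S-1, (S-1)(n-1)), F(session) ~ F(K-1, (K-1)(n-1)),
    F(seed x session) ~ F((K-1)(S-1), (K-1)(S-1)(n-1)).
    Returns ``{"session": StatMap, "seed": StatMap, "interaction": StatMap}``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 3:
        raise ValueError("data must be (subjects, sessions, seeds, voxels...)")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k, s = data.shape[:3]
    if n < 2 or k < 2 or s < 2:
        raise ValueError("need >= 2 subjects, sessions and seeds")
    m = data.mean(axis=(0, 1, 2))
    m_i = data.mean(axis=(1, 2))
    m_j = data.mean(axis=(0, 2))
    m_s = data.mean(axis=(0, 1))
    m_ij = data.mean(axis=2)
    m_is = data.mean(axis=1)
    m_js = data.mean(axis=0)

    ss_subj = k * s * ((m_i - m) ** 2).sum(axis=0)
    ss_sess = n * s * ((m_j - m) ** 2).sum(axis=0)
    ss_seed = n * k * ((m_s - m) ** 2).sum(axis=0)
    ss_sess_subj = s * ((m_ij - m_i[:, None] - m_j[None, :] + m) ** 2).sum(axis=(0, 1))
    ss_seed_subj = k * ((m_is - m_i[:, None] - m_s[None, :] + m) ** 2).sum(axis=(0, 1))
    ss_inter = n * ((m_js - m_j[:, None] - m_s[None, :] + m) ** 2).sum(axis=(0, 1))
    ss_total = ((data - m) ** 2).sum(axis=(0, 1, 2))
    ss_resid = (
        ss_total - ss_subj - ss_sess - ss_seed - ss_sess_subj - ss_seed_subj - ss_inter
    )
    ss_resid = np.maximum(ss_resid, 0.0)

    def f_map(ss_eff, df_eff, ss_err, df_err, label):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df_eff) / (ss_err / df_err)
        f = np.where(np.isfinite(f), f, 0.0)
        return StatMap(f, "F", (df_eff, df_err), label)

    return {
        "session": f_map(ss_sess, k - 1, ss_sess_subj, (k - 1) * (n - 1), "session"),
        "seed": f_map(ss_seed, s - 1, ss_seed_subj, (s - 1) * (n - 1), "seed"),
        "interaction": f_map(
            ss_inter,
            (k - 1) * (s - 1),
            ss_resid,
            (k - 1) * (s - 1) * (n - 1),
            "session x seed",
        ),
    }


def icc31_map(data: np.ndarray) -> StatMap:
    """ICC(3,1) per voxel from a (subjects, sessions, ...voxels...) array.

    Two-way mixed, single measures:
    ICC = (BMS - EMS) / (BMS + (k - 1) EMS), with BMS the between-subject
    and EMS the residual mean square of the subject x session two-way
    decomposition.  Degenerate voxels (denominator <= 0) are set to the
    floor value -1/(k-1) and flagged.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape[:2]
    if k < 2:
        raise ValueError("need >= 2 sessions")
    if n < 3:
        raise ValueError("need >= 3 subjects")
    m = data.mean(axis=(0, 1))
    m_i = data.mean(axis=1)
    m_j = data.mean(axis=0)
    ss_subj = k * ((m_i - m) ** 2).sum(axis=0)
    ss_sess = n * ((m_j - m) ** 2).sum(axis=0)
    ss_total = ((data - m) ** 2).sum(axis=(0, 1))
    ss_resid = np.maximum(ss_total - ss_subj - ss_sess, 0.0)
    bms = ss_subj / (n - 1)
    ems = ss_resid / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    flagged = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (bms - ems) / denom
    icc = np.where(flagged, -1.0 / (k - 1), icc)
    return StatMap(icc, "icc", (n - 1, (n - 1) * (k - 1)), "ICC(3,1)", flagged)


@dataclass
class ClusterNull:
    """Monte-Carlo cluster-size null and the derived minimum cluster size."""

    fwhm: float
    voxel_p: float
    n_iter: int
    alpha: float
    min_cluster_size: int
    seed: int
    max_sizes: np.ndarray = None

    def __post_init__(self):
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def _max_cluster_size(supra_pos, supra_neg, structure) -> int:
    best = 0
    for supra in (supra_pos, supra_neg):
        lab, nlab = ndimage.label(supra, structure=structure)
        if nlab:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def mc_cluster_threshold(
    mask: np.ndarray,
    voxel_size: float = 2.0,
    fwhm: float = 10.0,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
) -> ClusterNull:
    """Simulate the max-cluster-size null over the mask.

    Each iteration fills the mask's bounding grid with white Gaussian
    noise, smooths to the assumed ``fwhm``, standardizes within the mask,
    thresholds two-sided at ``voxel_p`` (signs clustered separately), and
    records the maximum cluster size.  The minimum surviving size is the
    ceiling of the (1 - alpha) quantile plus a one-voxel safeguard, so a
    cluster survives only if strictly larger than the null quantile.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if fwhm > 0 and fwhm < voxel_size:
        log.warning("fwhm %.2f mm below voxel size; proceeding unsmoothed", fwhm)
        fwhm = 0.0
    z_thr = stats.norm.ppf(1 - voxel_p / 2)
    structure = _STRUCTURES[connectivity]
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        field = rng.standard_normal(mask.shape)
        if fwhm > 0:
            field = smooth_gaussian(field, voxel_size, fwhm)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        supra = np.abs(field) > z_thr
        max_sizes[it] = _max_cluster_size(
            (field > z_thr) & mask, (field < -z_thr) & mask, structure
        )
    if alpha >= 1:
        min_size = 1
    else:
        min_size = int(np.ceil(np.quantile(max_sizes, 1 - alpha))) + 1
    return ClusterNull(fwhm, voxel_p, n_iter, alpha, min_size, seed, max_sizes)


def extract_clusters(
    stat_map: StatMap,
    voxel_threshold: float,
    null: ClusterNull,
    mask: np.ndarray = None,
    connectivity: int = 6,
) -> pd.DataFrame:
    """Connected supra-threshold components surviving the cluster null.

    Positive and negative excursions are clustered separately under face
    connectivity (configurable); components smaller than
    ``null.min_cluster_size`` are discarded.  Columns: x, y, z (peak voxel
    index), size, peak_stat, sign.
    """
    stat = np.asarray(stat_map.stat, dtype=float)
    if mask is None:
        mask = np.ones(stat.shape, dtype=bool)
    structure = _STRUCTURES[connectivity]
    rows = []
    for sign, supra in ((1, stat > voxel_threshold), (-1, stat < -voxel_threshold)):
        lab, nlab = ndimage.label(supra & mask, structure=structure)
        for c in range(1, nlab + 1):
            sel = lab == c
            size = int(sel.sum())
            if size < null.min_cluster_size:
                continue
            vals = np.where(sel, stat, 0.0)
            peak_flat = np.argmax(np.abs(vals))
            peak = np.unravel_index(peak_flat, stat.shape)
            rows.append(
                {
                    "x": peak[0],
                    "y": peak[1],
                    "z": peak[2],
                    "size": size,
                    "peak_stat": float(stat[peak]),
                    "sign": sign,
                }
            )
    table = pd.DataFrame(rows, columns=["x", "y", "z", "size", "peak_stat", "sign"])
    return table.sort_values("size", ascending=False, ignore_index=True)
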