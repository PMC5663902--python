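"""Multi-subject phantom generator with planted community structure.

Phantoms emulate resting-state BOLD acquisitions on a small voxel grid: ROI
voxels group into K planted communities that share band-limited latent
signals (0.01-0.10 Hz, inside the analysis passband so temporal filtering
preserves the planted structure), whole-brain "target" regions correlate
with specific communities, white-matter and CSF compartments carry shared
nuisance signals that leak into grey-matter voxels, motion traces contain
occasional spikes, and block-design task runs modulate ROI voxels with
known percent-signal-change amplitudes.

Correlation targets are achieved with a factor model

    x_v = sqrt(rho) * g_k + sqrt(1 - rho) * sd * eps_v  (+ drift + nuisance)

where ``g_k`` is the community latent and ``eps_v`` idiosyncratic white
noise, both unit variance.  With ``noise_sd = 1`` the pairwise correlation
of two voxels in community k is ``rho`` up to a small dilution from the
drift and nuisance-leak terms (see docs/methods.md); between-community
correlation is controlled by giving the K latents an equicorrelated
structure ``rho_g = between_corr / within_corr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .core import MotionTrace, TimeSeriesVolume
from .task import TaskDesign, build_condition_regressors

__all__ = [
    "Block",
    "PhantomSpec",
    "GroundTruth",
    "PhantomMasks",
    "PhantomDataset",
    "default_spec",
    "make_resting_dataset",
    "iter_resting_runs",
    "make_resting_run",
    "roi_timeseries_dataset",
    "make_motion_trace",
    "make_task_dataset",
]

# Block = ((x0, x1), (y0, y1), (z0, z1)) half-open voxel index ranges.
Block = tuple


def block_mask(shape, block) -> np.ndarray:
    (x0, x1), (y0, y1), (z0, z1) = block
    m = np.zeros(shape, dtype=bool)
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def _block_in_grid(block, shape) -> bool:
    return all(0 <= lo < hi <= n for (lo, hi), n in zip(block, shape))


@dataclass
class PhantomSpec:
    """Study conditions for one phantom dataset (defaults are the desk-scale
    conditions used throughout the test-bed: 3 planted communities of
    60/70/70 voxels in a 24x24x18 grid, within-community correlation 0.6,
    between-community 0.1)."""

    n_subjects: int = 30
    n_runs: int = 2
    n_frames: int = 304  # 300 analysed frames after dropping 4
    tr: float = 0.72
    voxel_size: float = 2.0
    grid_shape: tuple = (24, 24, 18)
    # (community_id, block) pairs; communities must be disjoint, in-grid.
    roi_layout: list = field(
        default_factory=lambda: [
            (1, ((3, 7), (3, 8), (6, 9))),     # 60 voxels
            (2, ((9, 14), (3, 10), (6, 8))),   # 70 voxels
            (3, ((3, 10), (11, 16), (6, 8))),  # 70 voxels
        ]
    )
    within_corr: float = 0.6
    between_corr: float = 0.1
    # (block, linked community_id, effect correlation with the latent)
    target_regions: list = field(
        default_factory=lambda: [
            (((16, 20), (12, 16), (10, 13)), 1, 0.3),
            (((4, 8), (16, 20), (10, 13)), 2, 0.3),
            (((10, 14), (16, 20), (3, 6)), 3, 0.3),
        ]
    )
    wm_block: Block = ((16, 20), (3, 9), (3, 6))
    csf_block: Block = ((16, 20), (3, 9), (10, 13))
    noise_sd: float = 1.0
    rest_baseline: float = 1000.0  # mean signal level inside the brain
    drift_amp: float = 0.2  # sd of per-voxel slow drift, signal units
    nuisance_amp: float = 0.15  # sd of WM/CSF nuisance leak into GM voxels
    motion_spike_rate: float = 0.02
    motion_spike_size: float = 1.0  # mm
    # module id -> face-vs-shape percent signal change
    task_amplitudes: dict = field(default_factory=lambda: {1: 0.2, 2: 0.5, 3: 0.8})
    # sd of a per-subject factor scaling both target connectivity and task
    # amplitude (0 = subjects identical; >0 plants a shared across-subject
    # factor coupling connectivity strength to task activation)
    subject_coupling_sd: float = 0.0
    task_baseline: float = 1000.0
    task_noise_pct: float = 0.5  # task noise sd, percent of baseline
    n_drop: int = 4  # initial volumes later removed in preprocessing
    band: tuple = (0.01, 0.10)  # Hz passband of the latent signals
    seed: int = 0

    def validate(self) -> None:
        if not (self.within_corr > self.between_corr):
            raise ValueError("within_corr must exceed between_corr")
        if not (0 <= self.within_corr <= 1):
            raise ValueError("within_corr must be in [0, 1]")
        if abs(self.between_corr) > 1:
            raise ValueError("between_corr must be in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if (self.n_frames - self.n_drop) % 4 != 0:
            raise ValueError(
                "n_frames minus dropped volumes must be divisible by 4 "
                "(exact subseries splitting)"
            )
        shape = self.grid_shape
        seen = np.zeros(shape, dtype=bool)
        for cid, blk in self.roi_layout:
            if not _block_in_grid(blk, shape):
                raise ValueError(f"community {cid} block lies outside the grid")
            m = block_mask(shape, blk)
            if (seen & m).any():
                raise ValueError(f"community {cid} block overlaps another community")
            seen |= m
        for blk, cid, r in self.target_regions:
            if not _block_in_grid(blk, shape):
                raise ValueError("target block lies outside the grid")
            if cid not in {c for c, _ in self.roi_layout}:
                raise ValueError(f"target linked to unknown community {cid}")
            if not (-1 < r < 1):
                raise ValueError("target effect correlation must be in (-1, 1)")
        for blk in (self.wm_block, self.csf_block):
            if not _block_in_grid(blk, shape):
                raise ValueError("WM/CSF block lies outside the grid")
        # Latent equicorrelation matrix must be positive definite.
        np.linalg.cholesky(self._latent_corr())

    @property
    def n_communities(self) -> int:
        return len(self.roi_layout)

    def _latent_corr(self) -> np.ndarray:
        k = self.n_communities
        rho_g = 0.0 if self.within_corr == 0 else self.between_corr / self.within_corr
        c = np.full((k, k), rho_g)
        np.fill_diagonal(c, 1.0)
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "implied latent correlation structure is not positive definite "
                f"(equicorrelation {rho_g:.3f} with K={k})"
            ) from err
        return c

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=list, indent=1))


@dataclass
class PhantomMasks:
    roi: np.ndarray
    brain: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size: float


@dataclass
class GroundTruth:
    """Everything planted, recorded for exact recovery scoring downstream."""

    roi_labels: np.ndarray  # community id per ROI voxel (lexicographic order)
    label_volume: np.ndarray  # 3D, 0 outside ROI
    target_map: dict  # community id -> 3D sign volume in {-1, 0, +1}
    target_effect: dict  # community id -> effect correlation
    task_beta_map: np.ndarray  # 3D true face-shape contrast, percent
    spike_frames: dict = field(default_factory=dict)  # (subj, run) -> indices

    def save(self, path) -> None:
        payload = {
            "roi_labels": self.roi_labels.tolist(),
            "label_volume": self.label_volume.tolist(),
            "target_map": {str(k): v.tolist() for k, v in self.target_map.items()},
            "target_effect": {str(k): v for k, v in self.target_effect.items()},
            "task_beta_map": self.task_beta_map.tolist(),
            "spike_frames": {
                f"{s}_{r}": list(map(int, v)) for (s, r), v in self.spike_frames.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class PhantomDataset:
    runs: list  # runs[subject][run] -> TimeSeriesVolume
    motion: list  # motion[subject][run] -> MotionTrace
    masks: PhantomMasks
    truth: GroundTruth
    spec: PhantomSpec


def default_spec(**overrides) -> PhantomSpec:
    spec = PhantomSpec(**overrides)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# latent machinery


def _bandlimit(x: np.ndarray, tr: float, band) -> np.ndarray:
    """Band-pass rows of x to the passband and standardize to unit variance."""
    low, high = band
    nyq = 0.5 / tr
    b, a = sp_signal.butter(2, [low / nyq, high / nyq], btype="bandpass")
    y = sp_signal.filtfilt(b, a, x, axis=-1)
    y -= y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd

def _drift_basis(t: int) -> np.ndarray:
    """Two unit-variance slow regressors: linear ramp and half-cosine."""
    ramp = np.linspace(-1, 1, t)
    cosine = np.cos(np.pi * np.arange(t) / max(t - 1, 1))
    basis = np.vstack([ramp, cosine])
    basis -= basis.mean(axis=1, keepdims=True)
    basis /= basis.std(axis=1, keepdims=True)
    return basis


def _run_rng(spec: PhantomSpec, subject: int, run: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), stream, int(subject), int(run)])
    )


def subject_factor(spec: PhantomSpec, subject: int) -> float:
    """Per-subject coupling factor ~ max(0.1, N(1, subject_coupling_sd))."""
    if spec.subject_coupling_sd <= 0:
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 6, int(subject)]))
    return float(max(0.1, 1.0 + spec.subject_coupling_sd * rng.standard_normal()))


def _latents(spec: PhantomSpec, rng: np.random.Generator, t: int):
    """Community latents (equicorrelated), 3 WM + 3 CSF nuisance latents."""
    k = spec.n_communities
    chol = np.linalg.cholesky(spec._latent_corr())
    g = _bandlimit(chol @ rng.standard_normal((k, t)), spec.tr, spec.band)
    g = _bandlimit(g, spec.tr, spec.band)  # re-standardize after mixing
    wm = _bandlimit(rng.standard_normal((3, t)), spec.tr, spec.band)
    csf = _bandlimit(rng.standard_normal((3, t)), spec.tr, spec.band)
    return g, wm, csf


def masks_for(spec: PhantomSpec) -> PhantomMasks:
    shape = spec.grid_shape
    roi = np.zeros(shape, dtype=bool)
    for _, blk in spec.roi_layout:
        roi |= block_mask(shape, blk)
    brain = np.zeros(shape, dtype=bool)
    brain[1:-1, 1:-1, 1:-1] = True  # one-voxel background rim
    wm = block_mask(shape, spec.wm_block)
    csf = block_mask(shape, spec.csf_block)
    brain |= wm | csf | roi
    return PhantomMasks(roi, brain, wm, csf, spec.voxel_size)


def ground_truth_for(spec: PhantomSpec) -> GroundTruth:
    shape = spec.grid_shape
    label_volume = np.zeros(shape, dtype=int)
    for cid, blk in spec.roi_layout:
        label_volume[block_mask(shape, blk)] = cid
    roi = label_volume > 0
    roi_labels = label_volume[roi]  # np boolean indexing is C-order/lexicographic
    target_map = {}
    target_effect = {}
    for cid, _ in spec.roi_layout:
        target_map[cid] = np.zeros(shape, dtype=int)
    for blk, cid, r in spec.target_regions:
        target_map[cid][block_mask(shape, blk)] = int(np.sign(r))
        target_effect[cid] = float(r)
    beta = np.zeros(shape, dtype=float)
    for cid, blk in spec.roi_layout:
        beta[block_mask(shape, blk)] = spec.task_amplitudes.get(cid, 0.0)
    return GroundTruth(roi_labels, label_volume, target_map, target_effect, beta)


# ---------------------------------------------------------------------------
# resting-state volumes


def _assemble_rest_voxels(spec, masks, truth, g, wm_lat, csf_lat, rng, t, factor=1.0):
    """Flat (n_voxels_in_grid, t) array of one run's voxel series."""
    shape = spec.grid_shape
    nvox = int(np.prod(shape))
    flat = np.zeros((nvox, t))

    drift = _drift_basis(t)
    # the per-subject coupling factor scales the seed circuitry's overall
    # connectivity strength: community coherence and target correlation
    rho_w = float(np.clip(spec.within_corr * factor, 0.0, 0.95))
    sqrt_w = np.sqrt(rho_w)
    sqrt_noise = np.sqrt(1.0 - rho_w) * spec.noise_sd

    def idx(mask):
        return np.flatnonzero(mask.ravel())

    brain_idx = idx(masks.brain & ~masks.wm & ~masks.csf)
    # idiosyncratic noise + drift + nuisance leak for every grey voxel
    nb = brain_idx.size
    base = spec.noise_sd * rng.standard_normal((nb, t))
    base += spec.drift_amp * (rng.standard_normal((nb, 2)) / np.sqrt(2)) @ drift
    leak_sign = rng.choice([-1.0, 1.0], size=nb)
    base += spec.nuisance_amp * leak_sign[:, None] * wm_lat[0][None, :]
    flat[brain_idx] = base

    # ROI voxels: community factor model (replaces the generic noise scale)
    for cid, blk in spec.roi_layout:
        vi = idx(block_mask(shape, blk))
        nv = vi.size
        series = sqrt_w * g[cid - 1][None, :]
        series = series + sqrt_noise * rng.standard_normal((nv, t))
        series = series + spec.drift_amp * (
            rng.standard_normal((nv, 2)) / np.sqrt(2)
        ) @ drift
        series = series + spec.nuisance_amp * rng.choice(
            [-1.0, 1.0], size=nv
        )[:, None] * wm_lat[0][None, :]
        flat[vi] = series

    # target regions: scaled copy of the linked community latent
    for blk, cid, r in spec.target_regions:
        r = float(np.clip(r * factor, -0.95, 0.95))
        vi = idx(block_mask(shape, blk))
        nv = vi.size
        series = r * g[cid - 1][None, :]
        series = series + np.sqrt(1 - r**2) * spec.noise_sd * rng.standard_normal(
            (nv, t)
        )
        series = series + spec.drift_amp * (
            rng.standard_normal((nv, 2)) / np.sqrt(2)
        ) @ drift
        flat[vi] = series

    # tissue compartments: mixtures of the shared nuisance latents
    for mask, lat in ((masks.wm, wm_lat), (masks.csf, csf_lat)):
        vi = idx(mask)
        nv = vi.size
        mix = rng.standard_normal((nv, 3)) / np.sqrt(3)
        flat[vi] = mix @ lat + 0.3 * rng.standard_normal((nv, t))

    # baseline signal level (removed again by band-pass filtering, but
    # required for percent-scaled quantities such as DVARS)
    flat[idx(masks.brain)] += spec.rest_baseline
    return flat


def make_resting_run(spec: PhantomSpec, subject: int, run: int):
    """One subject/run resting phantom: (TimeSeriesVolume, MotionTrace)."""
    spec.validate()
    masks = masks_for(spec)
    truth = ground_truth_for(spec)
    t = spec.n_frames
    rng = _run_rng(spec, subject, run, stream=1)
    g, wm_lat, csf_lat = _latents(spec, rng, t)
    factor = subject_factor(spec, subject)
    flat = _assemble_rest_voxels(spec, masks, truth, g, wm_lat, csf_lat, rng, t, factor)
    data = flat.reshape(spec.grid_shape + (t,))
    motion, spikes = make_motion_trace(
        t,
        spec.motion_spike_rate,
        spec.motion_spike_size,
        rng=_run_rng(spec, subject, run, stream=2),
    )
    vol = TimeSeriesVolume(data, spec.voxel_size, spec.tr)
    return vol, motion, spikes


def iter_resting_runs(spec: PhantomSpec):
    """Yield (subject, run, TimeSeriesVolume, MotionTrace, spike_frames)
    lazily; preferred over :func:`make_resting_dataset` for large specs."""
    spec.validate()
    for s in range(spec.n_subjects):
        for r in range(spec.n_runs):
            vol, motion, spikes = make_resting_run(spec, s, r)
            yield s, r, vol, motion, spikes


def make_resting_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Materialize the full resting phantom (use small specs; the per-run
    iterator avoids holding every volume in memory)."""
    spec.validate()
    masks = masks_for(spec)
    truth = ground_truth_for(spec)
    runs = [[None] * spec.n_runs for _ in range(spec.n_subjects)]
    motion = [[None] * spec.n_runs for _ in range(spec.n_subjects)]
    for s, r, vol, mot, spikes in iter_resting_runs(spec):
        runs[s][r] = vol
        motion[s][r] = mot
        truth.spike_frames[(s, r)] = spikes
    return PhantomDataset(runs, motion, masks, truth, spec)


def roi_timeseries_dataset(spec: PhantomSpec, drop_initial: bool = True):
    """Fast path for graph-level studies: per-run ROI voxel matrices only.

    Returns ``(list of (n_roi_voxels, t) arrays, roi_labels)`` where rows
    follow the lexicographic voxel ordering used by the connectome module.
    Voxel series follow the same factor model as the full generator, without
    building whole-brain volumes.  Initial equilibration volumes are dropped
    here when ``drop_initial`` (no other preprocessing is applied).
    """
    spec.validate()
    truth = ground_truth_for(spec)
    labels = truth.roi_labels
    t = spec.n_frames
    drift = _drift_basis(t)
    sqrt_w = np.sqrt(spec.within_corr)
    sqrt_noise = np.sqrt(1.0 - spec.within_corr) * spec.noise_sd
    nv = labels.size
    mats = []
    for s in range(spec.n_subjects):
        for r in range(spec.n_runs):
            rng = _run_rng(spec, s, r, stream=3)
            g, wm_lat, _ = _latents(spec, rng, t)
            x = sqrt_w * g[labels - 1]
            x = x + sqrt_noise * rng.standard_normal((nv, t))
            x = x + spec.drift_amp * (rng.standard_normal((nv, 2)) / np.sqrt(2)) @ drift
            x = x + spec.nuisance_amp * rng.choice([-1.0, 1.0], size=nv)[:, None] * wm_lat[0]
            mats.append(x[:, spec.n_drop :] if drop_initial else x)
    return mats, labels


# ---------------------------------------------------------------------------
# motion


def make_motion_trace(
    n_frames: int,
    spike_rate: float,
    spike_size: float = 1.0,
    seed: int = None,
    rng: np.random.Generator = None,
    baseline_amp: float = 0.02,
):
    """Smooth low-amplitude 6-parameter trace plus spikes.

    Spikes are single-frame x-translation offsets of magnitude
    ``spike_size`` mm with alternating sign, at Bernoulli(``spike_rate``)
    frames; ground-truth spike frame indices are returned.  The smooth
    baseline (sd ``baseline_amp`` mm / 20 mrad equivalents) keeps framewise
    displacement well below the 0.5 mm censoring threshold on its own.
    """
    if not (0 <= spike_rate <= 1):
        raise ValueError("spike_rate must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    smooth = rng.standard_normal((n_frames + 40, 6))
    kernel = np.exp(-0.5 * (np.arange(-15, 16) / 5.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, smooth
    )[20 : 20 + n_frames]
    smooth[:, :3] *= baseline_amp / max(smooth[:, :3].std(), 1e-12)
    smooth[:, 3:] *= (baseline_amp / 50.0) / max(smooth[:, 3:].std(), 1e-12)
    spikes = np.flatnonzero(rng.random(n_frames) < spike_rate)
    params = smooth.copy()
    for k, t in enumerate(spikes):
        params[t, 0] += spike_size * (-1.0) ** k
    return MotionTrace(params), spikes


# ---------------------------------------------------------------------------
# task runs


def make_task_dataset(spec: PhantomSpec, design: TaskDesign) -> PhantomDataset:
    """Block-design task phantom: 2 runs per subject.

    Voxel series = baseline * (1 + sum_c beta_c * x_c(t) / 100) + noise,
    where ``x_c`` are the unit-peak, temporally demeaned HRF-convolved
    condition regressors and ``beta_c`` is the planted percent signal
    change (face condition carries the module amplitude; shape is 0, so
    the face-shape contrast equals the planted amplitude).
    """
    spec.validate()
    design.validate()
    if design.last_event_end() > design.n_frames * design.tr + 1e-9:
        raise ValueError("design timing does not fit the run duration")
    masks = masks_for(spec)
    truth = ground_truth_for(spec)
    shape = spec.grid_shape
    t = design.n_frames
    regs = build_condition_regressors(design)  # (t, n_conditions), unit peak
    regs = regs - regs.mean(axis=0, keepdims=True)
    face = regs[:, design.condition_names.index("face")]

    beta_flat = truth.task_beta_map.ravel()
    brain_flat = masks.brain.ravel()
    n_runs = 2
    runs = [[None] * n_runs for _ in range(spec.n_subjects)]
    motion = [[None] * n_runs for _ in range(spec.n_subjects)]
    noise_sd = spec.task_baseline * spec.task_noise_pct / 100.0
    for s in range(spec.n_subjects):
        factor = subject_factor(spec, s)
        for r in range(n_runs):
            rng = _run_rng(spec, s, r, stream=4)
            flat = np.zeros((beta_flat.size, t))
            bi = np.flatnonzero(brain_flat)
            flat[bi] = spec.task_baseline * (
                1.0 + factor * beta_flat[bi, None] * face[None, :] / 100.0
            )
            if noise_sd > 0:
                flat[bi] += noise_sd * rng.standard_normal((bi.size, t))
            runs[s][r] = TimeSeriesVolume(
                flat.reshape(shape + (t,)), spec.voxel_size, design.tr
            )
            mot, spikes = make_motion_trace(
                t,
                spec.motion_spike_rate,
                spec.motion_spike_size,
                rng=_run_rng(spec, s, r, stream=5),
            )
            motion[s][r] = mot
            truth.spike_frames[(s, r)] = spikes
    return PhantomDataset(runs, motion, masks, truth, spec)
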