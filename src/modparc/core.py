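"""Core data containers shared across the pipeline.

The pipeline operates on small 4D voxel grids (x, y, z, frame).  Frames can
be flagged as censored via a boolean ``frame_mask``; every downstream
statistic uses only retained frames.  Volumes are read and written as
NIfTI-1 through :mod:`nibabel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesVolume",
    "MotionTrace",
    "SignedGraph",
    "Partition",
    "FCMap",
    "StatMap",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]


@dataclass
class TimeSeriesVolume:
    """One run's 4D voxel grid with acquisition geometry and frame retention.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values, arbitrary units.
    voxel_size : float
        Isotropic voxel edge, mm.
    tr : float
        Repetition time, seconds.
    frame_mask : ndarray of bool, shape (t,)
        True for retained frames.  Defaults to all-retained.
    """

    data: np.ndarray
    voxel_size: float
    tr: float
    frame_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.data.shape[3], dtype=bool)
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
        if self.frame_mask.shape != (self.data.shape[3],):
            raise ValueError("frame_mask length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    @property
    def shape(self):
        return self.data.shape[:3]

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.frame_mask)

    def copy(self) -> "TimeSeriesVolume":
        return TimeSeriesVolume(
            self.data.copy(), self.voxel_size, self.tr, self.frame_mask.copy()
        )


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per frame.

    ``params`` columns: 3 translations (mm), then 3 rotations (radians).
    Rotations are only converted to mm displacements inside framewise
    displacement / Euclidean-norm computations, on a 50 mm sphere.
    """

    params: np.ndarray  # (t, 6)

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("motion trace must have 6 columns")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def save(self, path):
        np.savetxt(path, self.params, fmt="%.8f")

    @classmethod
    def load(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass
class SignedGraph:
    """Fully connected signed weighted graph over ROI voxels.

    ``weights`` is the symmetric voxel-by-voxel (net) edge-weight matrix in
    correlation units; the diagonal is zero at the voxel level.  Aggregated
    (super-node) graphs additionally carry the positive and negative weight
    layers explicitly (``pos``/``neg``), including self-loop diagonals, so
    that signed modularity remains exactly invariant under aggregation even
    when positive and negative inter-community sums would otherwise cancel.
    """

    weights: np.ndarray
    node_coords: np.ndarray = None  # (n, 3) voxel indices, or None
    voxel_volume: float = 8.0  # mm^3 per voxel (2 mm isotropic default)
    pos: np.ndarray = None  # explicit positive layer (aggregated graphs)
    neg: np.ndarray = None  # explicit negative layer (>=0 entries)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        self.weights = w
        if self.node_coords is not None:
            self.node_coords = np.asarray(self.node_coords)
            if self.node_coords.shape != (w.shape[0], 3):
                raise ValueError("node_coords must be (n, 3)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def layers(self):
        """Positive and negative weight layers (both entrywise >= 0)."""
        if self.pos is not None:
            return self.pos, self.neg
        w = self.weights
        return np.maximum(w, 0.0), np.maximum(-w, 0.0)

    def save(self, path):
        """Dense matrix in a portable .npz container plus JSON sidecar."""
        path = Path(path)
        np.savez(path, weights=self.weights)
        sidecar = {
            "n_nodes": int(self.n_nodes),
            "voxel_volume_mm3": float(self.voxel_volume),
            "node_coords": None
            if self.node_coords is None
            else self.node_coords.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "SignedGraph":
        path = Path(path)
        w = np.load(path.with_suffix(".npz"))["weights"]
        side = json.loads(path.with_suffix(".json").read_text())
        coords = side.get("node_coords")
        return cls(
            w,
            None if coords is None else np.asarray(coords),
            side.get("voxel_volume_mm3", 8.0),
        )


@dataclass
class Partition:
    """Community affiliation vector plus its signed modularity."""

    labels: np.ndarray  # community id per node, contiguous ints from 1
    q: float
    n_modules: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.n_modules + 1)):
            raise ValueError("labels must cover 1..n_modules contiguously")
        if not np.isfinite(self.q):
            raise ValueError("q must be finite")


@dataclass
class FCMap:
    """Per-voxel Fisher-z partial-correlation map for one seed module."""

    z: np.ndarray  # 3D
    df: float  # effective degrees of freedom
    seed_id: int
    subject_id: int = 0
    session_id: int = 0  # 0 = full series, 1..4 = subseries

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class StatMap:
    """Voxelwise statistic map (t, F or ICC)."""

    stat: np.ndarray
    kind: str  # "t" | "F" | "icc"
    df: tuple
    contrast_label: str = ""
    flagged: np.ndarray = None  # voxels with degenerate input, if any


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_volume(vol: TimeSeriesVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_size))
    img.header.set_zooms((vol.voxel_size,) * 3 + (vol.tr,))
    nib.save(img, str(path))


def load_volume(path, frame_mask=None) -> TimeSeriesVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asarray(img.get_fdata())
    return TimeSeriesVolume(data, float(zooms[0]), float(zooms[3]), frame_mask)


def save_mask(mask: np.ndarray, voxel_size: float, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5
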