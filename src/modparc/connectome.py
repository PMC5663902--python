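"""Group-level voxelwise signed correlation graph inside the ROI mask.

Each run contributes a Pearson correlation matrix over ROI voxels
(retained frames only); matrices are averaged elementwise across subjects
and runs as raw r values to form the final connectivity matrix M, with the
diagonal zeroed.  Node order is lexicographic in voxel indices (x, y, z),
recorded in the graph so partitions map back to volumes deterministically.
"""

from __future__ import annotations

import numpy as np

from .core import SignedGraph, TimeSeriesVolume

__all__ = [
    "extract_roi_timeseries",
    "voxel_correlation_matrix",
    "average_matrices",
    "build_group_graph",
]


def extract_roi_timeseries(run: TimeSeriesVolume, roi_mask: np.ndarray):
    """(n_voxels, n_retained_frames) matrix plus the (n, 3) voxel coords.

    Rows follow the lexicographic (x, y, z) voxel ordering of the mask.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != run.shape:
        raise ValueError("ROI mask voxels fall outside the data grid")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    retained = run.retained_indices()
    if retained.size < 10:
        raise ValueError("fewer than 10 retained frames")
    coords = np.argwhere(mask)  # C-order: lexicographic by (x, y, z)
    ts = run.data[mask][:, retained]
    return ts, coords


def voxel_correlation_matrix(
    ts: np.ndarray, coords: np.ndarray = None, voxel_volume: float = 8.0
) -> SignedGraph:
    """Pairwise Pearson correlations between voxel rows; zero diagonal."""
    ts = np.asarray(ts, dtype=float)
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance voxel rows: {bad[:10].tolist()}")
    w = np.corrcoef(ts)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return SignedGraph(w, coords, voxel_volume)


def average_matrices(graphs) -> SignedGraph:
    """Elementwise arithmetic mean of raw r values across subjects/runs.

    A ``fisher`` keyword is intentionally not offered here: averaging raw r
    is the default contract; see :func:`build_group_graph` for the optional
    z-averaging sensitivity mode.
    """
    return _average(graphs, fisher=False)


def _average(graphs, fisher: bool) -> SignedGraph:
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs to average")
    first = graphs[0]
    acc = np.zeros_like(first.weights)
    for g in graphs:
        if g.n_nodes != first.n_nodes:
            raise ValueError("mismatched node sets")
        if (
            g.node_coords is not None
            and first.node_coords is not None
            and not np.array_equal(g.node_coords, first.node_coords)
        ):
            raise ValueError("mismatched node coordinates")
        acc += np.arctanh(np.clip(g.weights, -1 + 1e-12, 1 - 1e-12)) if fisher else g.weights
    acc /= len(graphs)
    if fisher:
        acc = np.tanh(acc)
    np.fill_diagonal(acc, 0.0)
    return SignedGraph(acc, first.node_coords, first.voxel_volume)


def build_group_graph(
    run_matrices, coords=None, voxel_volume: float = 8.0, fisher_average: bool = False
) -> SignedGraph:
    """Correlate each run's (voxels, frames) matrix and average across runs.

    ``fisher_average=True`` averages Fisher-z transformed matrices and maps
    back with tanh (sensitivity mode; the default reproduces raw-r
    averaging).
    """
    graphs = [voxel_correlation_matrix(m, coords, voxel_volume) for m in run_matrices]
    return _average(graphs, fisher=fisher_average)
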