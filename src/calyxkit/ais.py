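"""Axon-initial-segment length from 3D fluorescence stacks.

Pipeline: an IsoData threshold on the middle plane of the stack gives the
lower threshold; the upper threshold is twice the lower; 3D hysteresis
thresholding (keep 26-connected components of the lower-threshold mask
that contain at least one voxel above the upper threshold) produces the
binary structure; the largest component is thinned to a one-voxel-wide
skeleton and the AIS length is the anisotropic Euclidean length of the
longest geodesic path along it.

Conventions documented in the methods note: middle plane = ``n_z // 2``;
26-connectivity; (n-1)-step path length with no end-cap padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .synth import ImageStack

__all__ = [
    "AISMeasurement",
    "isodata_threshold",
    "hysteresis_3d",
    "skeletal_length",
    "measure_ais",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class AISMeasurement:
    length: float  # μm
    n_skeleton_voxels: int
    thresholds: tuple[float, float]  # (T_low, T_high); T_high = 2 * T_low
    branched: bool


def isodata_threshold(plane: np.ndarray, tol: float = 0.5,
                      max_iter: int = 500) -> float:
    """IsoData threshold of a single 2D plane.

    Iterates ``T <- (mean(pixels <= T) + mean(pixels > T)) / 2`` from the
    global mean until the update is below ``tol`` intensity units.
    Intensities are treated as continuous.  A constant plane has no
    foreground/background split and raises ``ValueError``.
    """
    x = np.asarray(plane, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        raise ValueError("IsoData undefined on a constant or empty plane")
    T = float(x.mean())
    for _ in range(max_iter):
        lo = x[x <= T]
        hi = x[x > T]
        if lo.size == 0 or hi.size == 0:
            break
        T_new = 0.5 * (lo.mean() + hi.mean())
        if abs(T_new - T) < tol:
            return float(T_new)
        T = T_new
    return float(T)


def hysteresis_3d(stack: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Keep 26-connected components above ``t_low`` that reach ``t_high``."""
    vox = np.asarray(stack)
    mask_low = vox > t_low
    labels, n = ndimage.label(mask_low, structure=_STRUCT26)
    if n == 0:
        return np.zeros_like(mask_low)
    seeds = np.unique(labels[vox > t_high])
    seeds = seeds[seeds > 0]
    return np.isin(labels, seeds)


def _skeleton_graph(coords: np.ndarray, spacing: np.ndarray) -> sparse.csr_matrix:
    """Sparse graph of 26-neighbor skeleton voxels, anisotropic edge lengths."""
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    rows, cols, w = [], [], []
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
    offsets = [o - 1 for o in offsets]
    for i, c in enumerate(coords):
        for o in offsets:
            j = index.get(tuple(c + o))
            if j is not None and j > i:
                d = float(np.linalg.norm(o * spacing))
                rows += [i, j]
                cols += [j, i]
                w += [d, d]
    n = len(coords)
    return sparse.csr_matrix((w, (rows, cols)), shape=(n, n))


def skeletal_length(mask: np.ndarray, spacing) -> AISMeasurement:
    """Skeletonize a binary mask and measure the longest geodesic (μm).

    The mask is thinned to a unit-width centerline; voxel steps are
    weighted by the anisotropic Euclidean distance; the reported length
    is the longest shortest path between any two skeleton voxels
    (double-sweep Dijkstra).  ``branched`` is set when the skeleton has
    more than two endpoints.
    """
    spacing = np.asarray(spacing, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        warnings.warn("empty mask: skeletal length is 0", stacklevel=2)
        return AISMeasurement(0.0, 0, (np.nan, np.nan), False)
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if coords.shape[0] == 1:
        return AISMeasurement(0.0, 1, (np.nan, np.nan), False)
    graph = _skeleton_graph(coords, spacing)
    # endpoints: skeleton voxels with exactly one neighbor
    degrees = np.diff(graph.indptr)
    branched = bool((degrees == 1).sum() > 2)
    # double sweep: farthest node from an arbitrary start, then from there
    d0 = dijkstra(graph, indices=0, directed=False)
    d0[~np.isfinite(d0)] = -1.0
    u = int(np.argmax(d0))
    d1 = dijkstra(graph, indices=u, directed=False)
    d1[~np.isfinite(d1)] = -1.0
    length = float(d1.max())
    return AISMeasurement(length, int(coords.shape[0]), (np.nan, np.nan), branched)


def measure_ais(stack: ImageStack) -> AISMeasurement:
    """Full pipeline: IsoData on the middle plane, 2x hysteresis, largest
    component, skeletal length."""
    vox = stack.voxels
    mid = vox[vox.shape[0] // 2]
    t_low = isodata_threshold(mid)
    t_high = 2.0 * t_low
    mask = hysteresis_3d(vox, t_low, t_high)
    if not mask.any():
        raise ValueError("hysteresis mask empty: no structure above threshold")
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    largest = int(np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1)))) + 1
    meas = skeletal_length(labels == largest, stack.spacing)
    return AISMeasurement(meas.length, meas.n_skeleton_voxels,
                          (float(t_low), float(t_high)), meas.branched)
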