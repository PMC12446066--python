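"""Point-cloud sampling and reduction from segmentation masks.

Surfaces are sampled by running a 2D Canny detector over each z-slice of the
binarized mask (membrane pixels), then reduced by uniform every-k-th
sampling, voxel-grid binning and statistical outlier removal before
registration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import canny

from .volio import LabelVolume, PointCloud

__all__ = [
    "surface_points",
    "uniform_downsample",
    "voxel_bin",
    "remove_statistical_outliers",
    "reduce_cloud",
]


def surface_points(mask: LabelVolume, canny_sigma: float = 1.0,
                   source: str = "") -> PointCloud:
    """Sample membrane pixels of a binary mask, slice by slice.

    The mask should already be on an isotropic grid.  Every Canny edge pixel
    becomes one point; ordering is deterministic (z, then row-major in-slice)
    so that downstream uniform downsampling is reproducible.
    """
    binary = mask.binary()
    pts = []
    for z in range(binary.shape[0]):
        sl = binary[z]
        if not sl.any():
            continue
        edges = canny(sl.astype(float), sigma=canny_sigma)
        ys, xs = np.nonzero(edges)
        if ys.size:
            pts.append(np.column_stack([np.full(ys.size, z, dtype=float), ys, xs]))
    points = np.concatenate(pts, axis=0) if pts else np.empty((0, 3))
    step = mask.voxel_size[0] if len(set(mask.voxel_size)) == 1 else None
    return PointCloud(points=points, space="pixel", grid_step_nm=step, source=source)


def uniform_downsample(pc: PointCloud, k: int) -> PointCloud:
    """Keep every k-th point starting from index 0 (sampling frequency 1/k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return PointCloud(points=pc.points[::k].copy(), space=pc.space,
                      grid_step_nm=pc.grid_step_nm, source=pc.source)


def voxel_bin(pc: PointCloud, s=(15, 15, 15)) -> PointCloud:
    """Voxel-grid binning: one point (the mean) per occupied s-sized cell.

    The grid is anchored at the coordinate origin, not the cloud minimum, so
    clouds from different modalities fall on commensurate grids.  Output
    order is lexicographic in cell index.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 1):
        raise ValueError("bin sizes must be >= 1")
    if len(pc) == 0:
        return PointCloud(points=pc.points.copy(), space=pc.space,
                          grid_step_nm=pc.grid_step_nm, source=pc.source)
    cells = np.floor(pc.points / s).astype(np.int64)
    uniq, inv = np.unique(cells, axis=0, return_inverse=True)
    sums = np.zeros((uniq.shape[0], 3))
    np.add.at(sums, inv, pc.points)
    counts = np.bincount(inv, minlength=uniq.shape[0]).astype(float)
    means = sums / counts[:, None]
    return PointCloud(points=means, space=pc.space,
                      grid_step_nm=pc.grid_step_nm, source=pc.source)


def remove_statistical_outliers(pc: PointCloud, n_neighbors: int = 20,
                                std_ratio: float = 2.0) -> PointCloud:
    """Drop points whose mean kNN distance exceeds mu + std_ratio * sigma.

    The statistic is each point's mean distance to its ``n_neighbors``
    nearest neighbours; mu and sigma are taken over the cloud.  Clouds with
    too few points are returned unchanged with a warning.
    """
    n = len(pc)
    if n <= n_neighbors:
        warnings.warn("cloud smaller than n_neighbors; outlier removal skipped")
        return PointCloud(points=pc.points.copy(), space=pc.space,
                          grid_step_nm=pc.grid_step_nm, source=pc.source)
    tree = cKDTree(pc.points)
    # +1 because the nearest neighbour of a point is itself
    dists, _ = tree.query(pc.points, k=n_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    keep = mean_d <= mu + std_ratio * sigma
    return PointCloud(points=pc.points[keep].copy(), space=pc.space,
                      grid_step_nm=pc.grid_step_nm, source=pc.source)


def reduce_cloud(pc: PointCloud, k: int = 30, bin_size=(15, 15, 15),
                 outlier_neighbors: int = 20, outlier_std: float = 2.0) -> PointCloud:
    """Standard reduction chain: uniform k-th sampling, voxel binning,
    statistical outlier removal."""
    out = uniform_downsample(pc, k)
    out = voxel_bin(out, bin_size)
    return remove_statistical_outliers(out, outlier_neighbors, outlier_std)
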