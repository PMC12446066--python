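"""Volume warping: inverse-mapping affine warps and 3D thin-plate splines.

All warps use the inverse-projection convention: for every voxel of the
*output* grid the transform (or its inverse) gives the location to sample in
the input volume, interpolated with a spline of configurable order.  The TPS
field is therefore fitted from output-space control points to input-space
control points.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .transforms import (AffineTransform, RigidTransform,
                         ThinPlateSplineTransform)
from .volio import PointCloud, Volume

__all__ = [
    "ThinPlateSpline",
    "affine_warp_volume",
    "tps_fit",
    "tps_warp_volume",
    "resample_to_em",
]


def _out_grid_geometry(out_grid) -> Tuple[tuple, tuple]:
    """Accept a Volume, a (shape, voxel_size) pair, or a bare shape."""
    if isinstance(out_grid, Volume):
        return out_grid.shape, out_grid.voxel_size
    if (isinstance(out_grid, tuple) and len(out_grid) == 2
            and isinstance(out_grid[0], (tuple, list))):
        return tuple(out_grid[0]), tuple(out_grid[1])
    return tuple(int(n) for n in out_grid), None


def affine_warp_volume(v: Volume, transform, out_grid=None, order: int = 3) -> Volume:
    """Warp ``v`` through a rigid/affine transform onto ``out_grid``.

    ``transform`` maps input-volume pixel coordinates to output-grid pixel
    coordinates; each output voxel p is sampled at ``transform^-1(p)``.
    Out-of-bounds samples are filled with 0.
    """
    if order not in (0, 1, 3):
        raise ValueError("interpolation order must be 0, 1 or 3")
    if out_grid is None:
        out_grid = v
    shape, voxel_size = _out_grid_geometry(out_grid)
    if voxel_size is None:
        voxel_size = v.voxel_size
    if isinstance(transform, RigidTransform):
        transform = transform.as_affine()
    inv = transform.inverse()
    # scipy's affine_transform applies  input_coord = matrix @ output_coord
    # + offset, which is exactly the inverse mapping we need.
    out = ndimage.affine_transform(
        np.asarray(v.data, dtype=np.float64),
        matrix=inv.matrix,
        offset=inv.translation,
        output_shape=shape,
        order=order,
        mode="grid-constant",
        cval=0.0,
    )
    return Volume(data=out, voxel_size=voxel_size, channel_name=v.channel_name)


class ThinPlateSpline(BaseEstimator):
    """3D thin-plate spline interpolator, kernel phi(r) = r.

    ``fit(source_ctrl, target_ctrl)`` solves the TPS linear system so that
    ``transform(source_ctrl) == target_ctrl`` exactly (zero regularization).
    Fitted attributes: ``affine_matrix_``, ``affine_translation_``,
    ``weights_``, ``transform_`` (a :class:`ThinPlateSplineTransform`).

    The side conditions of the biharmonic spline hold by construction: the
    kernel weights sum to zero and are orthogonal to the control coordinates,
    which makes the far field purely affine.
    """

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, source_ctrl, target_ctrl):
        c = np.atleast_2d(np.asarray(
            source_ctrl.points if isinstance(source_ctrl, PointCloud) else source_ctrl,
            dtype=float))
        t = np.atleast_2d(np.asarray(
            target_ctrl.points if isinstance(target_ctrl, PointCloud) else target_ctrl,
            dtype=float))
        if c.shape != t.shape or c.shape[1] != 3:
            raise ValueError("control point sets must be matching Mx3 arrays")
        m = c.shape[0]
        if m < 4:
            raise ValueError("need at least 4 control point pairs")
        k = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        if self.regularization:
            k = k + self.regularization * np.eye(m)
        p = np.hstack([np.ones((m, 1)), c])
        lhs = np.zeros((m + 4, m + 4))
        lhs[:m, :m] = k
        lhs[:m, m:] = p
        lhs[m:, :m] = p.T
        rhs = np.zeros((m + 4, 3))
        rhs[:m] = t
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular TPS system (coplanar or duplicate control points)"
            ) from exc
        cond = np.linalg.cond(lhs)
        if cond > 1e12:
            raise ValueError(
                f"degenerate TPS control geometry (condition number {cond:.1e}); "
                "controls may be coplanar")
        self.control_points_ = c
        self.weights_ = sol[:m]
        self.affine_translation_ = sol[m]
        self.affine_matrix_ = sol[m + 1:].T
        self.transform_ = ThinPlateSplineTransform(
            control_points=c,
            affine_matrix=self.affine_matrix_,
            affine_translation=self.affine_translation_,
            weights=self.weights_,
        )
        return self

    def transform(self, points):
        pts = np.atleast_2d(np.asarray(
            points.points if isinstance(points, PointCloud) else points, dtype=float))
        return self.transform_.apply(pts)


def tps_fit(source_ctrl, target_ctrl) -> ThinPlateSplineTransform:
    """Fit an exact-interpolation 3D TPS mapping source controls to targets."""
    return ThinPlateSpline().fit(source_ctrl, target_ctrl).transform_


def tps_warp_volume(v: Volume, tps_field: ThinPlateSplineTransform,
                    out_grid=None, chunks=(2, 2, 2), order: int = 1,
                    grid_step: int = 0) -> Volume:
    """Warp a volume through a TPS displacement field, in sequential chunks.

    ``tps_field`` must be the *inverse* mapping: it takes output-grid pixel
    coordinates to input-volume pixel coordinates.  The output grid is split
    ``chunks`` ways per axis and processed sequentially to bound peak memory;
    because evaluation is pointwise the chunked result is bit-identical to
    the monolithic one.

    ``grid_step > 0`` enables the approximate accelerator: the field is
    evaluated exactly on a coarse lattice with that step (in output voxels)
    and interpolated linearly in between.  ``grid_step = 0`` is the exact
    reference path.
    """
    if out_grid is None:
        out_grid = v
    shape, voxel_size = _out_grid_geometry(out_grid)
    if voxel_size is None:
        voxel_size = v.voxel_size
    chunks = tuple(int(c) for c in chunks)
    if any(c < 1 for c in chunks):
        raise ValueError("chunk counts must be >= 1")
    data = np.asarray(v.data, dtype=np.float64)
    out = np.zeros(shape, dtype=np.float64)

    bounds = [np.linspace(0, n, c + 1, dtype=int) for n, c in zip(shape, chunks)]
    for iz, iy, ix in product(range(chunks[0]), range(chunks[1]), range(chunks[2])):
        sl = tuple(slice(b[i], b[i + 1])
                   for b, i in zip(bounds, (iz, iy, ix)))
        sub_shape = tuple(s.stop - s.start for s in sl)
        if any(n == 0 for n in sub_shape):
            continue
        axes = [np.arange(s.start, s.stop, dtype=float) for s in sl]
        if grid_step and grid_step > 1:
            src = _approx_field(tps_field, axes, grid_step)
        else:
            zz, yy, xx = np.meshgrid(*axes, indexing="ij")
            pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
            src = tps_field.apply(pts)
        out[sl] = ndimage.map_coordinates(
            data, src.T.reshape(3, *sub_shape), order=order,
            mode="grid-constant", cval=0.0)
    return Volume(data=out, voxel_size=voxel_size, channel_name=v.channel_name)


def _approx_field(field, axes, step: int) -> np.ndarray:
    """Evaluate the TPS on a coarse lattice and interpolate linearly."""
    coarse_axes = []
    for ax in axes:
        lo, hi = ax[0], ax[-1]
        n = max(2, int(np.ceil((hi - lo) / step)) + 1)
        coarse_axes.append(np.linspace(lo, hi, n))
    zz, yy, xx = np.meshgrid(*coarse_axes, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    vals = field.apply(pts).reshape(zz.shape + (3,))
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator(coarse_axes, vals, method="linear")
    fz, fy, fx = np.meshgrid(*axes, indexing="ij")
    fine = np.column_stack([fz.ravel(), fy.ravel(), fx.ravel()])
    return interp(fine)


def resample_to_em(v: Volume, em: Volume, order: int = 1) -> Volume:
    """Resample ``v`` onto the EM volume's grid (shared physical origin)."""
    if v.voxel_size is None or em.voxel_size is None:
        raise ValueError("both volumes need voxel sizes")
    if v.shape == em.shape and np.allclose(v.voxel_size, em.voxel_size):
        return Volume(data=np.asarray(v.data, dtype=np.float64).copy(),
                      voxel_size=em.voxel_size, channel_name=v.channel_name)
    scale = np.asarray(em.voxel_size, dtype=float) / np.asarray(v.voxel_size, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(em.shape, scale)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=np.float64),
        np.stack([zz.ravel(), yy.ravel(), xx.ravel()]),
        order=order, mode="grid-constant", cval=0.0,
    ).reshape(em.shape)
    return Volume(data=out, voxel_size=em.voxel_size, channel_name=v.channel_name)
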