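"""Spatial transforms shared across the pipeline.

All transforms act on (z, y, x) coordinates.  A transform carries a ``units``
tag (``"pixel"`` for an isotropic pixel grid, ``"nm"`` for physical space) so
that point clouds and transforms cannot be combined across spaces by accident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "ThinPlateSplineTransform",
    "SpatialTransform",
    "to_physical",
    "write_transform",
    "read_transform",
]

_ORTHO_TOL = 1e-8


@dataclass
class RigidTransform:
    """Similarity transform ``p -> scale * R @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    units: str = "pixel"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (|R'R - I| = {err:.2e})")
        if np.linalg.det(self.rotation) <= 0:
            raise ValueError("rotation must have det +1 (no reflection)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(
            rotation=r_inv,
            translation=-(r_inv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
            units=self.units,
        )

    def as_affine(self) -> "AffineTransform":
        return AffineTransform(
            matrix=self.scale * self.rotation,
            translation=self.translation.copy(),
            units=self.units,
        )

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle in degrees (0..180)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AffineTransform:
    """General linear transform ``p -> matrix @ p + translation``."""

    matrix: np.ndarray
    translation: np.ndarray
    units: str = "pixel"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        m_inv = np.linalg.inv(self.matrix)
        return AffineTransform(m_inv, -(m_inv @ self.translation), units=self.units)

    def as_affine(self) -> "AffineTransform":
        return self


@dataclass
class ThinPlateSplineTransform:
    """3D thin-plate spline ``f(p) = A p + t + sum_i W_i * phi(|p - C_i|)``.

    The kernel is the 3D biharmonic fundamental solution ``phi(r) = r``.
    ``control_points`` are in the transform's *input* space; evaluating at a
    control point reproduces its fitted target exactly when the spline was fit
    without regularization.
    """

    control_points: np.ndarray
    affine_matrix: np.ndarray
    affine_translation: np.ndarray
    weights: np.ndarray
    units: str = "pixel"

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=float)
        self.affine_translation = np.asarray(self.affine_translation, dtype=float).reshape(3)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be Mx3")
        if self.weights.shape != self.control_points.shape:
            raise ValueError("weights must match control_points shape")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.affine_matrix.T + self.affine_translation
        # phi(r) = r; evaluate in blocks to bound memory on voxel grids
        block = 1 << 18
        for start in range(0, pts.shape[0], block):
            chunk = pts[start : start + block]
            r = np.linalg.norm(chunk[:, None, :] - self.control_points[None, :, :], axis=2)
            out[start : start + block] += r @ self.weights
        return out

    def as_affine(self):  # pragma: no cover - guard
        raise TypeError("thin-plate spline transform has no exact affine form")


SpatialTransform = Union[RigidTransform, AffineTransform, ThinPlateSplineTransform]


def to_physical(transform, grid_step_nm: float):
    """Convert a pixel-space rigid/affine transform to physical (nm) units.

    On an isotropic grid with step ``grid_step_nm`` the linear part is
    unit-free; only the translation picks up the scale factor.
    """
    if grid_step_nm <= 0:
        raise ValueError("grid step must be positive")
    if isinstance(transform, RigidTransform):
        return RigidTransform(
            rotation=transform.rotation.copy(),
            translation=transform.translation * grid_step_nm,
            scale=transform.scale,
            units="nm",
        )
    if isinstance(transform, AffineTransform):
        return AffineTransform(
            matrix=transform.matrix.copy(),
            translation=transform.translation * grid_step_nm,
            units="nm",
        )
    raise TypeError(f"cannot convert {type(transform).__name__} to physical units")


def to_pixel(transform, grid_step_nm: float):
    """Inverse of :func:`to_physical`."""
    out = to_physical(transform, 1.0 / grid_step_nm)
    out.units = "pixel"
    return out


def _transform_to_dict(t: SpatialTransform) -> dict:
    if isinstance(t, RigidTransform):
        return {
            "kind": "rigid",
            "scale": float(t.scale),
            "rotation": t.rotation.tolist(),
            "translation": t.translation.tolist(),
            "units": t.units,
        }
    if isinstance(t, AffineTransform):
        return {
            "kind": "affine",
            "matrix": t.matrix.tolist(),
            "translation": t.translation.tolist(),
            "units": t.units,
        }
    if isinstance(t, ThinPlateSplineTransform):
        return {
            "kind": "tps",
            "control_points": t.control_points.tolist(),
            "affine_matrix": t.affine_matrix.tolist(),
            "affine_translation": t.affine_translation.tolist(),
            "weights": t.weights.tolist(),
            "units": t.units,
        }
    raise TypeError(f"unknown transform type {type(t).__name__}")


def _transform_from_dict(d: dict) -> SpatialTransform:
    kind = d.get("kind")
    if kind == "rigid":
        return RigidTransform(
            rotation=np.asarray(d["rotation"]),
            translation=np.asarray(d["translation"]),
            scale=float(d["scale"]),
            units=d.get("units", "pixel"),
        )
    if kind == "affine":
        return AffineTransform(
            matrix=np.asarray(d["matrix"]),
            translation=np.asarray(d["translation"]),
            units=d.get("units", "pixel"),
        )
    if kind == "tps":
        return ThinPlateSplineTransform(
            control_points=np.asarray(d["control_points"]),
            affine_matrix=np.asarray(d["affine_matrix"]),
            affine_translation=np.asarray(d["affine_translation"]),
            weights=np.asarray(d["weights"]),
            units=d.get("units", "pixel"),
        )
    raise ValueError(f"unknown transform kind {kind!r}")


def write_transform(path, transform: SpatialTransform) -> None:
    Path(path).write_text(json.dumps(_transform_to_dict(transform), indent=2))


def read_transform(path) -> SpatialTransform:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed transform JSON in {path}: {exc}") from exc
    return _transform_from_dict(d)
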