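"""Volume / label-volume containers, TIFF and CSV I/O, and grid resampling.

Conventions used throughout the package:

* axis order is ``(z, y, x)``, 0-based, with voxel centers at integer
  coordinates and all grids anchored at physical coordinate 0;
* voxel sizes are in nanometres;
* point clouds are N x 3 arrays in the same ``(z, y, x)`` order, tagged with
  the space they live in (``pixel`` on an isotropic grid, or ``nm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelVolume",
    "PointCloud",
    "read_stack",
    "write_stack",
    "read_label_stack",
    "resample_isotropic",
    "bin_volume",
    "merge_masks_by_sum",
    "write_point_cloud",
    "read_point_cloud",
]

#: 26-connectivity structuring element for 3D connected components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _check_voxel_size(voxel_size) -> tuple:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be three positive values, got {voxel_size}")
    return vs


@dataclass
class Volume:
    """A 3D scalar intensity grid with per-axis voxel size in nm."""

    data: np.ndarray
    voxel_size: tuple
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        z, y, x = self.voxel_size
        return abs(z - y) <= tol and abs(y - x) <= tol


@dataclass
class LabelVolume:
    """A 3D instance-label grid; 0 is background, ids need not be contiguous."""

    labels: np.ndarray
    voxel_size: tuple

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label data must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.int32)
            else:
                raise ValueError("labels must be an integer (or boolean) array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class PointCloud:
    """Ordered N x 3 point set in (z, y, x) order with a declared space."""

    points: np.ndarray
    space: str = "pixel"
    grid_step_nm: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an Nx3 array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if self.space not in ("pixel", "nm"):
            raise ValueError(f"space must be 'pixel' or 'nm', got {self.space!r}")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


def read_stack(path, voxel_size, channel_name: str = "") -> Volume:
    """Read a multi-page TIFF as a Volume; page order maps to z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        raise ValueError("volume must have >=2 z-slices")
    if data.ndim != 3:
        raise ValueError(f"expected 3D TIFF content, got ndim={data.ndim}")
    return Volume(data=np.asarray(data, dtype=np.float32), voxel_size=voxel_size,
                  channel_name=channel_name)


def read_label_stack(path, voxel_size) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        raise ValueError("label volume must have >=2 z-slices")
    return LabelVolume(labels=np.asarray(data).astype(np.int32), voxel_size=voxel_size)


def write_stack(path, volume) -> None:
    """Write a Volume or LabelVolume as a multi-page TIFF."""
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int32)
    else:
        data = volume.data.astype(np.float32)
    tifffile.imwrite(str(path), data)


def resample_isotropic(v, target_nm: float, mode: Optional[str] = None):
    """Resample a Volume or LabelVolume onto an isotropic ``target_nm`` grid.

    Output shape is ``round(extent_nm / target_nm)`` per axis (at least 1).
    Intensities are interpolated linearly, labels by nearest neighbour; linear
    interpolation on a LabelVolume is rejected because it invents labels.
    """
    if target_nm <= 0:
        raise ValueError("target_nm must be positive")
    is_labels = isinstance(v, LabelVolume)
    if mode is None:
        mode = "nearest" if is_labels else "linear"
    if is_labels and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")

    data = v.labels if is_labels else v.data
    old = np.asarray(v.voxel_size, dtype=float)
    new_shape = tuple(
        max(1, int(np.round(n * s / target_nm))) for n, s in zip(data.shape, old)
    )
    if new_shape == data.shape and np.allclose(old, target_nm):
        out = data.copy()
    else:
        axes = [np.arange(n) * target_nm / s for n, s in zip(new_shape, old)]
        coords = np.meshgrid(*axes, indexing="ij", sparse=False)
        order = 0 if mode == "nearest" else 1
        out = ndimage.map_coordinates(
            data.astype(np.float32 if mode == "linear" else data.dtype),
            np.stack([c.ravel() for c in coords]),
            order=order,
            mode="nearest",
        ).reshape(new_shape)
    vs = (target_nm,) * 3
    if is_labels:
        return LabelVolume(labels=out.astype(v.labels.dtype), voxel_size=vs)
    return Volume(data=out, voxel_size=vs, channel_name=v.channel_name)


def bin_volume(v: Volume, factors) -> Volume:
    """Block-mean downsample by integer factors; voxel size scales up.

    Axes that are not an exact multiple of their factor are cropped to the
    largest tiling extent before averaging.
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("binning factors must be >= 1")
    if any(f > n for f, n in zip(factors, v.shape)):
        raise ValueError(f"binning factor {factors} exceeds volume shape {v.shape}")
    data = v.data
    trimmed = tuple((n // f) * f for n, f in zip(data.shape, factors))
    data = data[: trimmed[0], : trimmed[1], : trimmed[2]].astype(np.float64)
    nz, ny, nx = (t // f for t, f in zip(trimmed, factors))
    fz, fy, fx = factors
    out = data.reshape(nz, fz, ny, fy, nx, fx).mean(axis=(1, 3, 5))
    vs = tuple(s * f for s, f in zip(v.voxel_size, factors))
    return Volume(data=out, voxel_size=vs, channel_name=v.channel_name)


def merge_masks_by_sum(masks: Sequence[LabelVolume]) -> LabelVolume:
    """Merge instance masks by summation + binarization, then relabel.

    The union foreground is relabelled into 26-connected components, so
    instance identities of the inputs do not survive merging.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    for m in masks[1:]:
        if m.shape != ref.shape or not np.allclose(m.voxel_size, ref.voxel_size):
            raise ValueError("all masks must share shape and voxel size")
    total = np.zeros(ref.shape, dtype=np.int64)
    for m in masks:
        total += m.binary().astype(np.int64)
    labels, _ = ndimage.label(total > 0, structure=STRUCT_26)
    return LabelVolume(labels=labels.astype(np.int32), voxel_size=ref.voxel_size)


def write_point_cloud(path, pc: PointCloud) -> None:
    """Write a point cloud as CSV with a `# space=...` header comment."""
    header = f"# space={pc.space}"
    if pc.space == "pixel" and pc.grid_step_nm is not None:
        header += f" step_nm={pc.grid_step_nm:.9g}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("z,y,x\n")
        for z, y, x in pc.points:
            fh.write(f"{z:.9f},{y:.9f},{x:.9f}\n")


def read_point_cloud(path) -> PointCloud:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# space="):
            raise ValueError(f"{path}: missing '# space=' header comment")
        tokens = first[2:].split()
        meta = dict(tok.split("=", 1) for tok in tokens if "=" in tok)
        space = meta.get("space")
        if space not in ("pixel", "nm"):
            raise ValueError(f"{path}: invalid space {space!r} in header")
        step = float(meta["step_nm"]) if "step_nm" in meta else None
        df = pd.read_csv(fh)
    for col in ("z", "y", "x"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing coordinate column {col!r}")
    pts = df[["z", "y", "x"]].to_numpy(dtype=float)
    return PointCloud(points=pts, space=space, grid_step_nm=step)
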