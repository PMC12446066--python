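"""Synthetic paired FM/EM fixtures with known ground truth.

The generator emulates the layout of a real vCLEM acquisition at desk scale:
ellipsoidal landmark organelles (mitochondria) scattered through an
ellipsoidal cell in a near-isotropic EM grid, spherical 0.3-1 um target
structures (lysosome-like) present in both modalities, and a fluorescence
stack produced on its own anisotropic grid by pushing the EM-space geometry
through the *inverse* of a known rigid ground-truth transform, blurring with
an anisotropic Gaussian PSF, attenuating with depth and adding noise.

Everything is deterministic given the seed, so the fixtures double as test
data for every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import evalx
from .transforms import RigidTransform
from .volio import LabelVolume, PointCloud, Volume, write_point_cloud, write_stack
from .transforms import write_transform

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "degrade_fixture",
           "write_fixture"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ~1/2.355


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic paired volume.

    Sizes are physical (nm) except the grid shapes.  Defaults emulate a
    FIB-SEM-style acquisition binned to 20 nm isotropic EM voxels, with an
    Airyscan-like FM grid of (100, 40, 40) nm voxels and a PSF of
    350 / 120 nm FWHM in z / xy.
    """

    seed: int = 0
    shape: Tuple[int, int, int] = (72, 352, 352)
    em_voxel_nm: float = 20.0
    n_mito: int = 40
    mito_major_semi_nm: Tuple[float, float] = (300.0, 500.0)
    mito_minor_semi_nm: Tuple[float, float] = (150.0, 250.0)
    min_gap_nm: float = 150.0
    n_targets: int = 5
    target_diameter_nm: Tuple[float, float] = (300.0, 1000.0)
    rotation_deg: float = 10.0
    translation_px: Tuple[float, float, float] = (5.0, 10.0, 10.0)
    fm_voxel_nm: Tuple[float, float, float] = (100.0, 40.0, 40.0)
    psf_fwhm_nm: Tuple[float, float, float] = (350.0, 120.0, 120.0)
    attenuation_per_slice: float = 0.005
    noise_sigma: float = 0.05
    poisson: bool = False
    cell_fraction: float = 0.46
    fm_margin_factor: float = 1.25

    def __post_init__(self) -> None:
        if self.n_mito < 4:
            raise ValueError("need at least 4 landmark instances")
        for rng_pair in (self.mito_major_semi_nm, self.mito_minor_semi_nm,
                         self.target_diameter_nm):
            if rng_pair[0] <= 0 or rng_pair[1] < rng_pair[0]:
                raise ValueError(f"invalid positive range {rng_pair}")
        if any(v <= 0 for v in self.fm_voxel_nm) or self.em_voxel_nm <= 0:
            raise ValueError("voxel sizes must be positive")
        if any(v <= 0 for v in self.psf_fwhm_nm):
            raise ValueError("PSF FWHM must be positive")


@dataclass
class Fixture:
    spec: FixtureSpec
    em_labels: LabelVolume
    em_intensity: Volume
    fm_landmarks: Volume
    fm_targets: Volume
    truth_nm: RigidTransform           # FM physical (nm) -> EM physical (nm)
    truth_px: RigidTransform           # same transform on the isotropic pixel grid
    landmark_pairs: Tuple[PointCloud, PointCloud]  # (moving FM nm, fixed EM nm)
    target_truth: List[evalx.TargetStructure]
    target_labels: LabelVolume


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    """Rotation about the z (first) axis in (z, y, x) coordinates."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _place_ellipsoid(occupied: np.ndarray, cell_center: np.ndarray,
                     cell_semi: np.ndarray, semi_px: np.ndarray,
                     rot: np.ndarray, rng: np.random.Generator,
                     margin_px: float = 0.0, max_attempts: int = 5000):
    """Find a non-overlapping pose for one ellipsoid inside the cell.

    Centers are sampled uniformly through the cell ellipsoid; poses whose
    bounding box leaves the grid or whose margin-grown envelope collides
    with previously placed instances are rejected, enforcing a minimum
    surface separation between instances.  Returns (instance voxel index
    tuple, margin-envelope index tuple, center) or None after max_attempts.
    """
    shape = np.asarray(occupied.shape)
    r_inst = semi_px.max()
    r_max = r_inst + margin_px
    grown = semi_px + margin_px
    for _ in range(max_attempts):
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u ** 2).sum() > 1.0:
            continue
        center = cell_center + u * 0.92 * cell_semi
        # the instance itself must fit the grid; its margin envelope may be
        # clipped at the borders
        if np.any(center - r_inst < 0) or np.any(center + r_inst + 1 > shape):
            continue
        lo = np.maximum(np.floor(center - r_max).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(center + r_max).astype(int) + 2, shape)
        axes = [np.arange(l, h) for l, h in zip(lo, hi)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
        local = rel @ rot  # rotate into the ellipsoid frame
        inside = ((local / semi_px) ** 2).sum(axis=-1) <= 1.0
        if not inside.any():
            continue
        envelope = ((local / grown) ** 2).sum(axis=-1) <= 1.0
        env_idx = tuple(c[envelope] for c in (zz, yy, xx))
        if occupied[env_idx].any():
            continue
        idx = tuple(c[inside] for c in (zz, yy, xx))
        return idx, env_idx, center
    return None


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one paired FM/EM fixture; see the module docstring."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.shape)
    em_nm = float(spec.em_voxel_nm)

    # ---- EM-space geometry -------------------------------------------------
    cell_center = np.asarray(shape, dtype=float) / 2.0
    cell_semi = spec.cell_fraction * np.asarray(shape, dtype=float)

    # place the (few, large) target spheres first, then pack mitochondria
    # around them -- large-first placement packs far more reliably
    em_labels = np.zeros(shape, dtype=np.int32)
    target_labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    margin_px = spec.min_gap_nm / em_nm
    for j in range(spec.n_targets):
        r = rng.uniform(*spec.target_diameter_nm) / 2.0 / em_nm
        semi = np.array([r, r, r])
        placed = _place_ellipsoid(occupied, cell_center, cell_semi, semi,
                                  np.eye(3), rng, margin_px=margin_px)
        if placed is None:
            raise RuntimeError(
                f"could not place target sphere {j + 1}/{spec.n_targets}; "
                "spec is overcrowded")
        idx, _, _ = placed
        target_labels[idx] = j + 1
        occupied[idx] = True

    for i in range(spec.n_mito):
        a = rng.uniform(*spec.mito_major_semi_nm) / em_nm
        b = rng.uniform(*spec.mito_minor_semi_nm) / em_nm
        c = rng.uniform(*spec.mito_minor_semi_nm) / em_nm
        semi = np.array([a, b, c])
        rot = _random_rotation(rng)
        placed = _place_ellipsoid(occupied, cell_center, cell_semi, semi, rot,
                                  rng, margin_px=margin_px)
        if placed is None:
            raise RuntimeError(
                f"could not place landmark instance {i + 1}/{spec.n_mito}; "
                "spec is overcrowded")
        idx, _, _ = placed
        em_labels[idx] = i + 1
        occupied[idx] = True

    # ---- EM intensity: bright embedding, dark stained organelles ----------
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), 2.0)
    em_int = 0.55 + 0.06 * texture
    em_int[em_labels > 0] = 0.22
    em_int[target_labels > 0] = 0.35
    em_int += rng.normal(0.0, 0.03, size=shape)
    em_int = np.clip(em_int, 0.0, 1.0)

    # ---- ground-truth transform (FM phys nm -> EM phys nm) ----------------
    rot = _rotation_about_z(spec.rotation_deg)
    em_extent = np.asarray(shape) * em_nm
    fm_voxel = np.asarray(spec.fm_voxel_nm, dtype=float)
    fm_extent = spec.fm_margin_factor * em_extent
    fm_shape = tuple(int(np.ceil(e / v)) for e, v in zip(fm_extent, fm_voxel))
    c_em = em_extent / 2.0
    c_fm = np.asarray(fm_shape) * fm_voxel / 2.0
    delta = np.asarray(spec.translation_px, dtype=float) * em_nm
    t_nm = c_em - rot @ c_fm + delta
    truth_nm = RigidTransform(rotation=rot, translation=t_nm, scale=1.0, units="nm")
    truth_px = RigidTransform(rotation=rot.copy(), translation=t_nm / em_nm,
                              scale=1.0, units="pixel")

    # ---- FM channels on the anisotropic grid -------------------------------
    fm_landmarks = _render_fm_channel(em_labels > 0, truth_nm, fm_shape,
                                      fm_voxel, em_nm, spec, rng)
    fm_targets = _render_fm_channel(target_labels > 0, truth_nm, fm_shape,
                                    fm_voxel, em_nm, spec, rng)

    # ---- paired held-out landmarks (instance centroids) --------------------
    ids = np.arange(1, spec.n_mito + 1)
    centroids_px = np.asarray(ndimage.center_of_mass(em_labels > 0, em_labels, ids))
    fixed_nm = centroids_px * em_nm
    inv = truth_nm.inverse()
    moving_nm = inv.apply(fixed_nm)
    pairs = (
        PointCloud(points=moving_nm, space="nm", source="fm"),
        PointCloud(points=fixed_nm, space="nm", source="em"),
    )

    # ---- target ground truth -----------------------------------------------
    targets = []
    margin = 5
    for j in range(1, spec.n_targets + 1):
        mask = (target_labels == j).astype(np.int32)
        nz = np.nonzero(mask)
        box = tuple((max(int(c.min()) - margin, 0),
                     min(int(c.max()) + 1 + margin, s))
                    for c, s in zip(nz, shape))
        targets.append(evalx.TargetStructure(
            em_mask=LabelVolume(labels=mask, voxel_size=(em_nm,) * 3),
            fm_crop_box=box, id=j))

    return Fixture(
        spec=spec,
        em_labels=LabelVolume(labels=em_labels, voxel_size=(em_nm,) * 3),
        em_intensity=Volume(data=em_int, voxel_size=(em_nm,) * 3,
                            channel_name="em"),
        fm_landmarks=fm_landmarks,
        fm_targets=fm_targets,
        truth_nm=truth_nm,
        truth_px=truth_px,
        landmark_pairs=pairs,
        target_truth=targets,
        target_labels=LabelVolume(labels=target_labels, voxel_size=(em_nm,) * 3),
    )


def _render_fm_channel(em_binary: np.ndarray, truth_nm: RigidTransform,
                       fm_shape, fm_voxel, em_nm: float, spec: FixtureSpec,
                       rng: np.random.Generator) -> Volume:
    """Project EM-space geometry into the FM frame, blur, attenuate, noise."""
    axes = [np.arange(n) * v for n, v in zip(fm_shape, fm_voxel)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    em_px_coords = truth_nm.apply(pts) / em_nm
    signal = ndimage.map_coordinates(
        em_binary.astype(np.float64), em_px_coords.T, order=1,
        mode="constant", cval=0.0,
    ).reshape(fm_shape)
    sigma_px = (np.asarray(spec.psf_fwhm_nm) * FWHM_TO_SIGMA) / fm_voxel
    signal = ndimage.gaussian_filter(signal, sigma_px)
    decay = np.exp(-spec.attenuation_per_slice * np.arange(fm_shape[0]))
    signal *= decay[:, None, None]
    if spec.poisson:
        signal = rng.poisson(np.maximum(signal, 0.0) * 200.0) / 200.0
    signal = signal + rng.normal(0.0, spec.noise_sigma, size=fm_shape)
    return Volume(data=np.clip(signal, 0.0, None),
                  voxel_size=tuple(fm_voxel), channel_name="fm")


def degrade_fixture(fx: Fixture, missing_fraction: float, mode: str = "random",
                    seed: int = 0) -> Fixture:
    """Ablate a fraction of EM landmark instances, leaving FM untouched."""
    new_labels = evalx.ablate_instances(fx.em_labels, missing_fraction,
                                        mode=mode, seed=seed)
    return Fixture(
        spec=fx.spec,
        em_labels=new_labels,
        em_intensity=fx.em_intensity,
        fm_landmarks=fx.fm_landmarks,
        fm_targets=fx.fm_targets,
        truth_nm=fx.truth_nm,
        truth_px=fx.truth_px,
        landmark_pairs=fx.landmark_pairs,
        target_truth=fx.target_truth,
        target_labels=fx.target_labels,
    )


def write_fixture(fx: Fixture, out_dir) -> None:
    """Persist a fixture as TIFFs plus truth/landmark sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(out / "em_labels.tif", fx.em_labels)
    write_stack(out / "em_intensity.tif", fx.em_intensity)
    write_stack(out / "fm_landmarks.tif", fx.fm_landmarks)
    write_stack(out / "fm_targets.tif", fx.fm_targets)
    write_stack(out / "target_labels.tif", fx.target_labels)
    write_transform(out / "truth_nm.json", fx.truth_nm)
    write_transform(out / "truth_px.json", fx.truth_px)
    write_point_cloud(out / "landmarks_moving_nm.csv", fx.landmark_pairs[0])
    write_point_cloud(out / "landmarks_fixed_nm.csv", fx.landmark_pairs[1])
    meta = asdict(fx.spec)
    meta["fm_shape"] = list(fx.fm_landmarks.shape)
    (out / "spec.json").write_text(json.dumps(meta, indent=2))
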