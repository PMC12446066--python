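"""Fluorescence-channel landmark segmentation.

Mitochondria in the fluorescence volume are segmented by a thresholded
Laplacian-of-Gaussian: the volume is min-max normalized, filtered with a
difference of Gaussians (sigma2/sigma1 = 1.6, the classic LoG approximation),
thresholded slice-by-slice with a dynamic threshold that tracks the per-slice
mean response (so that depth-dependent signal attenuation does not starve
deep slices), and finally cleaned with a component-size percentile filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_yen

from .volio import LabelVolume, STRUCT_26, Volume

__all__ = [
    "FMSegParams",
    "minmax_normalize",
    "dog_filter",
    "dynamic_threshold",
    "size_filter",
    "clip_overexposed",
    "otsu_segment",
    "segment_fm",
]

#: DoG scale ratio approximating the Laplacian of Gaussian (Marr-Hildreth)
LOG_RATIO = 1.6


@dataclass
class FMSegParams:
    """Parameters of the LoG segmentation.

    sigma : first Gaussian scale in pixels (match to blob radius)
    ratio : second-to-first scale ratio; 1.6 approximates the LoG
    threshold_T : relative dynamic threshold (response kept above
        T x mean positive response of its z-slice)
    size_low_pct / size_high_pct : component-size percentile band to keep
    """

    sigma: float = 3.0
    ratio: float = LOG_RATIO
    threshold_T: float = 1.2
    size_low_pct: float = 5.0
    size_high_pct: float = 95.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.ratio <= 1:
            raise ValueError("ratio must exceed 1")
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be >= 0")
        if not (0 < self.size_low_pct < self.size_high_pct <= 100):
            raise ValueError("require 0 < size_low_pct < size_high_pct <= 100")

    @property
    def sigma2(self) -> float:
        """Second DoG scale, ``ratio * sigma``."""
        return self.ratio * self.sigma


def minmax_normalize(v: Volume) -> Volume:
    """Rescale intensities to [0, 1]: x_scaled = (x - x_min) / (x_max - x_min)."""
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant volume")
    return Volume(data=(data - lo) / (hi - lo), voxel_size=v.voxel_size,
                  channel_name=v.channel_name)


def dog_filter(v: Volume, params: FMSegParams) -> Volume:
    """Difference of Gaussians G(sigma) - G(ratio*sigma), separably in z/y/x.

    Bright blobs of radius around ``sigma`` come out positive (narrow minus
    wide convention).  ``sigma`` is expressed in pixels of the finest axis;
    on anisotropic grids the per-axis kernel width is scaled by the voxel
    size so the filter has the same physical footprint along every axis
    (on isotropic volumes this reduces to a single scalar sigma).
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    data = np.asarray(v.data, dtype=np.float64)
    vs = np.asarray(v.voxel_size, dtype=float)
    per_axis = params.sigma * vs.min() / vs
    narrow = ndimage.gaussian_filter(data, per_axis)
    wide = ndimage.gaussian_filter(data, params.ratio * per_axis)
    return Volume(data=narrow - wide, voxel_size=v.voxel_size,
                  channel_name=v.channel_name)


def dynamic_threshold(response: Volume, T: float,
                      reference: Volume = None,
                      floor_frac: float = 0.0) -> LabelVolume:
    """Per-slice relative threshold on the DoG response.

    A voxel of slice z is kept iff its response exceeds ``T`` times that
    slice's statistic, so the cut tracks the per-slice signal level and
    compensates depth-dependent attenuation.  The statistic is the mean
    intensity of the slice of ``reference`` -- normally the min-max
    normalized input volume, whose per-slice mean dims together with the
    signal as imaging depth increases.  When no reference is supplied the
    statistic falls back to the mean of the positive part of the response
    slice itself (the response is signed and near zero-mean, so its raw mean
    would make a relative factor of ~1.2 meaningless).

    ``floor_frac`` optionally floors the slice statistic at that fraction of
    the same statistic taken over the whole volume, guarding signal-free
    slices against keeping a fixed quantile of their own noise.  Slices
    whose statistic is not positive produce empty masks.
    """
    data = np.asarray(response.data, dtype=np.float64)
    if reference is not None:
        if reference.shape != response.shape:
            raise ValueError("reference volume must match the response shape")
        stat_src = np.asarray(reference.data, dtype=np.float64)
    else:
        stat_src = data
    mask = np.zeros(data.shape, dtype=bool)
    global_stat = float(np.maximum(stat_src, 0.0).mean())
    for z in range(data.shape[0]):
        stat = float(np.maximum(stat_src[z], 0.0).mean())
        stat = max(stat, floor_frac * global_stat)
        if stat <= 0:
            continue
        mask[z] = data[z] > T * stat
    return LabelVolume(labels=mask.astype(np.int32), voxel_size=response.voxel_size)


def size_filter(mask: LabelVolume, low_pct: float = 5.0, high_pct: float = 95.0) -> LabelVolume:
    """Label 26-connected components and keep sizes inside [P_low, P_high].

    Percentiles are linear-interpolated over the component-size distribution;
    components exactly on a percentile boundary are retained.
    """
    binary = mask.binary()
    labels, n = ndimage.label(binary, structure=STRUCT_26)
    if n == 0:
        return LabelVolume(labels=np.zeros(mask.shape, dtype=np.int32),
                           voxel_size=mask.voxel_size)
    sizes = np.bincount(labels.ravel())[1:]
    lo = np.percentile(sizes, low_pct)
    hi = np.percentile(sizes, high_pct)
    keep = np.flatnonzero((sizes >= lo) & (sizes <= hi)) + 1
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelVolume(labels=lut[labels], voxel_size=mask.voxel_size)


def clip_overexposed(v: Volume) -> Volume:
    """Clip overexposed punctate artifacts at the global Yen threshold."""
    data = np.asarray(v.data, dtype=np.float64)
    if data.max() == data.min():
        return Volume(data=data.copy(), voxel_size=v.voxel_size,
                      channel_name=v.channel_name)
    t = float(threshold_yen(data))
    return Volume(data=np.minimum(data, t), voxel_size=v.voxel_size,
                  channel_name=v.channel_name)


def otsu_segment(v: Volume, roi=None) -> LabelVolume:
    """Binary Otsu segmentation, optionally restricted to a (z,y,x) slice ROI.

    ``roi`` is a tuple of three ``slice`` objects (or None for the full
    volume).  Constant input yields an empty mask.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if roi is None:
        roi = (slice(None), slice(None), slice(None))
    sub = data[tuple(roi)]
    if sub.size == 0:
        raise ValueError("degenerate ROI (empty)")
    out = np.zeros(data.shape, dtype=np.int32)
    if sub.max() > sub.min():
        t = float(threshold_otsu(sub))
        out[tuple(roi)] = (sub > t).astype(np.int32)
    return LabelVolume(labels=out, voxel_size=v.voxel_size)


def segment_fm(v: Volume, params: FMSegParams = None) -> LabelVolume:
    """Full LoG landmark segmentation: normalize -> DoG -> dynamic threshold
    -> size filter.  Returns an instance label volume."""
    if params is None:
        params = FMSegParams()
    norm = minmax_normalize(v)
    response = dog_filter(norm, params)
    binary = dynamic_threshold(response, params.threshold_T, reference=norm)
    return size_filter(binary, params.size_low_pct, params.size_high_pct)
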