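"""Normalization, scaling, slab selection and 2.5D sample assembly.

The delayed volume is intensity-normalized to SUVR against the occipital
reference VOI, capped at SUVR 10 and mapped linearly to [-1, 1]; early frames
are min-max scaled to [-1, 1] (by default jointly over all five frames of a
subject, preserving inter-frame kinetic contrast).  Each frame is expanded
into three resolution channels (original, 4 mm and 8 mm FWHM smoothed), and
training samples condition on five consecutive axial slices of all channels
to predict the central delayed slice: 5 slices x 5 frames x 3 scales = 75
input channels under the defaults.

Axial index 0 is the most superior slice throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import FWHM_TO_SIGMA, DualPhaseStudy

SUVR_CAP = 10.0
MULTISCALE_FWHM_MM = (0.0, 4.0, 8.0)

#: slab for the 96 mm-tall default phantom grid: 45 slices - 3 - 2 = 40,
#: tolerant of the vertex landing a few slices below the top of the grid
PHANTOM_SLAB_FOV_MM = 90.0


@dataclass(frozen=True)
class NormalizationParams:
    suvr_cap: float = SUVR_CAP
    early_scope: str = "per-subject"  # or "per-frame"

    def __post_init__(self):
        if self.early_scope not in ("per-subject", "per-frame"):
            raise ValueError(f"unknown early_scope {self.early_scope!r}")


@dataclass(frozen=True)
class SlabSpec:
    fov_mm: float = 150.0
    drop_top: int = 3
    drop_bottom: int = 2
    #: vertex = topmost slice whose max exceeds this fraction of the volume max
    vertex_threshold: float = 0.05


@dataclass
class TrainingSample:
    input_stack: np.ndarray   # (C, H, W) in [-1, 1]
    target_slice: np.ndarray  # (H, W) in [-1, 1]
    slice_index: int          # axial index of the central slice within the slab


# ----------------------------------------------------------------------------
# Slab selection
# ----------------------------------------------------------------------------

def slab_range(volume: np.ndarray, voxel_mm: float,
               slab: SlabSpec = SlabSpec()) -> slice:
    """Axial slice range of the analysis slab.

    The field of view extends ``fov_mm`` downward from the skull vertex (the
    topmost slice with above-threshold signal); the top ``drop_top`` and
    bottom ``drop_bottom`` slices of that FOV are discarded as carrying
    minimal anatomy.
    """
    n_fov = int(np.floor(slab.fov_mm / voxel_mm))
    thr = slab.vertex_threshold * float(volume.max())
    above = np.flatnonzero(volume.reshape(volume.shape[0], -1).max(axis=1) > thr)
    if above.size == 0:
        raise ValueError("volume contains no above-threshold signal")
    vertex = int(above[0])
    available = volume.shape[0] - vertex
    if available < n_fov:
        raise ValueError(
            f"axial extent insufficient: slab needs {n_fov} slices below the "
            f"vertex but only {available} are available")
    start = vertex + slab.drop_top
    stop = vertex + n_fov - slab.drop_bottom
    if stop - start < 5:
        raise ValueError("slab too thin: fewer than 5 slices remain")
    return slice(start, stop)


def select_slab(volume: np.ndarray, voxel_mm: float,
                slab: SlabSpec = SlabSpec()) -> np.ndarray:
    """Extract the slab sub-volume (see :func:`slab_range`)."""
    return volume[slab_range(volume, voxel_mm, slab)]


# ----------------------------------------------------------------------------
# Intensity normalization and [-1, 1] scaling
# ----------------------------------------------------------------------------

def normalize_suvr(delayed: np.ndarray, occipital_mask: np.ndarray) -> np.ndarray:
    """Divide the delayed volume by its occipital-VOI mean (SUVR image)."""
    if occipital_mask.shape != delayed.shape:
        raise ValueError("mask shape does not match volume shape")
    if not occipital_mask.any():
        raise ValueError("occipital mask is empty")
    ref = float(delayed[occipital_mask].mean())
    if ref <= 0:
        raise ValueError(f"occipital reference mean must be positive, got {ref}")
    return (delayed / ref).astype(np.float32)


def scale_delayed(suvr: np.ndarray,
                  params: NormalizationParams = NormalizationParams()) -> np.ndarray:
    """Map SUVR in [0, cap] linearly onto [-1, 1], clipping above the cap."""
    cap = params.suvr_cap
    return (np.clip(suvr, 0.0, cap) * (2.0 / cap) - 1.0).astype(np.float32)


def inverse_scale_delayed(scaled: np.ndarray,
                          params: NormalizationParams = NormalizationParams()) -> np.ndarray:
    """Inverse of :func:`scale_delayed` on [-1, 1] -> [0, cap]."""
    cap = params.suvr_cap
    return ((np.asarray(scaled) + 1.0) * (cap / 2.0)).astype(np.float32)


def scale_early(frames: list[np.ndarray],
                params: NormalizationParams = NormalizationParams()
                ) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Min-max scale early frames to [-1, 1].

    Under the default per-subject scope a single (min, max) over all five
    frames is used, so inter-frame kinetic contrast survives scaling; the
    per-frame scope normalizes each frame independently.  Returns the scaled
    frames and the (min, max) pair(s) used, for exact inversion at inference.
    """
    if params.early_scope == "per-subject":
        lo = min(float(f.min()) for f in frames)
        hi = max(float(f.max()) for f in frames)
        if hi <= lo:
            raise ValueError("early frames are constant over the scaling scope")
        scaled = [((f - lo) * (2.0 / (hi - lo)) - 1.0).astype(np.float32)
                  for f in frames]
        return scaled, [(lo, hi)] * len(frames)
    scaled, ranges = [], []
    for f in frames:
        lo, hi = float(f.min()), float(f.max())
        if hi <= lo:
            raise ValueError("early frame is constant over the scaling scope")
        scaled.append(((f - lo) * (2.0 / (hi - lo)) - 1.0).astype(np.float32))
        ranges.append((lo, hi))
    return scaled, ranges


def multiscale_stack(image: np.ndarray, voxel_mm: float,
                     fwhms_mm: tuple[float, ...] = MULTISCALE_FWHM_MM) -> np.ndarray:
    """Stack the image with Gaussian-smoothed copies (default 4 and 8 mm FWHM).

    Works on 2D slices or 3D volumes; channel 0 is always the unmodified
    input.  Smoothing uses nearest-edge extension so values stay within the
    input's range (each output voxel is a convex combination of inputs).
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    channels = []
    for fwhm in fwhms_mm:
        if fwhm <= 0:
            channels.append(np.asarray(image, dtype=np.float32))
        else:
            sigma = fwhm * FWHM_TO_SIGMA / voxel_mm
            channels.append(gaussian_filter(np.asarray(image, dtype=np.float32),
                                            sigma, mode="nearest"))
    return np.stack(channels, axis=0)


# ----------------------------------------------------------------------------
# 2.5D sample assembly
# ----------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    norm: NormalizationParams = field(default_factory=NormalizationParams)
    slab: SlabSpec = field(default_factory=SlabSpec)
    n_slices: int = 5
    fwhms_mm: tuple[float, ...] = MULTISCALE_FWHM_MM
    #: if True, sum the five 2-min frames into one 10-min early image
    sum_frames: bool = False

    @property
    def n_scales(self) -> int:
        return len(self.fwhms_mm)

    @classmethod
    def for_phantom(cls, **kwargs) -> "PreprocessConfig":
        """Defaults with the slab FOV sized for the default phantom grid."""
        kwargs.setdefault("slab", SlabSpec(fov_mm=PHANTOM_SLAB_FOV_MM))
        return cls(**kwargs)


@dataclass
class PreparedStudy:
    """Slab-cropped, scaled, multi-scale channel volumes for one subject.

    ``early_channels`` has shape (n_frames * n_scales, nz, H, W) ordered
    frame-major (frame, scale); ``delayed_scaled`` is (nz, H, W) in [-1, 1].
    """
    early_channels: np.ndarray
    delayed_scaled: np.ndarray | None
    slab: slice
    scale_ranges: list[tuple[float, float]]
    voxel_mm: float


def prepare_study(study: DualPhaseStudy,
                  cfg: PreprocessConfig = PreprocessConfig()) -> PreparedStudy:
    """Run the full preprocessing chain for one subject.

    Slab placement is computed on the delayed volume and applied identically
    to every frame (phantom volumes share the grid).
    """
    voxel = study.atlas.voxel_mm
    sl = slab_range(study.delayed, voxel, cfg.slab)
    occ = study.atlas.mask("occipital")
    suvr = normalize_suvr(study.delayed, occ)
    delayed_scaled = scale_delayed(suvr[sl], cfg.norm)

    frames = study.early_frames
    if cfg.sum_frames:
        frames = [np.sum(frames, axis=0)]
    scaled, ranges = scale_early([f[sl] for f in frames], cfg.norm)
    chans = [multiscale_stack(f, voxel, cfg.fwhms_mm) for f in scaled]
    early_channels = np.concatenate(chans, axis=0).astype(np.float32)
    return PreparedStudy(early_channels=early_channels,
                         delayed_scaled=delayed_scaled, slab=sl,
                         scale_ranges=ranges, voxel_mm=voxel)


def stack_for_slice(prepared: PreparedStudy, z: int, n_slices: int = 5,
                    pad: bool = False) -> np.ndarray:
    """Assemble the (C, H, W) conditioning stack centred on slab slice ``z``.

    Channel order is slice-major: for each of the ``n_slices`` consecutive
    slices (superior to inferior), all frame x scale channels of that slice.
    With ``pad`` the slice axis is replicate-extended by half the stack on
    each end (used at inference); training uses only valid unpadded stacks.
    """
    half = n_slices // 2
    nz = prepared.early_channels.shape[1]
    idx = np.arange(z - half, z + half + 1)
    if pad:
        idx = np.clip(idx, 0, nz - 1)
    elif idx[0] < 0 or idx[-1] >= nz:
        raise IndexError(f"slice {z} has no valid unpadded {n_slices}-stack")
    planes = [prepared.early_channels[:, i] for i in idx]  # each (F*S, H, W)
    return np.concatenate(planes, axis=0)


def make_training_samples(study: DualPhaseStudy,
                          cfg: PreprocessConfig = PreprocessConfig()
                          ) -> list[TrainingSample]:
    """One sample per valid central slice: a slab of n slices yields n - 4."""
    prepared = prepare_study(study, cfg)
    nz = prepared.early_channels.shape[1]
    if nz < cfg.n_slices:
        raise ValueError(f"slab has {nz} slices, need >= {cfg.n_slices}")
    half = cfg.n_slices // 2
    samples = []
    for z in range(half, nz - half):
        samples.append(TrainingSample(
            input_stack=stack_for_slice(prepared, z, cfg.n_slices),
            target_slice=prepared.delayed_scaled[z],
            slice_index=z))
    return samples
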