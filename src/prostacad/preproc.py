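"""Volume preprocessing: intensity normalization, resampling, crop/pad.

Every study is normalized, resampled to a fixed voxel spacing of
0.75 × 0.75 × 3 mm and cropped/padded to a fixed 149 × 149 × 32 grid, in
that order. Normalization is a per-volume z-score over the nonzero
(foreground) voxels: background stays at zero, the foreground has mean ≈ 0
and SD ≈ 1 afterwards, which makes the operation idempotent up to float
tolerance and leaves downstream gray-level quantization shift/scale free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from prostacad.volume import MODALITIES, MRIVolume, StudyCase

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    target_spacing_mm: tuple[float, float, float] = (0.75, 0.75, 3.0)
    target_shape: tuple[int, int, int] = (149, 149, 32)
    # the study chain normalizes over the nonzero foreground so that the
    # zero-padding added by crop_pad does not shift the statistics on
    # re-application (the chain is a fixed point)
    normalization: str = "zscore_fg"
    image_interpolation: str = "linear"
    mask_interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.target_shape):
            raise ValueError("target_shape must be positive integers")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target_spacing_mm must be positive")


def normalize(vol: MRIVolume, method: str = "zscore") -> MRIVolume:
    """Per-volume z-score normalization.

    ``zscore`` standardizes over all voxels (mean 0, SD 1 afterwards; exactly
    idempotent). ``zscore_fg`` standardizes over the nonzero foreground only,
    leaving background voxels at zero — useful when a volume is dominated by
    empty background. A constant input (zero SD) yields an all-zero volume
    and logs a warning rather than raising.
    """
    if method not in ("zscore", "zscore_fg"):
        raise ValueError(f"unknown normalization method: {method}")
    data = np.asarray(vol.data, dtype=np.float64)
    fg = (data != 0) if method == "zscore_fg" else np.ones(data.shape, dtype=bool)
    out = np.zeros_like(data)
    if not fg.any():
        logger.warning("normalize: volume is all zeros; returning zeros")
        return vol.with_data(out)
    vals = data[fg]
    sd = vals.std()
    if sd == 0:
        logger.warning("normalize: constant volume; returning zeros")
        return vol.with_data(out)
    out[fg] = (vals - vals.mean()) / sd
    return vol.with_data(out)


def _resample_array(data: np.ndarray, spacing, target_spacing, order: int) -> np.ndarray:
    """Resample onto a grid with the target spacing, origin-aligned.

    Output voxel i along an axis samples input coordinate
    ``i * target_spacing / spacing`` (voxel units); linear interpolation for
    images (order=1), nearest-neighbour for masks (order=0). Edge handling
    clamps to the nearest input voxel.
    """
    factors = [t / s for s, t in zip(spacing, target_spacing)]
    new_shape = [max(1, int(round(n / f))) for n, f in zip(data.shape, factors)]
    axes = [np.arange(m) * f for m, f in zip(new_shape, factors)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = map_coordinates(data.astype(np.float64), coords, order=order, mode="nearest")
    return out.reshape(new_shape)


def resample(vol: MRIVolume, target_spacing_mm) -> MRIVolume:
    """Resample an image volume to the target spacing (linear interpolation)."""
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if np.allclose(vol.spacing_mm, target):
        return vol
    out = _resample_array(vol.data, vol.spacing_mm, target, order=1)
    return vol.with_data(out, spacing_mm=target)


def resample_mask(mask: np.ndarray, spacing_mm, target_spacing_mm) -> np.ndarray:
    """Resample a binary mask (nearest-neighbour; stays binary)."""
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if np.allclose(spacing_mm, target):
        return mask
    out = _resample_array(mask.astype(np.float64), spacing_mm, target, order=0)
    return (out > 0.5).astype(np.uint8)


def _crop_pad_array(data: np.ndarray, target_shape) -> np.ndarray:
    """Center-crop and/or symmetrically zero-pad to the target shape."""
    out = data
    for ax, t in enumerate(target_shape):
        n = out.shape[ax]
        if n > t:
            start = (n - t) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + t)
            out = out[tuple(sl)]
        elif n < t:
            before = (t - n) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, t - n - before)
            out = np.pad(out, pad, mode="constant")
    return out


def crop_pad(vol: MRIVolume, target_shape) -> MRIVolume:
    """Crop/pad a volume to exactly target_shape, centred on the grid centre."""
    target = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target):
        raise ValueError("target_shape must be positive")
    if vol.shape == target:
        return vol
    return vol.with_data(_crop_pad_array(vol.data, target))


def crop_pad_mask(mask: np.ndarray, target_shape) -> np.ndarray:
    return _crop_pad_array(mask, tuple(int(t) for t in target_shape)).astype(np.uint8)


def preprocess_study(case: StudyCase, cfg: PreprocConfig | None = None) -> StudyCase:
    """Normalize → resample → crop/pad every sequence and mask of a case.

    Masks are resampled nearest-neighbour and cropped/padded with the same
    offsets as the images (offsets are a deterministic function of the grid
    shapes, which all sequences and masks share). Labels are untouched.
    """
    cfg = cfg or PreprocConfig()
    seqs = {"T2W": case.t2w, "ADC": case.adc, "DWI": case.dwi}
    for mod in MODALITIES:
        if seqs[mod] is None:
            raise ValueError(f"missing sequence: {mod}")
    proc = {}
    for mod, vol in seqs.items():
        v = normalize(vol, cfg.normalization)
        v = resample(v, cfg.target_spacing_mm)
        v = crop_pad(v, cfg.target_shape)
        proc[mod] = v

    def _proc_mask(m):
        if m is None:
            return None
        m2 = resample_mask(m, case.spacing_mm, cfg.target_spacing_mm)
        return crop_pad_mask(m2, cfg.target_shape)

    return replace(
        case,
        t2w=proc["T2W"], adc=proc["ADC"], dwi=proc["DWI"],
        gland_mask=_proc_mask(case.gland_mask),
        pz_mask=_proc_mask(case.pz_mask),
        lesion_masks=[(_proc_mask(m), lab) for m, lab in case.lesion_masks],
    )
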