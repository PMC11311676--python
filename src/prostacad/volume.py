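"""Core containers: a single MR volume and a multiparametric study case.

Conventions used throughout the package: arrays are indexed ``[x, y, z]``
with 0-based voxel indices; boxes are half-open intervals ``[lo, hi)``;
spacing is in millimetres per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

MODALITIES = ("T2W", "ADC", "DWI")

BENIGN, MALIGNANT = 0, 1


@dataclass
class MRIVolume:
    """A single 3D image with voxel spacing and a modality tag.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, finite.
    spacing_mm : tuple of float
        Voxel edge length per axis in millimetres; strictly positive.
    modality : str
        One of ``T2W``, ``ADC``, ``DWI`` (or a free tag for masks/derived maps).
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "T2W"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray, spacing_mm=None) -> "MRIVolume":
        return replace(self, data=data,
                       spacing_mm=self.spacing_mm if spacing_mm is None else spacing_mm)


@dataclass
class StudyCase:
    """One patient case: three co-registered sequences, optional masks, label.

    ``lesion_masks`` is a list of ``(mask, lesion_label)`` pairs where the
    label is 0 (clinically insignificant / benign) or 1 (clinically
    significant / malignant, Gleason > 3+3=6 in the labelling convention this
    emulates). The case label is 1 iff at least one lesion is malignant.
    """

    case_id: str
    t2w: MRIVolume
    adc: MRIVolume
    dwi: MRIVolume
    case_label: int
    gland_mask: Optional[np.ndarray] = None
    pz_mask: Optional[np.ndarray] = None
    lesion_masks: list[tuple[np.ndarray, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {self.t2w.shape, self.adc.shape, self.dwi.shape}
        for m in self._all_masks():
            shapes.add(tuple(m.shape))
        if len(shapes) != 1:
            raise ValueError(f"volumes/masks do not share one grid: {shapes}")
        if self.case_label not in (0, 1):
            raise ValueError("case_label must be 0 or 1")

    def _all_masks(self) -> list[np.ndarray]:
        out = []
        if self.gland_mask is not None:
            out.append(self.gland_mask)
        if self.pz_mask is not None:
            out.append(self.pz_mask)
        out.extend(m for m, _ in self.lesion_masks)
        return out

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2w.shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.t2w.spacing_mm

    def sequences(self) -> dict[str, MRIVolume]:
        """Sequences in canonical order (T2W, ADC, DWI)."""
        return {"T2W": self.t2w, "ADC": self.adc, "DWI": self.dwi}

    def validate_nesting(self) -> None:
        """Assert PZ ⊂ gland and every lesion ⊂ gland; raise otherwise."""
        if self.gland_mask is None:
            return
        g = self.gland_mask.astype(bool)
        if self.pz_mask is not None and np.any(self.pz_mask.astype(bool) & ~g):
            raise ValueError("pz_mask not contained in gland_mask")
        for i, (m, _) in enumerate(self.lesion_masks):
            if np.any(m.astype(bool) & ~g):
                raise ValueError(f"lesion mask {i} not contained in gland_mask")

    def label_consistent(self) -> bool:
        expected = int(any(lab == MALIGNANT for _, lab in self.lesion_masks))
        return self.case_label == expected


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: MRIVolume, path: str | Path) -> None:
    """Write a volume to NIfTI (.nii or .nii.gz), spacing in the affine."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing_mm, vol.origin))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          _affine(spacing_mm, (0.0, 0.0, 0.0)))
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: str = "T2W") -> MRIVolume:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return MRIVolume(data=data, spacing_mm=spacing, modality=modality, origin=origin)


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
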