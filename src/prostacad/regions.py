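"""Regional classifier inputs: whole image, gland box, PZ box (ADC only), lesions.

Each anatomical setting crops a bounding box around the relevant mask
(expanded by a small margin to capture peritumoral texture) and resamples
the sub-volume to a fixed per-kind shape so that texture features have
consistent spatial support across cases. The peripheral-zone setting uses
only the ADC sequence, where PZ tumours are most conspicuous; all other
settings use all three sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import zoom

from prostacad.volume import MRIVolume, StudyCase

REGION_KINDS = ("whole", "gland", "pz", "lesion", "window")

# Fixed feature-support shapes per region kind, sized once from the default
# phantom geometry (roughly the 95th-percentile box of each kind).
DEFAULT_REGION_SHAPES: dict[str, tuple[int, int, int]] = {
    "whole": (149, 149, 32),
    "gland": (96, 96, 18),
    "pz": (96, 56, 18),
    "lesion": (28, 28, 8),
    "window": (70, 65, 3),
}

DEFAULT_MARGIN = (2, 2, 0)  # voxels in-plane, none across slices


@dataclass
class RegionBox:
    """A half-open axis-aligned voxel box [lo, hi) with a region kind."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    kind: str = "whole"
    source_mask_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box: lo={self.lo}, hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def volume(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains(self, other: "RegionBox") -> bool:
        return all(sl <= ol and oh <= sh
                   for sl, sh, ol, oh in zip(self.lo, self.hi, other.lo, other.hi))


def bounding_box(mask: np.ndarray, margin_voxels=0, kind: str = "gland",
                 source_mask_id: Optional[str] = None) -> RegionBox:
    """Tightest box containing all mask voxels, expanded by margin, clamped."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("bounding_box of an empty mask")
    if np.isscalar(margin_voxels):
        margin = (int(margin_voxels),) * 3
    else:
        margin = tuple(int(m) for m in margin_voxels)
    idx = np.nonzero(mask)
    lo = [max(0, int(a.min()) - m) for a, m in zip(idx, margin)]
    hi = [min(n, int(a.max()) + 1 + m) for a, m, n in zip(idx, margin, mask.shape)]
    return RegionBox(lo=tuple(lo), hi=tuple(hi), kind=kind, source_mask_id=source_mask_id)


def extract_box(data: np.ndarray, box: RegionBox) -> np.ndarray:
    """Raw sub-array of a box (no resizing)."""
    return data[box.slices()]


def resize_to(data: np.ndarray, target_shape, order: int = 1) -> np.ndarray:
    """Resample an array to an exact target shape (linear by default)."""
    target = tuple(int(t) for t in target_shape)
    if tuple(data.shape) == target:
        return np.asarray(data, dtype=np.float64)
    factors = [t / n for t, n in zip(target, data.shape)]
    out = zoom(np.asarray(data, dtype=np.float64), factors, order=order,
               mode="nearest", grid_mode=True)
    # zoom with grid_mode can be off by one on extreme ratios; enforce shape
    if out.shape != target:
        pad = [(0, max(0, t - s)) for t, s in zip(target, out.shape)]
        out = np.pad(out, pad, mode="edge")[tuple(slice(0, t) for t in target)]
    return out


@dataclass
class RegionInput:
    """One classifier input: fixed-shape sub-volumes per sequence plus label."""

    case_id: str
    kind: str
    volumes: dict[str, MRIVolume]
    label: int
    box: RegionBox


def _subvolume(vol: MRIVolume, box: RegionBox, shape) -> MRIVolume:
    sub = resize_to(extract_box(vol.data, box), shape)
    return MRIVolume(data=sub, spacing_mm=vol.spacing_mm, modality=vol.modality)


def extract_region_inputs(case: StudyCase, region_kind: str,
                          region_shapes: Optional[dict] = None,
                          margin_voxels=DEFAULT_MARGIN) -> list[RegionInput]:
    """Classifier inputs for one case under a regional setting.

    whole  -> one input, full grid, all three sequences, case label;
    gland  -> one input, gland box, all three sequences, case label;
    pz     -> one input, PZ box, ADC only, case label;
    lesion -> one input per lesion with that lesion's own label (an empty
              list for a case without lesions — a valid benign case).
    """
    shapes = dict(DEFAULT_REGION_SHAPES)
    if region_shapes:
        shapes.update(region_shapes)
    if region_kind not in ("whole", "gland", "pz", "lesion"):
        raise ValueError(f"unknown region kind {region_kind!r}")
    seqs = case.sequences()

    if region_kind == "whole":
        box = RegionBox(lo=(0, 0, 0), hi=case.shape, kind="whole")
        vols = {m: _subvolume(v, box, shapes["whole"]) for m, v in seqs.items()}
        return [RegionInput(case.case_id, "whole", vols, case.case_label, box)]

    if region_kind == "gland":
        if case.gland_mask is None or not case.gland_mask.any():
            raise ValueError(f"case {case.case_id}: gland mask required for gland region")
        box = bounding_box(case.gland_mask, margin_voxels, kind="gland")
        vols = {m: _subvolume(v, box, shapes["gland"]) for m, v in seqs.items()}
        return [RegionInput(case.case_id, "gland", vols, case.case_label, box)]

    if region_kind == "pz":
        if case.pz_mask is None or not case.pz_mask.any():
            raise ValueError(f"case {case.case_id}: PZ mask required for pz region")
        box = bounding_box(case.pz_mask, margin_voxels, kind="pz")
        vols = {"ADC": _subvolume(seqs["ADC"], box, shapes["pz"])}
        return [RegionInput(case.case_id, "pz", vols, case.case_label, box)]

    # lesion kind: one entry per lesion, per-lesion label
    out = []
    for i, (mask, lab) in enumerate(case.lesion_masks):
        if not mask.any():
            continue
        box = bounding_box(mask, margin_voxels, kind="lesion", source_mask_id=f"lesion_{i}")
        vols = {m: _subvolume(v, box, shapes["lesion"]) for m, v in seqs.items()}
        out.append(RegionInput(case.case_id, "lesion", vols, int(lab), box))
    return out


def boxes_to_tsv(rows: list[tuple[str, RegionBox, int]], path: str | Path) -> None:
    """Audit table of boxes: case_id, kind, lo/hi per axis, label (TSV)."""
    with open(path, "w") as f:
        f.write("case_id\tkind\tlo_x\tlo_y\tlo_z\thi_x\thi_y\thi_z\tlabel\n")
        for case_id, box, label in rows:
            f.write("\t".join(map(str, [case_id, box.kind, *box.lo, *box.hi, label])) + "\n")
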