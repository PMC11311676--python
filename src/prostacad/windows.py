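"""Sliding-window classification machinery.

A 70 × 65 × 3 voxel window is moved across the grid with 50% overlap
(stride = floor(dim / 2) per axis, plus one final clamped window per axis so
every voxel is covered). Windows are labelled by their overlap with lesions:
if the window/lesion overlap ratio — |window ∩ lesion| / |lesion| — exceeds
0.5, the window takes that lesion's label (malignant wins across lesions),
otherwise it is background. Per-window malignancy confidences are
accumulated into a voxel-wise heatmap (mean over covering windows), the
heatmap is thresholded at a cutoff chosen on validation data from the ROC
curve (Youden's J), and the image-level label is malignant iff any voxel
(optionally: any sufficiently large connected component, optionally within
the gland) exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from prostacad.regions import RegionBox

DEFAULT_WINDOW_SHAPE = (70, 65, 3)
DEFAULT_OVERLAP = 0.5

BACKGROUND, BENIGN_WIN, MALIGNANT_WIN = "background", "benign", "malignant"


@dataclass
class WindowGrid:
    grid_shape: tuple[int, int, int]
    window_shape: tuple[int, int, int]
    overlap_fraction: float
    boxes: list[RegionBox]

    def __len__(self) -> int:
        return len(self.boxes)


def _axis_origins(n: int, w: int, overlap: float) -> list[int]:
    stride = int(np.floor(w * (1.0 - overlap)))
    last = n - w
    if stride <= 0:
        origins = [0]
    else:
        origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)   # final clamped window guarantees coverage
    return origins


def make_windows(grid_shape, window_shape=DEFAULT_WINDOW_SHAPE,
                 overlap: float = DEFAULT_OVERLAP) -> WindowGrid:
    """Regular overlapping window placement covering the whole grid.

    Ordering is deterministic: z varies slowest, then y, then x.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    window_shape = tuple(int(w) for w in window_shape)
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    for n, w in zip(grid_shape, window_shape):
        if w > n:
            raise ValueError(f"window {window_shape} larger than grid {grid_shape}")
    ox = _axis_origins(grid_shape[0], window_shape[0], overlap)
    oy = _axis_origins(grid_shape[1], window_shape[1], overlap)
    oz = _axis_origins(grid_shape[2], window_shape[2], overlap)
    boxes = [
        RegionBox(lo=(x, y, z),
                  hi=(x + window_shape[0], y + window_shape[1], z + window_shape[2]),
                  kind="window")
        for z in oz for y in oy for x in ox
    ]
    return WindowGrid(grid_shape=grid_shape, window_shape=window_shape,
                      overlap_fraction=overlap, boxes=boxes)


def label_window(box: RegionBox, lesion_masks: Sequence[tuple[np.ndarray, int]],
                 ratio_threshold: float = 0.5, denominator: str = "lesion") -> str:
    """Three-way window label from lesion overlap.

    ratio = |window ∩ lesion| / |lesion| (default) or / |window|. The label
    is taken only when the ratio strictly exceeds the threshold; malignant
    wins when several lesions qualify.
    """
    hit_labels = []
    for mask, lab in lesion_masks:
        lesion_vol = int(np.count_nonzero(mask))
        if lesion_vol == 0:
            continue
        inter = int(np.count_nonzero(mask[box.slices()]))
        denom = lesion_vol if denominator == "lesion" else box.volume()
        if inter / denom > ratio_threshold:
            hit_labels.append(lab)
    if not hit_labels:
        return BACKGROUND
    return MALIGNANT_WIN if 1 in hit_labels else BENIGN_WIN


@dataclass
class Heatmap:
    """Voxel-wise confidence in [0, 1] plus the window-coverage count grid."""

    confidence: np.ndarray
    coverage: np.ndarray


def build_heatmap(grid: WindowGrid, scores: Sequence[float],
                  accumulation: str = "mean") -> Heatmap:
    """Accumulate per-window confidences into a voxel-wise heatmap.

    Mean accumulation (default) averages the scores of all windows covering
    each voxel and is order-independent; "max" takes the maximum instead.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(grid.boxes):
        raise ValueError(f"{len(scores)} scores for {len(grid.boxes)} windows")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("window scores must lie in [0, 1]")
    acc = np.zeros(grid.grid_shape, dtype=np.float64)
    cov = np.zeros(grid.grid_shape, dtype=np.int64)
    if accumulation == "mean":
        for box, s in zip(grid.boxes, scores):
            acc[box.slices()] += s
            cov[box.slices()] += 1
        conf = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    elif accumulation == "max":
        for box, s in zip(grid.boxes, scores):
            np.maximum(acc[box.slices()], s, out=acc[box.slices()])
            cov[box.slices()] += 1
        conf = acc
    else:
        raise ValueError(f"unknown accumulation {accumulation!r}")
    if cov.min() < 1:
        raise AssertionError("window grid does not cover every voxel")
    return Heatmap(confidence=conf, coverage=cov)


def choose_cutoff(val_scores: Sequence[float], val_labels: Sequence[int]
                  ) -> tuple[float, dict]:
    """ROC cutoff maximizing Youden's J on validation scores.

    Candidate cutoffs are the midpoints between adjacent distinct scores
    (plus outer boundaries); for perfectly separated classes this returns the
    midpoint of the separating gap. If the best achievable J is <= 0 the
    returned info dict flags the cutoff as degenerate.
    """
    scores = np.asarray(val_scores, dtype=np.float64)
    labels = np.asarray(val_labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels contain a single class")
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_c, best_j = candidates[0], -np.inf
    for c in candidates:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_c = j, c
    info = {"youden_j": float(best_j), "degenerate": bool(best_j <= 0)}
    return float(best_c), info


def image_label(heatmap: Heatmap, cutoff: float, min_area: Optional[int] = None,
                gland_mask: Optional[np.ndarray] = None) -> int:
    """Image-level label: 1 iff supra-cutoff confidence exists.

    Optional restrictions: a minimum connected-component size (in voxels),
    and a gland mask outside of which confidences are ignored (suppressing
    lesion-like findings outside the prostate).
    """
    conf = heatmap.confidence
    supra = conf > cutoff
    if gland_mask is not None:
        supra = supra & (np.asarray(gland_mask) > 0)
    if not supra.any():
        return 0
    if min_area is None:
        return 1
    labelled, n = ndimage.label(supra)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, index=range(1, n + 1))
    return int(np.any(sizes >= min_area))
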