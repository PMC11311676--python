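"""3D texture radiomics: Haralick/GLCM, local binary patterns, HOG.

One sequence yields exactly 297 features:

* 169 Haralick features — the 13 classic co-occurrence statistics computed
  separately on each of the 13 unique 3D offset directions at distance 1
  (no offset averaging),
* 64 LBP features — the normalized histogram of 6-neighbour (face-adjacent)
  3D local binary pattern codes (2^6 = 64 codes),
* 64 HOG features — 16 solid-angle orientation bins (an
  icosahedron-derived partition of the hemisphere, antipodal directions
  merged) in each of 4 spatial cells (2 × 2 × 1 grid).

A full T2W + ADC + DWI study therefore yields 3 × 297 = 891 features, in a
fixed canonical order with modality-prefixed names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from prostacad.volume import MODALITIES, MRIVolume

_EPS = 1e-12

# 13 unique 3D direction vectors at Chebyshev distance 1 (one per antipodal
# pair of the 26-neighbourhood), fixed lexicographic order.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in ((-1, 0, 1) if dx == 1 else (0, 1))
    for dz in ((-1, 0, 1) if (dx, dy) != (0, 0) else (1,))
)
assert len(OFFSETS_13) == 13

HARALICK_STATS = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
)

# 6 face neighbours in fixed order: bit k set iff that neighbour >= centre
LBP_NEIGHBORS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def _icosahedron_directions() -> np.ndarray:
    """16 unit directions: icosahedron vertices and face centres, one per
    antipodal pair (6 vertex + 10 face directions)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1.0, phi)]:
        verts += [(0, a, b), (0, a, -b), (0, -a, b), (0, -a, -b)]
        verts += [(a, b, 0), (a, -b, 0), (-a, b, 0), (-a, -b, 0)]
        verts += [(b, 0, a), (-b, 0, a), (b, 0, -a), (-b, 0, -a)]
    verts = np.array(verts, dtype=np.float64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    # face centres: triples of mutually nearest vertices
    from itertools import combinations
    d = verts @ verts.T
    # vertices are adjacent iff their dot product is ~1/sqrt(5) ≈ 0.447
    faces = []
    for i, j, k in combinations(range(12), 3):
        if d[i, j] > 0.4 and d[i, k] > 0.4 and d[j, k] > 0.4:
            c = verts[i] + verts[j] + verts[k]
            faces.append(c / np.linalg.norm(c))
    faces = np.array(faces)
    assert len(faces) == 20, f"expected 20 icosahedron faces, got {len(faces)}"

    def dedupe_antipodal(dirs):
        kept = []
        for v in dirs:
            if any(np.allclose(v, -u, atol=1e-9) for u in kept):
                continue
            kept.append(v)
        return np.array(kept)

    out = np.concatenate([dedupe_antipodal(verts), dedupe_antipodal(faces)])
    assert out.shape == (16, 3)
    return out


HOG_DIRECTIONS = _icosahedron_directions()


@dataclass
class FeatureConfig:
    """Texture feature configuration; defaults satisfy the 297 contract."""

    glcm_levels: int = 32
    glcm_offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13
    haralick_stats: tuple[str, ...] = HARALICK_STATS
    lbp_bins: int = 64
    hog_cells: tuple[int, int, int] = (2, 2, 1)
    hog_bins: int = 16

    def __post_init__(self) -> None:
        n = self.n_features()
        if n != 297:
            raise ValueError(
                f"configuration yields {n} features per sequence; the "
                "per-sequence contract is 297")

    def n_haralick(self) -> int:
        return len(self.haralick_stats) * len(self.glcm_offsets)

    def n_hog(self) -> int:
        return int(np.prod(self.hog_cells)) * self.hog_bins

    def n_features(self) -> int:
        return self.n_haralick() + self.lbp_bins + self.n_hog()

    def to_dict(self) -> dict:
        return {
            "glcm_levels": self.glcm_levels,
            "glcm_offsets": [list(o) for o in self.glcm_offsets],
            "haralick_stats": list(self.haralick_stats),
            "lbp_bins": self.lbp_bins,
            "hog_cells": list(self.hog_cells),
            "hog_bins": self.hog_bins,
        }


@dataclass
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrices, one per offset."""

    matrices: np.ndarray  # (n_offsets, L, L), each sums to 1
    levels: int
    offsets: tuple[tuple[int, int, int], ...]


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def quantize(data: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of intensities into ``levels`` gray levels.

    A constant volume maps to level 0 everywhere.
    """
    data = np.asarray(data, dtype=np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros(data.shape, dtype=np.intp)
    q = np.floor((data - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_3d(vol: MRIVolume | np.ndarray, cfg: FeatureConfig | None = None) -> GLCM:
    """Build symmetric normalized co-occurrence matrices for each 3D offset."""
    cfg = cfg or FeatureConfig()
    data = vol.data if isinstance(vol, MRIVolume) else np.asarray(vol)
    L = cfg.glcm_levels
    for off in cfg.glcm_offsets:
        for n, d in zip(data.shape, off):
            if abs(d) >= n:
                raise ValueError(f"volume shape {data.shape} smaller than offset reach {off}")
    q = quantize(data, L)
    mats = np.empty((len(cfg.glcm_offsets), L, L), dtype=np.float64)
    for k, (dx, dy, dz) in enumerate(cfg.glcm_offsets):
        def sl(d, n):
            if d >= 0:
                return slice(0, n - d), slice(d, n)
            return slice(-d, n), slice(0, n + d)
        (ax0, bx0), (ay0, by0), (az0, bz0) = (
            sl(dx, q.shape[0]), sl(dy, q.shape[1]), sl(dz, q.shape[2]))
        a = q[ax0, ay0, az0].ravel()
        b = q[bx0, by0, bz0].ravel()
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
        counts = counts + counts.T  # symmetrize
        total = counts.sum()
        mats[k] = counts / total if total > 0 else counts
    return GLCM(matrices=mats, levels=L, offsets=tuple(cfg.glcm_offsets))


def _haralick_one(p: np.ndarray) -> dict[str, float]:
    """The 13 classic Haralick statistics of one normalized GLCM (log base 2).

    Gray levels are indexed 0..L-1. When a marginal SD is zero the
    correlation and IMC statistics are undefined; they fall back to 0.
    """
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    def xlogx(v):
        v = np.asarray(v)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    energy = float((p ** 2).sum())
    contrast = float(((I - J) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((I * J * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((I - mu_x) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (I - J) ** 2)).sum())

    # sum / difference distributions
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (I + J).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    sum_average = float((k_sum * psum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    sum_entropy = float(-xlogx(psum).sum())

    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(I - J).astype(int).ravel(), p.ravel())
    k_d = np.arange(L, dtype=np.float64)
    mu_d = (k_d * pdiff).sum()
    difference_variance = float(((k_d - mu_d) ** 2 * pdiff).sum())
    difference_entropy = float(-xlogx(pdiff).sum())

    entropy = float(-xlogx(p).sum())
    # information measures of correlation
    pxy = np.outer(px, py)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    hxy2 = float(-xlogx(pxy).sum())
    hx = float(-xlogx(px).sum())
    hy = float(-xlogx(py).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "energy": energy, "contrast": contrast, "correlation": correlation,
        "variance": variance, "homogeneity": homogeneity,
        "sum_average": sum_average, "sum_variance": sum_variance,
        "sum_entropy": sum_entropy, "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1, "imc2": imc2,
    }


def haralick_features(glcm: GLCM, cfg: FeatureConfig | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """13 statistics per offset, fixed order: 169 values for 13 offsets."""
    cfg = cfg or FeatureConfig()
    values, names = [], []
    for k, off in enumerate(glcm.offsets):
        stats = _haralick_one(glcm.matrices[k])
        tag = f"off{off[0]}{off[1]}{off[2]}".replace("-", "m")
        for s in cfg.haralick_stats:
            values.append(stats[s])
            names.append(f"glcm_{s}_{tag}")
    return np.asarray(values), names


def lbp_3d(vol: MRIVolume | np.ndarray, cfg: FeatureConfig | None = None
           ) -> tuple[np.ndarray, list[str]]:
    """Normalized histogram of 6-neighbour 3D LBP codes over interior voxels.

    Bit k of the code is 1 iff neighbour k's intensity >= the centre's
    (ties encode as 1); a constant volume therefore puts all its mass in
    code 63 (all neighbours >= centre).
    """
    cfg = cfg or FeatureConfig()
    data = vol.data if isinstance(vol, MRIVolume) else np.asarray(vol)
    if any(n < 3 for n in data.shape):
        raise ValueError(f"volume shape {data.shape} too small for a radius-1 neighbourhood")
    center = data[1:-1, 1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.intp)
    for bit, (dx, dy, dz) in enumerate(LBP_NEIGHBORS):
        nb = data[1 + dx: data.shape[0] - 1 + dx,
                  1 + dy: data.shape[1] - 1 + dy,
                  1 + dz: data.shape[2] - 1 + dz]
        codes |= (nb >= center).astype(np.intp) << bit
    hist = np.bincount(codes.ravel(), minlength=cfg.lbp_bins).astype(np.float64)
    hist /= hist.sum()
    names = [f"lbp_code{c:02d}" for c in range(cfg.lbp_bins)]
    return hist, names


def hog_3d(vol: MRIVolume | np.ndarray, cfg: FeatureConfig | None = None,
           spacing_mm=None) -> tuple[np.ndarray, list[str]]:
    """3D histogram of oriented gradients.

    Central-difference gradients (spacing-aware when spacing is known) are
    binned into 16 merged-antipodal solid-angle bins, weighted by gradient
    magnitude, within each cell of a 2×2×1 spatial grid; each cell histogram
    is L2-normalized with an epsilon guard. A constant volume yields the
    all-zero descriptor.
    """
    cfg = cfg or FeatureConfig()
    if isinstance(vol, MRIVolume):
        data, spacing = vol.data, vol.spacing_mm
    else:
        data = np.asarray(vol, dtype=np.float64)
        spacing = spacing_mm or (1.0, 1.0, 1.0)
    if any(n < 2 for n in data.shape):
        raise ValueError("volume must have at least 2 voxels per axis")
    gx, gy, gz = np.gradient(data.astype(np.float64), *spacing)
    G = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)   # (N, 3)
    mag = np.sqrt((G * G).sum(axis=1)).reshape(data.shape)
    # antipodal directions are merged: bin by the largest |g . d_k|
    proj = np.abs(G @ HOG_DIRECTIONS.T)                          # (N, 16)
    bins = np.argmax(proj, axis=1).reshape(data.shape)

    cx, cy, cz = cfg.hog_cells
    edges = [np.linspace(0, n, c + 1).astype(int) for n, c in zip(data.shape, (cx, cy, cz))]
    values, names = [], []
    for ix in range(cx):
        for iy in range(cy):
            for iz in range(cz):
                sl = (slice(edges[0][ix], edges[0][ix + 1]),
                      slice(edges[1][iy], edges[1][iy + 1]),
                      slice(edges[2][iz], edges[2][iz + 1]))
                h = np.bincount(bins[sl].ravel(), weights=mag[sl].ravel(),
                                minlength=cfg.hog_bins).astype(np.float64)
                norm = np.sqrt((h ** 2).sum())
                if norm > _EPS:
                    h = h / norm
                else:
                    h = np.zeros_like(h)
                values.append(h)
                names.extend(f"hog_cell{ix}{iy}{iz}_bin{b:02d}" for b in range(cfg.hog_bins))
    return np.concatenate(values), names


def extract_sequence_features(vol: MRIVolume, cfg: FeatureConfig | None = None
                              ) -> FeatureVector:
    """297 texture features of one sequence: [Haralick 169, LBP 64, HOG 64]."""
    cfg = cfg or FeatureConfig()
    hv, hn = haralick_features(glcm_3d(vol, cfg), cfg)
    lv, ln = lbp_3d(vol, cfg)
    gv, gn = hog_3d(vol, cfg)
    prefix = vol.modality.lower()
    values = np.concatenate([hv, lv, gv])
    names = [f"{prefix}_{n}" for n in hn + ln + gn]
    fv = FeatureVector(values=values, names=names)
    assert len(fv) == 297
    return fv


def extract_study_features(volumes: dict[str, MRIVolume] | "object",
                           cfg: FeatureConfig | None = None) -> FeatureVector:
    """891 features of a full study: T2W, ADC, DWI concatenated canonically.

    Accepts either a StudyCase or a mapping modality → MRIVolume. The order
    of the mapping is irrelevant: output order is always T2W, ADC, DWI. A
    single-sequence mapping (e.g. peripheral-zone mode, ADC only) yields a
    297-feature vector.
    """
    cfg = cfg or FeatureConfig()
    if hasattr(volumes, "sequences"):
        volumes = volumes.sequences()
    mods = [m for m in MODALITIES if m in volumes]
    if len(volumes) != len(mods):
        unknown = set(volumes) - set(MODALITIES)
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    if len(mods) > 1 and len(mods) != 3:
        missing = [m for m in MODALITIES if m not in volumes]
        raise ValueError(f"missing sequence(s): {missing}")
    parts = [extract_sequence_features(volumes[m], cfg) for m in mods]
    return FeatureVector(
        values=np.concatenate([p.values for p in parts]),
        names=[n for p in parts for n in p.names],
    )


def feature_matrix(feature_vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors (identical name contracts) into a DataFrame."""
    if not feature_vectors:
        return pd.DataFrame()
    names = feature_vectors[0].names
    for fv in feature_vectors[1:]:
        if fv.names != names:
            raise ValueError("inconsistent feature name contracts")
    return pd.DataFrame(np.vstack([fv.values for fv in feature_vectors]), columns=names)
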