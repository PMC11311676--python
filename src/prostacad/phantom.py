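"""Synthetic multiparametric prostate MRI phantoms.

Generates study cases with three co-registered sequences (T2W, ADC, DWI),
nested anatomy masks (gland ⊃ peripheral zone, gland ⊃ lesions) and
class-dependent texture, standing in for clinical cohorts that cannot be
shared. Texture is modelled as Gaussian random fields with class-specific
mean, variance and correlation length, so that second-order statistics
(co-occurrence, local binary patterns, gradient histograms) — not mean
intensity alone — separate benign from malignant tissue.

Anatomy model: the gland is an axis-aligned ellipsoid; the peripheral zone
is the posterior shell of the gland (a crescent in transverse slices);
lesions are spheres rejection-sampled inside the gland, with 70% of
placements targeted at the peripheral zone, matching the clinical prior
that roughly 70% of prostate lesions arise there. Lesion appearance follows
mpMRI qualitatively: hypointense on ADC, hyperintense on DWI, mildly
hypointense on T2W.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from prostacad.volume import BENIGN, MALIGNANT, MODALITIES, MRIVolume, StudyCase, write_mask, write_volume


@dataclass
class TextureParams:
    """Gaussian-random-field texture for one tissue class on one sequence.

    mean/sd are in arbitrary normalized intensity units; corr_len_mm is the
    Gaussian kernel sigma of the field in millimetres (larger = coarser
    texture).
    """

    mean: float
    sd: float
    corr_len_mm: float


def _default_texture() -> dict[str, dict[str, TextureParams]]:
    # Background prostate tissue, benign lesions, malignant lesions.
    # Malignant/benign lesion means are separated by many noise SDs on ADC
    # and DWI and the correlation lengths differ, so both first- and
    # second-order statistics carry class signal.
    return {
        "background": {
            "T2W": TextureParams(1.00, 0.10, 1.5),
            "ADC": TextureParams(1.00, 0.10, 1.5),
            "DWI": TextureParams(1.00, 0.10, 1.5),
        },
        "benign": {
            "T2W": TextureParams(0.90, 0.10, 2.0),
            "ADC": TextureParams(0.95, 0.10, 2.0),
            "DWI": TextureParams(1.10, 0.10, 2.0),
        },
        "malignant": {
            "T2W": TextureParams(0.60, 0.18, 4.0),
            "ADC": TextureParams(0.50, 0.18, 4.0),   # hypointense
            "DWI": TextureParams(1.60, 0.18, 4.0),   # hyperintense
        },
    }


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort generator.

    The default class composition (718 benign : 448 malignant) and grid
    geometry (149×149×32 voxels at 0.75×0.75×3 mm) mirror the study
    conditions this phantom emulates.
    """

    grid_shape: tuple[int, int, int] = (149, 149, 32)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 3.0)
    gland_radius_mm: float = 20.0
    pz_shell_fraction: float = 0.35
    lesion_count_range: tuple[int, int] = (0, 2)
    lesion_radius_mm_range: tuple[float, float] = (4.0, 8.0)
    texture_params: dict[str, dict[str, TextureParams]] = field(default_factory=_default_texture)
    noise_sd: float = 0.05
    class_ratio: tuple[int, int] = (718, 448)   # benign : malignant
    pz_lesion_fraction: float = 0.7
    air_level: float = 0.2
    seed: int = 0

    # ellipsoid semi-axes as fractions of gland_radius_mm (x, y, z)
    gland_axis_fractions: tuple[float, float, float] = (1.0, 0.9, 0.65)

    def __post_init__(self) -> None:
        self.validate()

    def semi_axes_mm(self) -> tuple[float, float, float]:
        return tuple(self.gland_radius_mm * f for f in self.gland_axis_fractions)

    def validate(self) -> None:
        if not (0.0 < self.pz_shell_fraction < 1.0):
            raise ValueError("pz_shell_fraction must be in (0, 1)")
        if any(c <= 0 for c in self.class_ratio):
            raise ValueError("class_ratio components must be positive")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid lesion_count_range")
        rlo, rhi = self.lesion_radius_mm_range
        if rlo <= 0 or rhi < rlo:
            raise ValueError("invalid lesion_radius_mm_range")
        if rhi >= self.gland_radius_mm:
            raise ValueError(
                f"lesion radius {rhi} mm must be smaller than gland radius "
                f"{self.gland_radius_mm} mm")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        for ax, ext in zip(self.semi_axes_mm(), extent):
            if 2 * ax >= ext:
                raise ValueError("gland does not fit inside the grid")


def _physical_coords(shape, spacing):
    """Voxel-centre physical coordinates per axis, centred on the grid."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def _ellipsoid_rho(shape, spacing, semi_axes, center_mm):
    """Normalized ellipsoid radius field: rho <= 1 is inside the gland."""
    cx, cy, cz = _physical_coords(shape, spacing)
    X = (cx - center_mm[0])[:, None, None] / semi_axes[0]
    Y = (cy - center_mm[1])[None, :, None] / semi_axes[1]
    Z = (cz - center_mm[2])[None, None, :] / semi_axes[2]
    return np.sqrt(X ** 2 + Y ** 2 + Z ** 2)


def _random_field(rng, shape, spacing, params: TextureParams) -> np.ndarray:
    """Stationary Gaussian random field with the requested first two moments."""
    noise = rng.standard_normal(shape)
    sigma_vox = [max(params.corr_len_mm / s, 1e-6) for s in spacing]
    f = gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return params.mean + params.sd * f


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    cx, cy, cz = _physical_coords(shape, spacing)
    d2 = ((cx - center_mm[0]) ** 2)[:, None, None] \
        + ((cy - center_mm[1]) ** 2)[None, :, None] \
        + ((cz - center_mm[2]) ** 2)[None, None, :]
    return (d2 <= radius_mm ** 2).astype(np.uint8)


def _place_lesion(rng, spec: PhantomSpec, rho, pz_mask, gland_mask, spacing):
    """Rejection-sample one spherical lesion fully inside the gland.

    With probability ``pz_lesion_fraction`` the centre is drawn from the PZ,
    otherwise from the inner gland. Returns (mask, radius_mm) or None if no
    admissible placement is found.
    """
    shape = gland_mask.shape
    coords = _physical_coords(shape, spacing)
    pz_idx = np.argwhere(pz_mask > 0)
    inner_idx = np.argwhere((gland_mask > 0) & (pz_mask == 0))
    for _ in range(200):
        radius = rng.uniform(*spec.lesion_radius_mm_range)
        in_pz = rng.random() < spec.pz_lesion_fraction and len(pz_idx) > 0
        pool = pz_idx if in_pz else inner_idx
        if len(pool) == 0:
            pool = np.argwhere(gland_mask > 0)
        vx = pool[rng.integers(len(pool))]
        center = tuple(coords[a][vx[a]] for a in range(3))
        mask = _sphere_mask(shape, spacing, center, radius)
        if mask.sum() == 0:
            continue
        if np.all(gland_mask[mask > 0] > 0):
            return mask, radius
    return None


def generate_case(spec: PhantomSpec, label: int, seed: int,
                  case_id: str | None = None) -> StudyCase:
    """Generate one synthetic study case with the requested case label.

    Deterministic given (spec, label, seed). Malignant cases (label 1)
    contain at least one lesion with malignant texture; benign cases may
    contain benign lesions or none, per ``spec.lesion_count_range``.
    """
    spec.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm

    # gland centre jittered slightly so cases are not perfectly co-located
    jitter = rng.uniform(-2.0, 2.0, size=3) * np.array([1.0, 1.0, 0.5])
    semi = spec.semi_axes_mm()
    rho = _ellipsoid_rho(shape, spacing, semi, jitter)
    gland = (rho <= 1.0).astype(np.uint8)

    # posterior shell of the gland; +y is posterior
    cy = _physical_coords(shape, spacing)[1] - jitter[1]
    posterior = (cy > 0)[None, :, None]
    pz = ((rho <= 1.0) & (rho > 1.0 - spec.pz_shell_fraction) & posterior).astype(np.uint8)

    # lesions
    lo, hi = spec.lesion_count_range
    if label == MALIGNANT:
        n_lesions = int(rng.integers(max(lo, 1), hi + 1)) if hi >= max(lo, 1) else 1
        n_malignant = int(rng.integers(1, n_lesions + 1))
    else:
        n_lesions = int(rng.integers(lo, hi + 1))
        n_malignant = 0
    lesion_masks: list[tuple[np.ndarray, int]] = []
    for i in range(n_lesions):
        placed = _place_lesion(rng, spec, rho, pz, gland, spacing)
        if placed is None:
            continue
        mask, _ = placed
        lab = MALIGNANT if i < n_malignant else BENIGN
        lesion_masks.append((mask, lab))
    if label == MALIGNANT and not any(l == MALIGNANT for _, l in lesion_masks):
        raise RuntimeError("failed to place a malignant lesion; enlarge the gland "
                           "or shrink the lesion radius range")

    # compose intensities: air background, gland field, per-lesion fields
    volumes = {}
    tp = spec.texture_params
    for mod in MODALITIES:
        img = np.full(shape, spec.air_level, dtype=np.float64)
        gland_field = _random_field(rng, shape, spacing, tp["background"][mod])
        img[gland > 0] = gland_field[gland > 0]
        for mask, lab in lesion_masks:
            cls = "malignant" if lab == MALIGNANT else "benign"
            les_field = _random_field(rng, shape, spacing, tp[cls][mod])
            img[mask > 0] = les_field[mask > 0]
        img += rng.normal(0.0, spec.noise_sd, size=shape)
        volumes[mod] = MRIVolume(data=img, spacing_mm=spacing, modality=mod)

    case = StudyCase(
        case_id=case_id or f"case_{seed}",
        t2w=volumes["T2W"], adc=volumes["ADC"], dwi=volumes["DWI"],
        case_label=label, gland_mask=gland, pz_mask=pz, lesion_masks=lesion_masks,
    )
    case.validate_nesting()
    return case


def cohort_labels(n_cases: int, class_ratio: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Case labels for a cohort: counts follow class_ratio, order shuffled.

    The malignant count is ``round(n * malignant_share)``; for the default
    718:448 ratio and n = 1166 this yields exactly 718 benign and 448
    malignant cases.
    """
    b, m = class_ratio
    n_mal = int(round(n_cases * m / (b + m)))
    n_mal = min(max(n_mal, 1), n_cases - 1)
    labels = np.array([MALIGNANT] * n_mal + [BENIGN] * (n_cases - n_mal))
    rng.shuffle(labels)
    return labels


def _case_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def generate_cohort(spec: PhantomSpec, n_cases: int, seed: int
                    ) -> tuple[list[StudyCase], pd.DataFrame]:
    """Generate a cohort and its manifest (case_id, label, n_lesions, seed)."""
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2 (cohort must be splittable)")
    rng = np.random.default_rng(seed)
    labels = cohort_labels(n_cases, spec.class_ratio, rng)
    seeds = _case_seeds(seed, n_cases)
    cases, rows = [], []
    for i, (lab, s) in enumerate(zip(labels, seeds)):
        cid = f"case_{i:04d}"
        case = generate_case(spec, int(lab), s, case_id=cid)
        cases.append(case)
        rows.append({"case_id": cid, "label": int(lab),
                     "n_lesions": len(case.lesion_masks), "seed": s})
    manifest = pd.DataFrame(rows)
    return cases, manifest


def write_cohort(cases: list[StudyCase], manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a cohort as NIfTI volumes/masks plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        d = out / case.case_id
        d.mkdir(exist_ok=True)
        for mod, vol in case.sequences().items():
            write_volume(vol, d / f"{mod.lower()}.nii.gz")
        if case.gland_mask is not None:
            write_mask(case.gland_mask, case.spacing_mm, d / "gland_mask.nii.gz")
        if case.pz_mask is not None:
            write_mask(case.pz_mask, case.spacing_mm, d / "pz_mask.nii.gz")
        for i, (m, lab) in enumerate(case.lesion_masks):
            write_mask(m, case.spacing_mm, d / f"lesion_{i}_label{lab}.nii.gz")
    manifest.to_csv(out / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
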