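"""Texture features vs brute-force oracles; dimensionality contracts."""

import numpy as np
import pytest

from prostacad import FeatureConfig, MRIVolume, extract_sequence_features, extract_study_features
from prostacad.features import (
    HOG_DIRECTIONS,
    LBP_NEIGHBORS,
    OFFSETS_13,
    feature_matrix,
    glcm_3d,
    haralick_features,
    hog_3d,
    lbp_3d,
    quantize,
)
from tests.conftest import random_volume


# ------------------------------------------------------------- oracles

def brute_force_glcm(data, levels, offset):
    """Exhaustive pair enumeration: symmetric normalized co-occurrence."""
    q = quantize(data, levels)
    counts = np.zeros((levels, levels))
    nx, ny, nz = q.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                x2, y2, z2 = x + dx, y + dy, z + dz
                if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                    counts[q[x, y, z], q[x2, y2, z2]] += 1
                    counts[q[x2, y2, z2], q[x, y, z]] += 1
    s = counts.sum()
    return counts / s if s else counts


def brute_force_lbp(data):
    """Per-voxel 6-neighbour codes by explicit loops (ties encode as 1)."""
    nx, ny, nz = data.shape
    hist = np.zeros(64)
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                code = 0
                for bit, (dx, dy, dz) in enumerate(LBP_NEIGHBORS):
                    if data[x + dx, y + dy, z + dz] >= data[x, y, z]:
                        code |= 1 << bit
                hist[code] += 1
    return hist / hist.sum()


def brute_force_hog(data, spacing=(1.0, 1.0, 1.0), cells=(2, 2, 1), bins=16):
    """Per-voxel orientation binning with manual central differences."""
    nx, ny, nz = data.shape

    def grad_at(x, y, z):
        def d(axis, i, n, h):
            idx = [x, y, z]
            if 0 < i < n - 1:
                lo, hi = idx.copy(), idx.copy()
                lo[axis] -= 1
                hi[axis] += 1
                return (data[tuple(hi)] - data[tuple(lo)]) / (2 * h)
            if i == 0:
                hi = idx.copy()
                hi[axis] += 1
                return (data[tuple(hi)] - data[tuple(idx)]) / h
            lo = idx.copy()
            lo[axis] -= 1
            return (data[tuple(idx)] - data[tuple(lo)]) / h
        return np.array([d(0, x, nx, spacing[0]), d(1, y, ny, spacing[1]),
                         d(2, z, nz, spacing[2])])

    edges = [np.linspace(0, n, c + 1).astype(int) for n, c in zip(data.shape, cells)]
    out = []
    for ix in range(cells[0]):
        for iy in range(cells[1]):
            for iz in range(cells[2]):
                h = np.zeros(bins)
                for x in range(edges[0][ix], edges[0][ix + 1]):
                    for y in range(edges[1][iy], edges[1][iy + 1]):
                        for z in range(edges[2][iz], edges[2][iz + 1]):
                            g = grad_at(x, y, z)
                            mag = np.linalg.norm(g)
                            if mag == 0:
                                b = 0
                            else:
                                b = int(np.argmax(np.abs(HOG_DIRECTIONS @ g)))
                            h[b] += mag
                norm = np.sqrt((h ** 2).sum())
                out.append(h / norm if norm > 1e-12 else np.zeros(bins))
    return np.concatenate(out)


# ---------------------------------------------------------------- GLCM

class TestGLCM:
    def test_constant_volume_single_entry(self):
        g = glcm_3d(np.full((4, 4, 4), 2.0))
        for m in g.matrices:
            assert m[0, 0] == pytest.approx(1.0)
            assert m.sum() == pytest.approx(1.0)
            assert np.count_nonzero(m) == 1

    def test_checkerboard_hand_counts(self):
        data = np.indices((2, 2, 2)).sum(axis=0) % 2
        cfg = FeatureConfig()
        g = glcm_3d(data.astype(float), cfg)
        k = cfg.glcm_offsets.index((1, 0, 0))
        m = g.matrices[k]
        # 4 ordered pairs along +x, all between the two levels (0 and 31);
        # symmetrization puts half the mass at (0,31) and half at (31,0)
        assert m[0, 31] == pytest.approx(0.5)
        assert m[31, 0] == pytest.approx(0.5)
        assert m.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("shape,seed", [((4, 4, 4), 0), ((8, 8, 4), 1), ((5, 7, 3), 2)])
    def test_matches_bruteforce_enumeration(self, shape, seed):
        rng = np.random.default_rng(seed)
        data = rng.random(shape)
        cfg = FeatureConfig()
        g = glcm_3d(data, cfg)
        for k, off in enumerate(cfg.glcm_offsets):
            np.testing.assert_allclose(g.matrices[k],
                                       brute_force_glcm(data, cfg.glcm_levels, off),
                                       atol=1e-12)

    def test_symmetric_and_normalized(self):
        g = glcm_3d(random_volume((6, 6, 4), seed=5).data)
        for m in g.matrices:
            np.testing.assert_allclose(m, m.T, atol=0)
            assert m.sum() == pytest.approx(1.0)

    def test_offset_reach_error(self):
        with pytest.raises(ValueError, match="offset"):
            glcm_3d(np.zeros((4, 4, 1)))


class TestHaralick:
    def test_constant_volume_values(self):
        vals, names = haralick_features(glcm_3d(np.full((4, 4, 4), 1.0)))
        stats = dict(zip(names, vals))
        for off in ("off100", "off001"):
            assert stats[f"glcm_energy_{off}"] == pytest.approx(1.0)
            assert stats[f"glcm_entropy_{off}"] == pytest.approx(0.0)
            assert stats[f"glcm_contrast_{off}"] == pytest.approx(0.0)

    def test_entropy_matches_direct_formula(self):
        data = (np.indices((2, 2, 2)).sum(axis=0) % 2).astype(float)
        cfg = FeatureConfig()
        g = glcm_3d(data, cfg)
        vals, names = haralick_features(g, cfg)
        k = cfg.glcm_offsets.index((1, 0, 0))
        m = g.matrices[k]
        expected = -sum(p * np.log2(p) for p in m.ravel() if p > 0)
        tag = "off100"
        assert dict(zip(names, vals))[f"glcm_entropy_{tag}"] == pytest.approx(expected)

    def test_length_and_stable_names(self):
        v = random_volume((6, 6, 4), seed=8)
        vals, names = haralick_features(glcm_3d(v.data))
        vals2, names2 = haralick_features(glcm_3d(v.data))
        assert len(vals) == 169 and len(names) == 169
        assert names == names2
        assert len(set(names)) == 169

    def test_degenerate_correlation_defined(self):
        vals, names = haralick_features(glcm_3d(np.full((3, 3, 3), 5.0)))
        stats = dict(zip(names, vals))
        assert stats["glcm_correlation_off100"] == 0.0
        assert np.all(np.isfinite(vals))


class TestLBP:
    def test_constant_volume_all_ones_code(self):
        hist, names = lbp_3d(np.zeros((4, 4, 4)))
        assert hist[63] == pytest.approx(1.0)
        assert hist.sum() == pytest.approx(1.0)

    def test_single_bright_center(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 10.0
        hist, _ = lbp_3d(data)
        # the only interior voxel is the bright centre: all neighbours below it
        assert hist[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("shape,seed", [((5, 5, 3), 0), ((8, 8, 4), 3)])
    def test_matches_bruteforce_oracle(self, shape, seed):
        data = np.random.default_rng(seed).random(shape)
        hist, _ = lbp_3d(data)
        np.testing.assert_allclose(hist, brute_force_lbp(data), atol=1e-12)

    def test_histogram_sums_to_one(self):
        hist, _ = lbp_3d(random_volume((7, 6, 5), seed=4).data)
        assert hist.sum() == pytest.approx(1.0)


class TestHOG:
    def test_constant_volume_zero_descriptor(self):
        vals, _ = hog_3d(np.full((6, 6, 4), 3.0))
        assert np.all(vals == 0)

    def test_x_ramp_single_orientation_bin(self):
        data = np.tile(np.arange(8.0)[:, None, None], (1, 8, 4))
        vals, _ = hog_3d(data)
        per_cell = vals.reshape(4, 16)
        expected_bin = int(np.argmax(np.abs(HOG_DIRECTIONS @ np.array([1.0, 0, 0]))))
        for cell in per_cell:
            assert np.count_nonzero(cell) == 1
            assert cell[expected_bin] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_oracle(self, seed):
        data = np.random.default_rng(seed).random((8, 8, 4))
        vals, _ = hog_3d(data)
        np.testing.assert_allclose(vals, brute_force_hog(data), atol=1e-10)

    def test_direction_set_is_antipodally_unique(self):
        assert HOG_DIRECTIONS.shape == (16, 3)
        np.testing.assert_allclose(np.linalg.norm(HOG_DIRECTIONS, axis=1), 1.0)
        dots = HOG_DIRECTIONS @ HOG_DIRECTIONS.T
        off_diag = dots[~np.eye(16, dtype=bool)]
        assert np.abs(off_diag).max() < 1.0 - 1e-9  # no duplicated/antipodal pair


class TestAssembly:
    def test_sequence_contract_297(self, small_malignant_case):
        fv = extract_sequence_features(small_malignant_case.t2w)
        assert len(fv) == 297
        assert all(n.startswith("t2w_") for n in fv.names)

    def test_study_contract_891(self, small_malignant_case):
        fv = extract_study_features(small_malignant_case)
        assert len(fv) == 891
        assert len(set(fv.names)) == 891

    def test_pz_mode_adc_only_is_297(self, small_malignant_case):
        fv = extract_study_features({"ADC": small_malignant_case.adc})
        assert len(fv) == 297
        assert all(n.startswith("adc_") for n in fv.names)

    def test_canonical_order_independent_of_supply_order(self, small_benign_case):
        seqs = small_benign_case.sequences()
        a = extract_study_features({"T2W": seqs["T2W"], "ADC": seqs["ADC"], "DWI": seqs["DWI"]})
        b = extract_study_features({"DWI": seqs["DWI"], "T2W": seqs["T2W"], "ADC": seqs["ADC"]})
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)

    def test_purity_and_name_stability(self):
        v = random_volume((10, 10, 6), seed=9)
        a = extract_sequence_features(v)
        b = extract_sequence_features(v)
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_modality_rejected(self, small_benign_case):
        with pytest.raises(ValueError, match="missing"):
            extract_study_features({"T2W": small_benign_case.t2w,
                                    "ADC": small_benign_case.adc})

    def test_all_features_finite_fuzz(self):
        rng = np.random.default_rng(0)
        for i in range(30):
            shape = tuple(rng.integers(4, 12, size=2)) + (int(rng.integers(3, 6)),)
            v = MRIVolume(data=rng.standard_normal(shape) * rng.uniform(0.01, 100),
                          spacing_mm=(1, 1, 1), modality="T2W")
            fv = extract_sequence_features(v)
            assert np.all(np.isfinite(fv.values))

    def test_translation_invariance_of_periodic_texture(self):
        x = np.arange(12)
        data = np.sin(2 * np.pi * np.add.outer(np.add.outer(x, x), np.arange(4) * 3) / 4)
        shifted = np.roll(data, shift=4, axis=0)   # shift by one full period
        g1 = glcm_3d(data).matrices
        g2 = glcm_3d(shifted).matrices
        np.testing.assert_allclose(g1, g2, atol=0.02)
        h1, _ = lbp_3d(data)
        h2, _ = lbp_3d(shifted)
        np.testing.assert_allclose(h1, h2, atol=0.05)

    def test_feature_matrix_contract(self, small_benign_case, small_malignant_case):
        fvs = [extract_study_features(small_benign_case),
               extract_study_features(small_malignant_case)]
        df = feature_matrix(fvs)
        assert df.shape == (2, 891)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError, match="297"):
            FeatureConfig(lbp_bins=32)
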