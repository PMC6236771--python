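import numpy as np
import pytest

from lucad.features import (
    FEATURE_NAMES,
    GLCM_DESCRIPTORS,
    GLCMConfig,
    extract_all,
    glcm,
    gtf_features,
    haralick_descriptors,
    quantize,
    sbf_features,
    ssf_features,
    tef_features,
)

from conftest import disk_mask

DIDX = {name: i for i, name in enumerate(GLCM_DESCRIPTORS)}


def brute_force_glcm(img, levels, dr, dc):
    """Independent oracle: explicit pair counting + symmetrization."""
    q = quantize(img, levels)
    m = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
    m = m + m.T
    return m / m.sum()


class TestSSF:
    def test_constant_sample_degenerate_conventions(self):
        out = ssf_features(np.full(50, 0.3))
        mean, std, var, skew, kurt, entropy = out
        assert mean == pytest.approx(0.3)
        assert std == var == 0.0
        assert skew == kurt == 0.0
        assert entropy == 0.0

    def test_two_point_distribution_closed_form(self):
        sample = np.array([0.0] * 50 + [1.0] * 50)
        mean, std, var, skew, kurt, entropy = ssf_features(sample)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.25)
        assert skew == pytest.approx(0.0)
        assert entropy == pytest.approx(1.0)  # one bit

    def test_symmetric_sample_zero_skewness(self):
        sample = np.array([0.2, 0.5, 0.8] * 10)
        assert ssf_features(sample)[3] == pytest.approx(0.0)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            ssf_features(np.array([0.5]))


class TestSBF:
    def test_large_disk_is_round(self):
        mask = disk_mask((100, 100), (50, 50), 30)
        out = sbf_features(mask)
        named = dict(zip([n for n in FEATURE_NAMES if n.startswith("sbf")], out))
        assert 0.95 <= named["sbf_circularity"] <= 1.05
        assert named["sbf_eccentricity"] <= 0.15
        assert named["sbf_solidity"] >= 0.98

    def test_square_exact_raster_geometry(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        out = sbf_features(mask)
        named = dict(zip([n for n in FEATURE_NAMES if n.startswith("sbf")], out))
        assert named["sbf_area"] == 100.0
        assert named["sbf_extent"] == 1.0
        assert named["sbf_aspect_ratio"] == pytest.approx(1.0)

    def test_spiculated_rougher_than_disk(self):
        from lucad.phantom import _spiculated_mask

        rng = np.random.default_rng(3)
        disk = disk_mask((80, 80), (40, 40), 15)
        spic = _spiculated_mask((80, 80), (40, 40), 15, 0.3, 10, rng)
        d = dict(zip([n for n in FEATURE_NAMES if n.startswith("sbf")],
                     sbf_features(disk)))
        s = dict(zip([n for n in FEATURE_NAMES if n.startswith("sbf")],
                     sbf_features(spic)))
        assert s["sbf_radial_std"] > d["sbf_radial_std"]
        assert s["sbf_circularity"] < d["sbf_circularity"]

    def test_scale_monotonicity(self):
        small = sbf_features(disk_mask((60, 60), (30, 30), 10))
        big = sbf_features(disk_mask((120, 120), (60, 60), 20))
        assert big[0] / small[0] == pytest.approx(4.0, rel=0.05)  # area
        assert big[1] / small[1] == pytest.approx(2.0, rel=0.05)  # perimeter

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sbf_features(np.zeros((10, 10), bool))


class TestGLCM:
    def test_hand_counted_2x2(self):
        img = np.array([[0.0, 0.0], [0.6, 0.6]])
        p = glcm(img, GLCMConfig(distance=1, levels=2), angle_deg=0.0)
        assert p == pytest.approx(np.array([[0.5, 0.0], [0.0, 0.5]]))

    def test_constant_roi_single_entry(self):
        p = glcm(np.full((8, 8), 0.5), GLCMConfig(distance=1, levels=4), 0.0)
        assert p.sum() == pytest.approx(1.0)
        assert np.count_nonzero(p) == 1

    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, 135.0])
    def test_matches_brute_force_counting(self, angle):
        rng = np.random.default_rng(7)
        img = rng.random((12, 12))
        cfg = GLCMConfig(distance=2, levels=8)
        p = glcm(img, cfg, angle)
        # skimage angle convention: (dr, dc) = (d sin, d cos)
        dr = int(round(2 * np.sin(np.deg2rad(angle))))
        dc = int(round(2 * np.cos(np.deg2rad(angle))))
        expected = brute_force_glcm(img, 8, dr, dc)
        assert p == pytest.approx(expected)

    def test_roi_smaller_than_displacement_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((2, 2)), GLCMConfig(distance=3), 0.0)


class TestHaralickDescriptors:
    def test_two_level_diagonal_matrix(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        d = haralick_descriptors(p)
        assert d[DIDX["contrast"]] == pytest.approx(0.0)
        assert d[DIDX["asm"]] == pytest.approx(0.5)
        assert d[DIDX["correlation"]] == pytest.approx(1.0)
        assert d[DIDX["entropy"]] == pytest.approx(1.0)
        assert d[DIDX["homogeneity"]] == pytest.approx(1.0)

    def test_constant_roi_descriptor_limits(self):
        out = gtf_features(np.full((10, 10), 0.4), GLCMConfig(distance=1))
        per_angle = out.reshape(4, 22)
        for block in per_angle:
            assert block[DIDX["contrast"]] == pytest.approx(0.0)
            assert block[DIDX["asm"]] == pytest.approx(1.0)
            assert block[DIDX["homogeneity"]] == pytest.approx(1.0)
            assert block[DIDX["entropy"]] == pytest.approx(0.0)

    def test_descriptors_match_brute_force_moments(self):
        # independent recomputation of contrast/dissimilarity/ASM from
        # the brute-force matrix
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        cfg = GLCMConfig(distance=2, levels=8)
        p = brute_force_glcm(img, 8, 0, 2)
        d = haralick_descriptors(glcm(img, cfg, 0.0))
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        assert d[DIDX["contrast"]] == pytest.approx((((i - j) ** 2) * p).sum())
        assert d[DIDX["dissimilarity"]] == pytest.approx((np.abs(i - j) * p).sum())
        assert d[DIDX["asm"]] == pytest.approx((p**2).sum())
        assert d[DIDX["max_probability"]] == pytest.approx(p.max())

    def test_gtf_length_88(self):
        out = gtf_features(np.random.default_rng(0).random((20, 20)))
        assert out.shape == (88,)


class TestTEF:
    def test_energies_sum_to_one(self):
        rng = np.random.default_rng(2)
        out = tef_features(rng.random((32, 32)))
        assert out.shape == (13,)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0)

    def test_constant_roi_energy_in_approximation(self):
        out = tef_features(np.full((32, 32), 0.7))
        assert out[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(out[:-1] < 1e-9)

    def test_checkerboard_dominated_by_level1_diagonal(self):
        # zero-mean board so the DC term does not park energy in the
        # approximation subband
        board = (np.indices((32, 32)).sum(axis=0) % 2) - 0.5
        out = tef_features(board)
        named = dict(zip([n for n in FEATURE_NAMES if n.startswith("tef")], out))
        d1 = named["tef_l1_d"]
        assert all(d1 > v for k, v in named.items() if k != "tef_l1_d")

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError, match="16"):
            tef_features(np.zeros((8, 8)))


class TestExtractAll:
    def test_vector_has_123_named_features(self):
        img = np.full((40, 40), 0.2)
        mask = disk_mask((40, 40), (20, 20), 10)
        img[mask] = 0.8
        fv = extract_all(img, mask)
        assert len(fv) == 123
        assert len(FEATURE_NAMES) == 123
        assert len(set(fv.names)) == 123

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        img = rng.random((40, 40))
        mask = disk_mask((40, 40), (20, 20), 12)
        a = extract_all(img, mask)
        b = extract_all(img, mask)
        assert np.array_equal(a.values, b.values)

    def test_rotation_permutes_angle_blocks(self):
        rng = np.random.default_rng(5)
        img = rng.random((24, 24))
        cfg = GLCMConfig(distance=1, levels=8)
        orig = gtf_features(img, cfg).reshape(4, 22)  # 0,45,90,135
        rot = gtf_features(np.rot90(img), cfg).reshape(4, 22)
        assert rot[2] == pytest.approx(orig[0])  # 0 -> 90
        assert rot[0] == pytest.approx(orig[2])  # 90 -> 0
        assert rot[3] == pytest.approx(orig[1])  # 45 -> 135
        assert rot[1] == pytest.approx(orig[3])  # 135 -> 45

    def test_malign_population_has_higher_variance(self):
        # generator encodes malignancy as internal noise + spiculation:
        # the first-order variance feature must separate the populations
        from lucad.phantom import PhantomSpec, make_slice

        spec = PhantomSpec(image_size=192, size_range_mm=(8.0, 16.0))
        var_idx = FEATURE_NAMES.index("ssf_variance")
        values = {"benign": [], "malign": []}
        for seed in range(25):
            ct, _, truths = make_slice(
                spec, seed=100 + seed,
                nodules=[(12.0, "malign"), (12.0, "benign")])
            for t in truths:
                fv = extract_all(ct.pixels, t.mask)
                values[t.label].append(fv.values[var_idx])
        assert np.mean(values["malign"]) > np.mean(values["benign"])

    def test_shape_mismatch_and_family_error_naming(self):
        with pytest.raises(ValueError, match="shapes"):
            extract_all(np.zeros((10, 10)), np.zeros((12, 12), bool))
        with pytest.raises(ValueError, match="SBF|SSF"):
            extract_all(np.zeros((20, 20)), np.zeros((20, 20), bool))
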