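"""Texture families and quantization against hand values and brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import make_quantized, make_suv, random_quantized
from petrad.features import texture
from petrad.features.quantize import quantize
from petrad.volume import BtvMask

SPACING = (1.17, 1.17, 3.27)


class TestQuantize:
    def test_one_value_per_bin(self):
        arr = np.zeros((1, 1, 64), np.float32)
        arr[0, 0, :] = np.arange(1, 65)
        vol = make_suv(arr)
        mask = BtvMask(np.ones((1, 1, 64), bool), SPACING)
        q = quantize(vol, mask, 64)
        np.testing.assert_array_equal(q.levels[0, 0], np.arange(1, 65))

    def test_constant_region_maps_to_level_one(self):
        vol = make_suv(np.full((3, 3, 2), 4.2))
        mask = BtvMask(np.ones((3, 3, 2), bool), SPACING)
        assert np.all(quantize(vol, mask, 64).levels == 1)

    def test_matches_per_voxel_bin_oracle(self, rng):
        arr = (rng.random((6, 6, 4)) * 9 + 0.5).astype(np.float32)
        maskvox = np.ones((6, 6, 4), bool)
        vol, mask = make_suv(arr), BtvMask(maskvox, SPACING)
        q = quantize(vol, mask, 64)
        lo, hi = arr.min(), arr.max()
        for idx, v in np.ndenumerate(arr):
            expected = min(int((v - lo) / (hi - lo) * 64) + 1, 64)
            assert q.levels[idx] == expected

    def test_affine_rescale_invariance(self, rng):
        arr = (rng.random((5, 5, 3)) * 5).astype(np.float32)
        maskvox = np.ones((5, 5, 3), bool)
        mask = BtvMask(maskvox, SPACING)
        q1 = quantize(make_suv(arr), mask, 32)
        q2 = quantize(make_suv(2.5 * arr + 1.0), mask, 32)
        np.testing.assert_array_equal(q1.levels, q2.levels)


class TestCooccurrence:
    def test_hand_enumerated_line(self):
        # 1x1x4 line [1,1,2,2]: 6 ordered pairs along z
        q = make_quantized([1, 1, 2, 2], n_levels=2)
        f = texture.cooccurrence_features(q)
        assert f["second_angular_moment"] == pytest.approx(10 / 36, abs=1e-12)
        assert f["contrast"] == pytest.approx(2 / 6, abs=1e-12)

    def test_constant_lesion(self):
        q = make_quantized(np.ones((3, 3, 2), int))
        f = texture.cooccurrence_features(q)
        assert f["second_angular_moment"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["homogeneity"] == pytest.approx(1.0)

    def test_single_voxel_is_nan(self):
        q = make_quantized(np.ones((1, 1, 1), int))
        assert np.isnan(texture.cooccurrence_features(q)["entropy"])


class TestRunLength:
    def test_hand_enumerated_runs_single_direction(self):
        q = make_quantized([1, 1, 2, 2, 2], n_levels=2)
        f = texture.voxel_alignment_features(q, offsets=[(0, 0, 1)])
        assert f["short_run_emphasis"] == pytest.approx((1 / 4 + 1 / 9) / 2, abs=1e-12)

    def test_constant_line_single_direction(self):
        n = 7
        q = make_quantized([1] * n, n_levels=1)
        f = texture.voxel_alignment_features(q, offsets=[(0, 0, 1)])
        assert f["long_run_emphasis"] == pytest.approx(n ** 2)
        assert f["run_percentage"] == pytest.approx(1 / n)


class TestSizeZone:
    def test_two_zone_percentage(self):
        q = make_quantized([1, 1, 1, 1, 2, 2], n_levels=2)
        assert texture.size_zone_features(q)["zone_percentage"] == pytest.approx(2 / 6)

    def test_constant_lesion_large_zone(self):
        q = make_quantized(np.ones((2, 3, 2), int))
        f = texture.size_zone_features(q)
        assert f["large_zone_emphasis"] == pytest.approx(12 ** 2)


class TestNgtdm:
    def test_constant_lesion_degenerates(self):
        q = make_quantized(np.ones((3, 3, 2), int))
        f = texture.nid_features(q)
        assert f["contrast"] == 0 and f["busyness"] == 0 and f["complexity"] == 0
        assert f["coarseness"] == pytest.approx(1e6)

    def test_level_shift_leaves_contrast_unchanged(self):
        grid = np.array([[[1], [2], [1]], [[2], [3], [2]], [[1], [2], [1]]])
        a = texture.nid_features(make_quantized(grid, n_levels=4))
        b = texture.nid_features(make_quantized(grid + 1, n_levels=4))
        assert a["contrast"] == pytest.approx(b["contrast"], abs=1e-12)


class TestNgldm:
    def test_single_voxel(self):
        q = make_quantized(np.ones((1, 1, 1), int))
        f = texture.ngld_features(q)
        assert f["small_number_emphasis"] == pytest.approx(1.0)

    def test_constant_lesion_maximizes_large_number_emphasis(self, rng):
        shape = (4, 4, 3)
        const = make_quantized(np.ones(shape, int))
        rand = make_quantized(rng.integers(1, 5, size=shape), np.ones(shape, bool), 4)
        assert (texture.ngld_features(const)["large_number_emphasis"]
                >= texture.ngld_features(rand)["large_number_emphasis"])


class TestTextureSpectrum:
    def test_constant_lesion_single_unit(self):
        q = make_quantized(np.ones((5, 5, 1), int))
        f = texture.texture_spectrum_features(q)
        assert f["max_spectrum"] == pytest.approx(1.0)
        assert f["black_white_symmetry"] == pytest.approx(1.0)

    def test_intensity_inversion_preserves_black_white_symmetry(self, rng):
        grid = rng.integers(1, 5, size=(6, 6, 2))
        mask = np.ones(grid.shape, bool)
        a = texture.texture_spectrum_features(make_quantized(grid, mask, 5))
        inverted = 5 - grid  # maps level L to 5-L, swapping above/below
        b = texture.texture_spectrum_features(make_quantized(inverted, mask, 5))
        assert a["black_white_symmetry"] == pytest.approx(b["black_white_symmetry"],
                                                          abs=1e-12)

    def test_thin_lesion_is_nan(self):
        q = make_quantized(np.ones((2, 2, 3), int))
        assert np.isnan(texture.texture_spectrum_features(q)["max_spectrum"])


class TestTfc:
    def test_constant_lesion_flat_codes(self):
        q = make_quantized(np.ones((5, 5, 2), int))
        f = texture.tfc_features(q)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["variance"] == pytest.approx(0.0)

    def test_uniform_level_shift_leaves_code_map_unchanged(self, rng):
        grid = rng.integers(1, 6, size=(6, 6, 2))
        mask = np.ones(grid.shape, bool)
        code_a, _ = texture.tfc_code_map(make_quantized(grid, mask, 7))
        code_b, _ = texture.tfc_code_map(make_quantized(grid + 1, mask, 7))
        np.testing.assert_array_equal(code_a, code_b)


ALL_FAMILIES = [
    ("glcm", texture.cooccurrence_features, oracles.glcm_features),
    ("rlm", texture.voxel_alignment_features, oracles.rlm_features),
    ("ngtdm", texture.nid_features, oracles.ngtdm_features),
    ("szm", texture.size_zone_features, oracles.szm_features),
    ("nglcm", texture.normalized_cooccurrence_features, oracles.nglcm_features),
    ("ts", texture.texture_spectrum_features, oracles.texture_spectrum_features),
    ("tfc", texture.tfc_features, oracles.tfc_features),
    ("tfcc", texture.tfcc_features, oracles.tfcc_features),
    ("ngldm", texture.ngld_features, oracles.ngldm_features),
]

NEEDS_NLEVELS = {"glcm", "nglcm", "ngtdm", "ngldm"}


@pytest.mark.parametrize("fam,impl,oracle", ALL_FAMILIES, ids=[f[0] for f in ALL_FAMILIES])
@pytest.mark.parametrize("case", range(4))
def test_family_matches_brute_force_oracle(fam, impl, oracle, case):
    """Every texture family equals independent brute-force enumeration to 1e-9
    on small random fixtures (including ragged masks)."""
    rng = np.random.default_rng(100 + case)
    q = random_quantized(rng, shape=(5, 5, 3), n_levels=4,
                         p_mask=1.0 if case == 0 else 0.75)
    got = impl(q)
    if fam in NEEDS_NLEVELS:
        want = oracle(q.levels, q.mask, q.n_levels)
    else:
        want = oracle(q.levels, q.mask)
    for k, v in want.items():
        if np.isnan(v):
            assert np.isnan(got[k]), k
        else:
            assert got[k] == pytest.approx(v, abs=1e-9), f"{fam}:{k}"


def test_rotation_invariance_of_texture_features(rng):
    """All 59 texture features are invariant under 90-degree in-plane rotation."""
    q = random_quantized(rng, shape=(6, 6, 3), n_levels=5, p_mask=0.8)
    rot_levels = np.rot90(q.levels, axes=(0, 1)).copy()
    rot_mask = np.rot90(q.mask, axes=(0, 1)).copy()
    q_rot = make_quantized(rot_levels, rot_mask, q.n_levels)
    for fam, impl, _ in ALL_FAMILIES:
        a, b = impl(q), impl(q_rot)
        for k in a:
            if np.isnan(a[k]):
                assert np.isnan(b[k])
            else:
                assert a[k] == pytest.approx(b[k], abs=1e-9), f"{fam}:{k}"


def test_probability_matrices_sum_to_one(rng):
    """Normalized matrix forms integrate to 1 (checked via their builders)."""
    q = random_quantized(rng, shape=(5, 5, 3), n_levels=4)
    c = texture._cooccurrence_counts(q.levels, q.mask, q.n_levels)
    assert (c / c.sum()).sum() == pytest.approx(1.0, abs=1e-9)
    rows = c.sum(axis=1)
    p = np.zeros_like(c)
    p[rows > 0] = c[rows > 0] / rows[rows > 0, None]
    assert (p / p.sum()).sum() == pytest.approx(1.0, abs=1e-9)
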