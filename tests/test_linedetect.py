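import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msld import DetectorParams, FovMask, build_kernel, single_scale_response, standardize
from msld.linedetect import FULL_SCALES, ResponseMap
from oracles import line_response_bf


def kernels_for(L, params=None):
    params = params or DetectorParams()
    return [build_kernel(L, a).offsets for a in params.angles]


class TestBuildKernel:
    def test_single_point_at_any_angle(self):
        for angle in DetectorParams().angles:
            assert build_kernel(1, angle).offsets == ((0, 0),)

    def test_horizontal_line_is_a_row(self):
        k = build_kernel(15, 0)
        assert set(k.offsets) == {(0, c) for c in range(-7, 8)}

    def test_diagonal_L5_matches_enumerated_rounding_rule(self):
        # hand enumeration: k=1 -> (-1,1); k=2 rounds onto (-1,1), nudged
        # to k=2.25 -> (-2,2); negative half mirrors
        k = build_kernel(5, 45)
        assert set(k.offsets) == {(-2, 2), (-1, 1), (0, 0), (1, -1), (2, -2)}

    @given(
        L=st.sampled_from(FULL_SCALES),
        angle_idx=st.integers(min_value=0, max_value=11),
    )
    @settings(derandomize=True, max_examples=96)
    def test_kernel_invariants(self, L, angle_idx):
        k = build_kernel(L, angle_idx * 15.0)
        assert len(set(k.offsets)) == L
        assert (0, 0) in k.offsets
        negated = {(-r, -c) for r, c in k.offsets}
        assert negated == set(k.offsets)

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            build_kernel(4, 0)


class TestSingleScaleResponse:
    def test_constant_image_gives_zero_response(self):
        img = np.full((32, 32), 0.37)
        r = single_scale_response(img, 7)
        assert np.allclose(r.values, 0.0)

    def test_shift_invariance(self, random_img32, disk_fov32):
        a = single_scale_response(random_img32, 7, fov=disk_fov32)
        b = single_scale_response(random_img32 + 0.1, 7, fov=disk_fov32)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_homogeneity(self, random_img32, disk_fov32):
        a = single_scale_response(random_img32, 9, fov=disk_fov32)
        b = single_scale_response(3.0 * random_img32, 9, fov=disk_fov32)
        assert np.allclose(b.values, 3.0 * a.values, atol=1e-12)

    @pytest.mark.parametrize("L", FULL_SCALES)
    def test_matches_bruteforce_all_scales(self, L, random_img32, disk_fov32):
        r = single_scale_response(random_img32, L, fov=disk_fov32)
        ref = line_response_bf(
            random_img32, kernels_for(L), 15, disk_fov32.inside
        )
        assert np.max(np.abs(r.values - ref)) <= 1e-9

    def test_scale_exceeding_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            single_scale_response(np.zeros((32, 32)), 17)

    def test_bar_phantom_peak_angle_and_contrast(self):
        # bright horizontal bar of width 3, contrast +0.3 on flat background
        img = np.full((48, 64), 0.4)
        img[23:26, :] = 0.7
        fov = FovMask.full(img.shape)
        for L in (3, 5, 7, 9, 11, 13, 15):
            # centerline response beats off-vessel response 10+ px away
            r = single_scale_response(img, L, fov=fov)
            assert r.values[24, 32] > r.values[24 + 12, 32]
            # the maximizing angle at the centerline is 0 (horizontal)
            pad = 15
            padded = np.pad(img, pad, mode="symmetric")
            line_means = []
            for angle in DetectorParams().angles:
                k = build_kernel(L, angle)
                line_means.append(
                    np.mean([padded[pad + 24 + dr, pad + 32 + dc] for dr, dc in k.offsets])
                )
            if L >= 3:
                assert int(np.argmax(line_means)) == 0

    def test_rotation_equivariance(self):
        # 90-degree rotation permutes the response map by the same rotation
        img = np.full((40, 40), 0.4)
        img[18:21, 5:35] = 0.7
        fov = FovMask.full(img.shape)
        r = single_scale_response(img, 11, fov=fov)
        r_rot = single_scale_response(np.rot90(img), 11, fov=fov)
        assert np.max(np.abs(r_rot.values - np.rot90(r.values))) <= 1e-9


class TestStandardize:
    def test_mean_zero_sd_one_in_fov(self, random_img32, disk_fov32):
        r = single_scale_response(random_img32, 7, fov=disk_fov32)
        z = standardize(r, disk_fov32)
        vals = z.values[disk_fov32.inside]
        assert abs(vals.mean()) <= 1e-12
        assert abs(vals.std() - 1.0) <= 1e-12
        assert np.all(z.values[~disk_fov32.inside] == 0)

    def test_idempotent_on_standardized_map(self, random_img32, disk_fov32):
        r = single_scale_response(random_img32, 7, fov=disk_fov32)
        z1 = standardize(r, disk_fov32)
        z2 = standardize(z1, disk_fov32)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_three_value_hand_case(self):
        fov = FovMask(np.array([[True, True, True], [False] * 3, [False] * 3]))
        r = ResponseMap(
            values=np.array([[1.0, 2.0, 3.0], [0] * 3, [0] * 3]), scale=1
        )
        z = standardize(r, fov)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)
        assert np.allclose(z.values[0], expected, atol=1e-4)

    def test_zero_variance_error_names_scale(self):
        fov = FovMask(np.ones((4, 4), bool))
        r = ResponseMap(values=np.ones((4, 4)), scale=7, source_tag="I1:local")
        with pytest.raises(ValueError, match="scale=7"):
            standardize(r, fov)
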