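import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miaclust import (
    ParameterError,
    PreprocessParams,
    Volume,
    background_mask,
    invert_foreground,
    median_filter,
)
from oracles import brute_force_median


def vol(data, bit_depth=16):
    return Volume(np.asarray(data), voxel_size_um=1.0, bit_depth=bit_depth)


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        v = vol(np.full((5, 5, 5), 123, dtype=np.uint16))
        assert np.array_equal(median_filter(v, 3).data, v.data)

    def test_isolated_bright_voxel_removed(self):
        data = np.zeros((5, 5, 5), dtype=np.uint16)
        data[2, 2, 2] = 100
        out = median_filter(vol(data), 3)
        assert out.data.max() == 0

    def test_matches_neighborhood_sort_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.integers(0, 1000, size=(6, 6, 6), dtype=np.uint16)
        got = median_filter(vol(data), 3).data
        want = brute_force_median(data, 3)
        assert np.array_equal(got, want)

    def test_idempotent_on_piecewise_constant_regions(self):
        data = np.zeros((10, 10, 10), dtype=np.uint16)
        data[:, :, 5:] = 400  # two half-spaces, diameter >> kernel
        once = median_filter(vol(data), 3)
        twice = median_filter(once, 3)
        assert np.array_equal(once.data, twice.data)

    def test_never_invents_values(self):
        rng = np.random.default_rng(1)
        data = rng.choice([0, 17, 300, 60000], size=(6, 6, 6)).astype(np.uint16)
        out = median_filter(vol(data), 3).data
        assert set(np.unique(out)) <= set(np.unique(data))

    @pytest.mark.parametrize("kernel", [2, 4, 0])
    def test_even_or_tiny_kernel_rejected(self, kernel):
        with pytest.raises(ParameterError):
            median_filter(vol(np.zeros((5, 5, 5), dtype=np.uint16)), kernel)


class TestBackgroundMask:
    def test_zero_threshold_keeps_everything(self):
        v = vol(np.arange(27, dtype=np.uint16).reshape(3, 3, 3))
        assert background_mask(v, 0).all()

    def test_boundary_is_inclusive(self):
        v = vol(np.array([[[5, 10, 15]]], dtype=np.uint16))
        assert background_mask(v, 10).tolist() == [[[False, True, True]]]

    @settings(derandomize=True, max_examples=30)
    @given(t1=st.floats(0, 70000), t2=st.floats(0, 70000))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(3)
        v = vol(rng.integers(0, 65535, size=(4, 4, 4), dtype=np.uint16))
        lo, hi = sorted((t1, t2))
        assert not (background_mask(v, hi) & ~background_mask(v, lo)).any()


class TestInvertForeground:
    def test_double_inversion_is_identity(self):
        rng = np.random.default_rng(5)
        v = vol(rng.integers(0, 65535, size=(4, 4, 4), dtype=np.uint16))
        mask = rng.random(v.shape) < 0.5
        back = invert_foreground(invert_foreground(v, mask), mask)
        assert np.array_equal(back.data, v.data)

    def test_bit_depth_arithmetic(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        v16 = vol(np.array([[[0]]], dtype=np.uint16))
        assert invert_foreground(v16, mask).data[0, 0, 0] == 65535
        v8 = vol(np.array([[[100]]], dtype=np.uint8), bit_depth=8)
        assert invert_foreground(v8, mask).data[0, 0, 0] == 155

    def test_shape_mismatch_rejected(self):
        v = vol(np.zeros((3, 3, 3), dtype=np.uint16))
        with pytest.raises(ParameterError):
            invert_foreground(v, np.ones((2, 2, 2), dtype=bool))


def test_preprocess_params_validation():
    with pytest.raises(ParameterError):
        PreprocessParams(median_kernel=4)
    with pytest.raises(ParameterError):
        PreprocessParams(background_threshold=-1)
    assert PreprocessParams().median_kernel == 0
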