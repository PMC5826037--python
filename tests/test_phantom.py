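import numpy as np
import pytest

from miaclust import (
    GeometryError,
    ParameterError,
    PhantomSpec,
    local_thickness,
    make_phantom,
    phantom_report,
)


def coil_spec(**overrides):
    base = dict(kind="plate_coil", shape=(32, 96, 96), thickness_vox=5,
                foreground_level=30000, background_level=0, seed=0)
    base.update(overrides)
    return PhantomSpec(**base)


class TestPlateCoil:
    def test_noiseless_volume_has_two_levels(self):
        truth = make_phantom(coil_spec())
        values = set(np.unique(truth.volume.data))
        assert values == {0, 30000}
        assert np.array_equal(truth.true_mask,
                              truth.volume.data == 30000)

    def test_determinism_and_seed_effect(self):
        spec = coil_spec(noise_sd=1000, seed=11)
        a = make_phantom(spec)
        b = make_phantom(coil_spec(noise_sd=1000, seed=11))
        assert np.array_equal(a.volume.data, b.volume.data)
        c = make_phantom(coil_spec(noise_sd=1000, seed=12))
        assert not np.array_equal(a.volume.data, c.volume.data)
        # different seeds change only noise, never the geometry
        assert np.array_equal(a.true_mask, c.true_mask)

    def test_true_mask_interior_thickness(self):
        truth = make_phantom(coil_spec())
        th = local_thickness(truth.true_mask)
        # mean over the band matches the spec'd thickness to half a voxel
        assert abs(th.mean_vox - 5.0) <= 0.5
        # and the band interior genuinely carries ~5-voxel spheres
        assert th.thickness_map.max() >= 4.5

    def test_artifacts_stay_in_bit_depth(self):
        truth = make_phantom(coil_spec(gradient_amplitude=0.3, noise_sd=4000,
                                       inclusion_density=0.01, seed=5))
        assert truth.volume.data.max() <= 65535
        assert truth.volume.data.min() >= 0

    def test_too_small_volume_rejected(self):
        with pytest.raises(GeometryError):
            make_phantom(coil_spec(shape=(32, 20, 20)))


class TestFossilLike:
    def make(self, **overrides):
        base = dict(kind="fossil_like", shape=(32, 64, 64), thickness_vox=4,
                    foreground_level=26000, background_level=2000,
                    matrix_level=34000, seed=3)
        base.update(overrides)
        return make_phantom(PhantomSpec(**base))

    def test_level_ordering_matches_taphonomy(self):
        """Background < bone < matrix; bright inclusions above everything."""
        truth = self.make(inclusion_density=0.001)
        data = truth.volume.data.astype(float)
        labels = truth.true_labels.labels
        incl = truth.inclusion_mask
        assert data[(labels == 1) & ~incl].max() < data[(labels == 2) & ~incl].min()
        assert np.median(data[(labels == 3) & ~incl]) > np.median(
            data[(labels == 2) & ~incl])
        if incl.any():
            assert data[incl].min() > 34000

    def test_matrix_level_required_and_brighter(self):
        with pytest.raises(ParameterError):
            PhantomSpec(kind="fossil_like", shape=(16, 32, 32))
        with pytest.raises(ParameterError):
            PhantomSpec(kind="fossil_like", shape=(16, 32, 32),
                        foreground_level=30000, matrix_level=20000)

    def test_bone_embedded_in_matrix(self):
        truth = self.make()
        labels = truth.true_labels.labels
        assert (labels == 2).any() and (labels == 3).any()
        assert np.array_equal(truth.true_mask, labels == 2)


class TestPhantomReport:
    def test_perfect_labels_score_one(self):
        truth = make_phantom(coil_spec())
        metrics = phantom_report(truth, truth.true_labels, 2)
        assert metrics["dice"] == pytest.approx(1.0)
        assert metrics["sensitivity"] == pytest.approx(1.0)
        assert metrics["specificity"] == pytest.approx(1.0)

    def test_empty_prediction_has_zero_sensitivity(self):
        from miaclust import LabelVolume

        truth = make_phantom(coil_spec())
        empty = LabelVolume(np.ones(truth.true_mask.shape, dtype=np.int32),
                            2, 1.0)
        metrics = phantom_report(truth, empty, 2)
        assert metrics["sensitivity"] == 0.0
        assert metrics["dice"] == 0.0

    def test_shape_mismatch_rejected(self):
        from miaclust import LabelVolume

        truth = make_phantom(coil_spec())
        other = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), 2, 1.0)
        with pytest.raises(ParameterError):
            phantom_report(truth, other, 2)
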