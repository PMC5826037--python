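import numpy as np
import pytest
from sklearn.base import clone

from miaclust import (
    LabelVolume,
    MembershipField,
    MIAClusterSegmenter,
    ParameterError,
    SegmentationConfig,
    Volume,
    admissible_prob_thresholds,
    assign_labels,
    binarize,
    local_refine,
    normalize_prob_threshold,
    segment,
)


def field(u, mask=None, vs=1.0):
    u = np.asarray(u, dtype=float)
    if mask is None:
        mask = np.ones(u.shape[1:], dtype=bool)
    return MembershipField(u, mask, vs)


class TestProbThreshold:
    def test_fifty_active_values(self):
        menu = admissible_prob_thresholds()
        assert len(menu) == 50
        assert menu[0] == 0.51 and menu[-1] == 1.0
        for t in menu:
            assert normalize_prob_threshold(t) == t

    def test_fifty_percent_is_off(self):
        assert normalize_prob_threshold(0.50) is None
        assert normalize_prob_threshold(50) is None
        assert normalize_prob_threshold(None) is None

    def test_integer_percent_spelling(self):
        assert normalize_prob_threshold(85) == 0.85

    @pytest.mark.parametrize("bad", [0.505, 0.49, 1.01, 101, 0.2])
    def test_off_menu_values_rejected(self, bad):
        with pytest.raises(ParameterError):
            normalize_prob_threshold(bad)


class TestAssignLabels:
    def test_argmax_without_threshold(self):
        mf = field(np.array([0.6, 0.3, 0.1]).reshape(3, 1, 1, 1))
        assert assign_labels(mf).labels[0, 0, 0] == 1

    def test_threshold_meet_or_exceed(self):
        mf = field(np.array([0.6, 0.3, 0.1]).reshape(3, 1, 1, 1))
        assert assign_labels(mf, 0.75).labels[0, 0, 0] == 0
        assert assign_labels(mf, 0.60).labels[0, 0, 0] == 1  # inclusive

    def test_two_class_fifty_percent_is_noop(self):
        rng = np.random.default_rng(0)
        u1 = rng.random((4, 4, 4))
        mf = field(np.stack([u1, 1 - u1]))
        a = assign_labels(mf, None).labels
        b = assign_labels(mf, 0.50).labels
        assert np.array_equal(a, b)

    def test_out_of_mask_is_zero_and_ties_go_low(self):
        mask = np.array([[[True, False]]])
        u = np.array([0.5, 0.5]).reshape(2, 1, 1, 1) * mask
        lv = assign_labels(MembershipField(u, mask))
        assert lv.labels[0, 0, 0] == 1  # tie -> lowest class index
        assert lv.labels[0, 0, 1] == 0


class TestBinarize:
    def _labels(self):
        labels = np.array([[[0, 1, 2, 3, 2]]], dtype=np.int32)
        return LabelVolume(labels, n_classes=3, voxel_size_um=1.0)

    def test_selectors(self):
        lv = self._labels()
        assert np.array_equal(binarize(lv, "brightest"), lv.labels == 3)
        assert np.array_equal(binarize(lv, "second-brightest"), lv.labels == 2)
        assert np.array_equal(binarize(lv, 1), lv.labels == 1)

    def test_classes_partition_the_volume(self):
        lv = self._labels()
        total = (lv.labels == 0).astype(int)
        for c in range(1, 4):
            total += binarize(lv, c).astype(int)
        assert (total == 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            binarize(self._labels(), 4)


class TestLocalRefine:
    def test_class_presence_drop_rule(self):
        # 1000-voxel cube, global memberships (0.98, 0.01, 0.01):
        # S_2 = S_3 = 10 < 0.02 * 1000 = 20 -> both dropped -> (1, 0, 0)
        shape = (10, 10, 10)
        data = np.zeros(shape)
        u = np.empty((3,) + shape)
        u[0], u[1], u[2] = 0.98, 0.01, 0.01
        cfg = SegmentationConfig(n_classes=3, grid_size=10)
        merged = local_refine(Volume(data, 1.0), np.ones(shape, bool), u,
                              np.array([0.0, 100.0, 200.0]), cfg)
        assert np.allclose(merged[0], 1.0)
        assert np.allclose(merged[1:], 0.0)

    def test_overlap_merge_is_unweighted_mean(self):
        # cube A drops class 2 (contributes (1, 0)); cube B keeps both but
        # is intensity-constant, so it passes its global memberships
        # through; a voxel covered by both ends up with the mean vector
        shape = (1, 1, 15)
        data = np.zeros(shape)
        u = np.zeros((2,) + shape)
        u[0, 0, 0, :7] = 1.0
        u[0, 0, 0, 7:] = 0.8
        u[1, 0, 0, 7:] = 0.2
        cfg = SegmentationConfig(n_classes=2, grid_size=10, overlap_stride=5,
                                 class_presence_threshold=0.1)
        merged = local_refine(Volume(data, 1.0), np.ones(shape, bool), u,
                              np.array([0.0, 100.0]), cfg)
        assert np.allclose(merged[:, 0, 0, 7], [0.9, 0.1])

    def test_merged_memberships_sum_to_one(self, small_coil, base_config):
        res = segment(small_coil.volume, None, base_config)
        res.local_memberships.validate(atol=1e-6)


class TestSegment:
    def test_noise_free_two_level_volume_exact(self, two_level_volume):
        volume, truth = two_level_volume
        for g in (6, 16):
            cfg = SegmentationConfig(n_classes=2, grid_size=g)
            res = segment(volume, None, cfg)
            assert np.array_equal(res.labels.labels, truth)
            assert res.labels.voxel_size_um == volume.voxel_size_um

    def test_bit_identical_determinism(self, small_coil, base_config):
        a = segment(small_coil.volume, None, base_config)
        b = segment(small_coil.volume, None, base_config)
        assert np.array_equal(a.labels.labels, b.labels.labels)
        assert np.array_equal(a.local_memberships.memberships,
                              b.local_memberships.memberships)

    def test_global_objective_non_increasing(self, small_coil, base_config):
        est = MIAClusterSegmenter(n_classes=2, grid_size=7, stride=4)
        est.fit(small_coil.volume)
        J = np.array(est.objective_)
        assert (np.diff(J) <= 1e-9 * J[0]).all()

    def test_threshold_label_sets_nested(self, small_coil):
        cfg = SegmentationConfig(n_classes=2, grid_size=7, overlap_stride=4)
        res = segment(small_coil.volume, None, cfg)
        prev = None
        for t in (0.51, 0.75, 0.95):
            nonzero = assign_labels(res.local_memberships, t).labels > 0
            if prev is not None:
                assert not (nonzero & ~prev).any()
            prev = nonzero


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self):
        est = MIAClusterSegmenter(n_classes=2, grid_size=9, prob_threshold=75)
        assert est.get_params()["grid_size"] == 9
        est2 = clone(est).set_params(grid_size=11)
        assert est2.grid_size == 11 and est.grid_size == 9

    def test_fit_predict_matches_labels(self, two_level_volume):
        volume, truth = two_level_volume
        est = MIAClusterSegmenter(n_classes=2, grid_size=8,
                                  voxel_size_um=volume.voxel_size_um)
        labels = est.fit_predict(volume.data)
        assert np.array_equal(labels, est.labels_)
        assert np.array_equal(labels, truth)
        assert (np.diff(est.centers_) > 0).all()

    def test_predict_before_fit_rejected(self):
        with pytest.raises(ParameterError):
            MIAClusterSegmenter().predict()

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            SegmentationConfig(n_classes=1, grid_size=7)
        with pytest.raises(ParameterError):
            SegmentationConfig(n_classes=2, grid_size=2)
        with pytest.raises(ParameterError):
            SegmentationConfig(n_classes=2, grid_size=7, overlap_stride=9)
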