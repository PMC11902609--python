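"""Tissue-classifier unit tests: votes, unknown rule, objects, shape filter."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from busseg import classify as cl
from busseg.errors import InvalidInputError, InvalidParameterError, TrainingError


@dataclass
class _StubTree:
    label: int

    def predict(self, x):
        return np.full(x.shape[0], self.label)


class _StubForest:
    """A forest whose trees cast fixed votes — isolates the vote arithmetic."""

    def __init__(self, votes_per_class):
        self.classes_ = np.arange(len(votes_per_class))
        self.estimators_ = [
            _StubTree(c) for c, n in enumerate(votes_per_class) for _ in range(n)
        ]


def stub_model(votes_per_class, n_classes=None):
    n_classes = n_classes or len(votes_per_class)
    names = tuple(f"class{i}" for i in range(n_classes))
    forest = _StubForest(votes_per_class)
    forest.classes_ = np.arange(n_classes)
    return cl.TissueModel(forest=forest, class_list=names, sigmas=(1.0, 2.0),
                          n_trees=len(forest.estimators_))


def two_band_frames(n_frames, seed):
    """Bright finely-textured band over dark coarse band: separable by design."""
    rng = np.random.default_rng(seed)
    frames, annotations = [], []
    for _ in range(n_frames):
        top = np.clip(180 + 40 * rng.standard_normal((32, 64)), 0, 255)
        bottom = np.clip(60 + 8 * rng.standard_normal((32, 64)), 0, 255)
        frames.append(np.vstack([top, bottom]).astype(np.uint8))
        annotations.append(np.vstack([np.zeros((32, 64), int),
                                      np.ones((32, 64), int)]))
    return frames, annotations


class TestVoteProbabilities:
    def test_published_vote_example(self):
        # 30 of 50 trees vote class 1 (fat), 20 vote class 0 (skin)
        model = stub_model([20, 30])
        frame = np.random.default_rng(0).integers(0, 256, (5, 5)).astype(np.uint8)
        probs, labels = cl.classify(model, frame)
        assert np.allclose(probs[..., 0], 0.4)
        assert np.allclose(probs[..., 1], 0.6)
        assert (labels == 1).all()

    def test_below_threshold_is_unknown(self):
        # best class gets 9/50 = 0.18 < 0.20
        model = stub_model([9, 9, 9, 9, 9, 5])
        frame = np.zeros((4, 4), dtype=np.uint8)
        probs, labels = cl.classify(model, frame, unknown_threshold=0.20)
        assert probs.max() == pytest.approx(0.18)
        assert (labels == cl.UNKNOWN).all()

    def test_unanimous_vote(self):
        model = stub_model([0, 0, 50])
        probs, labels = cl.classify(model, np.zeros((3, 3), np.uint8))
        assert np.allclose(probs[..., 2], 1.0)
        assert (labels == 2).all()

    def test_rows_sum_to_one_and_label_is_argmax(self, trained_model):
        rng = np.random.default_rng(2)
        frame = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        probs, labels = cl.classify(trained_model, frame,
                                    unknown_threshold=0.3)
        flat = probs.reshape(-1, probs.shape[-1])
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-9)
        argmax = flat.argmax(axis=1).reshape(labels.shape)
        confident = flat.max(axis=1).reshape(labels.shape) >= 0.3
        assert (labels[confident] == argmax[confident]).all()
        assert (labels[~confident] == cl.UNKNOWN).all()


class TestTraining:
    def test_two_class_phantom_heldout_accuracy(self):
        frames, annotations = two_band_frames(4, seed=0)
        model = cl.train_model(frames[:3], annotations[:3],
                               class_list=("bright", "dark"),
                               sigmas=(1.0, 2.0, 4.0), seed=0)
        _, labels = cl.classify(model, frames[3], unknown_threshold=0.0)
        accuracy = (labels == annotations[3]).mean()
        assert accuracy > 0.9

    def test_single_tree_degenerate_forest(self):
        frames, annotations = two_band_frames(1, seed=1)
        model = cl.train_model(frames, annotations, ("bright", "dark"),
                               n_trees=1, sigmas=(1.0,), seed=0)
        _, labels = cl.classify(model, frames[0], unknown_threshold=0.0)
        assert set(np.unique(labels)) <= {0, 1}

    def test_deterministic_given_seed(self):
        frames, annotations = two_band_frames(2, seed=2)
        kwargs = dict(class_list=("bright", "dark"), sigmas=(1.0, 2.0), seed=7)
        m1 = cl.train_model(frames, annotations, **kwargs)
        m2 = cl.train_model(frames, annotations, **kwargs)
        probe = two_band_frames(1, seed=3)[0][0]
        _, l1 = cl.classify(m1, probe)
        _, l2 = cl.classify(m2, probe)
        assert np.array_equal(l1, l2)

    def test_missing_class_named_in_error(self):
        frames, annotations = two_band_frames(1, seed=4)
        with pytest.raises(TrainingError, match="ghost"):
            cl.train_model(frames, annotations,
                           class_list=("bright", "dark", "ghost"),
                           sigmas=(1.0,), seed=0)

    def test_save_load_roundtrip_bit_identical(self, tmp_path):
        frames, annotations = two_band_frames(2, seed=5)
        model = cl.train_model(frames, annotations, ("bright", "dark"),
                               sigmas=(1.0, 2.0), seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = cl.TissueModel.load(path)
        assert loaded.class_list == model.class_list
        assert loaded.sigmas == model.sigmas
        probe = frames[0]
        p1, l1 = cl.classify(model, probe)
        p2, l2 = cl.classify(loaded, probe)
        assert np.array_equal(p1, p2)
        assert np.array_equal(l1, l2)


class TestRefineUnknownMask:
    def test_dilation_merges_nearby_pixels(self):
        from skimage import measure
        labels = np.zeros((9, 9), int)
        labels[4, 3] = cl.UNKNOWN
        labels[4, 5] = cl.UNKNOWN
        mask = cl.refine_unknown_mask(labels, dilation_radius=1, median_size=1)
        assert measure.label(mask, connectivity=2).max() == 1

    def test_median_removes_isolated_pixel(self):
        labels = np.zeros((9, 9), int)
        labels[4, 4] = cl.UNKNOWN
        mask = cl.refine_unknown_mask(labels, dilation_radius=0, median_size=3)
        assert not mask.any()

    def test_empty_input_empty_output(self):
        mask = cl.refine_unknown_mask(np.zeros((6, 6), int))
        assert not mask.any()

    def test_dense_cluster_survives_and_grows(self):
        labels = np.zeros((12, 12), int)
        labels[4:8, 4:8] = cl.UNKNOWN
        mask = cl.refine_unknown_mask(labels, dilation_radius=2, median_size=3)
        assert mask[4:8, 4:8].all()
        assert mask.sum() > 16  # dilation never removes a set pixel

    def test_even_median_rejected(self):
        with pytest.raises(InvalidParameterError):
            cl.refine_unknown_mask(np.zeros((5, 5), int), median_size=4)


class TestExtractObjects:
    def test_filled_square_statistics(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        frame = np.where(mask, 50, 200).astype(np.uint8)
        objs = cl.extract_objects(mask, frame)
        assert len(objs) == 1
        obj = objs[0]
        assert obj.area == 100
        assert obj.mean_intensity == pytest.approx(50.0)
        assert obj.eccentricity < 0.1
        cx, cy = obj.center
        assert cx == pytest.approx(9.5, abs=0.5)
        assert cy == pytest.approx(9.5, abs=0.5)

    def test_two_disjoint_blobs(self):
        mask = np.zeros((20, 20), bool)
        mask[2:6, 2:6] = True
        mask[12:17, 12:17] = True
        assert len(cl.extract_objects(mask, np.zeros((20, 20)))) == 2

    def test_thin_line_elongated(self):
        mask = np.zeros((10, 40), bool)
        mask[5, 5:35] = True
        obj = cl.extract_objects(mask, np.zeros((10, 40)))[0]
        assert obj.eccentricity > 0.9
        assert obj.shape_ratio > 0.1
        # second-moment oracle: eccentricity from raw pixel moments
        rows, cols = np.nonzero(mask)
        mu_rr = ((rows - rows.mean()) ** 2).mean() + 1 / 12
        mu_cc = ((cols - cols.mean()) ** 2).mean() + 1 / 12
        a2, b2 = max(mu_rr, mu_cc), min(mu_rr, mu_cc)
        assert obj.eccentricity == pytest.approx(np.sqrt(1 - b2 / a2), abs=0.01)


class TestFilterArtifacts:
    def _obj(self, intensity, ecc, ratio):
        contour = np.array([[0.0, 0.0]])
        area = 100
        return cl.CandidateObject(
            coords=np.zeros((area, 2), int), contour=contour,
            mean_intensity=intensity, eccentricity=ecc,
            perimeter=ratio * area, area=area, bbox=(0, 0, 1, 1))

    def test_all_three_criteria_remove(self):
        objs = [self._obj(100, 0.95, 0.12)]
        assert cl.filter_artifacts(objs) == []

    def test_round_object_kept_regardless_of_intensity(self):
        objs = [self._obj(250, 0.05, 0.5)]
        assert len(cl.filter_artifacts(objs)) == 1

    def test_boundary_intensity_kept(self):
        objs = [self._obj(93.0, 0.95, 0.12)]  # strict inequality
        assert len(cl.filter_artifacts(objs)) == 1

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_idempotent_and_single_criterion_never_removes(self, seed):
        rng = np.random.default_rng(seed)
        objs = [self._obj(rng.uniform(0, 255), rng.uniform(0, 1),
                          rng.uniform(0, 0.3)) for _ in range(8)]
        kept = cl.filter_artifacts(objs)
        assert cl.filter_artifacts(kept) == kept
        for obj in objs:
            fails = [obj.mean_intensity > 93, obj.eccentricity > 0.9,
                     obj.shape_ratio > 0.1]
            if sum(fails) < 3:
                assert obj in kept


class TestObjectCenter:
    def test_square_contour_symmetry(self):
        contour = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2],
                            [1, 2], [0, 2], [0, 1]], dtype=float)
        assert cl.object_center(contour) == (1.0, 1.0)

    def test_single_point(self):
        assert cl.object_center(np.array([[5.0, 7.0]])) == (5.0, 7.0)

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (20, 2))
        cx, cy = cl.object_center(pts)
        assert cx == pytest.approx(pts[:, 0].sum() / 20)
        assert cy == pytest.approx(pts[:, 1].sum() / 20)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            cl.object_center(np.empty((0, 2)))


class TestRoiBoxes:
    def _obj_with_bbox(self, bbox):
        return cl.CandidateObject(
            coords=np.zeros((1, 2), int), contour=np.array([[0.0, 0.0]]),
            mean_intensity=0, eccentricity=0, perimeter=1, area=1, bbox=bbox)

    def test_zero_padding_is_exact_bbox(self):
        box = cl.roi_boxes([self._obj_with_bbox((10, 10, 20, 20))],
                           (100, 100), pad_fraction=0.0)[0]
        assert (box.top, box.left, box.bottom, box.right) == (10, 10, 20, 20)

    def test_half_padding_arithmetic(self):
        box = cl.roi_boxes([self._obj_with_bbox((10, 10, 20, 20))],
                           (100, 100), pad_fraction=0.5)[0]
        assert (box.top, box.left, box.bottom, box.right) == (5, 5, 25, 25)

    def test_clipped_to_frame(self):
        box = cl.roi_boxes([self._obj_with_bbox((0, 90, 10, 100))],
                           (100, 100), pad_fraction=0.5)[0]
        assert box.top == 0 and box.right == 100
        assert box.contains(95, 5)
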