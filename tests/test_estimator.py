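import numpy as np
import pandas as pd
import pytest

import avve
from avve.errors import (
    DegenerateFeatureError,
    DegenerateLabelsError,
    GridAlignmentError,
    InvalidSplitError,
    MissingFeatureError,
)
from avve.estimator import TrainedEstimator, expand_categorical
from avve.voxel_features import FeatureTable


def separable_table(seed=0, n_subjects=8, rows=120, shift=3.0, sd=0.5):
    """Linearly separable two-feature table grouped into subjects."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        y = np.repeat([0, 1], rows // 2)
        frames.append(
            pd.DataFrame(
                {
                    "fa": rng.normal(shift * (2 * y - 1), sd),
                    "fb": rng.normal(-shift * (2 * y - 1), sd),
                    "label": y,
                    "subject_id": f"s{s}",
                }
            )
        )
    return FeatureTable(
        frame=pd.concat(frames, ignore_index=True),
        feature_names=("fa", "fb"),
        grids={f"s{s}": None for s in range(n_subjects)},
    )


class TestSplitBySubject:
    def test_cohort_of_44_splits_33_train_11_test(self):
        ids = [f"p{i}" for i in range(44)]
        splits = avve.split_by_subject(ids, fraction=0.75, folds=6, seed=0)
        assert len(splits) == 6
        for s in splits:
            assert len(s.train_ids) == 33
            assert len(s.test_ids) == 11

    def test_two_subjects_half_fraction(self):
        splits = avve.split_by_subject(["a", "b"], fraction=0.5, folds=2, seed=1)
        for s in splits:
            assert len(s.train_ids) == 1 and len(s.test_ids) == 1

    def test_sides_are_disjoint_and_exhaustive(self):
        ids = [f"p{i}" for i in range(13)]
        for s in avve.split_by_subject(ids, folds=5, seed=3):
            assert not (set(s.train_ids) & set(s.test_ids))
            assert set(s.train_ids) | set(s.test_ids) == set(ids)

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(10)]
        a = avve.split_by_subject(ids, seed=9)
        b = avve.split_by_subject(ids, seed=9)
        assert [s.train_ids for s in a] == [s.train_ids for s in b]

    @pytest.mark.parametrize("ids, fraction", [
        (["only"], 0.5),          # single subject
        (["a", "b"], 0.95),       # rounds to empty test side
        (["a", "b", "c"], 1.5),   # fraction out of range
    ])
    def test_degenerate_splits_rejected(self, ids, fraction):
        with pytest.raises(InvalidSplitError):
            avve.split_by_subject(ids, fraction=fraction)


class TestStandardize:
    def test_fit_and_transform_zero_mean_unit_sd(self):
        table = separable_table()
        scaled, params = avve.standardize(table)
        for name in table.feature_names:
            col = scaled.frame[name]
            assert abs(col.mean()) < 1e-9
            assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert set(params) == {"fa", "fb"}

    def test_out_of_sample_transform_need_not_center(self):
        table = separable_table(seed=1)
        _, params = avve.standardize(table)
        shifted = separable_table(seed=2)
        shifted.frame["fa"] += 5.0
        scaled, _ = avve.standardize(shifted, params)
        assert abs(scaled.frame["fa"].mean()) > 0.5

    def test_constant_feature_named_in_error(self):
        table = separable_table()
        table.frame["fb"] = 7.0
        with pytest.raises(DegenerateFeatureError, match="fb"):
            avve.standardize(table)


class TestTrainEstimator:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        table = separable_table(seed=0)
        est = avve.train_estimator(table, categorical_features=())
        X, y = table.features_matrix(), table.labels()
        assert (est.predict(X) == (y == 1)).mean() == 1.0

    def test_training_is_deterministic(self):
        table = separable_table(seed=1)
        e1 = avve.train_estimator(table, seed=4, categorical_features=())
        e2 = avve.train_estimator(table, seed=4, categorical_features=())
        assert e1.weights == e2.weights
        assert e1.bias == e2.bias

    def test_holds_up_on_subjects_from_same_process(self):
        table = separable_table(seed=2, n_subjects=10)
        split = avve.split_by_subject(table.subject_ids, folds=1, seed=0)[0]
        est = avve.train_estimator(table, split=split, categorical_features=())
        test_rows = table.frame["subject_id"].isin(split.test_ids).to_numpy()
        X = table.features_matrix()[test_rows]
        y = table.labels()[test_rows]
        assert (est.predict(X) == (y == 1)).mean() >= 0.95

    def test_single_class_training_rejected(self):
        table = separable_table()
        table.frame["label"] = 1
        with pytest.raises(DegenerateLabelsError):
            avve.train_estimator(table, categorical_features=())

    def test_negative_subsampling_keeps_all_positives(self):
        table = separable_table(seed=3)
        est = avve.train_estimator(
            table, subsample_negatives=1.0, categorical_features=()
        )
        n_pos = int(table.labels().sum())
        assert est.metadata["n_train_rows"] == 2 * n_pos

    def test_json_round_trip(self, tmp_path):
        table = separable_table(seed=4)
        est = avve.train_estimator(table, categorical_features=())
        path = tmp_path / "model.json"
        est.to_json(path)
        back = TrainedEstimator.from_json(path)
        assert back == est


class TestCategoricalEncoding:
    def test_indicator_expansion(self):
        X = np.array([[1.0, 5.0], [2.0, 6.0], [1.0, 7.0]])
        Xe, names = expand_categorical(X, ("cls", "cont"), {"cls": (1.0, 2.0)})
        assert names == ("cls==1", "cls==2", "cont")
        np.testing.assert_array_equal(Xe[:, 0], [1, 0, 1])
        np.testing.assert_array_equal(Xe[:, 1], [0, 1, 0])
        np.testing.assert_array_equal(Xe[:, 2], X[:, 1])

    def test_estimator_learns_nonmonotone_class_rule(self):
        """A middle category marks the positive class: impossible for a single
        ordinal column under a linear rule, easy once indicator-encoded."""
        rng = np.random.default_rng(0)
        frames = []
        for s in range(4):
            cls = rng.integers(1, 5, 400).astype(float)
            y = (cls == 2).astype(int)
            frames.append(
                pd.DataFrame(
                    {"cls": cls, "cont": rng.normal(size=400), "label": y,
                     "subject_id": f"s{s}"}
                )
            )
        table = FeatureTable(
            frame=pd.concat(frames, ignore_index=True),
            feature_names=("cls", "cont"),
            grids={f"s{s}": None for s in range(4)},
        )
        est = avve.train_estimator(table, categorical_features=("cls",))
        acc = (est.predict(table.features_matrix()) == (table.labels() == 1)).mean()
        assert acc == 1.0


class TestPredictMask:
    def _toy_estimator(self):
        return TrainedEstimator(
            base_features=("normalized_distance",),
            encodings={},
            feature_names=("normalized_distance",),
            means=(10.0,),
            sds=(5.0,),
            weights=(-1.0,),
            bias=0.0,
        )

    def test_positive_region_reassembled_on_grid(self):
        est = self._toy_estimator()
        vol = avve.VolumeImage(np.zeros((9, 9, 9)), np.eye(4), (1, 1, 1))
        nd = avve.normalized_distance(vol)
        mask = avve.predict_mask(est, vol, {"normalized_distance": nd})
        # decision = -(nd - 10)/5 > 0  <=>  nd < 10
        np.testing.assert_array_equal(mask.data, nd < 10)

    def test_missing_feature_named(self):
        est = self._toy_estimator()
        vol = avve.VolumeImage(np.zeros((5, 5, 5)), np.eye(4), (1, 1, 1))
        with pytest.raises(MissingFeatureError, match="normalized_distance"):
            avve.predict_mask(est, vol, {})

    def test_wrong_grid_rejected(self):
        est = self._toy_estimator()
        vol = avve.VolumeImage(np.zeros((5, 5, 5)), np.eye(4), (1, 1, 1))
        with pytest.raises(GridAlignmentError):
            avve.predict_mask(est, vol, {"normalized_distance": np.zeros((4, 5, 5))})
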