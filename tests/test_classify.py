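"""Linear SVM training, probability prediction, F1 and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from stsig import classify
from stsig.types import CLASSES, LOGNORM, RAW, SpotMatrix


def _toy(n_per_class=10, margin=5.0, seed=0, dataset="d1", n_features=2):
    """Linearly separable 3-class blobs in log space."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, n_features))
    centers[0, 0] = 0.0
    centers[1, 0] = 2 * margin
    centers[2, 1] = 2 * margin
    rows, labels = [], []
    for k, cls in enumerate(CLASSES):
        rows.append(centers[k] + 0.3 * rng.normal(size=(n_per_class, n_features)))
        labels.extend([cls] * n_per_class)
    X = np.abs(np.vstack(rows))
    idx = pd.MultiIndex.from_tuples(
        [(dataset, i + 1, 1) for i in range(len(X))],
        names=["dataset", "x", "y"])
    m = SpotMatrix(pd.DataFrame(X, index=idx,
                                columns=[f"tc{i}" for i in range(n_features)]),
                   LOGNORM)
    return m, pd.Series(labels, index=idx)


class TestTrainPredict:
    def test_separable_toy_perfect_training_accuracy(self):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        result = classify.predict(model, m)
        assert (result.predicted == labels).all()

    def test_probability_rows_sum_to_one(self):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        probs = classify.predict(model, m).probabilities.to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_duplicating_training_spots_keeps_boundaries(self):
        m, labels = _toy()
        dup_df = pd.concat([m.df, m.df.set_axis(
            pd.MultiIndex.from_tuples([("d1", x + 100, y) for (_d, x, y) in m.df.index],
                                      names=["dataset", "x", "y"]))])
        dup_labels = pd.concat([labels, labels.set_axis(dup_df.index[len(labels):])])
        m2 = SpotMatrix(dup_df, LOGNORM)
        a = classify.train({"d1": m}, labels, feature_mode="all")
        b = classify.train({"d1": m2}, dup_labels, feature_mode="all")
        ra, rb = classify.predict(a, m), classify.predict(b, m)
        # duplication rescales the loss-vs-margin trade-off slightly, so
        # probabilities can drift at the percent level; the decision
        # boundaries (predicted labels) must not move
        assert (ra.predicted == rb.predicted).all()
        np.testing.assert_allclose(ra.probabilities.to_numpy(),
                                   rb.probabilities.to_numpy(), atol=0.05)

    def test_permuting_test_rows_permutes_output(self, rng):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        perm = rng.permutation(m.shape[0])
        shuffled = SpotMatrix(m.df.iloc[perm], LOGNORM)
        a = classify.predict(model, m).probabilities.to_numpy()[perm]
        b = classify.predict(model, shuffled).probabilities.to_numpy()
        np.testing.assert_allclose(a, b)

    def test_all_zero_spot_is_valid_distribution(self):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        zero = SpotMatrix(
            pd.DataFrame([[0.0, 0.0]], columns=["tc0", "tc1"],
                         index=pd.MultiIndex.from_tuples(
                             [("dz", 1, 1)], names=["dataset", "x", "y"])),
            LOGNORM)
        probs = classify.predict(model, zero).probabilities.to_numpy()
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-9)

    def test_missing_test_features_impute_zero(self):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        partial = SpotMatrix(m.df[["tc0"]], LOGNORM)
        out = classify.predict(model, partial)
        assert out.probabilities.shape == (m.shape[0], 3)

    def test_signature_mode_needs_known_ids(self):
        m, labels = _toy()
        with pytest.raises(ValueError, match="unknown feature"):
            classify.train({"d1": m}, labels, feature_mode="signature",
                           signature=["nope"])

    def test_single_class_raises(self):
        m, labels = _toy()
        only = labels[labels == "DCIS"]
        with pytest.raises(ValueError, match="2 classes"):
            classify.train({"d1": m}, only, feature_mode="all")

    def test_empty_test_matrix_raises(self):
        m, labels = _toy()
        model = classify.train({"d1": m}, labels, feature_mode="all")
        empty = SpotMatrix(m.df.iloc[:0], LOGNORM)
        with pytest.raises(ValueError, match="empty"):
            classify.predict(model, empty)


class TestF1:
    def _series(self, values):
        idx = pd.MultiIndex.from_tuples(
            [("d", i, 1) for i in range(len(values))],
            names=["dataset", "x", "y"])
        return pd.Series(values, index=idx)

    def test_perfect_prediction(self):
        truth = self._series(["DCIS", "IDC", "non-malignant"])
        f1 = classify.f1_per_class(truth, truth)
        assert (f1 == 1.0).all()

    def test_formula_example(self):
        # DCIS: TP=8, FP=1, FN=3 -> 16/20 = 0.8
        truth = self._series(["DCIS"] * 11 + ["IDC"] * 1 + ["IDC"] * 5)
        pred = self._series(["DCIS"] * 8 + ["IDC"] * 3 + ["DCIS"] * 1 + ["IDC"] * 5)
        f1 = classify.f1_per_class(pred, truth)
        assert f1["DCIS"] == pytest.approx(0.8)

    def test_absent_class_scores_zero(self):
        truth = self._series(["DCIS", "DCIS"])
        pred = self._series(["DCIS", "DCIS"])
        f1 = classify.f1_per_class(pred, truth)
        assert f1["IDC"] == 0.0 and f1["non-malignant"] == 0.0

    def test_unassigned_truth_excluded(self):
        truth = self._series(["DCIS", "unassigned"])
        pred = self._series(["DCIS", "IDC"])
        f1 = classify.f1_per_class(pred, truth)
        assert f1["DCIS"] == 1.0 and f1["IDC"] == 0.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score
        truth = self._series(rng.choice(CLASSES, size=60))
        pred = self._series(rng.choice(CLASSES, size=60))
        mine = classify.f1_per_class(pred, truth)
        ref = f1_score(truth.to_numpy(), pred.to_numpy(),
                       labels=list(CLASSES), average=None, zero_division=0)
        np.testing.assert_allclose(mine.to_numpy(), ref)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify.f1_per_class(self._series(["DCIS"]),
                                  self._series(["DCIS", "IDC"]))


class TestLeaveOneDatasetOut:
    def _raw_pair(self, seed=3):
        """Two identical sections with separable class expression."""
        rng = np.random.default_rng(seed)
        n_per_class, n_tcs = 12, 60
        base = rng.integers(20, 60, size=n_tcs)
        counts = np.tile(base, (3 * n_per_class, 1))
        for k in range(3):
            counts[k * n_per_class:(k + 1) * n_per_class,
                   k * 10:(k + 1) * 10] *= 12
        mats, labels_parts = {}, []
        for ds in ("s1", "s2"):
            idx = pd.MultiIndex.from_tuples(
                [(ds, i + 1, 1) for i in range(3 * n_per_class)],
                names=["dataset", "x", "y"])
            cols = [f"chr1:{i * 100}-{i * 100 + 10}:+" for i in range(n_tcs)]
            mats[ds] = SpotMatrix(pd.DataFrame(counts, index=idx, columns=cols),
                                  RAW)
            labels_parts.append(pd.Series(
                np.repeat(list(CLASSES), n_per_class), index=idx))
        return mats, pd.concat(labels_parts)

    @pytest.mark.parametrize("mode", ["signature", "all"])
    def test_identical_separable_sections_score_one(self, mode):
        mats, labels = self._raw_pair()
        report = classify.leave_one_dataset_out(
            mats, labels, feature_mode=mode,
            min_spot_counts=10, min_spot_features=10, min_tc_spots=2)
        assert (report.f1.loc[["s1", "s2"]].to_numpy() == 1.0).all()
        assert (report.f1.loc["Avg"] == 1.0).all()

    def test_report_shape_and_mean_row(self, small_pipeline):
        from .conftest import SMALL_FILTER
        mats = {ds: small_pipeline.matrix.for_dataset(ds)
                for ds in small_pipeline.matrix.datasets}
        report = classify.leave_one_dataset_out(
            mats, small_pipeline.labels, feature_mode="all", **SMALL_FILTER)
        assert list(report.f1.columns) == list(CLASSES)
        assert list(report.f1.index) == list(mats) + ["Avg"]
        np.testing.assert_allclose(
            report.f1.loc["Avg"].to_numpy(),
            report.f1.drop(index="Avg").mean(axis=0).to_numpy())

    def test_shuffled_labels_destroy_transfer(self, small_pipeline, rng):
        from .conftest import SMALL_FILTER
        mats = {ds: small_pipeline.matrix.for_dataset(ds)
                for ds in small_pipeline.matrix.datasets}
        labels = small_pipeline.labels
        shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
        good = classify.leave_one_dataset_out(mats, labels, feature_mode="all",
                                              **SMALL_FILTER)
        bad = classify.leave_one_dataset_out(mats, shuffled, feature_mode="all",
                                             **SMALL_FILTER)
        assert good.f1.loc["Avg"].mean() >= 0.9
        assert bad.f1.loc["Avg"].mean() < 0.5

    def test_two_datasets_required(self, small_pipeline):
        mats = {"only": small_pipeline.matrix.for_dataset("dataset_1")}
        with pytest.raises(ValueError):
            classify.leave_one_dataset_out(mats, small_pipeline.labels)
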