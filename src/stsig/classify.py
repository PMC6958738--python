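"""Linear multi-class SVM label transfer and leave-one-dataset-out scoring.

Training spots from one or more sections are pooled and a one-vs-rest
linear maximum-margin classifier (fixed cost C=1, the library default) is
fitted per class on log-normalized expression of either the signature tag
clusters or all shared tag clusters. Per-spot class probabilities are the
softmax (temperature 1) of the three decision values, which keeps runs
deterministic; Platt-style calibration is available behind a flag.

Train and test sections are normalized independently, each with its own
size factors, and aligned by tag-cluster id (features absent from a
section contribute log value 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import LinearSVC

from . import preprocess
from .signature import SignatureSet, derive_signature
from .types import CLASSES, SpotMatrix, RAW, LOGNORM

__all__ = ["SvmModel", "PredictionResult", "EvaluationReport", "train",
           "predict", "f1_per_class", "confusion_counts",
           "leave_one_dataset_out"]

FEATURE_MODES = ("signature", "all")


@dataclass
class SvmModel:
    classes: tuple[str, ...]
    feature_ids: list[str]
    estimator: object
    feature_mode: str
    calibration: str
    training_datasets: list[str]

    @property
    def coef_(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def intercept_(self) -> np.ndarray:
        return self.estimator.intercept_


@dataclass
class PredictionResult:
    probabilities: pd.DataFrame          # spots x classes, rows sum to 1
    predicted: pd.Series                 # spot -> class

    @property
    def spot_keys(self) -> list:
        return list(self.probabilities.index)


@dataclass
class EvaluationReport:
    """Per held-out dataset and class F1, with an appended mean row."""

    f1: pd.DataFrame                     # index: datasets + "Avg"
    confusion: dict[str, pd.DataFrame] = field(default_factory=dict)
    predictions: dict[str, PredictionResult] = field(default_factory=dict)
    signatures: dict[str, SignatureSet] = field(default_factory=dict)
    feature_mode: str = "signature"

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Display copy rounded half-even; full precision stays in ``f1``."""
        return self.f1.round(decimals)


def _decision_matrix(est, X: np.ndarray, n_classes: int) -> np.ndarray:
    dec = est.decision_function(X)
    if dec.ndim == 1:                    # two-class estimator: +/- one margin
        dec = np.column_stack([-dec, dec])
    if dec.shape[1] != n_classes:
        full = np.full((dec.shape[0], n_classes), -np.inf)
        for k, cls_idx in enumerate(est.classes_):
            full[:, cls_idx] = dec[:, k]
        dec = full
    return dec


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def train(matrices: Mapping[str, SpotMatrix], labels: pd.Series,
          feature_mode: str = "signature",
          signature: SignatureSet | Sequence[str] | None = None,
          C: float = 1.0, calibration: str = "softmax") -> SvmModel:
    """Fit the one-vs-rest linear SVM on pooled labeled training spots.

    Parameters
    ----------
    matrices
        Per-dataset *log-normalized* matrices (each normalized with its own
        size factors).
    labels
        Series over (dataset, x, y); only canonical class values are used.
    feature_mode
        ``"signature"`` restricts features to the signature tag clusters;
        ``"all"`` uses every shared tag cluster.
    signature
        The signature set (required in signature mode).
    """
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    for ds, m in matrices.items():
        if m.space != LOGNORM:
            raise ValueError(f"training matrix {ds!r} is not log-normalized")
    universe: list[str] = list(dict.fromkeys(
        tc for m in matrices.values() for tc in m.tc_ids))
    if feature_mode == "signature":
        if signature is None:
            raise ValueError("signature mode needs a signature")
        feature_ids = list(signature.selected_tc_ids
                           if isinstance(signature, SignatureSet) else signature)
        if not feature_ids:
            raise ValueError("signature mode needs a non-empty signature")
        unknown = [tc for tc in feature_ids if tc not in set(universe)]
        if unknown:
            raise ValueError(f"unknown feature id(s): {unknown[:3]}")
    else:
        feature_ids = universe

    pooled = SpotMatrix.concat([m for m in matrices.values()]).reindex_tcs(feature_ids)
    labels = labels[labels.isin(CLASSES)]
    keys = pooled.df.index.intersection(labels.index)
    if len(keys) == 0:
        raise ValueError("no labeled training spots")
    X = pooled.df.loc[keys].to_numpy(dtype=float)
    y_names = labels.loc[keys]
    present = sorted(set(y_names), key=CLASSES.index)
    if len(present) < 2:
        raise ValueError("training needs at least 2 classes")
    y = y_names.map({c: i for i, c in enumerate(CLASSES)}).to_numpy()

    base = LinearSVC(C=C, dual=False)
    if calibration == "softmax":
        est = base.fit(X, y)
    elif calibration == "platt":
        est = CalibratedClassifierCV(base, method="sigmoid", cv=3).fit(X, y)
    else:
        raise ValueError("calibration must be 'softmax' or 'platt'")
    return SvmModel(
        classes=CLASSES, feature_ids=feature_ids, estimator=est,
        feature_mode=feature_mode, calibration=calibration,
        training_datasets=list(matrices),
    )


def predict(model: SvmModel, matrix: SpotMatrix) -> PredictionResult:
    """Class probabilities and argmax label for every spot of a matrix."""
    if matrix.space != LOGNORM:
        raise ValueError("predict expects a log-normalized matrix")
    if matrix.shape[0] == 0:
        raise ValueError("empty test matrix")
    X = matrix.reindex_tcs(model.feature_ids).df.to_numpy(dtype=float)
    if model.calibration == "platt":
        probs = model.estimator.predict_proba(X)
        if probs.shape[1] != len(CLASSES):
            raise ValueError("calibrated model is missing a class")
    else:
        probs = _softmax(_decision_matrix(model.estimator, X, len(CLASSES)))
    probs_df = pd.DataFrame(probs, index=matrix.df.index, columns=list(CLASSES))
    # argmax takes the first maximum, i.e. the canonical class order on ties
    predicted = pd.Series(
        [CLASSES[i] for i in np.argmax(probs, axis=1)],
        index=matrix.df.index, name="predicted",
    )
    return PredictionResult(probabilities=probs_df, predicted=predicted)


def f1_per_class(predicted: pd.Series, truth: pd.Series) -> pd.Series:
    """Per-class F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0.

    Spots whose truth label is not one of the three classes are excluded.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    keep = truth.isin(CLASSES).to_numpy()
    pred = predicted.to_numpy()[keep]
    true = truth.to_numpy()[keep]
    out = {}
    for cls in CLASSES:
        tp = int(np.sum((pred == cls) & (true == cls)))
        fp = int(np.sum((pred == cls) & (true != cls)))
        fn = int(np.sum((pred != cls) & (true == cls)))
        denom = 2 * tp + fp + fn
        out[cls] = 2 * tp / denom if denom else 0.0
    return pd.Series(out, name="F1")


def confusion_counts(predicted: pd.Series, truth: pd.Series) -> pd.DataFrame:
    keep = truth.isin(CLASSES).to_numpy()
    pred = predicted.to_numpy()[keep]
    true = truth.to_numpy()[keep]
    tab = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for t, p in zip(true, pred):
        if p in tab.columns:
            tab.loc[t, p] += 1
    tab.index.name = "truth"
    tab.columns.name = "predicted"
    return tab


def prepare_dataset(matrix: SpotMatrix,
                    min_spot_counts: int = preprocess.DEFAULT_MIN_SPOT_COUNTS,
                    min_spot_features: int = preprocess.DEFAULT_MIN_SPOT_FEATURES,
                    min_tc_spots: int = preprocess.DEFAULT_MIN_TC_SPOTS
                    ) -> tuple[SpotMatrix, pd.Series, SpotMatrix]:
    """Filter one section and normalize it with its own size factors.

    Returns ``(filtered_raw, size_factors, log_matrix)``.
    """
    filtered = preprocess.filter_matrix(
        matrix, min_spot_counts=min_spot_counts,
        min_spot_features=min_spot_features, min_tc_spots=min_tc_spots,
    )
    sf = preprocess.size_factors(filtered)
    return filtered, sf, preprocess.normalize_log(filtered, sf)


def leave_one_dataset_out(matrices: Mapping[str, SpotMatrix], labels: pd.Series,
                          feature_mode: str = "signature",
                          lfc_threshold: float = 2.0,
                          fdr_threshold: float = 0.01,
                          C: float = 1.0,
                          min_spot_counts: int = preprocess.DEFAULT_MIN_SPOT_COUNTS,
                          min_spot_features: int = preprocess.DEFAULT_MIN_SPOT_FEATURES,
                          min_tc_spots: int = preprocess.DEFAULT_MIN_TC_SPOTS
                          ) -> EvaluationReport:
    """Rotate each section out as the test set; report per-class F1.

    For every held-out section the remaining sections are pooled for
    training; in signature mode the signature is derived from the training
    sections only, so no information from the held-out section leaks into
    feature selection. Sections without a labeled spot are skipped.
    """
    if len(matrices) < 2:
        raise ValueError("leave-one-dataset-out needs at least 2 datasets")
    labels = labels[labels.isin(CLASSES)]
    prepared = {
        ds: prepare_dataset(m, min_spot_counts=min_spot_counts,
                            min_spot_features=min_spot_features,
                            min_tc_spots=min_tc_spots)
        for ds, m in matrices.items()
    }
    universe = list(dict.fromkeys(
        tc for m in matrices.values() for tc in m.tc_ids))

    rows = {}
    report = EvaluationReport(f1=pd.DataFrame(), feature_mode=feature_mode)
    for held_out in matrices:
        test_log = prepared[held_out][2]
        test_keys = test_log.df.index.intersection(labels.index)
        if len(test_keys) == 0:
            import logging
            logging.getLogger(__name__).warning(
                "dataset %r has no labeled spot; skipped", held_out)
            continue
        train_ds = [ds for ds in matrices if ds != held_out]

        signature = None
        if feature_mode == "signature":
            raw_parts, sf_parts = [], []
            for ds in train_ds:
                filtered, sf, _log = prepared[ds]
                lab_keys = filtered.df.index.intersection(labels.index)
                raw_parts.append(
                    SpotMatrix(filtered.df.loc[lab_keys], RAW).reindex_tcs(universe))
                sf_parts.append(sf.loc[lab_keys])
            pooled_raw = SpotMatrix.concat(raw_parts)
            pooled_sf = pd.concat(sf_parts)
            signature = derive_signature(
                pooled_raw, labels, lfc_threshold=lfc_threshold,
                fdr_threshold=fdr_threshold, size_factors_=pooled_sf,
            )
            report.signatures[held_out] = signature

        model = train(
            {ds: prepared[ds][2] for ds in train_ds}, labels,
            feature_mode=feature_mode, signature=signature, C=C,
        )
        result = predict(model, test_log.subset_spots(list(test_keys)))
        truth = labels.loc[test_keys]
        rows[held_out] = f1_per_class(result.predicted, truth)
        report.confusion[held_out] = confusion_counts(result.predicted, truth)
        report.predictions[held_out] = result

    f1 = pd.DataFrame(rows).T
    f1.index.name = "dataset"
    f1.loc["Avg"] = f1.mean(axis=0)
    report.f1 = f1
    return report
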