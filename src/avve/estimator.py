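"""The voxel classifier: standardization, subject-grouped splitting, linear
max-margin training, and mask prediction.

Training data is always partitioned *by subject* (the 0.75:0.25 convention),
never by voxel, so no subject contributes voxels to both sides of a split and
fold scores are honest out-of-subject estimates.  Features are z-scored with
parameters fitted on the training rows only; the classifier is a linear SVM
whose regularization strength is tuned by grouped cross-validation within the
training subjects.  Ventricle voxels are a small fraction of a head FOV, so
classes are weighted by inverse frequency by default, with optional seeded
subsampling of the negative class for tractability on large tables.

The histogram-classified-intensity feature is a *categorical* parcellation
factor: R2 (CSF) is not metrically "between" background and grey matter, so it
enters the linear decision function as one indicator column per class — the
standard treatment of a categorical covariate in a linear model.  The feature
table keeps its one-column-per-feature layout; expansion happens here.

A trained estimator is a frozen, portable document: base feature names, the
categorical encodings, per-column (mean, sd), hyperplane weights and bias —
serialized as versioned JSON, never an opaque pickle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold
from sklearn.svm import LinearSVC

from .errors import (
    DegenerateFeatureError,
    DegenerateLabelsError,
    GridAlignmentError,
    InvalidSplitError,
    MissingFeatureError,
)
from .image_io import BinaryMask, VolumeImage
from .voxel_features import FeatureTable

__all__ = [
    "SubjectSplit",
    "TrainedEstimator",
    "split_by_subject",
    "standardize",
    "expand_categorical",
    "train_estimator",
    "predict_mask",
    "DEFAULT_CATEGORICAL",
]

ESTIMATOR_FORMAT_VERSION = 1

#: features treated as categorical (indicator-encoded) by default
DEFAULT_CATEGORICAL = ("hci",)


@dataclasses.dataclass(frozen=True)
class SubjectSplit:
    """Disjoint train/test subject-id sets for one fold."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fold_index: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise InvalidSplitError(f"subjects on both sides of split: {sorted(overlap)}")
        if not self.train_ids or not self.test_ids:
            raise InvalidSplitError("both train and test sides must be non-empty")


def split_by_subject(
    subject_ids: Sequence[str],
    fraction: float = 0.75,
    folds: int = 6,
    seed: int = 0,
) -> list[SubjectSplit]:
    """Seeded train/test subject partitions, one per fold.

    Each fold re-randomizes the partition: ``round(fraction * n)`` subjects
    train, the rest test.  With 44 subjects at the default 0.75 fraction each
    fold trains on 33 and tests on 11.
    """
    unique = list(dict.fromkeys(subject_ids))
    n = len(unique)
    if n < 2:
        raise InvalidSplitError(f"need at least 2 subjects, got {n}")
    if not (0.0 < fraction < 1.0):
        raise InvalidSplitError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise InvalidSplitError(
            f"fraction {fraction} with {n} subjects leaves an empty side"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for fold in range(folds):
        order = rng.permutation(n)
        train = tuple(unique[i] for i in sorted(order[:n_train]))
        test = tuple(unique[i] for i in sorted(order[n_train:]))
        splits.append(SubjectSplit(train_ids=train, test_ids=test, fold_index=fold))
    return splits


def standardize(
    table: FeatureTable,
    params: dict[str, tuple[float, float]] | None = None,
) -> tuple[FeatureTable, dict[str, tuple[float, float]]]:
    """Z-score the feature columns; label/subject columns untouched.

    With ``params`` absent, per-feature (mean, sd) are fitted on the given
    rows, so the scaled columns have mean 0 and sd 1 there; with ``params``
    supplied (fitted elsewhere) the same affine map is applied out-of-sample.

    Raises :class:`DegenerateFeatureError` naming any zero-variance feature.
    """
    frame = table.frame.copy()
    if params is None:
        params = {}
        for name in table.feature_names:
            col = frame[name].to_numpy(dtype=float)
            mean, sd = float(col.mean()), float(col.std())
            if sd < 1e-12:
                raise DegenerateFeatureError(
                    f"feature {name!r} has zero variance on the fitting rows"
                )
            params[name] = (mean, sd)
    for name in table.feature_names:
        mean, sd = params[name]
        frame[name] = (frame[name].to_numpy(dtype=float) - mean) / sd
    scaled = FeatureTable(
        frame=frame, feature_names=table.feature_names, grids=table.grids
    )
    return scaled, params


def expand_categorical(
    X: np.ndarray,
    names: Sequence[str],
    encodings: Mapping[str, Sequence[float]],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Expand categorical columns of a base design matrix into indicators.

    Columns named in ``encodings`` become one ``{name}=={value}`` indicator
    per category value; other columns pass through unchanged.  Returns the
    expanded matrix and its column names.
    """
    X = np.asarray(X, dtype=float)
    cols: list[np.ndarray] = []
    out_names: list[str] = []
    for i, name in enumerate(names):
        if name in encodings:
            for v in encodings[name]:
                cols.append((X[:, i] == v).astype(float))
                out_names.append(f"{name}=={v:g}")
        else:
            cols.append(X[:, i])
            out_names.append(name)
    return np.stack(cols, axis=1), tuple(out_names)


@dataclasses.dataclass(frozen=True)
class TrainedEstimator:
    """Frozen linear voxel classifier.

    ``base_features`` are the feature volumes required at prediction time (in
    order); ``encodings`` records which of them expand to indicator columns;
    ``feature_names`` are the expanded design-matrix columns, aligned with the
    standardization parameters and hyperplane ``weights``.  A voxel is
    ventricle when ``sum_j w_j * (x_j - mean_j) / sd_j + bias > 0``.
    """

    base_features: tuple[str, ...]
    encodings: dict[str, tuple[float, ...]]
    feature_names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    bias: float
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        if not (len(self.means) == len(self.sds) == len(self.weights) == k):
            raise ValueError("per-column parameter lengths must match feature names")
        if any(sd <= 0 for sd in self.sds):
            raise ValueError("all standardization sds must be positive")
        unknown = set(self.encodings) - set(self.base_features)
        if unknown:
            raise ValueError(f"encodings for unknown features: {sorted(unknown)}")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Margin for rows of a *base* feature matrix (columns =
        ``base_features`` order); categorical expansion happens internally."""
        Xe, _ = expand_categorical(X, self.base_features, self.encodings)
        z = (Xe - np.asarray(self.means)) / np.asarray(self.sds)
        return z @ np.asarray(self.weights) + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "format_version": ESTIMATOR_FORMAT_VERSION,
                "base_features": list(self.base_features),
                "encodings": {k: list(v) for k, v in self.encodings.items()},
                "feature_names": list(self.feature_names),
                "standardization": {
                    name: {"mean": m, "sd": s}
                    for name, m, s in zip(self.feature_names, self.means, self.sds)
                },
                "weights": list(self.weights),
                "bias": self.bias,
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "TrainedEstimator":
        if isinstance(doc, Path) or (isinstance(doc, str) and doc.lstrip()[:1] != "{"):
            doc = Path(doc).read_text()
        parsed = json.loads(doc)
        if parsed.get("format_version") != ESTIMATOR_FORMAT_VERSION:
            raise ValueError(
                f"unsupported estimator format {parsed.get('format_version')!r}"
            )
        names = tuple(parsed["feature_names"])
        std = parsed["standardization"]
        return cls(
            base_features=tuple(parsed["base_features"]),
            encodings={k: tuple(v) for k, v in parsed["encodings"].items()},
            feature_names=names,
            means=tuple(std[n]["mean"] for n in names),
            sds=tuple(std[n]["sd"] for n in names),
            weights=tuple(parsed["weights"]),
            bias=float(parsed["bias"]),
            metadata=parsed.get("metadata", {}),
        )


def _subsample_negatives(y: np.ndarray, ratio: float, seed: int) -> np.ndarray:
    """Row mask keeping all positives and ``ratio`` negatives per positive."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    keep_n = min(len(neg), int(np.ceil(ratio * max(len(pos), 1))))
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg, size=keep_n, replace=False)
    keep = np.zeros(len(y), dtype=bool)
    keep[pos] = True
    keep[kept_neg] = True
    return keep


def train_estimator(
    table: FeatureTable,
    split: SubjectSplit | None = None,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    class_weight: str | dict | None = "balanced",
    subsample_negatives: float | None = None,
    cv_folds: int = 3,
    categorical_features: Sequence[str] = DEFAULT_CATEGORICAL,
) -> TrainedEstimator:
    """Fit the linear voxel classifier on the training side of ``split``.

    Standardization is fitted on the training rows only; C is tuned over
    ``grid`` by subject-grouped cross-validation (``cv_folds`` folds, capped
    at the number of training subjects) and the winner refitted on all
    training rows.  With ``split`` None, all subjects train (the published
    estimator is fitted on the full cohort after fold-wise evaluation).

    ``subsample_negatives`` keeps that many negative rows per positive row
    (seeded), after which ``class_weight`` ("balanced" by default) still
    applies to whatever imbalance remains.  Features listed in
    ``categorical_features`` (and present in the table) are indicator-encoded
    from their observed training values.
    """
    frame = table.frame
    if split is not None:
        rows = frame["subject_id"].isin(split.train_ids).to_numpy()
    else:
        rows = np.ones(len(frame), dtype=bool)
    X = table.features_matrix()[rows]
    y = table.labels()[rows]
    groups = table.groups()[rows]
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training rows contain a single class")
    if subsample_negatives is not None:
        keep = _subsample_negatives(y, subsample_negatives, seed)
        X, y, groups = X[keep], y[keep], groups[keep]

    encodings = {
        name: tuple(float(v) for v in np.unique(X[:, i]))
        for i, name in enumerate(table.feature_names)
        if name in categorical_features
    }
    Xe, expanded_names = expand_categorical(X, table.feature_names, encodings)

    means = Xe.mean(axis=0)
    sds = Xe.std(axis=0)
    low = np.flatnonzero(sds < 1e-12)
    if low.size:
        raise DegenerateFeatureError(
            f"zero-variance training column: {expanded_names[low[0]]!r}"
        )
    Z = (Xe - means) / sds

    grid = (
        np.logspace(-2, 2, 5) if grid is None else np.asarray(list(grid), dtype=float)
    )
    n_subj = len(np.unique(groups))
    best_c = float(grid[0])
    if len(grid) > 1 and n_subj >= 2:
        folds = min(cv_folds, n_subj)
        gkf = GroupKFold(n_splits=folds)
        mean_acc = np.zeros(len(grid))
        for tr, te in gkf.split(Z, y, groups):
            if len(np.unique(y[tr])) < 2:
                continue
            for i, c in enumerate(grid):
                clf = LinearSVC(
                    C=c, dual=False, class_weight=class_weight, random_state=seed
                )
                clf.fit(Z[tr], y[tr])
                mean_acc[i] += clf.score(Z[te], y[te])
        best_c = float(grid[int(np.argmax(mean_acc))])

    clf = LinearSVC(C=best_c, dual=False, class_weight=class_weight, random_state=seed)
    clf.fit(Z, y)
    return TrainedEstimator(
        base_features=table.feature_names,
        encodings=encodings,
        feature_names=expanded_names,
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
        weights=tuple(float(w) for w in clf.coef_.ravel()),
        bias=float(clf.intercept_[0]),
        metadata={
            "train_subjects": sorted(set(map(str, groups))),
            "seed": int(seed),
            "grid": [float(c) for c in grid],
            "best_c": best_c,
            "class_weight": str(class_weight),
            "subsample_negatives": subsample_negatives,
            "n_train_rows": int(len(y)),
        },
    )


def predict_mask(
    est: TrainedEstimator,
    vol: VolumeImage,
    feature_volumes: dict[str, np.ndarray],
    largest_component_only: bool = False,
) -> BinaryMask:
    """Classify every voxel and reassemble the positive class into a mask.

    Each voxel is positive when the sign of the standardized linear decision
    function is positive; no post-processing is applied by default.  The
    optional largest-connected-component filter exists behind a flag for
    exploratory use.

    Raises :class:`MissingFeatureError` naming any absent feature and
    :class:`GridAlignmentError` on a feature volume with the wrong grid.
    """
    cols = []
    for name in est.base_features:
        if name not in feature_volumes:
            raise MissingFeatureError(f"feature volume {name!r} not supplied")
        fv = np.asarray(feature_volumes[name])
        if fv.shape != vol.shape:
            raise GridAlignmentError(
                f"feature {name!r} grid {fv.shape} does not match volume {vol.shape}"
            )
        cols.append(fv.ravel().astype(np.float64))
    X = np.stack(cols, axis=1)
    positive = est.predict(X).reshape(vol.shape)
    if largest_component_only and positive.any():
        from scipy import ndimage

        labels, n = ndimage.label(positive)
        if n > 1:
            sizes = ndimage.sum_labels(positive, labels, index=np.arange(1, n + 1))
            positive = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(data=positive, affine=vol.affine, spacing=vol.spacing)
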