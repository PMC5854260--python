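"""Strong-force feature selection: exhaustive subset search with a tuned
linear max-margin classifier.

Every non-empty subset of the candidate features is scored by the
cross-validated accuracy of a linear SVM whose regularization strength C is
tuned over a 50-point logarithmic grid from 1e-4 to 1e3.  Cross-validation
folds are grouped by subject so voxels of one subject never appear on both
sides of a fold.  The best-scoring subset wins; ties break toward the smaller
subset.

The search is exhaustive by design ("strong force"): with the handful of
candidate features in play, 2^k - 1 subsets are cheap, and enumeration of
subsets subsumes enumeration of ordered feature groupings (a classifier does
not care about column order, and an inner k-best filter is redundant once the
subset is explicit).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import DegenerateLabelsError
from .voxel_features import FeatureTable

__all__ = ["FeatureSelectionReport", "strong_force_select", "default_regularization_grid"]


def default_regularization_grid() -> np.ndarray:
    """50 regularization strengths log-spaced over [1e-4, 1e3]."""
    return np.logspace(-4, 3, 50)


@dataclasses.dataclass(frozen=True)
class FeatureSelectionReport:
    """Outcome of the exhaustive search.

    ``participants[i]`` is the i-th evaluated feature subset and ``scores[i]``
    its best mean cross-validated accuracy over the regularization grid;
    ``selected`` is the argmax subset (ties to the smaller subset).
    """

    scores: tuple[float, ...]
    participants: tuple[tuple[str, ...], ...]
    selected: tuple[str, ...]
    grid: tuple[float, ...]
    best_c: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.participants):
            raise ValueError("one score per evaluated subset required")
        if self.selected not in self.participants:
            raise ValueError("selected subset was not evaluated")
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def best_score(self) -> float:
        return self.scores[self.participants.index(self.selected)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": ["+".join(p) for p in self.participants],
                "n_features": [len(p) for p in self.participants],
                "score": self.scores,
                "best_c": self.best_c,
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "selected": list(self.selected),
                "best_score": self.best_score,
                "grid": list(self.grid),
                "subsets": [
                    {"features": list(p), "score": s, "best_c": c}
                    for p, s, c in zip(self.participants, self.scores, self.best_c)
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc


def _tuned_cv_score(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    folds: int,
    grid: np.ndarray,
    seed: int,
) -> tuple[float, float]:
    """Best mean grouped-CV accuracy over the C grid, and the winning C.

    Standardization is fit inside each training fold only.
    """
    gkf = GroupKFold(n_splits=folds)
    accs = np.zeros((len(grid), folds))
    for f, (tr, te) in enumerate(gkf.split(X, y, groups)):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        for i, c in enumerate(grid):
            clf = LinearSVC(C=c, dual=False, random_state=seed)
            clf.fit(Xtr, y[tr])
            accs[i, f] = clf.score(Xte, y[te])
    mean = accs.mean(axis=1)
    best = int(np.argmax(mean))
    return float(mean[best]), float(grid[best])


def strong_force_select(
    table: FeatureTable,
    candidates: tuple[str, ...] | None = None,
    folds: int = 5,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> FeatureSelectionReport:
    """Exhaustively score every non-empty subset of ``candidates``.

    Parameters
    ----------
    table:
        Labeled feature table with at least two subjects and both classes.
    candidates:
        Feature names to search over; defaults to the table's features.
    folds:
        Number of subject-grouped cross-validation folds (capped at the
        number of subjects).
    seed:
        Estimator seed; with the deterministic primal solver the search is
        fully reproducible given (table, seed).
    grid:
        Regularization strengths; defaults to the 50-point log grid.
    """
    candidates = tuple(table.feature_names if candidates is None else candidates)
    if len(candidates) == 0:
        raise ValueError("need at least one candidate feature")
    unknown = set(candidates) - set(table.feature_names)
    if unknown:
        raise KeyError(f"candidates not in table: {sorted(unknown)}")
    y = table.labels()
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("feature selection needs both classes present")
    groups = table.groups()
    folds = min(folds, len(np.unique(groups)))
    if folds < 2:
        raise DegenerateLabelsError("feature selection needs at least two subjects")
    grid = default_regularization_grid() if grid is None else np.asarray(grid, float)

    X_all = table.features_matrix()
    col = {name: i for i, name in enumerate(table.feature_names)}
    participants: list[tuple[str, ...]] = []
    scores: list[float] = []
    best_c: list[float] = []
    # enumerate by increasing size so argmax ties resolve to the smaller subset
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            X = X_all[:, [col[f] for f in subset]]
            s, c = _tuned_cv_score(X, y, groups, folds, grid, seed)
            participants.append(subset)
            scores.append(s)
            best_c.append(c)
    selected = participants[int(np.argmax(scores))]
    return FeatureSelectionReport(
        scores=tuple(scores),
        participants=tuple(participants),
        selected=selected,
        grid=tuple(float(c) for c in grid),
        best_c=tuple(best_c),
    )
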