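"""End-to-end orchestration: resample -> features -> table -> folds -> final
estimator, and segmentation of new subjects with Table-style evaluation.

These functions operate on in-memory volumes; the command-line layer handles
paths.  Every stage logs shapes and row counts at info level, and both
pipelines are deterministic given (inputs, config, seeds).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AvveError, InvalidSplitError
from .estimator import TrainedEstimator, predict_mask, split_by_subject, train_estimator
from .image_io import BinaryMask, VolumeImage, resample_isotropic, resample_mask
from .metrics import compare_masks, volume_mm3
from .voxel_features import (
    DEFAULT_FEATURES,
    CardinalityConfig,
    NeighborRule,
    build_feature_table,
    compute_feature_volumes,
)

__all__ = ["RunConfig", "run_training_pipeline", "run_segmentation_pipeline"]

log = logging.getLogger("avve.pipeline")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the training and segmentation pipelines."""

    resample_target: float = 1.0
    features: tuple[str, ...] = DEFAULT_FEATURES
    cardinality_dividers: tuple[int, int, int] = (16, 16, 16)
    neighbor_ratio: float = 0.2
    fraction: float = 0.75
    folds: int = 6
    seed: int = 0
    grid: tuple[float, ...] = tuple(np.logspace(-2, 2, 5))
    cv_folds: int = 3
    class_weight: str = "balanced"
    subsample_negatives: float | None = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise InvalidSplitError(f"fraction must be in (0, 1), got {self.fraction}")

    @property
    def cardinality_cfg(self) -> CardinalityConfig:
        return CardinalityConfig(*self.cardinality_dividers)

    @property
    def neighbor_rule(self) -> NeighborRule:
        return NeighborRule(ratio=self.neighbor_ratio)


def _prepare(
    vols: Sequence[VolumeImage],
    masks: Sequence[BinaryMask | None] | None,
    cfg: RunConfig,
) -> tuple[list[VolumeImage], list[BinaryMask | None] | None]:
    rvols = [resample_isotropic(v, cfg.resample_target) for v in vols]
    if masks is None:
        return rvols, None
    rmasks = [
        resample_mask(m, cfg.resample_target) if m is not None else None for m in masks
    ]
    return rvols, rmasks


def run_training_pipeline(
    vols: Sequence[VolumeImage],
    masks: Sequence[BinaryMask],
    subject_ids: Sequence[str],
    cfg: RunConfig | None = None,
) -> tuple[TrainedEstimator, pd.DataFrame]:
    """Train the voxel classifier on a labeled cohort.

    Resamples everything to the working grid, builds the feature table, runs
    the subject-grouped fold evaluation (each fold re-randomizes the
    train:test partition at ``cfg.fraction``), then fits the final estimator
    on all subjects.  Returns the estimator and a per-fold report with
    held-out voxel accuracy and per-held-out-subject Jaccard.
    """
    cfg = cfg or RunConfig()
    if len(set(subject_ids)) < 2:
        raise InvalidSplitError("training needs at least 2 subjects")
    log.info("resampling %d volumes to %.2f mm", len(vols), cfg.resample_target)
    rvols, rmasks = _prepare(vols, masks, cfg)
    log.info("extracting features %s", cfg.features)
    table = build_feature_table(
        rvols,
        rmasks,
        features=cfg.features,
        subject_ids=subject_ids,
        cardinality_cfg=cfg.cardinality_cfg,
        neighbor_rule=cfg.neighbor_rule,
    )
    log.info("feature table: %d rows x %d features", len(table.frame),
             len(table.feature_names))

    splits = split_by_subject(subject_ids, cfg.fraction, cfg.folds, cfg.seed)
    by_id = {sid: (v, m) for sid, v, m in zip(subject_ids, rvols, rmasks)}
    fold_rows = []
    for split in splits:
        est = train_estimator(
            table,
            split=split,
            grid=cfg.grid,
            seed=cfg.seed,
            class_weight=cfg.class_weight,
            subsample_negatives=cfg.subsample_negatives,
            cv_folds=cfg.cv_folds,
        )
        test_rows = table.frame["subject_id"].isin(split.test_ids).to_numpy()
        X = table.features_matrix()[test_rows]
        y = table.labels()[test_rows]
        acc = float((est.predict(X) == (y == 1)).mean())
        jaccards = []
        for sid in split.test_ids:
            vol, mask = by_id[sid]
            feats = compute_feature_volumes(
                vol, cfg.features, cfg.cardinality_cfg, cfg.neighbor_rule
            )
            pred = predict_mask(est, vol, feats)
            jaccards.append(compare_masks(mask, pred, sid).jaccard)
        fold_rows.append(
            {
                "fold": split.fold_index,
                "n_train_subjects": len(split.train_ids),
                "n_test_subjects": len(split.test_ids),
                "best_c": est.metadata["best_c"],
                "test_voxel_accuracy": acc,
                "mean_test_jaccard": float(np.mean(jaccards)),
            }
        )
        log.info(
            "fold %d: %d/%d subjects, accuracy %.4f, mean Jaccard %.3f",
            split.fold_index, len(split.train_ids), len(split.test_ids),
            acc, fold_rows[-1]["mean_test_jaccard"],
        )

    final = train_estimator(
        table,
        split=None,
        grid=cfg.grid,
        seed=cfg.seed,
        class_weight=cfg.class_weight,
        subsample_negatives=cfg.subsample_negatives,
        cv_folds=cfg.cv_folds,
    )
    return final, pd.DataFrame(fold_rows)


def run_segmentation_pipeline(
    vols: Sequence[VolumeImage],
    truth_masks: Sequence[BinaryMask | None] | None,
    subject_ids: Sequence[str],
    est: TrainedEstimator,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, BinaryMask]]:
    """Segment new subjects and report volumes (plus comparisons when truth
    masks are supplied; their columns are NaN otherwise).

    Per-subject failures are logged and skipped so one corrupt input does not
    abort the batch; failed subjects appear with an ``error`` column.
    """
    cfg = cfg or RunConfig()
    if truth_masks is None:
        truth_masks = [None] * len(vols)
    rows = []
    predicted: dict[str, BinaryMask] = {}
    for vol, truth, sid in zip(vols, truth_masks, subject_ids):
        try:
            rvol = resample_isotropic(vol, cfg.resample_target)
            rtruth = (
                resample_mask(truth, cfg.resample_target) if truth is not None else None
            )
            feats = compute_feature_volumes(
                rvol, est.base_features, cfg.cardinality_cfg, cfg.neighbor_rule
            )
            pred = predict_mask(est, rvol, feats)
            predicted[sid] = pred
            if rtruth is not None:
                c = compare_masks(rtruth, pred, sid)
                rows.append(dataclasses.asdict(c) | {"error": ""})
            else:
                rows.append(
                    {
                        "subject_id": sid,
                        "manual_volume": np.nan,
                        "auto_volume": volume_mm3(pred),
                        "difference": np.nan,
                        "jaccard": np.nan,
                        "error": "",
                    }
                )
            log.info("segmented %s: %.1f mm3", sid, volume_mm3(pred))
        except (AvveError, OSError) as exc:
            log.warning("segmentation stage failed for %s: %s", sid, exc)
            rows.append(
                {
                    "subject_id": sid,
                    "manual_volume": np.nan,
                    "auto_volume": np.nan,
                    "difference": np.nan,
                    "jaccard": np.nan,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    frame = pd.DataFrame(rows).rename(
        columns={
            "manual_volume": "manual_volume_mm3",
            "auto_volume": "auto_volume_mm3",
            "difference": "difference_mm3",
        }
    )
    return frame, predicted
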