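"""Volume and overlap metrics for comparing manual and automatic segmentations.

The clinical quantity is the ventricular volume in mm^3 (positive voxel count
times voxel volume); agreement between a manual and an automatic mask is
reported as the signed volume difference (manual - auto) and the Jaccard index
|A ∩ B| / |A ∪ B|.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import GridAlignmentError
from .image_io import BinaryMask, voxel_volume_mm3

__all__ = [
    "SegmentationComparison",
    "volume_mm3",
    "volume_difference",
    "jaccard_index",
    "compare_masks",
    "comparison_frame",
]


@dataclasses.dataclass(frozen=True)
class SegmentationComparison:
    """One Table-style comparison row between a manual and an automatic mask."""

    subject_id: str
    manual_volume: float
    auto_volume: float
    difference: float
    jaccard: float

    def __post_init__(self) -> None:
        if not np.isnan(self.jaccard) and not (0.0 <= self.jaccard <= 1.0):
            raise ValueError(f"jaccard must be in [0, 1], got {self.jaccard}")


def volume_mm3(mask: BinaryMask) -> float:
    """Physical volume of a mask: positive voxel count times voxel volume."""
    return float(np.count_nonzero(mask.data)) * voxel_volume_mm3(mask.spacing)


def volume_difference(manual: float, auto: float) -> float:
    """Signed volume difference, manual minus automatic, in mm^3."""
    return manual - auto


def jaccard_index(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection-over-union of two grid-aligned masks.

    Defined as 1.0 when both masks are empty (perfect agreement on absence).
    """
    if a.shape != b.shape:
        raise GridAlignmentError(f"mask grids differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a.data | b.data)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a.data & b.data)) / float(union)


def compare_masks(
    manual: BinaryMask, auto: BinaryMask, subject_id: str = ""
) -> SegmentationComparison:
    """Volumes, signed difference and Jaccard index for one subject."""
    mv = volume_mm3(manual)
    av = volume_mm3(auto)
    return SegmentationComparison(
        subject_id=subject_id,
        manual_volume=mv,
        auto_volume=av,
        difference=volume_difference(mv, av),
        jaccard=jaccard_index(manual, auto),
    )


def comparison_frame(rows: Iterable[SegmentationComparison]) -> pd.DataFrame:
    """Per-subject comparison rows as a DataFrame (one CSV-ready row each)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "manual_volume_mm3": r.manual_volume,
                "auto_volume_mm3": r.auto_volume,
                "difference_mm3": r.difference,
                "jaccard": r.jaccard,
            }
            for r in rows
        ]
    )
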