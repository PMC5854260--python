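"""Per-voxel features and assembly of the supervised feature table.

The segmenter works voxel-by-voxel: each voxel of a (1 mm resampled) volume is
described by four hand-crafted features that jointly separate ventricular CSF
from everything else:

``hci``
    Histogram-classified intensity, the parcellation factor 1..4 (see
    :mod:`avve.histogram_parcellation`).  Contrast-adaptive intensity class.
``normalized_distance``
    Euclidean distance, in voxel-index space, from the voxel to the scanner
    central voxel (SCV, the pre-image of the world origin under the affine),
    multiplied by the voxel volume.  On the 1 mm working grid the multiplier is
    1, so the value is a distance in mm.  A positional prior: ventricles sit
    near the isocenter.
``cardinality``
    Index of the axis-aligned block of the field of view containing the voxel,
    numbered consecutively along x, then y, then z.  Coarse absolute position,
    disambiguating radially-equidistant voxels.
``neighboring``
    Count (0..26) of the voxel's 26 directions whose relative-contrast test
    fires: direction k counts when ``|I(V) - I(V_N)| > ratio * |I(V_N) -
    I(V_NN)|`` with ``V_N``/``V_NN`` the first and second voxels along k.
    Acts as a boundary detector.

A pool of rejected candidates (raw intensity, discrete Laplacian, Laplacian of
Gaussian at sigma 1..3 voxels) is also provided for feature-selection studies.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridAlignmentError, InvalidGeometryError
from .image_io import BinaryMask, VolumeImage, voxel_volume_mm3
from . import histogram_parcellation as hp

__all__ = [
    "DEFAULT_FEATURES",
    "CANDIDATE_FEATURES",
    "CardinalityConfig",
    "NeighborRule",
    "FeatureTable",
    "normalized_distance",
    "cardinality",
    "neighboring",
    "candidate_pool",
    "compute_feature_volumes",
    "build_feature_table",
]

DEFAULT_FEATURES = ("hci", "normalized_distance", "cardinality", "neighboring")
CANDIDATE_FEATURES = ("intensity", "laplacian", "log_sigma1", "log_sigma2", "log_sigma3")

#: the 26 offsets with components in {-1, 0, 1}, excluding the null step
OFFSETS_26 = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)


@dataclasses.dataclass(frozen=True)
class CardinalityConfig:
    """Block edge lengths, in voxels, of the field-of-view division."""

    dx: int = 16
    dy: int = 16
    dz: int = 16

    def clamped(self, shape: tuple[int, int, int]) -> "CardinalityConfig":
        """Dividers larger than an axis clamp to the axis length (one block)."""
        d = [self.dx, self.dy, self.dz]
        if any(v < 1 for v in d):
            raise InvalidGeometryError(f"dividers must be >= 1, got {tuple(d)}")
        return CardinalityConfig(*(min(v, n) for v, n in zip(d, shape)))


@dataclasses.dataclass(frozen=True)
class NeighborRule:
    """Relative-contrast rule for the neighboring feature.

    ``ratio`` multiplies the far differential ``|I(V_N) - I(V_NN)|``; the
    default 0.2 means the near differential must exceed 20% of the far one.
    """

    ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")

    @property
    def offsets(self) -> tuple[tuple[int, int, int], ...]:
        return OFFSETS_26


def normalized_distance(vol: VolumeImage) -> np.ndarray:
    """Distance of every voxel to the scanner central voxel (SCV).

    The SCV is the inverse-affine image of the world origin; it may be
    fractional and may lie outside the grid (restricted fields of view).  The
    returned value is the index-space Euclidean distance multiplied by the
    voxel volume, which on the mandated 1 mm isotropic grid equals a distance
    in mm.
    """
    inv = np.linalg.inv(vol.affine)
    scv = inv[:3, 3]  # inverse image of (0, 0, 0, 1)
    v_size = voxel_volume_mm3(vol.spacing)
    grids = np.meshgrid(*(np.arange(n, dtype=np.float32) for n in vol.shape),
                        indexing="ij")
    sq = np.zeros(vol.shape, dtype=np.float32)
    for g, c in zip(grids, scv):
        sq += (g - np.float32(c)) ** 2
    return np.sqrt(sq) * np.float32(v_size)


def cardinality(vol: VolumeImage, cfg: CardinalityConfig | None = None) -> np.ndarray:
    """Consecutive block index of the FOV division containing each voxel.

    Blocks are numbered 1..m along x first, then y, then z; voxels in the same
    block share a value and consecutive blocks along x differ by 1.
    """
    cfg = (cfg or CardinalityConfig()).clamped(vol.shape)
    nx = -(-vol.shape[0] // cfg.dx)  # ceil division: blocks per axis
    ny = -(-vol.shape[1] // cfg.dy)
    gx, gy, gz = np.meshgrid(*(np.arange(n) for n in vol.shape), indexing="ij")
    card = gx // cfg.dx + nx * (gy // cfg.dy) + nx * ny * (gz // cfg.dz) + 1
    return card.astype(np.int32)


def neighboring(vol: VolumeImage, rule: NeighborRule | None = None) -> np.ndarray:
    """Count, per voxel, of the 26 directions passing the relative-contrast test.

    For direction k with offset ``(a, b, c)``: ``V_N`` is one step and ``V_NN``
    two steps away; the direction counts when ``|I(V) - I(V_N)| > ratio *
    |I(V_N) - I(V_NN)|`` (strict).  Directions whose ``V_N`` or ``V_NN`` fall
    outside the FOV contribute 0, so border voxels have fewer active
    directions.  Values lie in [0, 26].
    """
    rule = rule or NeighborRule()
    data = np.asarray(vol.data, dtype=np.float64)
    counts = np.zeros(vol.shape, dtype=np.int8)
    for off in rule.offsets:
        centre, near, far = [], [], []
        for axis, (n, o) in enumerate(zip(vol.shape, off)):
            if o == 1:
                c, nn, ff = slice(0, n - 2), slice(1, n - 1), slice(2, n)
            elif o == -1:
                c, nn, ff = slice(2, n), slice(1, n - 1), slice(0, n - 2)
            else:
                c = nn = ff = slice(0, n)
            centre.append(c)
            near.append(nn)
            far.append(ff)
        i_c = data[tuple(centre)]
        i_n = data[tuple(near)]
        i_nn = data[tuple(far)]
        fired = np.abs(i_c - i_n) > rule.ratio * np.abs(i_n - i_nn)
        counts[tuple(centre)] += fired
    return counts


def candidate_pool(vol: VolumeImage) -> dict[str, np.ndarray]:
    """The initially-explored feature pool: raw intensity, discrete 6-connected
    Laplacian, and Laplacian of Gaussian at sigma of 1, 2 and 3 voxels."""
    data = np.asarray(vol.data, dtype=float)
    pool = {
        "intensity": data,
        "laplacian": ndimage.laplace(data),
    }
    for sigma in (1, 2, 3):
        pool[f"log_sigma{sigma}"] = ndimage.gaussian_laplace(data, sigma)
    return pool


def compute_feature_volumes(
    vol: VolumeImage,
    features: Sequence[str] = DEFAULT_FEATURES,
    cardinality_cfg: CardinalityConfig | None = None,
    neighbor_rule: NeighborRule | None = None,
    envelope_kwargs: Mapping | None = None,
) -> dict[str, np.ndarray]:
    """Compute named feature volumes for one image.

    Supported names: the four selected features plus the candidate pool.
    """
    out: dict[str, np.ndarray] = {}
    pool: dict[str, np.ndarray] | None = None
    for name in features:
        if name == "hci":
            out[name] = hp.hci_feature(vol, **(dict(envelope_kwargs or {})))
        elif name == "normalized_distance":
            out[name] = normalized_distance(vol)
        elif name == "cardinality":
            out[name] = cardinality(vol, cardinality_cfg)
        elif name == "neighboring":
            out[name] = neighboring(vol, neighbor_rule)
        elif name in CANDIDATE_FEATURES:
            if pool is None:
                pool = candidate_pool(vol)
            out[name] = pool[name]
        else:
            raise KeyError(f"unknown feature {name!r}")
    return out


@dataclasses.dataclass(frozen=True)
class GridInfo:
    """Grid provenance of one subject's rows: enough to rebuild a mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    spacing: tuple[float, float, float]


@dataclasses.dataclass
class FeatureTable:
    """Per-voxel rows: feature columns, optional binary label, subject id.

    Rows are stored in C (row-major) voxel order per subject, subjects
    concatenated in input order, so grid coordinates are implicit in the row
    index and masks can be reconstructed from ``grids``.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...]
    grids: dict[str, GridInfo]

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.frame.columns]
        if missing:
            raise KeyError(f"feature columns missing from frame: {missing}")
        if self.frame.isna().any().any():
            raise ValueError("feature table contains missing values")
        if "label" in self.frame.columns:
            bad = set(np.unique(self.frame["label"])) - {0, 1}
            if bad:
                raise ValueError(f"label column must be binary, found {bad}")
        unknown = set(self.frame["subject_id"].unique()) - set(self.grids)
        if unknown:
            raise ValueError(f"rows reference unknown subjects: {sorted(unknown)}")

    @property
    def has_labels(self) -> bool:
        return "label" in self.frame.columns

    @property
    def subject_ids(self) -> list[str]:
        return list(self.grids)

    def features_matrix(self) -> np.ndarray:
        return self.frame.loc[:, list(self.feature_names)].to_numpy(dtype=np.float64)

    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise KeyError("table has no label column")
        return self.frame["label"].to_numpy(dtype=np.int8)

    def groups(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Serialize rows as CSV (columns: features, label, subject_id)."""
        self.frame.to_csv(path, index=False)


def build_feature_table(
    vols: Sequence[VolumeImage],
    masks: Sequence[BinaryMask | None] | None = None,
    features: Sequence[str] = DEFAULT_FEATURES,
    subject_ids: Sequence[str] | None = None,
    cardinality_cfg: CardinalityConfig | None = None,
    neighbor_rule: NeighborRule | None = None,
    envelope_kwargs: Mapping | None = None,
) -> FeatureTable:
    """Assemble the supervised feature table: one row per voxel per volume.

    When ``masks`` is None entirely the label column is omitted (inference
    table); a per-subject None mask yields label 0 for that subject.  Volumes
    and masks must be grid-aligned or a :class:`GridAlignmentError` is raised.
    """
    if subject_ids is None:
        subject_ids = [f"subject-{i:03d}" for i in range(len(vols))]
    if len(subject_ids) != len(vols):
        raise ValueError("need one subject id per volume")
    include_labels = masks is not None
    if masks is None:
        masks = [None] * len(vols)
    if len(masks) != len(vols):
        raise ValueError("need one mask (or None) per volume")

    pieces = []
    grids: dict[str, GridInfo] = {}
    for vol, mask, sid in zip(vols, masks, subject_ids):
        if mask is not None and not mask.same_grid_as(vol):
            raise GridAlignmentError(
                f"subject {sid}: mask grid {mask.shape} does not match "
                f"volume grid {vol.shape}"
            )
        feats = compute_feature_volumes(
            vol, features, cardinality_cfg, neighbor_rule, envelope_kwargs
        )
        cols = {name: feats[name].ravel().astype(np.float32) for name in features}
        if include_labels:
            labels = (
                mask.data.ravel().astype(np.int8)
                if mask is not None
                else np.zeros(int(np.prod(vol.shape)), dtype=np.int8)
            )
            cols["label"] = labels
        cols["subject_id"] = np.repeat(sid, int(np.prod(vol.shape)))
        pieces.append(pd.DataFrame(cols))
        grids[sid] = GridInfo(shape=vol.shape, affine=vol.affine, spacing=vol.spacing)
    frame = pd.concat(pieces, ignore_index=True)
    return FeatureTable(frame=frame, feature_names=tuple(features), grids=grids)
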