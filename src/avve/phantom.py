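"""Synthetic T1-like brain phantoms with ground-truth ventricle masks.

The generator emulates the aspects of clinical T1 head scans that the
segmenter's four features respond to, without attempting MR physics:

* four intensity classes with T1 ordering — background darkest, then CSF,
  grey matter, white matter — as nested axis-aligned ellipsoids (BG outside a
  GM shell wrapping a WM core);
* a mirrored pair of ellipsoidal ventricle-like CSF structures inside the WM
  core, rasterized at voxel centres into the ground-truth mask;
* additive Gaussian noise, a global contrast multiplier and an isocenter
  offset, standing in for the acquisition variability (flip angle, averaging,
  positioning) seen across clinical protocols;
* an optional CSF-intensity "cyst" ellipsoid adjacent to — touching but not
  overlapping — a ventricle and absent from the truth mask: a confounder that
  reproduces the arachnoid-cyst failure mode of ventricle segmenters.

Cohort generation jitters ventricle size (with an enlarged,
hydrocephalus-like tail), contrast, noise and isocenter offset per subject,
deterministically from a single seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .image_io import BinaryMask, VolumeImage
from .metrics import volume_mm3

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "CohortJitter",
    "PhantomResult",
    "generate_phantom",
    "generate_cohort",
    "with_cyst",
    "cohort_manifest",
]


@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre (mm, relative to grid centre) and semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(a * factor for a in self.semi_axes))


_DEFAULT_VENTRICLES = (
    Ellipsoid(center=(-7.0, 3.0, 0.0), semi_axes=(4.0, 8.0, 5.0)),
    Ellipsoid(center=(7.0, 3.0, 0.0), semi_axes=(4.0, 8.0, 5.0)),
)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; deterministic given ``seed``.

    ``class_means`` are the (BG, CSF, GM, WM) intensities and must increase in
    that order (T1 contrast: CSF dark relative to brain tissue, background
    lowest).  Default noise keeps a realistic T1 signal-to-noise ratio of
    about 30 (WM mean over noise sd).
    """

    shape: tuple[int, int, int] = (56, 56, 56)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_means: tuple[float, float, float, float] = (10.0, 60.0, 110.0, 180.0)
    noise_sd: float = 6.0
    contrast_scale: float = 1.0
    head: tuple[float, float, float] = (24.0, 26.0, 22.0)
    wm_core: tuple[float, float, float] = (17.0, 20.0, 16.0)
    ventricles: tuple[Ellipsoid, ...] = _DEFAULT_VENTRICLES
    cyst: Ellipsoid | None = None
    isocenter_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str = "phantom-000"
    seed: int = 0

    def validate(self) -> None:
        bg, csf, gm, wm = self.class_means
        if not (bg < csf < gm < wm):
            raise InvalidSpecError(
                f"class means must satisfy BG < CSF < GM < WM, got {self.class_means}"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.contrast_scale <= 0:
            raise InvalidSpecError(
                f"contrast_scale must be positive, got {self.contrast_scale}"
            )


@dataclasses.dataclass(frozen=True)
class PhantomResult:
    """One generated phantom: image, ground-truth ventricle mask, identity."""

    volume: VolumeImage
    mask: BinaryMask
    subject_id: str
    spec: PhantomSpec


def _inside(
    ellipsoid: Ellipsoid, coords: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> np.ndarray:
    acc = np.zeros(coords[0].shape, dtype=np.float32)
    for x, c, a in zip(coords, ellipsoid.center, ellipsoid.semi_axes):
        acc += ((x - np.float32(c)) / np.float32(a)) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rasterize one phantom at voxel centres.

    Intensity of each voxel is the class mean of its containing region times
    ``contrast_scale`` plus Gaussian noise.  The affine places the world
    origin (scanner isocenter) at the grid centre plus ``isocenter_offset``.

    Raises :class:`InvalidSpecError` when a ventricle or cyst voxel falls
    outside the WM core (checked on the rasterized grid).
    """
    spec.validate()
    shape = spec.shape
    spacing = np.asarray(spec.spacing, dtype=float)
    centre_idx = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    coords = tuple(
        (np.arange(n, dtype=np.float32) - np.float32(c)) * np.float32(s)
        for n, c, s in zip(shape, centre_idx, spacing)
    )
    grids = np.meshgrid(*coords, indexing="ij")

    head = _inside(Ellipsoid((0.0, 0.0, 0.0), spec.head), grids)
    core = _inside(Ellipsoid((0.0, 0.0, 0.0), spec.wm_core), grids)
    truth = np.zeros(shape, dtype=bool)
    for v in spec.ventricles:
        truth |= _inside(v, grids)
    if np.any(truth & ~core):
        raise InvalidSpecError("a ventricle ellipsoid extends outside the WM core")
    csf = truth.copy()
    if spec.cyst is not None:
        cyst_vox = _inside(spec.cyst, grids)
        if np.any(cyst_vox & ~core):
            raise InvalidSpecError("the cyst ellipsoid extends outside the WM core")
        csf |= cyst_vox

    bg, csf_mean, gm, wm = spec.class_means
    intensity = np.full(shape, bg, dtype=np.float64)
    intensity[head] = gm
    intensity[core] = wm
    intensity[csf] = csf_mean
    intensity *= spec.contrast_scale
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    # world origin at grid centre + isocenter offset
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(
        spacing * centre_idx + np.asarray(spec.isocenter_offset, dtype=float)
    )
    vol = VolumeImage(data=intensity, affine=affine, spacing=tuple(spacing))
    mask = BinaryMask(data=truth, affine=affine, spacing=tuple(spacing))
    return PhantomResult(volume=vol, mask=mask, subject_id=spec.subject_id, spec=spec)


def with_cyst(spec: PhantomSpec, radius: float = 3.5) -> PhantomSpec:
    """Place a spherical CSF-intensity cyst touching (not overlapping) the
    last ventricle, offset along -y where the WM core has room, outside the
    truth mask — the arachnoid-cyst-like confounder."""
    v = spec.ventricles[-1]
    center = (v.center[0], v.center[1] - v.semi_axes[1] - radius, v.center[2])
    return dataclasses.replace(
        spec, cyst=Ellipsoid(center=center, semi_axes=(radius,) * 3)
    )


@dataclasses.dataclass(frozen=True)
class CohortJitter:
    """Per-subject variation ranges applied by :func:`generate_cohort`.

    Ventricle size is scaled uniformly per subject; a ``hydrocephalus_fraction``
    of subjects instead draw from the enlarged ``hydrocephalus_scale_range``
    (the upper end is capped so ventricles stay inside the WM core of the
    default geometry).  Contrast, noise and isocenter offsets jitter the
    acquisition-like axes.
    """

    ventricle_scale_range: tuple[float, float] = (0.75, 1.35)
    hydrocephalus_fraction: float = 0.25
    hydrocephalus_scale_range: tuple[float, float] = (1.45, 1.75)
    contrast_range: tuple[float, float] = (0.85, 1.15)
    noise_range: tuple[float, float] = (4.0, 8.0)
    isocenter_range: float = 3.0

    @classmethod
    def none(cls) -> "CohortJitter":
        return cls(
            ventricle_scale_range=(1.0, 1.0),
            hydrocephalus_fraction=0.0,
            hydrocephalus_scale_range=(1.0, 1.0),
            contrast_range=(1.0, 1.0),
            noise_range=(6.0, 6.0),
            isocenter_range=0.0,
        )

    def is_zero(self) -> bool:
        return (
            self.ventricle_scale_range[0] == self.ventricle_scale_range[1]
            and self.hydrocephalus_fraction == 0.0
            and self.contrast_range[0] == self.contrast_range[1]
            and self.noise_range[0] == self.noise_range[1]
            and self.isocenter_range == 0.0
        )


def generate_cohort(
    n: int,
    base: PhantomSpec | None = None,
    jitter: CohortJitter | None = None,
    seed: int = 0,
) -> list[PhantomResult]:
    """Generate ``n`` phantoms with distinct subject ids, deterministically.

    With zero jitter all phantoms are identical apart from their subject id
    (they share the base seed, hence the same noise realization).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base = base or PhantomSpec()
    jitter = jitter or CohortJitter()
    rng = np.random.default_rng(seed)
    results = []
    for i in range(n):
        if jitter.is_zero():
            spec = dataclasses.replace(base, subject_id=f"phantom-{i:03d}")
        else:
            hydro = rng.random() < jitter.hydrocephalus_fraction
            lo, hi = (
                jitter.hydrocephalus_scale_range
                if hydro
                else jitter.ventricle_scale_range
            )
            scale = rng.uniform(lo, hi)
            noise = rng.uniform(*jitter.noise_range)
            contrast = rng.uniform(*jitter.contrast_range)
            offset = tuple(
                rng.uniform(-jitter.isocenter_range, jitter.isocenter_range)
                for _ in range(3)
            )
            spec = dataclasses.replace(
                base,
                ventricles=tuple(v.scaled(scale) for v in base.ventricles),
                noise_sd=noise,
                contrast_scale=contrast,
                isocenter_offset=offset,
                subject_id=f"phantom-{i:03d}",
                seed=int(rng.integers(2**31)),
            )
        results.append(generate_phantom(spec))
    return results


def cohort_manifest(phantoms: Sequence[PhantomResult]) -> pd.DataFrame:
    """Cohort summary: subject id, seed, truth volume and key spec fields."""
    rows = []
    for p in phantoms:
        rows.append(
            {
                "subject_id": p.subject_id,
                "seed": p.spec.seed,
                "truth_volume_mm3": volume_mm3(p.mask),
                "noise_sd": p.spec.noise_sd,
                "contrast_scale": p.spec.contrast_scale,
                "ventricle_semi_axes": str(p.spec.ventricles[0].semi_axes),
                "has_cyst": p.spec.cyst is not None,
            }
        )
    return pd.DataFrame(rows)
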