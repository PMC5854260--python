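# Methods

## Problem and model

The package estimates cerebral ventricular volume from a single T1-weighted
structural MR volume by voxel-wise binary classification. Each voxel of the
volume, resampled to a 1 mm isotropic working grid, is mapped to a
four-dimensional feature vector (histogram class, isocenter distance, FOV
block index, neighboring count) and classified by a linear max-margin
decision function; the ventricular volume is the positive voxel count times
the voxel volume. The approach assumes only that ventricles are CSF-dark on
T1 relative to brain tissue and sit near the scanner isocenter in a routine
head acquisition; it uses no atlas, template or registration, which is what
makes it applicable to restricted fields of view and variable clinical
protocols.

## Geometry conventions

Voxel indices are 0-based; a voxel's world position (mm) is the affine image
of its integer index (NIfTI voxel-centre convention), and the world origin is
the scanner isocenter. 4D payloads are rejected rather than silently sliced —
safer for a quantification tool. Resampling to the working grid uses linear
interpolation for intensities (never overshoots the input range) and
nearest-neighbour for masks (preserves binarity); the output grid spans
`ceil(extent/target)` voxels per axis anchored at the first voxel centre.
Manual masks are assumed to be drawn at native resolution and resampled with
nearest-neighbour, the standard choice where the scheme is otherwise
unspecified.

## Histogram parcellation (HCI)

MR contrast varies between acquisitions, so the intensity cut points
separating background, CSF, grey and white matter are detected per volume:

1. Histogram over 256 bins spanning the observed range padded by 15% per
   side; the bin axis doubles as the "stretched" standardized axis, and cut
   points are mapped back through the inverse affine stretch.
2. Envelope: Gaussian smoothing of the counts, default σ = 6 bins. The width
   is chosen so the envelope's kernel tails bridge the near-empty intensity
   gap between well-separated tissue modes; much narrower kernels leave
   zero-count plateaus between classes and the curvature signal degenerates.
3. Curvature signal: the second difference of `log1p(envelope)`, raised to
   the fifth power. On the log scale the signal spikes precisely where one
   mixture component stops dominating and the next takes over — i.e. at the
   inter-class density minima — rather than at the flanks of each component,
   which is where raw-envelope curvature peaks for well-separated modes. The
   `log1p` form leaves sparsely populated tail bins effectively linear, so
   isolated stragglers do not generate spurious corners. The fifth power is
   an odd, sign-preserving power; it amplifies the dominant slope changes
   relative to small fluctuations.
4. Peak selection: positive peaks above a threshold that starts at 50% of the
   signal maximum and halves per iteration (max 20) until at least four
   peaks exist *above the dominant histogram mode*; the four most prominent
   are kept and sorted. The dominant-mode restriction encodes a domain fact:
   background is the most populous class in a head FOV, and every class
   boundary lies above its mode. Fewer than four peaks (e.g. a
   single-Gaussian histogram) raises a parcellation failure; callers may
   fall back to quantile cuts.

Labels are assigned lower-inclusive/upper-exclusive: R1 below p₁, R2 in
[p₁,p₂), R3 in [p₂,p₃), R4 at and above p₃ (intensities above p₄ clamp to
R4 so every voxel is labelled). On four-component Gaussian mixtures with the
class proportions of a head FOV, the three lowest detected cut points land
within a few intensity units of the true inter-mode density minima across
seeds, and the fourth lands above the top class, where the labeling rule
ignores it.

## Features

- **Normalized distance**: Euclidean distance in index space from the voxel
  to the scanner central voxel (the inverse-affine image of the world
  origin, possibly fractional and outside the grid for restricted FOVs),
  multiplied by the voxel volume as defined. On the mandated 1 mm grid the
  multiplier is 1, so the unit ambiguity of that definition is inert.
- **Cardinality**: the FOV is divided into blocks of 16×16×16 voxels
  (configurable); blocks are numbered consecutively along x, then y, then z
  (row-major block index), and each voxel carries its block number.
  Dividers longer than an axis clamp to a single block.
- **Neighboring**: for each of the 26 unit directions, the test
  `|I(V) − I(V_N)| > ratio·|I(V_N) − I(V_NN)|` (strict, ratio 0.2) is
  evaluated; directions whose first or second step leaves the FOV contribute
  0. On a constant image the strict inequality `0 > 0` fails everywhere and
  the feature is identically zero.
- **Candidate pool** (for selection studies): raw intensity, discrete
  6-connected Laplacian, Laplacian of Gaussian at σ ∈ {1,2,3} voxels.

## Estimator

Features are z-scored with parameters fitted on the training rows only. The
HCI parcellation factor is *categorical* — CSF (R2) is not metrically
between background and grey matter — so it enters the linear model as four
indicator columns, the standard encoding of a categorical covariate; the
feature table keeps the one-column-per-feature layout and the expansion
happens inside the estimator. Without this, the positive class ("R2 and near
the isocenter") is a middle box that no single hyperplane can carve from an
ordinal axis, and the classifier leaks into background at the head pole and
white matter at the isocenter.

The classifier is a linear SVM (liblinear primal, deterministic), with the
regularization strength tuned over a log grid (default 5 points in
[10⁻², 10²]; the selection module uses the 50-point [10⁻⁴, 10³] grid) by
subject-grouped cross-validation within the training subjects. Ventricle
voxels are well under 1% of a head FOV, so classes are weighted by inverse
frequency, and an optional seeded negative-class subsampling (default 8
negatives per positive in the pipeline) keeps large cohorts tractable
without discarding any positive voxel. Decisions threshold the margin at
zero; no probability calibration and no post-processing by default (a
largest-connected-component filter exists behind a flag, off by default).

Data is always partitioned by subject: each evaluation fold re-randomizes a
0.75:0.25 train:test subject split (with 44 subjects, 33 train / 11 test),
and after fold-wise reporting the published estimator is refitted on all
subjects. Whether folds should instead rotate one fixed partition was open;
re-randomized seeded partitions were chosen as the variance-revealing
option. Trained estimators serialize as versioned JSON (feature names,
encodings, scaler parameters, weights, bias, metadata) — portable and
diffable, never a pickle.

## Feature selection

The "strong force" search enumerates every non-empty subset of the candidate
features (order is irrelevant to a classifier, so enumeration over subsets
subsumes enumeration over ordered groupings, and an inner k-best filter
would be redundant once the subset is explicit). Each subset is scored by
the best mean subject-grouped cross-validated accuracy over the C grid, with
standardization fitted inside each training fold. Ties break toward the
smaller subset by enumeration order.

## Synthetic phantoms

The generator emulates what the features respond to in a clinical T1 head
scan: four intensity classes in T1 order (background 10, CSF 60, grey matter
110, white matter 180, arbitrary units) arranged as a grey-matter shell
(semi-axes 24×26×22 mm) around a white-matter core (17×20×16 mm) in a 56³
grid at 1 mm; a mirrored pair of ventricle ellipsoids (semi-axes 4×8×5 mm at
±7 mm laterally) rasterized at voxel centres into the truth mask; additive
Gaussian noise (default σ = 6, i.e. SNR ≈ 30 against white matter, typical
of clinical T1); a global contrast multiplier; and an isocenter offset.
Cohorts jitter ventricle scale uniformly in [0.75, 1.35] with a 25%
hydrocephalus-like tail in [1.45, 1.75] (the cap keeps enlarged ventricles
inside the white-matter core), contrast in [0.85, 1.15], noise σ in [4, 8]
and isocenter offset in ±3 mm per axis — standing in for the flip-angle,
averaging and positioning variability of clinical protocols. The optional
cyst confounder is a CSF-intensity sphere (radius 3.5 mm) touching, not
overlapping, a ventricle on its −y side, and absent from the truth mask.

Deliberate simplifications: additive Gaussian rather than Rician noise
(adequate at these SNRs and simpler to reason about); *no partial-volume
mixing* — every voxel is a pure class draw; no bias fields or k-space
artifacts; no anatomical realism beyond nested ellipsoids. Consequently the
phantom suite demonstrates pipeline correctness and the geometry of the
feature space, not clinical accuracy: held-out phantom Jaccard near 1.0
should be read as "the pipeline recovers what its features can express", and
performance on real data will be bounded by partial volume effects, anatomy
and artifacts that the phantom deliberately omits. The cyst experiment shows
the converse: a confounder sharing the CSF signature is absorbed into the
mask, exactly the failure mode intensity-driven segmenters show on
arachnoid cysts adjacent to the ventricles.

## Problem sizes and numerical choices

The test and acceptance suites run the end-to-end experiment at 30 training
+ 10 held-out phantoms of 56³ voxels (≈5M training rows before the 8:1
negative subsampling), histogram-recovery checks on 250k-sample mixtures
over 20 seeds, and the exhaustive selection on 8-subject synthetic tables —
sizes chosen so the whole suite completes on a single CPU in minutes while
every check retains its statistical teeth. Degenerate inputs fail loudly and
early: constant images (no histogram), single-class labels, zero-variance
features (named in the error), empty split sides, ventricles escaping the
white-matter core. Both-empty masks score Jaccard 1.0 (perfect agreement on
absence). Determinism: all randomness flows from explicit integer seeds;
the SVM uses the deterministic primal solver, so training, selection and
pipelines are bit-reproducible given (inputs, config, seed).

## Known limitations

- The phantom's class separation (gaps ≥ 50 with σ ≤ 8) is generous; very
  low-contrast acquisitions would stress the parcellation before anything
  else, and its failure mode (an exception, with a quantile fallback left to
  the caller) is blunt.
- A single linear hyperplane over four features cannot represent ventricle
  shape; everything CSF-like near the isocenter is segmented, as the cyst
  experiment shows.
- The cardinality feature is near-constant-weight in trained models on
  phantoms (symmetric geometry); its value would only show on asymmetric
  pathology.
- DICOM ingestion is a single-series convenience wrapper, not a validated
  clinical path; NIfTI is the supported format.
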