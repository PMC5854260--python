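"""Full workflow: train the voxel classifier, segment held-out subjects,
and evaluate volumes against ground truth.

Training folds are split by subject (0.75:0.25), never by voxel; the final
estimator is refitted on all training subjects and applied to new volumes by
extracting the same four features and thresholding the linear decision
function at zero.  The last subject carries a CSF-intensity cyst adjacent to
a ventricle — a confounder absent from training that inflates its automatic
volume, the classic failure mode of intensity-driven ventricle segmenters.
"""

import avve

cohort = avve.generate_cohort(12, seed=9)
train, test = cohort[:9], cohort[9:]
cfg = avve.RunConfig(folds=3, seed=9)

est, folds = avve.run_training_pipeline(
    [p.volume for p in train], [p.mask for p in train],
    [p.subject_id for p in train], cfg,
)
print("fold report (held-out subjects only):")
print(folds.to_string(index=False))
print("\nhyperplane weights:")
for name, w in zip(est.feature_names, est.weights):
    print(f"  {name:>24}: {w:+.3f}")

cyst = avve.generate_phantom(avve.with_cyst(test[-1].spec))
vols = [p.volume for p in test[:-1]] + [cyst.volume]
masks = [p.mask for p in test[:-1]] + [cyst.mask]
ids = [p.subject_id for p in test[:-1]] + ["with-cyst"]
frame, _ = avve.run_segmentation_pipeline(vols, masks, ids, est, cfg)
print("\nheld-out evaluation (volumes in mm^3):")
print(frame.drop(columns="error").round(3).to_string(index=False))
print("\nNegative difference on 'with-cyst': the adjacent cyst is CSF-bright "
      "and near the isocenter, so it is absorbed into the automatic mask and "
      "the volume is overestimated; clean subjects agree to within a few "
      "voxels.")
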