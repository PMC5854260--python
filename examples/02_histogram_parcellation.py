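"""Parcellate a volume's intensity histogram into the four tissue classes.

MR contrast varies between acquisitions, so the cut points separating
background, CSF, grey matter and white matter are found per volume: the four
most prominent curvature peaks of the (log) histogram envelope.  Every voxel
then carries its interval label R1..R4 as the HCI feature.
"""

import numpy as np

import avve

phantom = avve.generate_phantom(avve.PhantomSpec(seed=3))
env = avve.compute_envelope(phantom.volume)
bounds = avve.detect_boundaries(env)
labels = avve.assign_labels(phantom.volume, bounds)

print("volume intensity range:",
      f"[{phantom.volume.data.min():.1f}, {phantom.volume.data.max():.1f}]")
print("detected cut points p1..p4:",
      [f"{p:.1f}" for p in bounds.as_tuple()])
print("generative class means (BG, CSF, GM, WM):",
      phantom.spec.class_means)

counts = np.bincount(labels.ravel(), minlength=5)[1:]
for r, (count, tissue) in enumerate(zip(counts, ("BG", "CSF", "GM", "WM")), 1):
    print(f"  R{r} ({tissue:>3}): {count:7d} voxels")

csf_labels = labels[phantom.mask.data]
print(f"\n{(csf_labels == 2).mean():.1%} of true ventricle voxels carry the "
      "CSF label R2 — the cut points fall in the empty intensity ranges "
      "between the class modes, so labels track tissue despite noise.")
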