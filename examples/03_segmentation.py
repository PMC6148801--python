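"""Segment insects into body / wing / background and persist the model.

Pixels are robust-scaled, reduced to 3 principal components and clustered
with K-means (k = 3). Storing the scaler, PCA basis and centroids lets new
images be labelled by nearest centroid without refitting or re-inspection.
"""

import tempfile

import numpy as np

import whitefly_msi as wm
from whitefly_msi.pipeline import fit_segmentation_on_scenes, segmentation_agreement

config = wm.SceneConfig()  # grey-card background, one insect per scene
train_scenes = wm.generate_scenes(config, n_scenes_per_class=3, seed=5)
model = fit_segmentation_on_scenes(train_scenes, seed=5)

evr = model.basis.explained_variance_ratio
print(f"variance explained by 3 PCs: {100 * evr.sum():.1f}%  (per PC: "
      + ", ".join(f"{100 * v:.1f}%" for v in evr) + ")")

with tempfile.TemporaryDirectory() as d:
    model.save(f"{d}/seg.model.json")
    reloaded = wm.SegmentationModel.load(f"{d}/seg.model.json")

new_scenes = wm.generate_scenes(config, n_scenes_per_class=2, seed=99)
agreement = segmentation_agreement(new_scenes, reloaded)
print(f"anatomy agreement with truth on unseen scenes: {100 * agreement:.2f}%")

cube, truth = new_scenes[0]
labels = wm.segment_cube(wm.trim_bands(cube), reloaded)
counts = {name: int((labels == code).sum())
          for code, name in ((0, "background"), (1, "body"), (2, "wing"))}
print("pixel counts on one scene:", counts)
print("-> only the body pixels feed the species classifier downstream")
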