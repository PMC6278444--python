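"""Render a pixel-wise prediction map for a held-out two-variety scene.

Trains a pixel-level SVM on representative pixels from a small study, then
classifies every ROI pixel of a mixed-class scene and paints the result.
"""

import numpy as np

import hsichem as h
from hsichem.classify import SVMConfig
from hsichem.evaluate import prediction_map, render_prediction_map
from hsichem.pipeline import RunConfig, build_tables

cfg = RunConfig.preset("desk", scenes_per_group=2)
scenes = h.generate_study(
    scenes_per_group=2, base_config=cfg.scene_config(), master_seed=11
)
pixels, _ = build_tables(scenes, cfg)
sel = h.select_by_pca_loadings(h.pca_fit(pixels.spectra, 7), n_select=17)

keep = h.select_representative_pixels(pixels.spectra, n_groups=400, seed=0).indices
X = pixels.spectra[keep][:, sel.band_indices]
y = pixels.meta["class"].to_numpy()[keep]
_, _, model = h.grid_search_svm(X, y, SVMConfig(log2_step=2.0), seed=0)
print(f"pixel SVM trained on {len(X)} representative pixels: "
      f"C={model.params['C']:g}, gamma={model.params['gamma']:g}")

# a fresh scene containing both varieties
scene = h.generate_scene(
    h.SceneConfig(seed=99), h.default_signatures(), class_assignment=["A", "B", "A", "B"]
)
corrected = h.correct_reflectance(scene.raw, scene.refs)
objmask = h.label_objects(h.segment_background(corrected))
raster, preds = prediction_map(model, corrected, objmask, sel.band_indices)

fg = (objmask.labels > 0) & (scene.truth.label_map > 0)
truth = np.array([scene.truth.class_codes[c] for c in scene.truth.class_map[fg]])
got = np.array([model.classes[r - 1] for r in raster[fg]])
print(f"map covers {int(fg.sum())} ROI pixels; "
      f"{100 * np.mean(got == truth):.1f}% agree with ground truth")

out = render_prediction_map(raster, list(model.classes), "scratch/prediction_map.png")
print(f"map image written to {out}")
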