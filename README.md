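# hsichem

Near-infrared hyperspectral image chemometrics for two-variety
classification of food kernels (e.g. raisin cultivars on a dark tray),
covering the full chain from raw line-scan cubes to per-pixel prediction
maps:

1. **Reflectance correction** of raw counts with white/dark reference
   frames: `R = (I_raw − I_dark) / (I_white − I_dark)`.
2. **Background segmentation** by thresholding the band nearest 1119 nm at
   reflectance 0.122, followed by 8-connected component labelling into
   per-kernel regions of interest (ROIs).
3. **Spectral preprocessing**: Daubechies-7 wavelet smoothing at
   decomposition level 3, then the standard normal variate (SNV) — each
   pixel spectrum is centred and scaled to zero mean and unit sample SD,
   removing the per-pixel multiplicative/additive scatter of granular
   samples. Object-wise spectra are the per-ROI means of the preprocessed
   pixel spectra.
4. **Effective-wavelength selection** from 200 collinear bands
   (975–1646 nm): by PCA loadings (band score = max over the first 7 PCs of
   `sqrt(EVR_j)·|l_jb|`, restricted to local maxima of the score profile)
   or by FastICA unmixing weights (mean `|W|` per band).
5. **Classification** with an RBF-kernel SVM (`(C, γ)` grid-searched over
   `2⁻⁸…2⁸` by stratified cross-validation), k-nearest neighbours, and an
   RBF network (Gaussian unit per training row, ridge least-squares
   readout). Huge pixel calibration sets are shrunk by k-means
   representative selection: cluster, then keep each cluster's
   nearest-to-centroid pixel.
6. **Evaluation designs**: an image-level 2:1 calibration/prediction split;
   a 3×3 *grade-transfer* grid (train on one size grade, predict all); and
   the *four-way* crossing of pixel-wise and object-wise spectra between
   training and prediction, with per-class `correct/total` counts,
   accuracy, sensitivity and specificity. Pixel-wise models also render
   per-pixel prediction maps.

Because no public image collection accompanies this kind of study, the
package ships a first-class **synthetic scene generator**: elliptical
kernels of three size grades with class signatures carrying absorbance dips
at 1123/1210/1308/1473 nm, a dark background, per-pixel scatter
(gain + offset), sensor noise and rippled white/dark frames — with full
ground truth, so every stage is testable end to end.

## Worked example

`examples/04_classify_four_way.py` builds an 18-scene study (2 classes × 3
grades × 3 scenes of 64×64×200), splits it 2:1 at the image level, selects
17 pixel-wise and 20 object-wise wavelengths by PCA loadings, and runs the
four-way design:

```
12 calibration scenes, 6 prediction scenes

prediction-set accuracy (%):
classifier          knn  rbfnn    svm
mode
object_to_object 100.00 100.00 100.00
object_to_pixel   99.67  99.67  99.67
pixel_to_object  100.00 100.00 100.00
pixel_to_pixel    99.33  99.67  99.33
```

Rows are `train level → predict level`. Object-wise prediction matches or
beats pixel-wise prediction because averaging a kernel's pixels suppresses
the per-pixel noise; the remaining pixel-level errors sit at kernel edges
where scatter is strongest. The other examples cover scene simulation and
correction (`01`), what WT+SNV removes (`02`), wavelength selection by PCA
vs ICA (`03`) and prediction-map rendering (`05`).

A thin CLI wraps the same machinery:

```bash
hsichem simulate --preset desk --seed 0 --out study/   # scenes + ground truth
hsichem run      --preset desk --seed 0 --out run/     # full pipeline
```

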