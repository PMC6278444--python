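# Methods

## The measurement model

A line-scan NIR imager records a raw cube `I_raw(r, c, b)` over 200 bands
spanning 975–1646 nm. Two reference frames calibrate it: a white bar of
near-100% reflectivity (`I_white`) and a closed-shutter dark frame
(`I_dark`). Relative reflectance is

    R = (I_raw − I_dark) / (I_white − I_dark),

applied elementwise with the references broadcast across bands (frames may
be 2-D per-pixel maps, the line-scan case, or full cubes). The correction
is refused when any white pixel does not exceed its dark counterpart, since
the ratio is then undefined.

Foreground is separated from the dark tray by thresholding a single band:
the band nearest 1119 nm (ties to the lower wavelength), with pixels
strictly above reflectance 0.122 kept as foreground. The strict inequality
is a deliberate convention — a pixel exactly at the threshold counts as
background — and both band and threshold are parameters. ROIs are
8-connected components of the foreground mask; components under 5 px are
discarded as salt noise. All rasters are row-major, 0-based, `(row, col)`
with the band axis last.

## Spectral preprocessing

Each ROI pixel spectrum is smoothed by a Daubechies-7 wavelet decomposition
at level 3 and reconstructed from the level-3 approximation with all detail
coefficients zeroed. This is a deterministic, parameter-free low-pass and a
*linear* operator, which makes its interaction with later linear algebra
easy to reason about; a soft-threshold alternative (universal threshold,
noise scale from the median absolute finest-detail coefficient) is exposed
via `detail="soft"` for users who prefer classical wavelet denoising.
Signals are extended symmetrically at the boundaries; the outermost bands
are therefore slightly biased toward their reflections, which is visible in
selector diagnostics as inflated edge scores on noisy components. Spectra
shorter than the level-3 db7 minimum (104 bands) are rejected rather than
silently decomposed to a shallower level.

SNV then centres and scales each spectrum to zero mean and unit *sample*
standard deviation (n−1 denominator — a documented constant; the choice
only rescales all spectra by a common factor). SNV removes exactly one
multiplicative gain and one additive offset per spectrum, which is exactly
the scatter structure granular samples produce. Zero-variance spectra are
rejected with their row index.

Object-wise spectra are the arithmetic means of each ROI's *preprocessed*
pixel spectra — preprocessing first, averaging second, so the scatter is
removed before it can bias the mean.

## Effective-wavelength selection

NIR bands are highly collinear; a few effective wavelengths carry the
discriminative information.

**PCA loadings.** PCA is fit on (pixel- or object-wise) preprocessed
spectra; 7 components are retained by default, the number that explains
>99% of variance on data of this kind. Each band `b` is scored
`max_j sqrt(EVR_j) · |l_jb|` over the retained components `j` — the
eigenvector-times-root-eigenvalue loading convention. The variance
weighting matters: all loading columns are unit vectors, so an unweighted
max lets noise components (whose loadings concentrate at wavelet-biased
spectrum edges) outrank the class-contrast component that actually carries
the signal; weighting by the square root of the explained-variance ratio
restores the dominance of the informative components while still letting a
strong secondary component contribute bands. Candidate bands are local
maxima of the score profile (a plateau counts once, at its lowest
wavelength), so the shoulders of one absorbance feature collapse to a
single pick; the top `n_select` by score (ties to the lower wavelength) are
returned, filled from non-peak bands when peaks run out. Selected bands are
reported sorted ascending in wavelength.

**ICA weights.** FastICA (fixed seed, `whiten="unit-variance"`,
non-convergence raised as an error with the iteration budget) estimates
sources `ŝ = W·(X − mean)`; each band is scored by the mean absolute
unmixing weight across components and the top `n_select` kept. The number
of components defaults to 7, mirroring the retained PCs. Sign and
permutation indeterminacy of ICA is inherent; tests compare sources up to
both.

`n_select` defaults to 20 for object-wise and 17 for pixel-wise selection.
These counts are user parameters, not outputs of a rule — nothing in the
method forces a particular cardinality.

## Classifiers

* **SVM** (RBF kernel): `(C, γ)` chosen by exhaustive grid search over
  `2⁻⁸…2⁸`, default log2 step 1.0 (a 17×17 grid; configurable finer),
  scored by stratified 5-fold cross-validated accuracy on the calibration
  set. Ties resolve to the smaller C, then smaller γ; the winner is refit
  on all calibration rows. Folds shrink automatically when a class has
  fewer members than folds.
* **k-NN**: Euclidean distances, `k` = 3 (pixel-wise) or 5 (object-wise)
  by default, uniform or inverse-distance weighting. Tie handling is part
  of the contract: equidistant training rows enter in index order (stable
  sort) and a tied vote falls back to the class of the single nearest
  neighbour.
* **RBF network**: one Gaussian hidden unit per training row with a common
  spread, output weights by ridge-regularised least squares onto one-hot
  labels (closed form, deterministic; exact interpolation as ridge → 0 for
  distinct rows). The default spread is the median pairwise training
  distance — a scale-free heuristic that keeps the kernel matrix well
  conditioned across feature-set sizes; a fixed spread can be supplied.

**Representative-pixel selection.** Pixel calibration sets run to hundreds
of thousands of rows; k-means (k-means++ init, 10 restarts, fixed seed)
clusters each variety's pixels — all grades pooled — into `n_groups`
groups and keeps each cluster's nearest-to-centroid member. With at most
`n_groups` rows the set is returned whole. The full-scale setting is
3000 groups; the desk preset uses 300, matching its smaller pixel counts.

## Evaluation designs

Scenes are split 2:1 into calibration and prediction sets *at the image
level*, stratified by class × grade, so no pixel of a held-out image leaks
into calibration (30 scenes per group split 20/10; n scenes split
`floor(2n/3)`).

**Grade transfer** probes robustness to kernel size: a model is calibrated
on all scenes of one grade (object-wise spectra, no inner split — the
own-grade cell of the 3×3 grid is a calibration result) and predicts every
grade.

**Four-way** crosses training and prediction levels for each classifier:
pixel→pixel, pixel→object, object→pixel, object→object. A pixel-trained
model scores an object by its average preprocessed spectrum restricted to
the pixel-wise effective wavelengths (hence the calibration columns of the
two pixel-trained rows are identical by construction); an object-trained
model scores prediction pixels directly at the object-wise wavelengths.
Both pixel calibration and pixel prediction sets pass through
representative selection, per variety.

Reports carry per-class `correct/total` counts; accuracy is pooled percent
correct, sensitivity the per-class accuracy of the designated positive
(first) variety, specificity that of the other. Metric identities are
re-verified in tests against an independent confusion-matrix computation.

**Prediction maps** assign every ROI pixel its predicted class; the raster
and the tabular predictions agree bitwise by construction, which is
asserted rather than assumed. Rendering uses a fixed two-class palette with
background black; PCA scores images use per-image min–max scaling and are
display-only.

## The synthetic scene generator

The generator emulates the study conditions the pipeline was designed for,
with every default chosen once as a realistic magnitude:

| parameter | default | meaning |
|---|---|---|
| bands / range | 200 over 975–1646 nm | analysed spectral axis |
| image shape | 64 × 64 | desk-scale frame |
| objects per scene | 4 | non-overlapping ellipses, axis ratio 0.6–1.0 |
| grade radii (px) | 8–10 / 6–7.5 / 4–5.5 | Grade1 > Grade2 > Grade3 in expectation |
| background | 0.05 reflectance | dark tray, below the 0.122 threshold |
| white / dark frames | ≈0.90 / ≈0.02 ± small ripple | makes the correction non-trivial |
| scatter gain SD | 0.12 | per-pixel multiplicative scatter |
| scatter offset SD | 0.02 | per-pixel additive scatter |
| noise SD | 0.01 | per-pixel-per-band sensor noise |

Class signatures are a baseline minus Gaussian absorbance dips at
1123/1210/1308/1473 nm (the C–H overtone bands and the water band); the
two default classes differ in baseline and dip depths, i.e. in *shape*, so
their contrast survives SNV. Class A's water dip is its deepest feature.
An optional per-grade drift term shifts a class's signature by
`(grade − 2) · scale` times a Gaussian bump (default centre 1570 nm, away
from the contrast bands), emulating composition that changes with kernel
size; Grade2 is drift-free, so drift degrades transfer from the extreme
grades more than from the middle one. The raw signal is

    raw = dark + (white − dark) · (R·gain + offset + noise),  clipped to [0, 1],

with one gain and one offset per pixel shared across bands — precisely the
structure SNV removes — so with zero noise and scatter the whole chain
through segmentation inverts the generative model exactly (≤1e−10), which
is the package's strongest self-check. All randomness flows from explicit
integer seeds (study seeds spawned from a master seed); there is no global
random state.

What the generator does **not** emulate: real kernel texture and
within-kernel compositional gradients, specular highlights, line-scan
motion blur, dead pixels, wavelength-dependent scatter. Passing tests
therefore demonstrate that the pipeline's machinery is correct and behaves
as the theory predicts under the stated noise model — not that any
particular accuracy would be attained on real images.

## Problem sizes and numerical choices

The desk preset (2 classes × 3 grades × 6 scenes of 64×64×200, 300 k-means
groups) is the package's standard experiment size, chosen so a full study
runs in about a minute on one CPU; the full preset (30 scenes per
group, 3000 groups) keeps the study-scale constants. Tolerances used
throughout: exact identities at 1e−10…1e−12 (correction, SNV, averaging),
linear-algebra oracles at 1e−8 (PCA/ICA), stochastic properties asserted
over multiple seeded replicates. Degenerate inputs are errors, not
warnings: zero-variance SNV rows, white = dark reference pixels,
infeasible object placement (bounded retries, then an error naming the
constraint), FastICA non-convergence, component requests beyond data rank.

## Known limitations

* The ENVI reader/writer covers the float BSQ/BIL subset this pipeline
  emits, not the full ENVI dialect zoo.
* Binary classification is assumed throughout the evaluation designs; the
  classifier layer itself is multiclass-clean but the reports designate one
  positive class.
* The PCA selector's local-peak rule depends on the score profile's
  smoothness; on very short spectra (few bands) most bands are peaks and
  the rule degenerates to plain ranking.
* Wavelet boundary handling biases the outermost bands; selections that
  repeatedly pick the first or last band on noisy data should be read with
  that in mind.
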