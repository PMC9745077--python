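# Methods

## Problem and model

A satellite multispectral pixel over an infested cotton field is a mixture:
part of the 10 m footprint is canopy stressed by aphids, part is healthy
background canopy. Under the linear spectral mixing model the pixel spectrum
is

    gamma(lambda_i) = sum_j F_j * gamma_j(lambda_i) + xi(lambda_i),

with endmember spectra `gamma_j`, abundances `F_j` and sensor noise `xi`.
For the two-endmember case (stressed fraction `F1`, healthy background
`F2`), dividing band-by-band by the background endmember and differentiating
with respect to wavelength gives

    d/dlambda (gamma / gamma2) = F1 * d/dlambda (gamma1 / gamma2),

so the derivative-of-ratio (DRS) feature vector is independent of the
background abundance `F2` and exactly linear in `F1`. This is the algebraic
core of the package (`aphiddrs.drs`), and both properties are asserted
numerically to 1e-10 relative tolerance in the test suite.

On the 10-band working subset of Sentinel-2B (B1–B8, B8A, B9; centers
442.3–943.2 nm) the derivative is implemented as the first-order forward
difference between adjacent band centers, divided by the center spacing in
nm and labeled by the left band of each pair — ten bands yield nine
features. Bands whose background reflectance falls inside the zero-divisor
guard (`eps = 1e-6` reflectance) are flagged invalid and dropped before
differencing. Forward differences over nm spacing were chosen because that
scheme uniquely produces nine features from ten bands; using band index
instead of nm as the denominator would only rescale each feature and leaves
tree-based classifiers unchanged.

## Sensor resampling

Narrow-band (1 nm) canopy spectra are converted to broadband reflectances
as the response-weighted mean `sum(w*r)/sum(w)` per band. The
normalization is deliberate: a constant reflectance must resample to itself
in every band, which an unnormalized integral does not guarantee. True
Sentinel-2B response curves are not bundled; the defaults are Gaussian
surrogates centered at the published band centers with nominal FWHM
bandwidths (B1 20, B2 65, B3 35, B4 30, B5 15, B6 15, B7 20, B8 105,
B8A 20, B9 20 nm). Measured response tables can be supplied as CSV
(`band_name, wavelength_nm, weight`) and override the surrogates.

## Synthetic data: what it emulates

The generator (`aphiddrs.synthetic`) provides every input the pipeline
needs without any download:

* **Healthy canopy spectrum** — parametric green-vegetation curve on a
  325–1075 nm grid: pigment troughs in blue/red, green bump at 550 nm,
  logistic red edge (midpoint 718 nm, scale 9 nm), NIR plateau near 0.5,
  shallow 970 nm water dip.
* **Severity effect** — aphid grade g in 0..4 multiplies visible
  reflectance by `1 + 0.15 g` (weighted by a Gaussian bump centered at
  620 nm, sigma 90 nm), multiplies NIR reflectance by `1 - 0.08 g`
  (weighted by a logistic ramp with midpoint 760 nm, scale 60 nm), and
  shifts the red edge left by `3 g` nm. The magnitudes are surrogates
  constrained by the qualitative field behavior (visible reflectance rises
  and NIR falls monotonically with grade); the wavelength *weights* are a
  deliberate design choice: a spectrally flat multiplier would cancel in
  the DRS derivative, whereas smooth wavelength-dependent weights give the
  stressed/healthy ratio a grade-proportional slope inside band segments,
  which is what the transform measures. With these defaults the
  visible-segment DRS features correlate positively with grade and the
  NIR-plateau feature (segment B8, 833→864 nm) negatively — the sign
  pattern the band-selection stage expects to recover.
* **Scenes** — 64×64 pixels at a single 10 m-equivalent resolution, six
  spatially clustered classes (cotton 40%, pear 15%, bare 20%, building
  10%, road 8%, cloud 7%) carved from a smoothed Gaussian random field
  with exact class counts. Cotton pixels are two-endmember mixtures with
  stressed fraction `F1 ~ U(0.75, 0.95)` (closed boll-stage canopy
  dominated by the surveyed stress), grade field clustered and weighted
  toward the scene border (aphids migrate in from field edges), per-band
  additive Gaussian noise with sd 0.002 (consistent with the radiometric
  SNR of modern multispectral sensors). A paired June scene has sparse
  cotton (soil-dominated mixture, NDVI ≈ 0.36) and dense pear orchard
  (NDVI ≈ 0.86), so the 0.45 NDVI threshold separates them exactly in the
  noise-free limit.
* **Ground points** — 60 survey points with grade counts 20/20/10/6/4,
  sampled without replacement from the cotton truth.

What the generator does **not** emulate: radiative-transfer realism
(PROSAIL-class canopy modelling), atmospheric residuals, sensor PSF/MTF,
mixed resolutions, or within-class endmember variability. Passing tests
therefore demonstrate the pipeline's algebra, plumbing and statistical
procedure — not field-level accuracy on real imagery.

## Cotton-area extraction

A five-class supervised classification (vegetation / buildings / roads /
bare lands / clouds; RBF support-vector machine by default, pluggable, with
a truth-oracle option for exact tests) yields the July vegetation mask; the
June NDVI threshold (strict `> 0.45`, ties fall to cotton) yields the pear
mask; cotton = vegetation AND NOT pear. The background endmember for
pixelwise DRS is the mean July band vector of the grade-0 *training*
points — the reproducible stand-in for "a healthy cotton spectrum".

## Band selection and grading

Pearson correlation between the ordinal grade of the 60 points and each of
the nine DRS features, two-sided t-test p-values, significance tiers at
0.05/0.01/0.001 (starred `*`/`**`/`***`); features with `p <= 0.01` become
classifier inputs. Constant features are flagged undefined and excluded.

Grades are treated as nominal classes for classification. The points are
split 2:1 (40 train / 20 test), stratified by grade with a fixed seed so
all five grades appear in the test set; a grade with fewer than 3 points
triggers a warning and a best-effort split. Hyperparameters are selected
by stratified k-fold cross-validation on the training split only (default
5 folds, capped by the rarest training grade; random forest grid: 100/300/
500 trees × sqrt/all features). Decision tree, RBF SVM and a
backpropagation network (one hidden layer of 16 units, standardized
inputs) are available under the same contract; the spectral angle mapper
is implemented directly (per-class mean reference vectors, angle
`arccos(x·ref/|x||ref|)`, ties to the lower class index) and is exactly
scale-invariant.

Accuracy is reported as a confusion matrix with rows = predicted and
columns = truth: overall accuracy `OA = sum(n_ii)/n`, user's accuracy
(row-wise), producer's accuracy (column-wise), and kappa
`(n*sum(n_ii) - sum(row_i*col_i)) / (n^2 - sum(row_i*col_i))`.

## Numerical choices

* Zero-divisor guard on the background: 1e-6 reflectance; guarded bands
  propagate as missing features and shrink the derivative feature set.
* Vegetation indices use the standard literature forms; indices with a
  vanishing denominator return NaN rather than raising. mNDVI705 is only
  bounded in [-1, 1] when blue reflectance stays below both red-edge
  bands, the physically typical ordering.
* All stochastic stages derive child seeds deterministically from the one
  pipeline seed; identical configurations produce byte-identical run
  reports.
* Benchmark problem sizes (64×64 scenes, 60 points, 10 comparison seeds)
  were chosen as the smallest sizes at which every grade has enough cotton
  pixels for the survey design and the comparison means stabilize.

## Known limitations

* Under the constrained two-endmember mixing model (`F1 + F2 = 1`, one
  scene-wide background endmember), raw band vectors and DRS features are
  related by a fixed affine map: DRS removes a direction that carries no
  between-pixel variance. The DRS-vs-raw accuracy comparison on this
  benchmark is therefore a statistical tie near perfect accuracy, and at
  higher noise DRS is *worse* than raw bands, because the ratio divides
  sensor noise by the small visible-band background reflectance
  (~0.04–0.08). Field reports of large DRS gains on real imagery involve
  background variability (soil fraction, illumination, canopy density)
  that this constrained generator deliberately does not model.
* Severity-grade amplitudes scale multiplicatively with `F1`, so for wide
  abundance ranges adjacent high grades overlap in feature amplitude in
  any linear feature space; the default `F1` range keeps grades separable
  noise-free.
* Real-product concerns — atmospheric correction, mosaicking, reprojection,
  mixed band resolutions — are out of scope; rasters are plain multiband
  TIFF with band order fixed by the working BandSet.
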