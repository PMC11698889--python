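# Methods

`lamap` implements a quantitative analysis chain for laser-ablation
ICP-ToF-MS elemental bioimaging of tissue sections: despiking, intensity
thresholding of the glass/adipose background, external calibration against
matrix-matched gelatine standards, response-factor normalization for an
uncalibrated element, and nonparametric region/group statistics.  Because
no raw clinical ablation data is distributable, every stage is validated on
ground-truthed synthetic phantoms generated by `lamap.synthetic`.

## Processing model

### Rolling-median despiking

Each element map is filtered with an edge-truncated `size x size`
(default 5 x 5) rolling window.  For pixel value `x` with window median `m`
and scaled median absolute deviation `s = 1.4826 * MAD`, the pixel is
replaced by `m` iff `|x - m| > k * s` (default `k = 3.0`); all other pixels
pass through bit-identically.  Choices pinned here:

* **Deviation measure.** The gate is the scaled MAD, the standard robust
  dispersion estimate; a plain-SD variant can be obtained by changing the
  gate, but is not exposed because the MAD gate is what makes single-pixel
  spikes removable in the presence of other spikes in the window.
* **Edges.** Windows are truncated at the image border; no padding values
  are invented.
* **Tie behaviour.** `|x - m| > k*s` is strict, so a constant window
  (`s = 0`, `x = m`) is never modified, while an isolated spike in a flat
  field (`s = 0`, `x != m`) always is.

### k-means background thresholding

Pixel intensities of each element are clustered independently (1-D
k-means, default `k = 3`) into background, low- and high-signal tissue.
Clusters are ordered by centroid; all pixels in clusters below index `t`
(default `t = 1`, i.e. only the lowest cluster) are masked.  The mask is
reproduced by a single scalar: the threshold is the minimum intensity
assigned to cluster `t`, and pixels `>= threshold` are retained (ties
retained, deterministic).  Lloyd's algorithm with k-means++ initialization,
10 restarts, `tol = 1e-8`, fixed seed: 1-D instances are cheap and the
restarts make the stochastic optimum reliably attained — the test suite
checks equality with an exact dynamic-programming 1-D clusterer.
Masking is monotone in `t`, and `t` can be overridden per element in the
run configuration.

Despiking runs **before** thresholding: salt spikes otherwise capture the
top cluster and drag the background/tissue boundary into the tissue
distribution.

The point of the mask is bias correction: glass and adipose pixels pull
the whole-image median far below the tissue median, so group-level
"sample medians" are computed over the retained pixel set.  Region-vs-region
comparisons (adipose vs epithelial, tumor niche vs stroma) instead use the
histology (H&E) annotation directly, without the k-means mask — the two
pixel-selection routes serve different questions and both appear in the
summaries table (the mask route under the pseudo-region name `retained`).

### Calibration and LOQ

Per standard, the mean intensity over all line pixels (target geometry:
5 lines x 200 pixels) is regressed by unweighted OLS on the *independently
measured* (acid-digestion) concentration — not the nominal spike value,
since spiking is the least reliable step of standard preparation.  The
blank standard deviation pools all blank pixels (`ddof = 1`).  The limit of
quantification is the 10-sigma convention, `LOQ = 10 * SD(blank) / slope`.
Calibrated maps are `(I - intercept) / slope`; pixels below the LOQ are
flagged in a companion mask but **not censored**, and negative calibrated
values are retained and counted — censoring or clipping would bias
low-concentration medians upward.  A fit with `R² < 0.98` triggers a
warning (well-behaved gelatine calibrations run ≈ 0.987–0.997), and a
non-positive slope is an error.

Barium carries no matched standards; its signal is converted to
Sr-equivalent µg/g through a single-point response factor from a spiked Sr
gelatine standard of 1.31 µg/g: `value = I * ref_conc / ref_intensity`,
with `ref_intensity` the *mean* intensity of the reference block (mean, not
median, to mirror how calibration standards are averaged).  This is a
response-factor estimate, not a matrix-matched calibration, so no LOQ is
attached and the unit string says so.

### Statistics

The inferential unit is always the **per-sample region median** (with
Q1/Q3, linear-interpolation quantile convention), never pooled pixels,
which would pseudo-replicate massively.  The battery:

* **Mann–Whitney U, one-tailed**, between patient groups (H = healthy,
  NM = non-metastatic, M = metastatic), testing elevation in the
  later/cancer group of each pair.  Exact null when `n1 + n2 <= 20` without
  ties, else normal approximation with tie and continuity corrections.
* **Wilcoxon signed-rank, two-tailed**, for paired regions within samples
  (adipose vs epithelial; tumor niche vs stroma).  Zero differences are
  dropped; at least 3 nonzero pairs required.  Exact null for `n <= 25`
  without tied |differences|; with ties at `n <= 15` the 2^n sign-flip
  permutation null is enumerated exactly (the classical exact table is
  invalid under ties); otherwise the corrected normal approximation.
  Samples lacking a stroma region are excluded from the stroma comparison
  with a logged count.
* **Spearman rank correlation** of two element maps within the epithelial
  mask (>= 10 pixels, non-constant inputs) for Sr–Ba colocalization, with a
  strength label on the signed coefficient: strong >= 0.8, moderate
  [0.4, 0.8), weak below.  Published strength conventions in this area are
  mutually inconsistent around 0.6–0.7; these round thresholds match how
  coefficients from ≈ 0.46 upward are counted as at-least-moderate.
* **No multiple-testing correction** by default (the report can append
  Benjamini–Hochberg q-values as extra columns).  α = 0.05 throughout.

Groups with fewer than two samples skip their comparisons with a warning
rather than an error; a single-group cohort yields summaries only.

## Synthetic phantoms

### What is emulated

* **Standards**: gelatine blocks at 0–33 µg/g (Fe) and 0–19 µg/g
  (Cu/Zn/Sr), 5 lines x 200 pixels, plus the 1.31 µg/g Sr reference.  The
  true spike concentration deviates from nominal by a 2% CV preparation
  error; the digestion cross-quantification *measures* that true value
  (that is why it is performed), so the regression x-values are accurate
  while nominal values are not.
* **Sections**: an elliptical tissue on glass, disc-shaped adipose
  inclusions, the remaining epithelium optionally split into a central
  tumor niche (35% of the epithelium by default) and surrounding stroma.
  Healthy sections have no niche/stroma split; a configurable number of
  cancer samples lack stroma entirely (defaults: 5 of 7 NM and 8 of 11 M
  retain stroma, emulating widespread lesions).
* **Concentration fields**: lognormal per region — concentrations are
  positive and right-skewed (Q3 >> median), and the lognormal is the
  simplest law pinned down by a median with asymmetric quartiles:
  `mu = ln(median)`, `sigma = ln(q3/q1) / (2 z_0.75)` (exact for a
  lognormal).  Default epithelial medians/quartiles per element and group,
  and adipose values, are set to concentrations reported for healthy,
  non-metastatic and metastatic breast tissue cohorts (e.g. Fe 2.9 / 12.6 /
  6.6 µg/g; Sr 0.5 / 1.8 / 1.4 µg/g); the Ba NM entry and all adipose Ba
  values are interpolated choices since no reference value exists.
* **Sr–Ba dependence**: a Gaussian copula shared by the Sr and Ba fields,
  with the Pearson score correlation set by the sine relation
  `r = 2 sin(pi * rho_s / 6)` so the configured *rank* correlation
  (default 0.90) is hit exactly in distribution.
* **Patient-level variability**: each cohort sample draws one lognormal
  median multiplier per element (`sigma_b = 0.6`) applied to all its
  regions.  Without this layer every sample of a group would have the same
  field median up to sampling error and *every* group contrast would come
  out significant, which no small clinical cohort shows.  With it, large
  contrasts (healthy vs cancer, ≈ 2.5 sigma_b in the log) are reliably
  detected at n = 4/7/11 while the NM-vs-M contrast (≈ 1 sigma_b) is
  borderline — matching the qualitative pattern of interest.  Because that
  borderline contrast is genuinely a coin flip at these sample sizes, the
  test suite asserts median recovery and the H-below-cancer ordering, not a
  fixed NM-vs-M verdict.
* **Tumor niche vs stroma**: a per-element niche/stroma concentration
  ratio (defaults: Cu 1.6, Zn 1.8, Sr 1.5, Ba 1.4, Fe 1.0) applied
  symmetrically (`niche x sqrt(ratio)`, `stroma / sqrt(ratio)`) so the
  epithelial geometric mean is preserved.  Fe gets no systematic excess —
  its tumor signal is dominated by focal hot spots instead (below).
* **Noise**: Poisson counting noise on expected counts
  (`cps x dwell`, effective pixel time 23 ms ≈ 22 binned spectra of
  1.03 ms), converted back to cps, so SNR grows with concentration as in
  real ablation; sparse multiplicative salt spikes (probability 5e-4,
  factor 30); Gaussian glass background (50 ± 15 cps, clipped at zero) off
  tissue.  Fe hot spots (3 discs, radius 3 px, amplitude x8) appear in
  metastatic samples only.
* **Sensitivities** (cps per µg/g: Fe 2e4, Cu 3e5, Zn 1.5e5, Sr/Ba 8e4)
  are set so the lowest configured tissue concentration of each calibrated
  element still yields ≳ 200 expected counts per pixel; below that,
  per-pixel recovery claims would be meaningless for the low-abundance
  elements (tens of ng/g for Cu/Zn).

### What is *not* emulated

* **Spatial structure.** Fields are white (pixel-wise independent) by
  default; `field_smooth_sigma > 0` provides Gaussian-correlated texture,
  but real tissue morphology, ducts, and gradients are absent.  One
  practical consequence: on a white heavy-tailed field the despike filter
  replaces several percent of legitimate tail pixels (they look like
  spikes to a 5 x 5 window), which slightly attenuates pixelwise
  correlations measured on *filtered* maps.  Medians are essentially
  unaffected (robustness), and colocalization validation is therefore run
  on unfiltered maps; on spatially coherent real data the filter's
  false-replacement rate is far lower.
* Paraffin washout, spectral interferences, detector dead-time, ablation
  drift, and histological realism of region shapes.  The pipeline consumes
  labels and intensities, not morphology, so simple geometry is sufficient
  for what the tests claim.
* Phantom blank standards carry only counting noise, so synthetic LOQs
  (≈ 1–15 ng/g) sit below instrument-realistic values; LOQ correctness is
  validated as a formula and a flagging mechanism, not as an absolute
  level.

Passing tests therefore demonstrate algorithmic correctness and
parameter recovery under the stated statistical model — not robustness to
morphological artifacts absent from the phantom.

## Numerical choices and degenerate inputs

* Quantiles: NumPy linear interpolation (type 7) everywhere, pinned for
  reproducibility.
* Images must be finite and nonnegative; NaN cells are zero-filled on read
  with a logged count, never dropped (keeps grids and masks congruent).
* Constant images cannot be thresholded (error recommending no threshold
  exists); constant maps are rank-degenerate for Spearman (error); all-zero
  paired differences are a degenerate pairing (error).
* k-means requires at least `k` distinct values; the threshold for `t = 0`
  degenerates to the image minimum (nothing masked), which is permitted for
  testing.
* Determinism: every stochastic component (k-means restarts, all phantom
  draws, per-sample cohort seeds spawned from the master seed) is driven by
  explicit integer seeds; identical configuration + seed reproduces every
  output file byte-for-byte.

## Problem sizes used in the validation suite

Default phantom sections are 120 x 160 px (≈ 10^4 epithelial pixels);
end-to-end pipeline tests use 60 x 80 px cohorts of 8 samples, the
masking-bias sweep uses 100 seeds at 48 x 64 px, statistical level/power
simulations use 500/200 draws of the median model without rendering images,
and the colocalization recovery averages 20 phantom seeds.  These sizes
give sampling error comfortably inside the asserted tolerances (e.g.
median SE ≈ 1.6% at 10^4 lognormal pixels with sigma ≈ 1) while keeping
the full suite under a minute of compute.
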