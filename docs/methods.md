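# Methods

## The analysis

`ftir_radsig` implements an end-to-end analysis for detecting ionizing
radiation exposure from ATR-FTIR hyperspectral images of mouse ear skin.
The measurement is a 128×128 focal-plane-array image in attenuated total
reflection mode: each detector pixel holds a mid-infrared absorbance
spectrum (4096 points over 3900–900 cm⁻¹, ~8 cm⁻¹ nominal resolution) of
the stratum corneum in contact with a germanium crystal. Exposure leaves a
biochemical signature — altered protein secondary structure, lipid
accumulation and oxidation, DNA conformation changes — that is read out as
small changes in band intensities and positions.

The pipeline stages are:

1. **Pixel QC** (`qc`). A pixel survives if its amide signal-to-noise
   ratio is ≥ 200 and its amide/CO₂ ratio is ≥ 15; within each image pool
   the 100 quietest surviving pixels (lowest noise level) are kept. The
   amide signal is the maximum absorbance in the amide I window
   [1600, 1700] cm⁻¹ (the dominant band, so the SNR is best-case); the
   noise level is the standard deviation in the quiet [1800, 2300] cm⁻¹
   region; the CO₂ signal is the maximum in [2300, 2400] cm⁻¹. The amide
   band choice and the noise window are this package's definitions — the
   thresholds (200, 15, 100) are the study's constants, the windows are
   configurable. A vanishing denominator (no noise, no CO₂) passes the
   corresponding test: absence of a contaminant must not reject a pixel.
2. **Pretreatment** (`preprocess`), five steps in fixed order: (i) clip to
   [900, 3600] cm⁻¹; (ii) fill dead pixels (total absorbance below 10% of
   the image median) with the mean spectrum of live neighbors in a 5×5
   window; (iii) 5×5 spatial median filter per wavenumber channel;
   (iv) rubber-band baseline subtraction; (v) divide each spectrum by its
   maximum in the amide II region [1480, 1590] cm⁻¹. Spatial filters
   truncate their window at the image boundary rather than padding.
3. **Region pooling**: either the central 21×21 detector window (scaled as
   ⌊edge·21/128⌋ on reduced geometries) or an embedding-based outlier mask:
   pixels are embedded in 2-D on the 1500–1700 cm⁻¹ band and a pixel is
   rejected when its mean distance to its 20 nearest embedding neighbors
   exceeds the 99.5th percentile of that score. QC runs within the pooled
   region per image.
4. **Second-derivative biomarkers** (`derivative`). Savitzky–Golay second
   derivatives (window 5, polyorder 3, derivative w.r.t. wavenumber using
   the actual axis spacing) of group-mean spectra; biomarker bands are
   local minima near the sixteen canonical positions; intensity is the
   value at the minimum, peak-to-peak the mean of the flanking maxima
   minus the minimum; shifts are treated-minus-control minimum positions.
5. **Classification** (`classify`, `nn`). Pixel-level binary classifiers
   (exposed = dose > 0) over features from [900, 1800] ∪ [2800, 3050]
   cm⁻¹ of the preprocessed spectra: L1- and L2-regularized logistic
   regression, linear SVM, a fully-connected net and a 1-D CNN. Sample
   predictions are the majority vote of the sample's pixels; the positive
   vote fraction is the sample-level score for ROC analysis. Train/test
   splits are at the sample (and mouse) level.
6. **Evaluation** (`evaluate`). Balanced accuracy, empirical ROC/AUC on
   vote fractions, specificity at a sensitivity threshold (largest cutoff
   reaching the target sensitivity), dose and day strata (dose strata pool
   that dose's exposed samples with all controls), and sample-level
   permutation p-values, p = (1 + #{permuted ≥ observed}) / (1 + n_perm).

## Synthetic cohorts

No public dataset accompanies this analysis, so `synth` generates seeded
cohorts with the statistical structure the pipeline assumes. A spectrum is
a sum of Gaussian bands at the sixteen biomarker positions (amide I at
1648 cm⁻¹ dominant, amide II ~1, FWHM 14–30 cm⁻¹ per band class) plus a
broad amide A background, a quadratic scattering baseline, an atmospheric
CO₂ band at 2350 cm⁻¹ with per-pixel amplitude, i.i.d. Gaussian noise
(sd 0.005 in normalized units) plus a heteroscedastic term (1% of clean
absorbance), dead pixels (rate 1%, spectrum scaled below 0.05), per-mouse
amplitude effects (sd 5%), and per-pixel contact jitter (sd 5%).

Exposure effects follow the biomarker table: each band's amplitude changes
by `direction · Δ · 10⁻⁴ · σ² · day_multiplier`, so the *second derivative*
at band center changes by exactly Δ·10⁻⁴ (for a Gaussian `A·exp(−(ν−c)²/2σ²)`
the second derivative at `c` is `−A/σ²`). The O–P–O band moves 1236→1240
and the ester carbonyl 1735→1743 cm⁻¹ under exposure. The dose response is
flat (threshold-like) over 0.1–2 Gy by default; the day profile
{5: 0.5, 14: 1.0, 21: 0.9, 49: 0.7, 90: 0.4} encodes the time course that
peaks at 14 days. The amide I sub-bands (1691/1648/1626) use FWHM
18 cm⁻¹: at the default amplitudes this keeps second-derivative cross-talk
between the 22 cm⁻¹-separated 1648/1626 pair below ~20%, which is what
makes the injected Δ values recoverable from the difference spectrum.

Cohort design mirrors the study: doses {0, 0.1, 0.5, 1, 2} Gy ×
days {5, 14, 21, 49, 90}, one dose per mouse, two strains alternating,
train/test split assigned per mouse (60/40) so no mouse leaks across
splits. Identical (config, seed) yields bit-identical cohorts.

**What the generator does not emulate:** ATR evanescent-wave depth
weighting, water-vapor rotational structure, strain-specific spectral
differences, spatially correlated tissue heterogeneity, or instrument
drift. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes — band-level effect sizes, shifts, time modulation —
not that it would reach the same accuracy on real skin spectra.

## Problem sizes

Cohort-scale experiments (`experiments`) run on a reduced geometry chosen
to keep a full run on one CPU in minutes: 32×32-pixel maps with 2048
spectral points over the full 3900–900 cm⁻¹ axis (1.47 cm⁻¹ spacing), 10
mice per dose group, all five doses and days (250 images). Maps of any
spatial size are supported; the native 128×128×4096 geometry is used for
the geometry and full-map baseline checks.

## Numerical choices

- **Rubber band.** The baseline interpolates support points — the spectrum
  minimum within ±25 cm⁻¹ of each anchor (3600, 2750, 1800, 900 cm⁻¹) —
  augmented by the lower convex hull of the spectrum between consecutive
  support points (monotone-chain, jitted); outside the outer support
  points the outermost hull segments extrapolate linearly, so a straight
  line is its own baseline everywhere. Anchor snapping replaces the
  interactive placement of manual control points for reproducibility.
- **SG settings.** Window 5, polyorder 3 — the standard second-derivative
  setting at this sampling. Edge samples where the window would truncate
  are NaN, never extrapolated. Derivatives are per-wavenumber (not
  per-index), so intensities are comparable across clip settings.
- **Median filter.** Truncated windows are computed exactly by sorting
  NaN-padded windows and indexing the middle of the valid prefix (the
  valid count is pure geometry); verified against brute force.
- **Ties.** Pixel-cap ties break by (row, col) lexicographic order;
  majority-vote ties predict unexposed (conservative); both configurable.
- **Degenerate pixels.** Zero/negative amide II maxima are dropped and
  logged, not fatal; images with zero surviving pixels are excluded from
  classification and counted in the run manifest.
- **Class weighting.** All five families weight classes inversely to
  frequency: the cohort design is 4:1 exposed:control, and unweighted
  training lets the majority class swamp the nets' decision threshold.
- **Penalty selection.** Selecting the regularization strength on the test
  set leaks; `select_penalty` uses a sample-grouped validation split
  carved from the training data. Defaults train at a fixed strength
  (C = 1).
- **1D-CNN.** Three conv blocks, kernel 7, stride 2, channels 8/16/32,
  ReLU, global average pooling, dense softmax head; Adam (lr 10⁻³), batch
  128, 25 epochs, balanced class weights, z-scored inputs. Strided
  convolutions replace pool layers to cut compute ~8× at equal receptive
  field for single-CPU training. The nets are plain numpy with seeded
  init and batch order, so refits are bit-reproducible.
- **Embedding backend.** The 2-D embedding is pluggable: UMAP (default)
  or PCA (exactly deterministic; used where test speed matters). The
  outlier rule — kNN-distance percentile — is this package's choice; the
  masks it produces are translation/rotation invariant.

## Known limitations

- The linear SVM reports probabilities through a sigmoid of its margin,
  which is uncalibrated; only its vote fractions should be compared across
  models.
- Multi-class dose prediction (`label_mode="dose"`) is exposed but weak by
  design under the flat dose response; it is reported, not optimized.
- The rubber-band hull assumes a single contiguous clipped axis; disjoint
  spectral windows need per-window baselines.
- Approximate idempotence of the pretreatment holds on noise-free maps;
  on noisy maps a second pass re-smooths (median of medians).
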