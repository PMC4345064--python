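# Methods

## Problem and model

Three botanically related root materials are to be told apart from
attenuated-total-reflection FT-IR absorbance spectra recorded on a
4000→650 cm⁻¹ grid at 2 cm⁻¹ resolution (1676 points, stored in the
descending instrument convention). The materials share every major
vibrational band; only relative band intensities differ. The pipeline
maps each spectrum to a small energy-feature vector and classifies it
with a kernel density (Parzen-window) classifier:

    baseline correction → [optional FSD] → multilevel DWT
    → band-energy features → PNN

Each stage is described below with its assumptions and the parameters
that matter.

## Synthetic data generator

No spectra for this task are publicly deposited, so the generator
stands in for them. It emulates the statistical structure the analysis
relies on:

* **Shared band structure.** All three class templates use the same 21
  band centres and widths: broad envelopes (O–H ~3300 cm⁻¹ with
  FWHM 300 cm⁻¹, amide-I/water ~1650 cm⁻¹, the carbohydrate C–O
  envelope ~1100 cm⁻¹) plus many narrow fingerprint modes
  (FWHM 10–24 cm⁻¹: ester C=O 1740, aromatic ring 1615/1515, CH
  deformations 1450–1320, glycosidic C–O–C 1240–1030, anomeric region
  930–890 cm⁻¹). Dried plant powders genuinely show this mixture of a
  few broad envelopes over many sharp peaks, and the sharp peaks are
  what gives the detail-scale wavelet coefficients their class
  information — a generator with only broad bands would make the
  feature set meaningless.
* **Class differences are intensity-only.** Per band, the three
  classes' peak amplitudes differ pairwise by 5–20%. The factors are
  tied to band family (narrow / medium / broad), because composition
  changes move whole compound families coherently; each class pair is
  contrasted strongly (~19%) on one family and moderately (~9%) on the
  other two. Noiseless class spectra have cosine similarity ≥ 0.995 —
  far too similar to separate by eye, which is the regime of interest.
* **Degradation model.** Additive white Gaussian noise
  (σ = 0.005 absorbance by default, i.e. peak SNR ≈ 100), a random
  linear baseline tilt (slope σ = 5·10⁻⁶ absorbance/cm⁻¹, emulating
  drift), and multiplicative intensity jitter (σ = 2%, emulating
  ATR contact-pressure variation). Lineshapes are Lorentzian by
  default (consistent with the FSD model); Gaussian is available.

These defaults are the study conditions for every evaluation in the
package. What the generator does *not* emulate: water-vapour /
CO₂ lines, Mie scattering, detector nonlinearity, wavenumber
miscalibration, or ATR penetration-depth dispersion. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour
under intensity-structured class differences, not performance on any
physical instrument's output.

## Baseline correction

The default is the rubberband method: the lower convex hull of the
trace (Andrew's monotone chain, robust to the collinear hulls of flat
or linear spectra) is interpolated and subtracted, leaving a
non-negative corrected spectrum. A least-squares polynomial detrend of
configurable degree is the alternative. Both are idempotent to 1e-9.
The exact algorithm behind vendor "autobaseline" buttons is
undocumented; rubberband is the standard stand-in for broadband ATR
baselines.

## Fourier self-deconvolution

FSD assumes each band is a Lorentzian of FWHM γ (the *bandwidth
factor*, default 77 cm⁻¹). In the conjugate domain (x, in cm) such a
band decays as exp(−πγ|x|); the filter

    D(x) = exp(πγ|x|) · exp(−π γ_eff |x|) · W(x/L)

divides the assumed decay out and re-imposes a faster one, narrowing
every band by the *enhancement factor* K (default 3.5) while leaving
apex positions (symmetric real filter) and integrated areas (DC bin
untouched) unchanged. Numerical choices:

* **Window-limited resolution.** The apodization window W (default
  triangular-squared, (1−u)²; also a smooth "bessel" bell (1−u²)² and
  boxcar) has its cutoff at L = c/(0.95·γ/K), the smallest L whose
  window alone can still resolve the target width (c is the window's
  transform FWHM at unit cutoff, measured numerically). The residual
  decay γ_eff is then calibrated by bisection on the cosine transform
  of the combined kernel so the output FWHM equals γ/K exactly. This
  keeps the filter gain minimal — noise amplification is the price of
  deconvolution and grows exponentially with x.
* **Identity configuration.** K = 1 with boxcar gives D ≡ 1: the
  operation is the exact identity, used as a regression anchor.
* **Edge handling.** The analysed segment is detrended by the ramp
  joining its endpoints before the FFT and the ramp is restored after;
  this removes the first-order wrap-around discontinuity of the
  implicit periodic extension. The default analysis region is
  2000–650 cm⁻¹ (the fingerprint region); points outside pass through
  untouched.
* **Noise warning.** If the filter gain exceeds 10⁶ anywhere a warning
  is logged and the result still returned (boxcar at K = 3.5 triggers
  this; the default window does not).

**FSD is off by default in the classification pipeline.** Deconvolution
trades signal-to-noise for resolution: at K = 3.5 the in-band filter
gain reaches ~10³, and at the default noise level the amplified noise
drowns the band-energy features (measured: surrogate accuracy ~40% with
FSD in-line vs ~100% without). The wavelet features are accordingly
extracted from the baseline-corrected spectrum itself, with FSD
available as an explicit comparative stage (`fsd_enabled=True`, the
`fsd` CLI subcommand, `analysis/02_fsd.py`).

## Wavelet band-energy features

A 5-level multilevel DWT with an orthogonal Daubechies wavelet
(default db4 — compact support suited to sharp absorption peaks; the
member is configurable) decomposes each 1676-point trace into one
approximation and details 1–5 (finest first). Padding is periodization,
which makes the transform orthonormal: reconstruction is exact to
1e-8, and Parseval's identity holds exactly on dyadic-divisible
lengths. (On the 1676-point grid, levels of odd length duplicate one
boundary sample, leaving Parseval accurate to ~10⁻⁴ relative — the
reason the energy-conservation test uses a dyadic length.) Symmetric
padding is available but excluded from the conservation guarantee.

Features: for each selected detail scale (default {2, 3, 4}) the
coefficient index axis is split into three contiguous equal-width bands
(explicit `band_edges` may override), and the feature is the **mean** of
squared coefficients in the band — 9 features in total, concatenated
level-ascending then band-ascending, identified by a config digest.
Sums instead of means are a config flag for sensitivity checks.
Features are non-negative and scale quadratically with the spectrum
(energy homogeneity), both property-tested.

On the choice of scales: the canonical nine-feature layout (three bands
× three detail signals) requires three scales, while a two-scale
variant ({3, 4}) would yield six features. The default takes scales
{2, 3, 4}, preserving the nine-feature layout; any subset is
configurable.

## Probabilistic neural network

The classic four-layer topology: input → pattern layer (every training
vector a centre) → summation layer → output layer.

* Parzen window: isotropic Gaussian with one shared bandwidth σ,
  H_k(x) = Σᵢ exp(−‖x − c_ki‖²/(2σ²)); outputs Y_j = Σ_k w_jk H_k(x)
  with default weights w_jk = δ_jk/n_j (the class-mean kernel density).
  Label = argmax, ties broken to the lowest class index
  (first-appearance order), documented and tested.
* Because band energies span four orders of magnitude across scales,
  features are z-scored with statistics fitted on the training set
  (toggleable).
* Scores are evaluated in the log domain (logsumexp), so σ → 0
  degrades gracefully to exact 1-nearest-neighbour classification and
  σ → ∞ to the prior-like tie broken by class order; both limits are
  tested. Posteriors are the softmax of log Y and sum to 1 within
  1e-12.
* σ is selected by stratified k-fold cross-validated accuracy over a
  candidate grid (default {0.1, 0.3, 1.0, 3.0} on z-scored features,
  5 folds), ties to the smaller σ, deterministic given the fold seed.
* Note on monotonicity: with *fixed* mixing weights, duplicating a
  centre can only increase its class's output; under the default
  1/n_j normalisation a duplicate can lower the class mean, so the
  monotonicity property is stated (and tested) for fixed weights.
* Degenerate inputs: single-centre classes are legal; NaN features,
  unseen dimensionalities, and classes with fewer samples than CV
  folds raise validation errors.

Models serialise to a versioned flat layout (manifest.json +
centers.csv), round-trip tested.

## Evaluation harness and problem sizes

`evaluate` fits on training features, classifies a held-out set, and
reports per-class accuracy, overall accuracy, and the confusion matrix
(rows sum to per-class test counts on every run). The surrogate study
layout is 60 training and 100 test spectra per class (180/300), the
layout used by `analysis/04_evaluate.py`, the acceptance script, and
the headline test. Supporting controls run at reduced sizes chosen for
tight test runtimes while keeping standard errors well inside the
asserted margins: the label-permutation null uses 30/30 per class over
20 seeds (standard error of the mean ≈ 1%, asserted band ±5%), and the
noise-degradation monotonicity check uses 20/20 per class over 3 seeds
per noise level with ±2 points of slack.

## Known limitations

* Synthetic-only validation; see the generator caveats above.
* The FSD stage reproduces the *mathematics* of vendor deconvolution
  dials; vendor-exact apodization shapes and normalisations are
  proprietary, so only qualitative agreement with vendor output can be
  expected.
* No resampling between grids: replicate averaging and SpectrumSet
  construction require bit-identical grids by design.
* JCAMP-DX support covers XYPOINTS and uncompressed AFFN XYDATA;
  SQZ/DIF/DUP-compressed files are rejected with a parse error rather
  than silently misread.
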