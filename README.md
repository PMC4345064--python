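# ftirclass

Authentication of herbal root materials from their ATR-FTIR fingerprints.

Pharmacopoeia-listed roots are routinely substituted in the marketplace by
closely related species of the same genus. Their mid-infrared spectra are
nearly identical — the same broad O–H stretch near 3300 cm⁻¹, the same
carbohydrate C–O envelope at 1030–1200 cm⁻¹ — differing only in relative
band intensities, which makes visual discrimination unreliable. This
package implements the chemometric pipeline used for that problem:

1. **Spectrum handling** — two-column CSV and JCAMP-DX I/O on the
   4000→650 cm⁻¹ instrument grid, replicate averaging, and automatic
   baseline correction (rubberband / polynomial).
2. **Fourier self-deconvolution (FSD)** — band narrowing of overlapped
   peaks. Assuming Lorentzian lines of FWHM *γ* (the *bandwidth factor*),
   the interferogram-domain filter
   `exp(πγ|x|) · exp(−πγ_eff|x|) · W(x/L)` reduces every band's width by
   the *enhancement factor* K (defaults K = 3.5, γ = 77 cm⁻¹) without
   moving apexes or changing areas.
3. **Wavelet band-energy features** — 5-level Daubechies (db4) DWT with
   periodization; for detail scales {2, 3, 4} the coefficient axis is cut
   into three bands and the feature is the mean squared coefficient per
   band, giving a 9-component energy signature per spectrum.
4. **Probabilistic neural network (PNN)** — a Parzen-window classifier:
   every training vector is a kernel centre, the summation layer pools
   `H_k(x) = Σᵢ exp(−‖x − c_ki‖²/2σ²)` per class, and the output layer
   takes `Y_j = Σ_k w_jk H_k(x)` with `label = argmax_j Y_j`. Training is
   deterministic storage; σ is chosen by stratified cross-validation.

Because no public spectra exist for this task, the package ships a
synthetic generator (`ftirclass.synth`) producing three spectrally
similar classes — shared band positions and widths, per-band intensity
differences of 5–20%, additive noise, baseline drift, and intensity
jitter — on which the whole pipeline is exercised and tested.

## Worked example

```python
import ftirclass as fc

train = fc.generate_dataset(60, fc.NoiseModel(seed=0))    # 180 spectra
test  = fc.generate_dataset(100, fc.NoiseModel(seed=1))   # 300 spectra
report = fc.evaluate(train, test, fc.PipelineConfig(seed=0))
print(report.per_class_accuracy, report.overall_accuracy)
```

Running the numbered analysis scripts reproduces the full study flow;
`python analysis/04_evaluate.py` prints

```
train n=180, test n=300, sigma=0.1 (CV-selected)
  genuine: 100.00%
  variant_a: 100.00%
  variant_b: 100.00%
overall accuracy: 100.00%
```

i.e. with 60 training spectra per class the PNN assigns every one of the
300 held-out spectra to the correct material, and the label-permutation
control that follows collapses to ~33% (chance for three balanced
classes), confirming the separation is carried by the class signatures
and not by the harness. `analysis/02_fsd.py` characterises the FSD
stage: a 77 cm⁻¹-wide Lorentzian deconvolved at K = 3.5 comes out
22.0 cm⁻¹ wide (target 77/3.5 = 22) with zero apex shift and area
preserved to 0.04%.

A `ftirclass` console command exposes the same stages as subcommands
(`simulate`, `fsd`, `features`, `train`, `classify`, `evaluate`); every
flag has a YAML config twin and each run is identified by a config
digest.

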