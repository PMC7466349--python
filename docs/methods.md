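# Methods

This note documents the models, constants and numerical choices behind
`arsqnmr`: what the synthetic data emulate, how the processing chain and
quantification work, and what the validation statistics do and do not show.

## 1. The quantification model

Quantitative ¹H NMR rests on the proportionality of a peak's integral to
(number of contributing nuclei) × (moles of the species). The assay
compares the 3-proton aromatic singlet of total 5-alkylresorcinols at
6.00 ppm with the 1-proton aldehyde singlet of a known amount of
syringaldehyde at 9.79 ppm, whose integral is set to 1:

    C [mmol/mg dry material] = (I_ARS / 3) · mmol_IS / M_sample

* `mmol_IS = 0.00270` — the published constant for 0.5 mg syringaldehyde.
  Strictly 0.5 mg / 182.17 g mol⁻¹ = 0.00274 mmol; the printed value is
  kept as the default so reported concentrations match the published
  tables, and the exact-MW figure is available via the `is_mmol` argument
  / `RunConfig.is_mmol`. The simulator places the *same* constant into the
  tube it synthesizes, so simulation and formula always share one
  bookkeeping convention and the discrepancy never contaminates parameter
  recovery.
* `M_sample = 330 mg`, the weighed sample portion.
* Mass units use `MW_avg = (376 + 404)/2 = 390 g/mol`, the arithmetic mean
  of the C19 and C21 homologue masses (the two dominant chain lengths).
  The method cannot resolve individual homologues — a single averaged MW
  is the honest conversion, and two published table rows that imply a
  different effective MW are flagged (`conversion_consistent=False`) and
  excluded from exact conversion checks rather than reconciled.

Report rounding follows the published convention: mg/Kg to the nearest
integer, mmol/Kg to two decimals. Detection status is decided purely by
signal-to-noise: S/N < 3 → `nd`, 3 ≤ S/N < 10 → `below_loq`, S/N ≥ 10 →
`quantified`, with boundaries belonging to the higher category.

## 2. The synthetic sample generator

Each resonance is simulated as an exponentially decaying complex sinusoid
(Lorentzian line after FT) with amplitude

    a = n_protons · amount · (1 − exp(−(d1 + aq)/T1)),

the last factor being the steady-state saturation of a 90° pulse train
with relaxation delay `d1` and acquisition time `aq`. Scans add
coherently; independent per-scan white Gaussian noise adds as √n_scans.
Seeds are mandatory — there is no hidden global randomness.

Defaults and the reasoning behind them:

| parameter | default | rationale |
|---|---|---|
| spectrometer frequency | 400 MHz | assay's instrument class |
| sweep width | 5263.18 Hz | instrument-reported value; the nominal "0–13 ppm" at 400 MHz would be 5200 Hz, so the Hz figure is taken as authoritative and the ppm extent derived from it (13.158 ppm) |
| td | 32768 real+imag points | "32 K"; complex length 16384, so aq = td/(2·sw) = 3.11 s and FID resolution 0.32 Hz are self-consistent |
| relaxation delay | 10 s | the delay-sweep experiment (§5) converges here |
| scans | 16 | standard; S/N ∝ √n_scans is a tested invariant |
| T₂ | 1/π s | natural linewidth 1/(πT₂) = 1.0 Hz: sharp, resolved singlets |
| T₁ (ARS / IS) | 1.2 s / 2.5 s | small aromatic vs. aldehyde proton; chosen so the 1–20 s delay sweep visibly converges at 10 s |
| noise σ (per scan, per point) | 5.5 × 10⁻⁴ | calibrated so a 45 mg/Kg sample — the quantification limit — measures S/N ≈ 10 under the default chain, tying the noise model to the assay's stated LOQ |
| extraction efficiency | 0.96 per cycle | single-pool model; first cycle recovers >95%, later cycles add <5% |

The matrix background holds carbohydrate-region singlets between 3.0 and
5.5 ppm plus the residual DMSO-d₅ line at 2.50 ppm (used for axis
referencing). Amounts total a few mg of DMSO-soluble sugars per 330 mg
flour — starch itself is insoluble — which is precisely what leaves the
aromatic region clean and makes the one-integral assay possible. An
`adversarial` preset adds a peak at 6.3 ppm, just outside the integration
window, to exercise window discipline (it moves the ARS integral by
<0.5%).

The nominal preset concentration is interpreted as *what one standard
extraction delivers to the tube* (the method-reported value). The
geometric extraction model — cycle k recovers eff·(1−eff)^(k−1) of the
pool — is used by the recovery study, where successive extracts of the
same sample are each quantified independently.

**What the generator does not emulate:** J-coupling multiplets (the DMSO
singlet convention makes them unnecessary for this assay), ¹³C satellites,
solvent suppression, field drift, lineshape distortions from poor
shimming, or T₁ noise. Passing tests therefore demonstrate the
correctness of the processing/quantification logic under idealised
Lorentzian conditions, not robustness to every real-spectrometer artefact.

## 3. Processing chain

`apodize → zero_fill → fourier_transform → phase → baseline_correct →
calibrate_ppm`, each appending one entry to the processing log.

* **Apodization**: exponential `exp(−π·lb·t)` with lb = 0.3 Hz; adds lb to
  every linewidth, leaves areas unchanged.
* **Zero filling**: ×2 by default (power of two enforced); interpolates the
  spectrum without changing areas.
* **FT**: the first FID point is halved (trapezoid-consistent convention,
  no constant baseline offset). The mid-sweep frequency maps to 6.5 ppm;
  fine referencing shifts the axis so the residual solvent line sits at
  2.50 ppm. The ppm axis is stored descending; all windows are
  `(high, low)` tuples.
* **Phasing**: automatic by default, exact manual override available. The
  automatic objective is thresholded negativity — only excursions below 3×
  the noise floor of a trace smoothed over ~one linewidth count — plus a
  tiny spectral-entropy term. A coarse 5°×15° grid over the zero/first
  order pair precedes Nelder–Mead refinement (the pair is nearly collinear
  for sparse spectra, so sequential optimisation can strand in a
  zero-order-compensation valley). A weak quadratic pull on the
  first-order term (μ = 5·10⁻³ on (φ₁/180°)²) keeps noise from wandering
  the ramp when the data cannot determine it. *Known limitation:* with
  only two or three peak clusters, a large genuine first-order error is
  fundamentally near-degenerate with a zero-order shift; the search may
  return the compensating zero-order solution. Spectra of this assay have
  no first-order error, and zero-order errors are recovered to well within
  1°. Non-convergence is flagged in the processing log, never silent.
* **Baseline**: polynomial (default cubic) fitted on signal-free anchor
  windows at 12.5–11.6, 9.4–8.6, 7.8–6.8 and 1.5–0.0 ppm. Anchors
  *bracket* both integration windows: anchoring only at the spectrum edges
  would let the interior of the polynomial wander by several times the
  point noise exactly where the integrals are taken. Anchors are checked
  for overlap against the integration windows. Asymmetric least squares
  (`method="als"`) is available as an alternative.

## 4. Integration, S/N and noise

Integrals are plain trapezoids over ±0.10 ppm windows on the real trace,
normalised to the IS window. S/N is peak height over **2× the detrended
RMS** of the 11.5–10.5 ppm noise window (an instrument-software
convention; the linear detrend stops the smooth far tails of real peaks
from masquerading as noise). A residual below 10⁻⁶ of the peak height —
far beyond any attainable experimental S/N — reports the `inf` sentinel
for noise-free synthetic data.

Near the quantification limit the *integral* of a ±0.10 ppm window (~80 Hz
wide around a 1.3 Hz line) accumulates noise from hundreds of points, so
single-measurement scatter at 45–63 mg/Kg is of order 20–30% RSD even
though peak-height S/N is 10 — an inherent property of wide-window
integration at the LOQ, mirrored in the validation statistics below.

## 5. Validation studies

* **Recovery**: successive extraction cycles quantified independently;
  per-cycle concentration divided by the all-cycle total reproduces the
  geometric series (0.960, 0.038, 0.002 for three cycles at the default
  efficiency).
* **Precision**: triplicates within a day and across three days; the
  interday perturbation is a seeded multiplicative day factor
  ~Normal(1, 2%) — the magnitude is configurable, since no day-effect
  model is implied by the assay itself. Intraday %RSD at 638 mg/Kg is
  ~2–3% at the default noise, safely inside the 10% specification.
* **LOD/LOQ**: linear S/N scaling from a measured point
  (`LOD = 3·C/SNR`, `LOQ = 10·C/SNR`), so LOQ/LOD = 10/3 exactly;
  reported both as mg/Kg and as absolute µg per 330 mg sample
  (45 mg/Kg ↔ 15 µg, 30 mg/Kg ↔ 10 µg). A dilution-series estimate would
  be an alternative; S/N scaling is what is implemented and labelled.
* **Delay sweep**: noise-free simulations at d1 ∈ {1, 2, 5, 8, 10, 15,
  20} s; the sufficient delay is the first whose successor changes the
  ARS/IS ratio by <0.5% (the default T₁ values give 10 s; spins with
  T₁ ≪ 1 s return the first entry). A sweep that never settles is
  returned flagged rather than raised.

## 6. Problem sizes and determinism

Synthetic FIDs are 16 K complex points (32 K after zero-filling); the
replicate counts are 10 seeds for recovery means, 20 for Monte-Carlo
scaling checks and 3×3 for precision — enough for the stated tolerances
while keeping a full test run in a few minutes on one core. Identical
configuration and seed give byte-identical outputs end to end, including
CSV reports and JCAMP-DX files.

## 7. File formats

JCAMP-DX 1D (AFFN, 10 significant digits): FIDs as NTUPLES with real and
imaginary pages, spectra as XYDATA real traces; acquisition parameters in
`##$` private labels, the processing log in `##$PROCESSING` JSON lines and
an optional CSV sidecar. Only 1D data are accepted; multi-dimensional
files raise a named error. Sample manifests and quantification reports
are CSV.
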