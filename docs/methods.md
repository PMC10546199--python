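# Methods

## Model

The package treats the tissue as a homogeneous, semi-infinite turbid medium
probed in reflection. Two measurements constrain it:

1. **SFDI** — sinusoidally patterned illumination at spatial frequencies
   fx = 0 and 0.3 mm⁻¹, three phases each, at 660/780/850 nm. Demodulated
   and phantom-calibrated reflectance pairs (Rd(0), Rd(0.3)) are inverted
   through the diffusion forward model
   `Rd = 3A(μs′/μtr) / ((μeff′/μtr + 1)(μeff′/μtr + 3A))` for per-pixel
   (μa, μs′). The boundary coefficient uses the polynomial effective
   reflection coefficient `Reff(n)` and `A = (1−Reff)/(2(1+Reff))`.
2. **LSI** — coherent 633 nm illumination; spatial speckle contrast over a
   5×5 window, exposure T = 10 ms. The correlation-diffusion solution for
   the field autocorrelation adds a lag-dependent "dynamic absorption"
   `⅓ μs′ k₀² · 6 Db τ` to μeff′, so the exposure-integrated contrast
   `K² = (2β/T)∫₀ᵀ g₁²(τ)(1−τ/T)dτ` links measured contrast to the
   Brownian diffusion coefficient Db once (μa, μs′) at 633 nm are known.
   LSI illumination is planar, so fx = 0 in the speckle model (the
   parameter is retained for testing).

The diffusion closed form also generates the reflectance lookup grids.
Monte-Carlo-based grids would differ a few percent at low albedo
(μs′/μtr small); using one forward family end to end keeps the synthetic
round trips exact and the inversion internally consistent. The known
diffusion-vs-transport discrepancy at low albedo is a documented
limitation, not modeled.

### Units

All lengths are millimetres internally; μa, μs′, μtr in mm⁻¹, Db in mm²/s,
times in seconds, concentrations in µM. Wavelengths are carried in nm and
converted to mm **only** when forming `k₀ = 2πn/λ` (`qhi.constants`);
mixing nm and mm there is the likeliest unit bug in this model family, so
the conversion lives in exactly one place.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| refractive index n | 1.4 | — | typical soft tissue; exposed everywhere, since published work rarely states it |
| exposure T | 0.010 | s | standard speckle exposure for this flow regime |
| raw frame rate | 50 | Hz | shared LSI/SFDI trigger; SFDI effective rate = 50/18 ≈ 2.8 Hz |
| contrast window | 5×5 | px | standard spatial-contrast window |
| Gaussian smoothing | 15 px window, σ = window/6 | px | window follows common practice; σ chosen so the kernel is well contained (the window alone does not determine σ) |
| reflectance LUT | 512×512 over μa ∈ [10⁻⁴, 0.2], μs′ ∈ [10⁻³, 3] | mm⁻¹ | linear axes |
| K² LUT | 256×128×128 over Db ∈ [0, 20×10⁻⁶], μa ∈ [10⁻⁴, 0.3], μs′ ∈ [10⁻³, 3] | mm²/s, mm⁻¹ | linear axes; Db ceiling covers reported tissue magnitudes (~10⁻⁶ mm²/s) with ample headroom and is a config value |
| extinction coefficients | compiled HbO₂/HbR tabulation at 633/660/780/850 nm | cm⁻¹/M | approximate (few %) Prahl/Gratzer-compiled values; fixed in `qhi.constants` with the μa convention `μa = ln10·(ε·C)·10⁻⁷` (C in µM, μa in mm⁻¹) so every internal round trip is exactly consistent |
| β | estimated, `(median K of static phantom)²` | — | median for robustness to <50% ROI contamination; clipped at 1 against sampling noise |

## Numerical choices

* **Demodulation constant.** The three-phase AC formula is implemented
  with √2/3, the unique constant for which phase images
  `DC + A·cos(2πfx·x + φk)` demodulate to exactly A (verified
  symbolically); typeset versions of the formula are ambiguous between 2/3
  and √2/3. fx = 0 slots are uniform illumination and therefore
  phase-independent; their amplitude is the three-frame mean
  (`demodulate_dc`), not the AC formula (which would return 0).
* **Inverse reflectance LUT.** Linear scattered-data interpolation over the
  forward grid's (Rd0, Rd03) point cloud; queries outside the convex hull
  are flagged invalid, never extrapolated — silent extrapolation produces
  unphysical μa. Inversion is deterministic.
* **K² quadrature.** `k2_forward` uses adaptive Gauss–Kronrod on [0, T]
  with relative tolerance 10⁻¹¹ and raises if the error estimate fails to
  converge. The LUT builder evaluates the same integral after substituting
  `x = μeff′/μtr`, which turns it into a smooth rational integral resolved
  by panelled Gauss–Legendre (10 geometric panels × 24 nodes); the two
  routes agree to ~10⁻¹⁵ and are cross-checked in the tests.
* **Db inversion.** (μa, μs′) are fixed by bilinear interpolation of the
  LUT, giving a strictly decreasing K²-vs-Db profile; the measured K² is
  bracketed on that profile and inverted linearly. This is monotone and
  unique, unlike 3-D scattered interpolation. `K² > β` (super-static) and
  `K²` below the grid minimum (beyond dynamic range) are flagged invalid;
  `K = √β` maps to Db = 0 with a 10⁻⁹ relative tolerance for round-off.
* **Contrast estimator.** σ is the *sample* standard deviation (N−1);
  windows that exit the frame are flagged invalid (2-px border), not
  padded — padding biases K near edges. Held fixed so the brute-force
  oracle matches bit-for-bit. Small-window estimator bias (a 5×5 window of
  exponentially distributed intensity reads ~0.95–0.97 when the true
  contrast is 1) is deliberately *not* corrected: it is absorbed into the
  phantom-derived β exactly as in a real instrument.
* **Degenerate inputs.** Out-of-range optical properties raise for scalar
  queries and produce invalid-pixel masks for maps; μtr = 0, non-positive
  μs′ in the power-law fit, empty ROIs and zero phantom amplitudes raise
  with specific messages.

## Acquisition model

18-frame cycles: wavelengths cycle fastest (660, 780, 850), the projected
pattern (fx, phase) advances every three frames; phase order within a
block is fixed 0°, 120°, 240° and carried explicitly in the schedule so
demodulation never guesses. Set grouping keys on the cycle/index fields of
the manifest, not timestamps (robust to trigger jitter); timestamps order
and report. A missing index in *either* stream discards the whole 18-frame
set for *both* — the correction needs matched optics and contrast.
Rejection is bookkeeping, not an error; only a dataset with no complete
set at all fails.

## Synthetic data

The generator emulates the study conditions, not the hardware:

* **SFDI frames** (16-bit, scaled to ≈40 000 counts on the calibration
  phantom): `I = Rd(0)·M_DC + Rd(fx)·M_AC·cos(2πfx·x + φ)` over
  piecewise-constant scenes, plus optional additive Gaussian noise and
  quantization. Since the renderer and the inversion share the forward
  model, noise-free renderings round-trip to interpolation precision.
* **Speckle stacks** (8-bit, mean ≈60 counts): each speckle mode is a
  circular complex Gaussian AR(1) process whose field autocorrelation is
  exp(−τ/τc), sampled 64× per exposure and intensity-averaged. The
  speckle-to-pixel ratio is set by rendering `oversample²` independent
  modes per camera pixel; the default oversample of 2 gives β ≈ 0.25, so a
  static phantom measures K ≈ 0.5 — the range seen on real static
  phantoms. A scene's Db is realized by solving for the τc whose
  *discretely* integrated exponential-decay contrast equals the
  correlation-diffusion K² at that Db (closed form for the AR(1) sum), so
  the synthesizer and the inversion meet exactly at the level of measured
  contrast. 64 substeps keep the temporal sampling floor (K² ≥ 1/M) below
  the smallest simulated contrast.
* **Scenes**: the four characterization phantoms (2×μa / 2×μs′ / both,
  anchored at the calibration-phantom values), a capillary flow-tube slab,
  and a cortex-like scene defined by hemoglobin concentrations
  (background 70/30 µM HbO₂/HbR, Db = 1×10⁻⁶ mm²/s; a focal patch at
  90/40 µM, 2×10⁻⁶ mm²/s; μs′ power law A = 1.0, b = −1.3) so the full
  chromophore → 633 nm → Db chain has exact ground truth.

What passing tests show — and don't. The synthesizer reproduces
fully-developed speckle statistics, exposure integration, β, quantization
and the acquisition structure, so the tests validate the *processing
algebra* end to end. They do not validate the correlation-diffusion model
against real tissue: the speckle fields here have exponential field decay
and no static scattering layer, no shot/read noise beyond quantization
(plus optional Gaussian noise on SFDI), no camera misregistration, no
heterogeneous depth structure. Agreement at 1% (optical properties) and 5%
(Db medians) on synthetic data is a consistency statement, not an in-vivo
accuracy claim.

## Problem sizes

Default test and demonstration runs use 256×256 scenes, 3 acquisition
cycles (54 LSI + 54 SFDI frames), 8 static-phantom frames for β, and the
full-resolution LUTs; these sizes make the complete simulate→process chain
a sub-minute operation on one CPU while leaving every pipeline stage
non-trivially exercised. Full-sensor 1200×1200 streams are supported by
the same code paths.

## Known limitations

* Homogeneous semi-infinite medium: no skull/layered correction; large
  vessels violate the multiple-unordered-scattering assumption behind the
  Brownian model, so their Db is qualitative.
* Diffusion (not transport/Monte Carlo) reflectance: few-percent bias at
  low albedo and high fx.
* Single-exposure contrast only; no multi-exposure (MESI) fitting, no
  static-scatterer partitioning of β beyond the phantom estimate.
* The 633 nm optical properties are extrapolated (chromophores + power
  law), not measured; errors there propagate into Db.
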