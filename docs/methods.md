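# Methods

## The model

Core-shell capsules are made by soaking a spherical hydrogel core (radius
`R_c`, micrometres) in CaCl₂ solution at concentration `c` (mM) and then
immersing it in alginate: the Ca²⁺ released from the core crosslinks an
alginate shell around it. The shell volume is assumed proportional to the
moles of Ca²⁺ the core absorbed, which are themselves proportional to
`V_c · c`. Writing both volumes through the radii gives the thickness law

    h = R_c · ((α·c + 1)^(1/3) − 1)

with a single proportionality constant `α` (mM⁻¹) absorbing the
crosslinking stoichiometry and unit factors. The law linearises exactly:

    y ≡ (h/R_c + 1)³ − 1 = α·c

so `α` is estimated by **through-origin** ordinary least squares of the
linearised response on concentration, `α̂ = Σ xᵢyᵢ / Σ xᵢ²` — the exact
global minimiser of the sum of squared residuals for a line constrained
through the origin. No intercept is fitted (the linearisation has none) and
no weights are applied. Each observation carries its own `R_c`; capsules
differ in size and the linearisation handles that exactly, so pooling
replicates is the default (per-concentration averaging is available through
the aggregation helper but is not used in the fit).

Zero-concentration observations are accepted and carry no leverage
(`x = 0`). The fit refuses datasets with fewer than two positive-
concentration observations, and refuses data implying `α ≤ 0`.

## Colour route and no-shell inference

Shells stained with iron-oxide nanoparticles appear reddish under
transmitted light, and very thin shells cannot be measured directly from a
micrograph. The colour route calibrates thickness against colour:

1. each image is partitioned into two RGB clusters (k-means, k = 2); the
   darker cluster is the capsule (transmitted light ⇒ bright background);
   the capsule mask is the largest connected component with holes filled;
2. a disc at the mask centroid with radius 0.1 × the mask's
   equivalent-circle radius (`√(area/π)`) is the centre region;
3. centre means of R, G, B and background means (background at least 5 px
   away from the capsule boundary, excluding the refraction halo) give the
   metrics `R`, `R − bg`, `R − B`;
4. measured thicknesses are regressed (OLS **with** intercept) on measured
   `R − B`: `h = slope·(R−B) + intercept`;
5. the line predicts a thickness for every capsule, including those whose
   shell could not be measured. A prediction at or below the absence
   tolerance (default 0 µm) is physically impossible and is classified
   `absent` — the no-shell signal;
6. the formation threshold is the largest tested concentration at which
   **all** replicates are classified absent (`None` if no concentration
   qualifies; a warning is logged if the pattern is non-monotone in
   concentration).

The intercept in step 4 is essential: a through-origin line cannot produce
negative predictions at non-negative colour intensity, and the negative
extrapolations are exactly the evidence that no shell formed. Calibration
uses only samples with a directly measured (positive) thickness at
concentrations ≥ `calibration_min_conc` (default 5 mM) — below that,
direct measurement is considered impossible, which is the reason the
colour route exists. The `α` fit likewise uses only measurably thick
samples.

The k-means initialisation uses the pixel values at the minimum- and
maximum-luminance pixels (first occurrence on ties). This is deterministic,
invariant to a global brightness offset that does not clip, and for
transmitted-light images equivalent to the two most separated colours
without the quadratic cost of an exact farthest-pair search. Clusters whose
means are closer than 10 intensity units, or a capsule cluster under 0.5 %
of the pixels, raise a no-capsule error rather than returning a noise
partition.

## Synthetic image generator

The generator is an optical *stand-in*, not a reconstruction of any
particular microscope: its purpose is to give the pipeline images whose
ground truth is known exactly.

- **Attenuation.** Per-channel Beer–Lambert absorption along the chord a
  ray travels through the shell material of a sphere:
  `I = background · exp(−μ_channel · L(d))`, where
  `L(d) = 2√(R_o²−d²) − 2√(R_c²−d²)` at lateral distance `d`
  (`R_o = R_c + h`). Over the capsule centre `L = 2h` (the ray crosses the
  shell twice), so the centre colour has a closed form used by the tests.
- **Staining.** `μ = (0.001, 0.004, 0.010) µm⁻¹` for (R, G, B): the
  iron-oxide-stained shell transmits red preferentially, so thicker shells
  are redder. Background `(240, 238, 235)`, 8-bit, Gaussian read-out noise
  σ = 2 intensity units, clipped and quantised.
- **Refraction rim.** A 2 µm rim at the outer boundary is darkened
  (transmittance 0.7, all channels). This models the halo at a
  hydrogel/water interface and is what keeps a *shell-less* capsule
  visible, as bare cores are in reality; without it a zero-thickness
  capsule would be optically absent and the low-concentration arm of the
  experiment could not be imaged at all.
- **Scenario shape.** Concentrations {0.1, 1, 2, 5, 10, 15, 20, 30, 50,
  100} mM, 4 replicates each, `α_true = 0.033 mM⁻¹`, no shell at or below
  the formation threshold (default 2 mM). Core radii are uniform on
  **40–60 µm** at 0.5 µm/px. The radius range is a deliberate design
  choice: the centre `R−B` response peaks at
  `h* = ln(μ_B·bg_B / (μ_R·bg_R)) / (2(μ_B−μ_R)) ≈ 127 µm`, and with
  `R_c ≤ 60 µm` the largest realised thickness (≈ 38 µm at 100 mM) stays
  well inside the strictly increasing, near-linear part of that response,
  which is the regime the affine calibration assumes. Larger (millimetre)
  capsules would push the blue channel into full extinction and the
  calibration into its curved regime.
- **Randomness.** One root seed; per-image seeds derived by counter
  (`(seed·100003 + index) mod 2³¹`), so datasets are bit-reproducible.

### What the generator does not emulate

Illumination gradients, vignetting, depth-of-field blur, off-centre or
touching capsules, debris, and any real radiometry of nanoparticle loading.
Passing tests therefore demonstrate that the *analysis chain* is correct
and internally consistent under a known optical model — not that the
calibration transfers to any particular instrument, which always requires
measured thicknesses from that instrument.

One qualitative feature of real stained capsules is **not reproducible**
under pure per-channel exponential attenuation: a raw-R response that
flattens at the highest concentrations while R−B keeps rising. In this
model `d(R−B)/dc = −2h′(c)·(μ_R R − μ_B B)`; because B decays strictly
faster than R, by the time R's slope has collapsed B carries no remaining
signal and R−B flattens with it (the bound is tight: equality only in the
degenerate limit μ_B → μ_R). The realisable counterpart — R−B strictly
increasing across every formed concentration step while R's change over the
top step is much smaller — holds and is tested. A model producing the full
contrast would need a red signal that *grows* and saturates with particle
loading (e.g. a scattering term), which would leave the simple
three-parameter attenuation family this package deliberately uses.

## Numerical choices

- Fits use closed-form normal equations (no iterative optimiser); the test
  suite cross-checks them against brute-force grid minimisation and an
  independent OLS implementation.
- `r²` is clipped to [0, 1] and defined as 1 for an exact fit to
  constant-thickness data.
- Means over pixel regions are computed in float64; images are uint8.
- The absence cut is `h_pred ≤ tolerance` with tolerance 0 µm by default:
  the boundary case (exactly 0) counts as absent, since 0 is not a
  continuous shell.
- Per-image analysis failures (unreadable file, no capsule found) skip the
  sample with a logged warning; only zero usable images is fatal.
- Degenerate inputs (all-equal colour values, empty masks, single-pixel
  masks) raise typed errors rather than returning NaNs.

## Accuracy of the colour route

On noiseless synthetic data the affine calibration tracks the true
thickness to within ~7 % of the calibrated thickness span (the residual is
the intrinsic concavity of the Beer–Lambert response, not noise).
Relative error at the very thinnest calibrated shells is necessarily
larger: thickness spans a factor ≈ 12 across the formed grid
(`g(100)/g(5)` with `g(c) = (0.033c+1)^{1/3}−1`), and no single affine map
is few-percent-relative at both ends of a 12× concave range. The
formation-threshold inference does not depend on that: it only needs the
extrapolation at background colour to be negative, which holds with margin.

## Problem sizes

Default study-shaped runs are 40 images of roughly 300–400 px square;
a full pipeline run takes a few seconds on one CPU and the entire test
suite well under a minute. These sizes were chosen so the whole analysis,
including the multi-scenario threshold-recovery checks, stays desk-scale.
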