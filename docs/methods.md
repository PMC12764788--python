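# Methods

## The physical model

Fast-field-cycling NMR measures the longitudinal relaxation rate R1 of
tissue water over proton Larmor frequencies f ≈ 0.01–10 MHz
(f = (γ/2π)·B with γ/2π = 42.58 MHz/T).  The dispersion profile R1(f) is
modelled with a three-time-constant relaxation model in which water
occupies two environments: a single adsorbed layer of thickness
δ = 0.27 nm at every "solid" surface (membranes, proteins, DNA), and
bulk water.  Surface water moves in-layer with time constant τℓ and
desorbs to the bulk with time constant τd; bulk water has time constant
τb (≈5 ps for pure water, several times slower in tissue).  The fraction
of water in the surface layer is x = Sδ/V.  Surface proton density Nℓ
and paramagnetic-ion (Fe³⁺, S = 5/2) density Nσ complete the six fit
parameters.  Derived diffusion coefficients are D_surface = δ²/(4τℓ)
and D_bulk = δ²/(6τb).

The measured rate is the sum of proton–ion (HM) and proton–proton (HH)
contributions,

    R1_HM = x·R1_σℓ + (1−x)·R1_σb
    R1_HH = x·(R1_ℓℓ + R1_ℓb) + (1−x)·(R1_bb + R1_bℓ)

Each component is a dipolar rate built from the spectral density J(ω) of
a normalised pair-correlation function G(t):

* homonuclear weights J(ω) + 4J(2ω);
* heteronuclear (ion–proton) weights J(ωS−ωI) + 3J(ωI) + 6J(ωS+ωI) with
  ωS/ωI = 658.21; the S(S+1) factor is absorbed into the intensity
  constant.

## Correlation functions and closed forms

The component mathematics is fixed here by contract, choosing the
simplest forms that reproduce the qualitative physics (slow surface
dynamics dominate low field, fast bulk dynamics dominate high field):

| family  | G(t)                                   | J(ω) |
|---------|----------------------------------------|------|
| surface (ℓℓ, σℓ) | exp(−t/τd)/(1 + t/τℓ)         | 2τℓ·Re[e^z E₁(z)], z = τℓ(1/τd − iω) |
| bulk (bb, σb)    | (1 + t/τb)^(−3/2)             | 4τb·Re[1 − √(πpτb)·erfcx(√(pτb))], p = −iω |
| cross (ℓb, bℓ)   | exp(−t/τd)(1 + t/τc)^(−3/2), 1/τc = 1/τℓ + 1/τb | same with p = 1/τd − iω |

The 1/t surface tail is the signature of two-dimensional in-layer
diffusion; the desorption cutoff keeps J(0) ≤ 2τd finite.  The t^(−3/2)
bulk tail is the intermolecular signature of three-dimensional diffusion
and produces the √ω departure of J from its low-frequency plateau.  All
G are completely monotone, so every J is positive and non-increasing.
The scaled special functions (e^z E₁(z) via asymptotic series above
|z| = 40; erfcx with a 1/(pτ) expansion above |pτ| = 10⁶) keep every
frequency regime finite; the closed forms agree with direct numerical
quadrature of G to better than 10⁻⁵ everywhere tested.  A pure
Lorentzian bulk form (G = e^(−t/τb)) is selectable for degenerate-case
checks.  The paramagnetic families share the proton-motion correlation
functions because the ions are fixed in the solid.

Component density scaling: ℓℓ, ℓb and bℓ scale with Nℓ (all surface-pair
terms vanish with the surface), bb with the fixed bulk proton density
66.6 spins/nm³, and σℓ/σb with Nσ.

## Intensity calibration

Two intensity constants A_HH and A_HM set the absolute rate scale.  Both
are solved, once, from the low-field operating point of healthy murine
tissue: R1(0.01 MHz) = 29.51 s⁻¹ of which 56% is carried by the x·R1_ℓℓ
term, evaluated at the healthy-tissue reference parameter set
(τℓ = 0.0786 μs, τd = 0.1395 μs, τb = 41.75 ps, x = 0.0134,
Nℓ = 20.79 /nm³, Nσ = 2.71 /nm³).  Both conditions are linear in the two
constants, so the solution is exact.  With this calibration a bulk-only
system at the pure-water τb = 5 ps yields a low-field R1 of ≈0.6 s⁻¹,
the right order for pure water.

## Pre-fit exclusion rules

Two instrument artifacts are masked, never deleted: all points beyond
8 MHz ("beyond" read as exclusive, so 8 MHz itself survives) where the
pulse-sequence protocol switch can produce a discontinuity, and the two
points nearest 2 MHz in log-frequency (ties resolved toward the lower
frequency) where the ¹H–¹⁴N quadrupolar peak sits.  A profile must keep
at least 6 unmasked points — one per fit parameter — or it is rejected
as unfittable.  The nearest-two rule and both thresholds are
configurable (`FilterPolicy`).

## Fitting

The objective is the sum of squared relative residuals over unmasked
points; relative residuals balance the decade-wide dynamic range of a
dispersion curve.  The search runs in two stages:

1. **Coarse scan** over (τℓ, τd, τb) restricted to every fifth node of
   the 16-per-decade grid (bounds: τℓ, τd ∈ 0.01–10 μs, τb ∈ 1–1000 ps)
   and a seven-point x ladder, solving the two near-linear amplitudes
   (Nℓ ∈ 5–60, Nσ ∈ 0–5 spins/nm³) per node by closed-form
   box-constrained least squares.
2. **Local refinement** from the best 12 coarse candidates (2% seeded
   jitter) by trust-region-reflective least squares on
   (log₁₀τℓ, log₁₀τd, log₁₀τb, x, Nℓ, Nσ), ftol 10⁻¹⁰, at most 500
   model evaluations per start.

A single profile does not identify all six parameters equally well: Nℓ
enters chiefly through the product x·Nℓ plus a ~20% share of the
bulk-shaped amplitude, τℓ and τd trade off along a ridge of
near-equivalent surface line shapes, and the paramagnetic terms overlap
the homonuclear surface shapes.  Left unregularised, those flat-valley
directions turn measurement noise into large, erratic per-sample errors
in x and Nσ.  The refinement therefore adds an adaptive ridge tethering
(log τℓ, log τd, Nℓ, Nσ) to the healthy-tissue reference point with soft
scales (0.5 dex, 0.5 dex, 10 /nm³, 1 /nm³).  The ridge weight is
κ·rss₁ with κ = 3, where rss₁ is the unpenalised optimum found first
(a discrepancy-principle weighting): for noiseless data the weight
vanishes and recovery is exact; at 3% noise it suppresses the
flat-valley wander at the price of shrinking the weakly identified
parameters toward the reference.  The two reported biomarkers (x, τb)
and the low-field rate remain data-driven; their gradients are not
imposed anywhere in the fit.  `FitResult` reports both the pure
objective at the returned parameters (`rss`) and the best unpenalised
rss found (`rss_ml`).  κ and the scales were chosen by
parameter-recovery quality on development cohorts.

The HH-only variant pins Nσ = 0 with identical machinery.  Rate tables
(16 nodes per decade, bilinear log–log interpolation, <2% off-node
error, hard range errors) are provided for precomputation workflows and
mirror the datafile architecture of the original fitting software.

## Synthetic cohort

The generator emulates the study design the screen assumes: groups
4T1/FARN/TSA of 11/11/10 samples; per group one healthy control (c = 0)
and the rest uniform over c ∈ [0, 83]%; per-sample parameters drawn as
intercept + group offset + gradient·c + N(0, σ), truncated to physical
bounds.  Gradients are the published trend values (τℓ: −2.515×10⁻⁴ μs/%,
τd: −3.347×10⁻⁴ μs/%, τb: −0.238 ps/%, x: −3.076×10⁻⁵ /%,
Nℓ: +2.079×10⁻² /nm³/%, Nσ: −1.899×10⁻³ /nm³/%), and intercepts follow
from the published fractional changes over 0–100% (intercept =
gradient×100/fraction).  Scatter sds (0.012 and 0.0106 μs, 3 ps,
2.5×10⁻⁴, 0.6 and 0.25 /nm³) size the dispersion about the trends so the
recovered variance-explained lands in the reported regime, with the τℓ
scatter capped so all samples respect the reported 0.03–0.2 μs surface-
time range; group offsets are non-zero only where the screen favours
supplier-specific intercepts (τb: ±2 ps; x: ±6×10⁻⁴) or shows supplier
structure without a gradient (Nℓ: ±1, Nσ: ±0.35 /nm³).  Parameters are
drawn independently; a correlation structure across parameters is not
modelled.

Profiles are forward-simulated on 28 log-spaced frequencies from 0.01 to
40 MHz as R1_model·(1 + bump)·(1 + step)·(1 + ε): a Gaussian-in-log₁₀f
quadrupolar bump at 2 MHz (5% amplitude, 0.05 decade width), a −5% step
beyond 8 MHz, and i.i.d. 3% multiplicative noise.  Both artifacts fall
inside the masked regions of the default filter.  The low-field rate
R1(0.01 MHz) is never generated directly — it is computed from each
sample's parameters through the forward model, so its ≈ −0.12 s⁻¹/%
effective gradient is an emergent consistency check, not an input.

What the generator does not emulate: magnetisation-recovery curves and
pulse-sequence timing, frequency-dependent (heteroscedastic) noise,
correlated parameter draws across samples from the same animal, and any
systematic difference between supplier groups beyond intercept offsets.
Passing tests therefore demonstrate internal consistency of the
pipeline under the assumed statistical structure, not performance on
real relaxometer exports.

## Biomarker screen

For each quantity y (six parameters + R1(0.01 MHz)) two common-gradient
models are fitted by OLS: parallel (per-supplier intercepts αᵢ + common
slope β) and coincident (single intercept).  The parallel model is
chosen when the nested F-test, F = [(RSS_c − RSS_p)/2]/[RSS_p/(n−4)]
against F(2, n−4), rejects equal intercepts at the 5% level.  The slope
significance is the two-sided t-test on β; adjusted R² uses the
R `summary.lm` convention 1 − (1−R²)(n−1)/(n−1−p) with p the number of
coefficients beyond one grand intercept (parallel 3, coincident 1).
Percent change over the full tumour-fraction range is 100·(β·100)/ŷ(0)
with ŷ(0) the coincident intercept or the group-size-weighted mean of
the parallel intercepts.  Classification: biomarker if p < 0.05 and
adjusted R² ≥ 0.5; significant-but-weak if p < 0.05 and 0.2 ≤ R² < 0.5;
none-suitable otherwise.  The 0.5/0.2 thresholds are configurable; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists).

## Numerical choices and degenerate inputs

* Frequencies are MHz externally, ω = 2π·f·10⁶ rad/s internally; τℓ, τd
  report in μs and τb in ps.
* Zero densities zero their components exactly; a parameter set with no
  spins at all makes the component decomposition undefined (raises).
* Rank-deficient screen designs (all c equal; fewer than two non-empty
  groups for the parallel model) raise rather than returning NaN.
* RSS ties in the coarse scan resolve by grid order; the 2% start
  jitter is seeded and recorded in the result.
* The F statistic is clamped at 0 when rounding makes RSS_c < RSS_p.

## Problem sizes

The default study fits 32 profiles of ~20 unmasked points each
(≈4 s/profile single-threaded); the acceptance run adds 8 paired
HH-only fits, a 50-input quadrature cross-check and a 2000-replicate
Monte-Carlo calibration of the gradient test, totalling a few minutes.

## Known limitations

* The component functional forms are this package's own contract
  realisation; numerical identity with the original fitting software is
  not claimed, and absolute parameter values inherit the calibration
  choice.
* With these forms the paramagnetic contribution's in-band shape can be
  largely absorbed by the flexible surface terms at 3% noise: HH-only
  fits are typically only ~5–50% worse in rss than full fits on
  synthetic cohorts, a weaker contrast than real tissue data shows.
* The stabilised inversion shrinks τℓ, τd, Nℓ and Nσ toward the
  reference point; their recovered gradients are attenuated and should
  be read qualitatively.  x inherits a uniform scale factor from the
  Nℓ tether; this does not affect its significance or variance
  explained.
* Single-profile uncertainties (bootstrap/covariance) are not computed;
  the screen treats fitted values as point estimates.
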