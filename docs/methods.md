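# Methods

## Signal model and sequences

Each sequence is reduced to its echo-time schedule: a strictly
increasing list of times (ms) at which the transverse decay
S(t) = S0·exp(−t/T2) is sampled. MESE (9 echoes, TE₁ = 12 ms,
ΔTE = 5.8 ms) is the reference; GraSE samples 9 echoes at TE₁ = 15 ms,
ΔTE = 7.7 ms; T2prep samples the preparation times 0, 25, 50, 75 ms.
The t = 0 T2prep point is treated as an ordinary sample of the decay
curve (its listed preparation time is zero, so the model value there is
S0). No Bloch/EPG simulation is attempted: stimulated-echo pathways,
bSSFP readout effects and black-blood prepulses are outside the model,
which is exactly why the package validates on synthetic data rather
than claiming to reproduce scanner measurements.

An optional T1 shine-through hook exists in the generator only: for
T2prep stacks the true amplitude can be scaled by
(1 + β·exp(−T_rec/T1)), default β = 0 (off), T_rec = 2500 ms. It
reproduces the *direction* of T1-dependent T2prep overestimation
(shorter T1 → larger apparent amplitude at later preparations) but no
claim is made about magnitudes, and the fitting side never sees it.

## Rician likelihood fitting

Magnitudes are modelled as Rician:
log p(m|ν,σ) = log m − 2 log σ − (m²+ν²)/2σ² + log I₀(mν/σ²), computed
with the exponentially scaled Bessel function (`i0e`), so the fit is
stable at arbitrarily high SNR where I₀ overflows. (scipy's
`rice.logpdf` underflows to −∞ in deep tails; the scaled form here does
not, which the tests check against both scipy and a 50-digit evaluation
of the closed form.) The expected magnitude uses the closed form
σ√(π/2)·L₁ᐟ₂(−ν²/2σ²) expressed through `i0e`/`i1e`.

Per pixel, (log S0, log T2) — and log σ when estimated jointly — are
optimised by L-BFGS-B with analytic gradients. Choices that matter:

* **σ policy.** Default is a fixed σ from the Rayleigh background
  estimate σ̂ = mean(background)/√(π/2) pooled over echoes; joint
  per-pixel estimation is the fallback when no background exists.
  Fixing σ stabilises the fit with only 4 samples (T2prep).
* **Bounds.** T2 ∈ [1, 500] ms by default (gel phantom and myocardium
  with margin); S0 bounded within [10⁻⁶, 10³]·max(m). A fit whose T2
  lands on a bound is flagged non-converged, never silently clipped.
* **Initialisation and multi-start.** The log-linear regression of
  log max(m, ε) on t (ε = σ̂/10, or 10⁻⁶·max(m) when σ is unknown)
  provides one start. Because the profile likelihood in T2 can be
  multimodal at low SNR, a coarse 24-point log-spaced T2 scan — with
  the Gaussian conditional-S0 amplitude per T2 — provides a second
  start near the global mode; the better optimum wins. The returned
  log-likelihood is guaranteed ≥ the best start (monotone improvement),
  and an exhaustive 0.1-resolution grid search over (S0, T2) is kept in
  the package as the independent oracle for this machinery.
* **Convergence.** Parameter tolerance 10⁻⁸, ≤ 200 iterations.
  Degenerate inputs (all-zero or perfectly flat series) return
  non-converged results with missing T2. Unmasked map pixels carry NaN,
  never 0.
* **Baseline.** A nonlinear least-squares fit of S0·exp(−t/T2) on the
  magnitudes (same initialiser) is included purely as the Gaussian-noise
  baseline: at low SNR the Rayleigh floor inflates its T2, and the gap
  to the MLE quantifies what the Rician model buys. At first-echo
  SNR 100 the two agree to < 0.5% on average, as they must in the
  Gaussian limit.

## Synthetic data

The generators define the validation conditions:

* **Phantom.** 12 non-overlapping discs (radius 9 px ≈ 256 px each) on a
  ring in a 128×128 image, carrying the reference gel phantom's printed
  per-vial (T1, T2) pairs (T2 50.3–196.4 ms), uniform S0 = 100,
  zero-amplitude background. Validation noise is set by first-echo SNR
  (amplitude of the dimmest vial's first echo over σ); the recovery
  criterion uses SNR 50, typical of phantom scans.
* **Cardiac short-axis slice.** An annular myocardium (endo 11 px, epi
  16 px at 2 mm/px — a 22 mm cavity radius and 10 mm wall), circular
  blood pool with T2 = 250 ms, background zero. Per-AHA-segment true T2
  defaults to 53.8 ms in every segment — the reference sequence's
  published global myocardial mean, chosen because no per-segment in
  vivo truth is published. A per-segment SD-inflation knob draws
  pixel-wise T2 from Normal(T2ₖ, f·T2ₖ) (truncated at 1 ms) to
  manufacture inhomogeneous segments for positive controls; default
  f = 0 (perfectly homogeneous tissue).
* **Noise.** m = √((A+n₁)² + n₂²) with independent N(0, σ²) draws per
  pixel *and per echo* (standard magnitude-image assumption; no
  inter-echo correlation). All generators take an explicit seed and are
  bit-reproducible; no global RNG state is touched.

What the generators deliberately omit — motion, B0/B1 inhomogeneity,
EPI ghosting, bright-blood artifacts, partial volume at the borders,
stimulated echoes — bounds what a passing test means: parameter
recovery here demonstrates the estimator and pipeline are correct under
the stated noise model, not that scanner-specific biases are absent.
The published in vivo headline values (59.3 ± 4.0 / 53.8 ± 2.5 /
52.4 ± 2.8 ms; 5%/10%/14% inhomogeneous segments) require the original
scans and are bundled as reference data only; the sole part reproducible
from print is the CI arithmetic.

## Segmentation conventions

A pixel belongs to the myocardium iff its center lies inside the
epicardial and outside the endocardial polygon (even-odd rule;
pixel-center sampling). Sectors are equal angular wedges around a
supplied LV center: pixel angle θ = atan2(−(row−row₀), col−col₀), i.e.
counterclockwise *as displayed* with image rows growing downward;
segment 1 starts at the RV-insertion reference ray (default 90°,
pointing up) and numbering proceeds counterclockwise. A pixel exactly
on a boundary ray joins the lower-numbered segment — note this
tie-break is intentionally deterministic but not rotation-equivariant,
which only matters for pixel centers lying exactly on a ray. The
16-segment model is used without the apex cap: 6/6/4 segments for
basal/mid/apical. Global myocardial T2 is the pixel-weighted mean over
the whole annulus, not the unweighted mean of segment means.
Respiratory alignment of contours across echoes is simplified to
identity (contours are taken as valid for all echoes of a stack).

## Comparison statistics

* Percent difference vs. reference: round(100·(T2_seq − T2_ref)/T2_ref)
  with halves away from zero. This reproduces 18 of 18 printed integer
  cells for the 9 phantom rows whose printed means are self-consistent;
  the other 3 rows cannot be reproduced from their printed 1-decimal
  means under any rounding rule and were evidently derived from
  unrounded data.
* Homogeneity: SD > 0.20·mean, strict inequality, missing-SD segments
  excluded from proportions. Every analysis can run with or without
  exclusion of flagged segments (one flag).
* Paired t-test: direct formula t = mean(d)/(SD(d)/√n), df = n−1,
  two-sided p; zero-variance differences are reported as degenerate
  rather than silently yielding a number.
* Summaries: mean, sample SD (n−1), CI = mean ± t_{0.975,n−1}·SD/√n,
  reported at 1 decimal. Applied to each printed volunteer (mean, SD,
  n = 12) row this reproduces all six printed CI bounds exactly, which
  pins down the published interval as the ordinary t-interval.
* Mixed-effects models, Tukey-type multiplicity and the binomial GLMM
  for proportions are intentionally not re-implemented — they are
  off-the-shelf procedures in standard statistical software; the
  pipeline exports tidy per-segment/per-sample tables for them.

## Problem sizes and tolerances

The validation suite uses the full 12-vial phantom (≈ 3000 pixel fits)
at first-echo SNR 50 with a 2% per-vial recovery tolerance; 1000
replicate pixels for the SNR-3 bias ordering; 50 random pixels against
the exhaustive 0.1-resolution likelihood grid (T2 grid restricted to
[1, 150] ms for those instances, which brackets their true values with
ample margin); and σ-recovery at 10⁴ background pixels within 2%.
Noiseless round-trips are checked to 10⁻³ relative (fit tolerance), and
closed-form identities to 10⁻⁹–10⁻¹² as appropriate.
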