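# Methods

## Signal model and estimator

The estimator assumes the vertical position of a runner's nose landmark,
captured at `fs = 30` Hz by a fixed front camera, is dominated by a single
sinusoid at the step frequency (one head bob per step), superimposed on slow
postural drift and tracker noise:

```
y(t) = A·cos(2π f_step t + φ) + drift(t) + ε(t),   ε ~ N(0, σ²)
```

Cadence is estimated per window of `N = 128` samples (≈ 4.27 s):

- **FFT.** An in-package iterative radix-2 Cooley–Tukey FFT (bit-reversal
  permutation + butterfly stages). Non-power-of-two input is rejected, never
  padded. The implementation is verified against an O(n²) direct-summation
  DFT oracle at sizes 2–256 (1e-9 relative tolerance) and satisfies
  Parseval's identity.
- **Dominant bin.** The magnitude argmax over bins `[5, N/2]` inclusive.
  The first five bins are discarded because slow head displacement
  concentrates energy there; the Nyquist bin is included in the search.
  Ties break toward the lowest bin — deterministic and conservative (the
  lower cadence wins). Bin `k` maps to `k/(N/fs)` Hz; steps/min = 60 × Hz.
- **Degenerate windows.** A window whose peak searched magnitude is below
  `1e-9 ×` the window's total energy raises a degenerate-signal error. The
  floor is *relative* because tracker units are arbitrary.
- **No taper.** The window is rectangular (the signal is used unfiltered),
  so spectral leakage from drift and off-bin tones is present; the
  discard rule and the dominance of the gait peak absorb it in practice.
- **Quantization.** Argmax-bin estimation quantizes frequency to the bin
  grid; the raw error is bounded by half a bin, `fs/(2N)` Hz =
  7.03 steps/min at the defaults. This bound is property-tested over a
  1.5–3.0 Hz sweep.

## Bias correction

Raw FFT estimates systematically overestimate true cadence, most at lower
speeds. A global two-parameter linear model maps raw to corrected cadence,
`ŷ = a·x + b`, fitted by ordinary least squares of truth on raw. Defaults
`a = 0.83`, `b = 13.70` steps/min. The correction is applied on the
steps/min scale: the shipped coefficients (intercept and residual standard
error in steps/min) are on that scale, and applying it before or after the
Hz→steps/min conversion is equivalent up to unit scaling of the intercept.
`fit_correction` reports R², residual SE (n−2 denominator) and a seeded
k-fold cross-validated MAE (default 5 folds).

## Peak-detection baseline

The comparison baseline counts local maxima of the windowed displacement
signal with prominence ≥ 0.5 × the window's sample SD and separation
≥ 0.25 s (both exposed as parameters), and converts the count to a rate.
This is the simplest defensible reading of "peak detection on vertical
displacement"; no authoritative specification of the baseline exists, so
its exact variant is a design choice of this package. Count-based rates are
quantized to one peak per window (≈ 14 steps/min at 4.27 s), inherently
coarser than the FFT route.

## Window extraction policy

For offline evaluation, the first 10 s of a recording are discarded
(start-up artifacts) and the centered 128-frame slice of the remainder is
analyzed. Both the skip and the length are parameters: published accounts
of the remaining-data length are internally inconsistent (41.6 s quoted
where 60 − 10 = 50 s), so the policy is parametric rather than guessed.
Streaming mode slides the window by a hop (default 128 frames,
non-overlapping — one estimate per ≈ 4.27 s, the real-time schedule).

## Head-yaw control

Per engine frame: `target = clamp(yaw × intensity, ±90°)` about the
vertical axis; the avatar orientation slerps toward the target by a
smoothing factor `s ∈ [0, 1]`. For same-axis rotations slerp equals linear
angle interpolation, so constant input is approached geometrically:
`|yaw_n − target| = |yaw_0 − target|·(1−s)^n` (property-tested, and
cross-checked against scipy's quaternion slerp on 1000 random cases).
Choices the sources leave open, fixed here: positive yaw = head turned to
the user's left as seen by the camera (sign configurable); smoothing is
per-frame at 30 Hz; `intensity` defaults to 1.0 and `s` to 0.5 — sensible
placeholders, not reconstructions of any tuned values, and both are
exposed. Non-finite yaw models tracking loss: the state is returned
unchanged with a `tracking_lost` flag.

## Agreement battery

Implemented from the standard formulas, each pinned to an independent
oracle in the tests:

- RMSE/MAE per speed and pooled (RMSE ≥ MAE by Cauchy–Schwarz,
  property-tested);
- Bland–Altman: bias = mean difference, LoA = bias ± 1.96 × sample SD,
  outliers counted strictly outside the LoA (coverage ≈ 95 % under
  Gaussian differences, simulation-tested);
- Pearson/Spearman with two-sided p-values (scipy);
- ICC, two-way random effects, absolute agreement — ICC(2,1) and ICC(2,k)
  from the ANOVA mean squares, F-based 95 % CIs (average-measures bounds by
  Spearman–Brown step-up); raters (methods) are crossed with subjects
  (trials), which is what makes the two-way random model the right form.
  Cross-checked against pingouin's ICC(A,1)/(A,k) and a hand ANOVA oracle;
- Cronbach's α from the item-variance formula;
- Wilcoxon signed-rank on paired error series: zeros dropped, tie-corrected
  normal approximation (scipy), effect size r = Z/√N; Cohen's d in both
  paired (mean diff / SD diff) and pooled-SD flavors, because the flavor
  behind published single numbers is generally ambiguous — both are
  labeled.

The bundled benchmark table carries per-trial *mean* cadences, not the
underlying per-window estimates; statistics recomputed from it (e.g.
pooled per-trial RMSE ≈ 8.2 steps/min) therefore differ from per-window
figures computed on unpublished raw data (6.74). The package asserts only
bounds that hold at per-trial resolution: pooled MAE < 8 steps/min, mean
relative error < 5 %, and the directional claim that the FFT-Corrected
method beats the peaks baseline. The names "Peaks" and "Derivative" refer
to the same baseline method.

## Synthetic generator: what it does and does not emulate

`generate_trace` produces the stated signal model with defaults: amplitude
1.0 tracker unit, linear drift 0.05 units/s, slow sway 5.0 units at a 20 s
period, noise SD 0.2, random phase per seed. The sway-to-oscillation ratio
(5×) is chosen so the low-frequency spectral peak genuinely exceeds the
gait peak — the discard-five-bins rule is then load-bearing, and a test
asserts it. With `bias_mode="inverse_correction"` the oscillation frequency
is set to `((c − b)/a)/60` Hz so the *raw* estimate reproduces the real
systematic overestimation and the corrected estimate recovers `c` within
`a ×` half a bin.

The generator emulates spectral structure only. It does not model
biomechanics (double support, left/right asymmetry, fatigue drift of
cadence), tracking dropouts, lighting artifacts, or camera rolling shutter.
A green pipeline test therefore establishes correctness of the signal
processing under the assumed model, not robustness to real-world tracking
failure modes. No published amplitude or noise figures exist for real nose
trajectories; the defaults are assumptions, flagged as such.

`generate_cohort` mirrors the evaluation design (subjects × fixed treadmill
speeds, one trace each), drawing each subject's cadence once per speed from
a per-speed uniform range.

## Numerical choices

- FFT: unnormalized forward transform; float64 throughout.
- OLS via centered normal equations (two parameters; no conditioning
  concerns at cadence magnitudes).
- ICC CIs: degenerate perfect-agreement case returns a zero-width interval
  instead of dividing by zero.
- Trace CSV serialization uses `%.17g` and round-trip float parsing, so
  write→read is bit-identical.
- Seeds: every stochastic routine takes an explicit seed; cohort members
  derive child seeds from one root stream.

## Known limitations

- Single-landmark, single-sinusoid assumption; no time–frequency analysis
  for non-stationary cadence (a step change in cadence is resolved only at
  window resolution).
- The correction is global and linear; per-user calibration is out of
  scope.
- The peaks baseline is a reconstruction; published baseline numbers may
  come from a different variant.
- Per-window headline statistics cannot be reproduced from the bundled
  per-trial table (see above); they are not asserted.
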