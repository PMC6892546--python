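# Methods

## Model definition

The delayed-normalization (DN) model maps a stimulus contrast time course
S(t) ∈ [0, 1] to a nonnegative response prediction through three stages:
linear convolution with a temporal impulse response, full-wave
rectification plus a pointwise power, and divisive normalization by a
delayed copy of the drive.

**Impulse response.** Each gamma lobe is h(τ) ∝ t·e^(−t/τ) (the shape
parameter of the generalized gamma family is fixed at m = 2, so the peak
falls at t = τ), normalized to unit sum so that convolution with a long
step asymptotes at the step height. The biphasic impulse response is
h₁(τ₁, w) = g(τ₁) − w·g(1.5 τ₁) with w ∈ [0, 1]; it sums to 1 − w. The
second lobe's peak is fixed at 1.5 τ₁. w = 0 gives a monophasic IRF (onset
transient only); w = 1 integrates to zero and predicts transients at both
onset and offset with no sustained response.

**Normalization.** The denominator is σⁿ + [(h₂(τ₂) ∗ |R_L|)(t)]ⁿ with
h₂(τ₂) ∝ e^(−t/τ₂): the rectified *linear* drive is low-pass filtered and
the filtered signal is then exponentiated. The alternative convention —
filtering the exponentiated drive |R_L|ⁿ — is available as
`pool_order="power_then_filter"`; the two coincide for n = 1 and for
constant inputs but differ transiently otherwise. We default to
filter-then-power because the drive to the gain pool is most naturally the
rectified linear response, and the exponent then acts symmetrically on
numerator and pool.

**h₂ normalization.** The low-pass kernel is normalized to unit sum. The
normalization pool is then a weighted average of the response history: a
constant drive passes through unchanged, σ stays commensurate with
contrast, and the steady state for constant contrast c (with w = 0) has
the closed form gain·cⁿ/(σⁿ + cⁿ), which the tests verify against long
simulations. Without this normalization σ's meaning would depend on dt
and τ₂.

**Nuisance parameters.** An onset latency `shift ≥ 0` delays the output;
an output `gain > 0` scales it. The shift is implemented as a
fractional-sample delay: the output is linearly interpolated between the
two neighbouring whole-sample delays, which is exact at integer multiples
of dt and continuous in between. Continuity matters because the latency is
optimized by a simplex search; a sample-quantized delay makes the
objective piecewise-constant along that axis and demonstrably traps the
search in local minima (we observed parameter errors up to ~47% on
noiseless contrast-family recoveries with a quantized shift, versus exact
recovery with the interpolated delay).

**Discretization.** The default grid is 1 kHz (dt = 1 ms), the rate of the
ECoG recordings this model class targets; kernels are truncated at
max(7 τ, 1.2 s). Seven time constants keep >99% of the gamma kernel's
analytic mass inside the grid (five would keep only 96%, which the
kernel-support check rejects). Convolutions are causal full convolutions
truncated to the signal length, computed by FFT; pool values are clipped
at zero before fractional powers to absorb FFT round-off. With σ = 0 and a
zero stimulus the response is defined as 0 (not NaN); σ = 0 with a nonzero
stimulus is allowed but warns.

**Cascade.** `cascade_dn` feeds the output back through identical DN
stages; the input to stage k ≥ 2 is the previous output rescaled to a
maximum of 1 so it is a valid contrast time course (the rescaling
convention is our choice; the gain/shift nuisances apply only at the final
stage so a one-stage cascade is bit-identical to `dn_response`). Cascading
delays the peak and damps offset transients, qualitatively matching
responses recorded anterior to V1.

## Comparison models

The **CTS** (compressive temporal summation) model normalizes by the
instantaneous drive, |R_L|ⁿ/(σⁿ + |R_L|ⁿ); it is the τ₂ → 0 limit of DN.
The limit is verified numerically at τ₂ = dt on a 0.1 ms grid: the
residual between the two models is O(dt) (the discrete low-pass with
τ₂ = dt still averages ~0.6 samples of history), so at 1 ms it is ~2×10⁻³
while at 0.1 ms it is well under 10⁻³. The **two-temporal-channels** model
is a·(g(τ₁) ∗ S) + b·(h₁(τ₁, 1) ∗ S)²; the original formulation's channel
filters are not fully specified in our sources, so we reuse the gamma
family as a surrogate — adequate for the qualitative contrasts tested
(no contrast-dependent latency, onset and offset bumps), not a
reimplementation of the original filters.

## Parameter estimation

Fitting minimizes the summed squared error between prediction and the
trial-averaged time course.

* **Grid stage.** 10 equal steps per parameter over τ₁ ∈ [0.07, 1] s,
  τ₂ ∈ [0.07, 1] s, n ∈ [1, 6], σ ∈ [0.01, 0.5] — 10⁴ nodes, evaluated
  with w = 0 and shift = 0. At each node the gain is the closed-form
  least-squares slope of the data on the prediction (clamped to a small
  positive floor, 10⁻¹²); the node with the highest squared Pearson
  correlation seeds the search, ties broken by lexicographic parameter
  order. Grid predictions are independent of the data, so one set of
  precomputed predictions serves every bootstrap draw or fold on the same
  stimulus.
* **Search stage.** Nelder–Mead over (τ₁, τ₂, n, σ, shift) with box
  bounds — lower [0.07, 0.07, 1, 0.01, 0.0001], upper [1, 1, 6, 0.5,
  0.1] — parameter and objective tolerances of 10⁻⁶, a budget of 5000
  objective evaluations split over one restart from the first optimum, and
  the gain profiled out analytically at every evaluation.
* **Joint contrast-family fit.** One parameter set is fit to all
  responses of a contrast series; the model input for contrast c is the
  base stimulus scaled by c. Two seed vectors — (0.1, 0.1, 2, 0.2, 0.03)
  and (0.1, 0.1, 3, 0.1, 0.04) for (τ₁, τ₂, n, σ, shift) — each start an
  unbounded simplex search (invalid regions return an infinite objective)
  and the better final objective wins.
* **Biphasic per-electrode fit.** (τ₁, w, τ₂, σ, shift) with n fixed at 2.
  Four standard seeds — (0.02, 0.8, 0.15, 0.1, 0.05),
  (0.03, 0.8, 0.1, 0.2, 0.05), (0.02, 0.4, 0.15, 0.1, 0.05),
  (0.03, 0.4, 0.1, 0.2, 0.05) — are scored by variance explained and the
  best starts the refinement. Because these seeds place τ₁ at 20–30 ms,
  below the standard τ₁ lower bound, this fit uses wider bounds
  (τ₁, τ₂, σ ∈ [10⁻³, 1], w ∈ [0, 1], shift ∈ [0, 0.1]).
* **Resampling.** Bootstrap over electrodes (100 draws with replacement by
  default; per-timepoint median and 25th–75th-percentile band of the
  fitted predictions) and leave-one-out cross-validation over trials or
  electrodes (fit on the average of the remainder, score the squared
  Pearson correlation on the held-out unit). Identical averaged traces
  within one call are fitted once and reused — a pure memoization with no
  effect on results. All resampling is deterministic given the seed.

Model accuracy is reported throughout as the squared Pearson correlation
(r²) between prediction and data, which is invariant to the gain and to
offsets.

## Summary metrics

For a sustained-stimulus response, `t_peak` is the time from stimulus
onset to the response maximum minus the fitted onset latency, and
`r_asymp` is the mean response over the final 20% of the (latency-
corrected) stimulus-on window divided by the peak. The 20% window is our
operationalization of "asymptote"; any late-stimulus window gives the same
value once the response has settled. Both metrics are undefined for
all-zero responses and raise.

## Broadband extraction

Raw voltage epochs (electrodes × trials × time, 1.2 s epochs from −200 ms
to +1000 ms around onset at 1 kHz) are band-pass filtered in ten 10-Hz
bins spanning 70–210 Hz. Any bin whose closed interval contains a multiple
of the mains frequency is dropped; at 60 Hz mains this removes the four
decades around 120 and 180 Hz and leaves exactly ten bins. Filters are
order-selected IIR band-passes (≤3 dB passband ripple, ≥60 dB attenuation
10 Hz beyond the band edges) applied forward–backward for zero phase; the
per-bin envelope is the magnitude of the analytic signal and its square is
the bin power. Bins are combined by a pointwise geometric mean (floored at
10⁻³⁰⁰ before the log) so the low-power high-frequency bins still
contribute. Per electrode, the trial-averaged broadband is divided by its
pre-stimulus (−200–0 ms) baseline mean and the post-division baseline mean
is subtracted, so every electrode's baseline is exactly 0 in fractional
signal-change units. Electrode selection keeps channels whose stimulus-
window mean exceeds the baseline mean and whose maximum exceeds 150% of
the pre-normalized baseline. Eccentricity binning groups electrodes into
<5°, 5–10°, and >10° bins, with boundary values assigned to the middle
bin.

## BOLD prediction

The 13 temporal conditions are one-pulse stimuli of duration
{0, 17, 33, 67, 134, 267, 533} ms and two-pulse stimuli of two 134 ms
flashes separated by ISIs of {17, 33, 67, 134, 267, 533} ms, each on a
4.5 s trial at 1 ms resolution. Our sources print only the endpoints and
the 134 ms pulse; the intermediate values follow the implied
frame-doubling series and are configurable. The DN prediction per
condition is the trial-summed response scaled by one nonnegative gain fit
across all conditions by least squares — a single scalar suffices because
the measured amplitudes already come from a GLM that absorbs the
hemodynamic response. The linear baseline predicts amplitude proportional
to total stimulus-on time and is therefore blind to ISI.

## Synthetic data

Generators emulate each analysis input: DN outputs plus iid additive
Gaussian noise on each trial (Gaussian noise is the matched noise model
for the SSE objective on trial averages); contrast families of PSTH-like
responses (ten contrasts, 0–0.9, 200 ms pulses); raw voltage as pink-noise
background plus 70–210 Hz Gaussian noise whose amplitude follows a given
envelope plus mains harmonics with random phase; and a 12-electrode demo
dataset (4 ROIs × 3 eccentricity bins) whose generating parameters follow
the qualitative cortical gradients — τ₁ from 80 ms (V1) to 130 ms
(anterior), σ from 0.10 down to 0.04 (stronger normalization anteriorly),
gain from 7 down to 1.5, and biphasic weight w of 0.1/0.45/0.8 from fovea
to periphery. All generators are pure functions of their arguments and
seed.

What the synthetic conditions do *not* emulate: correlated (non-iid,
non-Gaussian) trial noise, stimulus-class-specific responses, narrowband
oscillatory (gamma) components overlapping the broadband range, electrode
artifacts, or any spatial structure. Passing tests therefore demonstrate
the correctness and identifiability of the implementation under the
model's own assumptions, not performance on real recordings; the original
datasets are needed for the latter.

## Problem sizes and numerical choices

Tests and reference computations run at desk scale by choice: 1.2 s epochs
at 1 kHz, 10⁴-node grids, 20–30 resampling draws in unit tests and the
full 100-draw/30-fold settings in the end-to-end checks, and the
τ₂ → 0 limit on a 0.1 ms grid. Simplex tolerances are 10⁻⁶ with a
5000-evaluation budget; negative profiled gains are clamped to 10⁻¹²;
degenerate cases (constant data, all-zero references, empty electrode
selections) raise or warn explicitly rather than propagating NaNs.

## Known limitations

* The two-channel comparison model uses gamma-family surrogate filters,
  not the original psychophysically derived ones.
* The exact bin edges of the 85–175 Hz broadband variant are
  underdetermined in our sources (nine 10-Hz decades fit at most); the
  implementation applies the same closed-interval harmonic-exclusion rule
  to whatever range is requested.
* Whether the reference analyses filtered |R_L| or |R_L|ⁿ in the
  normalization pool is ambiguous; both are implemented, and the default
  follows the textual description of the computation.
* BOLD amplitudes are taken as given (GLM betas); no hemodynamic model is
  included beyond the single gain.
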