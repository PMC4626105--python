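# Methods

## Model

The flash response is expressed throughout as suppressed dark current
(positive-going, pA, zero in darkness; normalized figures use peak = 1).
The unregulated response is the Poisson kernel
x_s(t) = A_s·t³·e^(−t/τ), zero for t < 0, with analytic peak at
t = 3τ of value A_s·27τ³e⁻³. A_s (response-units·s⁻³) is treated as a
free amplitude: dim-flash fits on raw current traces give values of a
few hundred, fits on normalized responses give values placing the peak
near one; both conventions are supported and a free amplitude rescale
is available in the feedback fitter.

The regulated response obeys the delay recursion
x_o(t) = H·[x_s(t) − G·x_o(t−Δ)] with history x_o(t<0) = 0
(dark-adapted baseline), gain H (default 1, so G is the fraction of the
output fed back), feedback fraction 0 ≤ G < 1, and buffer delay Δ ≥ 0.
With Δ = 0 the recursion collapses to the algebraic fixed point
x_o = H·x_s/(1 + H·G), which is an attenuated copy of the input when
H(1−G) < 1. The loop damps iff |H·G| < 1; an unstable combination
raises a warning, not an error.

### Delay solver

Δ is rounded to the nearest integer number of samples d = round(Δ/dt)
(minimum 1 when Δ > 0), and the recursion
x[i] = H·(x_s[i] − G·x[i−d]) is evaluated block-wise in chunks of d
samples, which is exact because the dependency reaches exactly d
samples back. When Δ is an exact multiple of dt the sampled recursion
solves the functional equation exactly, so grid refinement changes the
solution only through the rounding of Δ (O(dt)); the accuracy guard
dt ≤ Δ/10 keeps that error ≲1%. Fitters bypass the guard because their
candidate delays sweep down to a single sample.

### Fitting the feedback model

Because Δ enters as an integer sample shift, the sum of squared
residuals is piecewise constant in Δ and cannot be descended by a
gradient method. `fit_feedback` therefore profiles Δ exhaustively over
integer delays 0…round(delta_max/dt) (delta_max default 0.2 s) and
re-optimises the smooth parameters — G, bounded to [0, 0.99], and
optionally a multiplicative amplitude — at each candidate with bounded
trust-region least squares; the smallest SSE wins, smaller delay
breaking ties. This is deterministic and recovers generating parameters
exactly on noiseless data. All other fitters (kernel, Hill/exponential
saturation, dye loading, recovery exponentials) are plain bounded
trust-region least squares with data-driven initial guesses;
multi-component exponential fits multi-start over time-constant splits
because single starts can collapse into equal-τ local minima.

## Recovery classification

The classifier labels a recovery **oscillatory**, **dual** or
**single** from the deviation from baseline:

* **oscillatory** — some post-peak extremum crosses the baseline by
  more than the noise floor (default 2% of peak, configurable). For
  oscillatory traces the period is the mean spacing of successive
  same-sign extrema and the damping ratio the geometric mean of
  successive extremum magnitude ratios; both are exact on the
  constant-drive loop (period 2Δ, damping G).
* **dual** — the post-peak decay speed s(t) = −d/dt x(t)/x_peak,
  Gaussian-smoothed over 15 ms, has an interior local minimum followed
  by a rebound larger than 1.5×: the shoulder that makes two kinetic
  components visible. The search region requires signal above
  max(2×noise floor, 5% of peak) — differentiation amplifies noise, so
  the dual test cannot approach the floor as closely as the undershoot
  test — rebound denominators are clipped at 10% of the maximum decay
  speed so a near-zero trough cannot yield an unbounded ratio, and
  troughs within one smoothing width of the region's end are discarded
  as derivative edge artifacts.
* **single** — otherwise.

A sum-of-positive-exponentials comparison (mono vs. bi-exponential SSE)
was evaluated first and rejected: the regulated recovery is a
rate-*modulated* decay whose local time constant shrinks and grows
again, a shape outside the span of positive exponential sums, so both
model orders hit the same residual floor on exactly the traces the rule
must separate. The slope-rebound rule separates them cleanly: with the
slow-cell kernel (τ = 0.052 s, G = 0.6) a Δ sweep from 0 to 0.1 s
crosses single → dual → oscillatory monotonically, while the fast cell
(τ = 0.035 s, G = 0.4) stays single at its fitted Δ = 0.055 s.
Exponential recovery fitting remains available as
`fit_recovery_exponentials` for conventional time-constant reporting.

Sensitivity note: at the slow-cell parameters with Δ = 0.1 s the
undershoot is 2.002% of peak — essentially at the default 2% noise
floor. On the standard 1 ms grid it classifies oscillatory; analyses on
much coarser grids, or with a raised floor, will see "dual" instead.
On noisy recordings the classifier should be given a noise floor well
above the post-smoothing residual noise (the pipeline uses
max(2% of peak, 4× the pre-flash baseline SD)).

## Trace processing

* **Averaging** aligns traces on their recorded flash times (integer
  sample shifts) and takes the pointwise mean over the overlap only.
* **smooth_local** is a degree-1 local regression with
  negative-exponential weights e^(−|t−t₀|/λ). A two-sided exponential
  kernel has |H(f)| = 1/(1+(2πfλ)²), so λ = √(√2−1)/(2πf_c) places the
  −3 dB point at the cutoff (default 30 Hz). Degree-1 fitting
  reproduces constants and ramps exactly (unit DC gain) including at
  the edges, where the truncated window is refitted via convolved
  moments rather than padded.
* **gaussian_lowpass** (default 20 Hz, for long slow traces) uses
  σ_t = √(ln 2)/(2πf_c), the −3 dB calibration of a Gaussian FIR.
* **Metrics**: fractional suppression averages the suppressed current
  over a stated window (default 2.5–6 s, where step responses are most
  stable) and divides by the dark current, clipped to [0, 1]; the
  rising slope is an OLS line over the 10–90% normalized-amplitude
  rising segment (the bounds are a package choice; the source analyses
  do not state their window); the collecting area is the geometric
  outer-segment area times the rod-derived capture ratio (~0.062),
  quoted to a single leading figure.

## Synthetic data

The generator reproduces the study conditions the analysis assumes:
dark current 18.7 pA; the ten-flash ladder 1.14·10²–3.76·10⁵
photons/μm² delivered in triplets; the flash-duration rule (1 ms up to
1.77·10⁴ photons/μm², 10 ms above); flash amplitudes following the
exponential-saturation curve with I₀ = 3·10³ photons/μm²; white
Gaussian recording noise (default 0.2 pA, a realistic whole-cell noise
level at this bandwidth) band-limited at 2 kHz; optional linear
baseline drift (default 0 — drift in real recordings arises in
inner-segment channels, outside this model). Simulation uses the
recording rate (19.2 kHz); averaged, smoothed traces are decimated to
~1 kHz for fitting, which fully represents a 30 Hz-limited signal.

Two deliberate design choices:

* **Intensity-dependent feedback.** The feedback fraction scales with
  fractional activation, G_eff(I) = G·(1−e^(−I/I₀)), so dim flashes are
  quasi-unregulated — the premise that lets the dim-flash kernel fit
  estimate τ. The printed per-flash fractions (0.6 slow, 0.4 fast at
  4.49·10³ photons/μm²) therefore correspond to saturating values
  G = 0.77 and 0.52 in the default cells. A constant-G mode is
  available. Consequence: "noise-off end-to-end identity" is
  approximate, not exact — G_eff at the dimmest flash is ~0.03, which
  biases the fitted τ by ~1% and the refitted G by ≤0.03; the pipeline
  tests assert recovery at these honest tolerances.
* **Steps of light.** Step responses drive the same delay loop with a
  sustained input scaled so the steady state suppresses a configurable
  fraction of the dark current (default 0.83, the stable value over the
  2.5–6 s window). The loop's relaxation produces the fast rise and
  slower sag to steady state; no separate adaptation state is
  introduced, and the flash-dose saturation curve is deliberately not
  applied to steady photon rates.
* **Dye loading.** Region-integrated fluorescence follows
  F(t) = A_f(1−e^(−t/τ_f)) + A_s(1−e^(−t/τ_s)) with an onset delay of
  at most 5 s; distal regions carry mono-exponential parameters (the
  fast component is attenuated by diffusion). The fitter fits both
  forms and selects mono when the biexponential's fast amplitude falls
  below 5% of the total *or* the two time constants collapse (ratio
  < 2, or one amplitude vanishing) — the degenerate solutions a
  one-component curve produces.

What the generator does **not** emulate: channel-noise spectra,
membrane-voltage dynamics, supersaturating-flash PDE saturation (model
recoveries at the top of the ladder keep the moderate-flash shape),
light adaptation beyond the steady-state step level, and fluorescence
imaging optics. Passing tests therefore demonstrate correctness of the
estimators and solver under the stated statistical conditions, not
fidelity to every feature of real recordings.

## Numerical choices and problem sizes

Model-trace analyses use a 0–1 s grid at 1 ms (the delay solver's guard
allows Δ ≥ 10 ms there); dye curves 0–50 s at 0.1 s; pipeline
simulation 1.1 s at 19.2 kHz, 10 intensities × 3 repeats × 2 cells.
Noisy recovery studies use 50 replicates at 5% of peak white noise.
These sizes run the whole suite in about a minute on one core.

Estimator precision at those sizes: noiseless refits recover generating
parameters to better than 10⁻⁴ relative; at 5% noise the relative RMSE
is ~0.3% (τ), ~1% (A_s, G, Δ) and ~4% (τ_s). The fast dye time
constant is the exception: at 0.1 s sampling the Cramér–Rao bound for
τ_f = 0.6 s is ~18% relative at that noise level, and the fitter sits
at that information limit (~20%); resolving τ_f better requires faster
fluorescence sampling, not a better estimator.

## Limitations

* The kernel's falling phase is intrinsically faster than slow
  experimental recoveries; the model reshapes recovery through (G, Δ)
  but does not add the slow mechanisms a full transduction model would.
* The delay-loop steady state is linear in its drive; true light
  adaptation (background-dependent sensitivity) is out of scope.
* Classification near threshold SNR is marginal by construction; labels
  should be read together with the reported noise floor and rebound.
* The exponential-saturation form is implemented with the physically
  required negative exponent, R(I) = 1 − e^(−I/I₀).
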