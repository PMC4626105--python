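# conekinetics

Modelling and analysis of cone photoresponse kinetics: why some cones
recover from a flash in a single kinetic step, others in two, and others
with damped ringing — and how a single parameter, the Ca²⁺-buffer delay,
explains all three.

## The science

Light transiently suppresses the dark current flowing into a cone's
outer segment. Whole-cell recordings from zebrafish green cones show
that the *rising* phase of this photoresponse is stereotyped across
cells, while the *recovery* phase varies dramatically from cell to cell.
This package implements the minimal model that reproduces that
variation:

* the **unregulated response** to a flash is the Poisson kernel

  x_s(t) = A_s · t³ · e^(−t/τ),

  which fits dim-flash responses (where Ca²⁺ feedback is negligible)
  and peaks at exactly t = 3τ;

* stronger flashes recruit a **delayed negative feedback** — the
  light-induced fall in intracellular Ca²⁺, sensed by Ca²⁺-binding
  proteins after a lag Δ set by the cytosolic Ca²⁺-buffering capacity:

  x_o(t) = H · [x_s(t) − G · x_o(t−Δ)],

  with gain H (default 1) and feedback fraction G. With Δ = 0 the
  output is just a scaled-down kernel (single-component recovery);
  moderate Δ adds a shoulder (dual-component recovery); large Δ rings
  (damped oscillations). Crucially, for t < Δ the regulated response is
  *identical* to the unregulated one: the buffer delay preserves the
  fast onset that feedback alone would compress.

Around the model, the package provides everything needed to analyse
such recordings end to end: trace alignment/averaging, 30 Hz
local-regression and 20 Hz Gaussian smoothing, fractional suppression
and rising-slope metrics, intensity–response fitting (Hill
R = I^m/(I^m+I₀^m) versus exponential saturation R = 1 − e^(−I/I₀)),
biexponential dye-loading fits for intracellular perfusion, a
synthetic-recording generator (dark current 18.7 pA, ten-flash
intensity ladder 1.14·10²–3.76·10⁵ photons/μm², 2 kHz band-limited
noise), and a deterministic simulate→process→fit→classify pipeline.

## Worked example

`examples/01_feedback_model.py` builds the slow-cell kernel and sweeps
the buffer delay:

```text
unregulated kernel: peak 0.983 at t = 3*tau = 0.156 s
G=0.6, delta=0.000 s -> single      (peak 0.614 at 0.156 s)
G=0.6, delta=0.060 s -> dual        (peak 0.686 at 0.113 s); onset identical to unregulated response
G=0.6, delta=0.100 s -> oscillatory (peak 0.891 at 0.129 s), ringing period 0.135 s, damping ratio 0.61; onset identical to unregulated response
```

Reading the numbers: with no delay the response is the kernel divided by
1 + G (0.983/1.6 ≈ 0.614) and recovers monotonically. A 60 ms delay
leaves the onset untouched, peaks earlier and higher, and produces the
shouldered, dual-component recovery; at 100 ms the recovery overshoots
the baseline and rings with a period of ~0.14 s, each swing ~0.6× the
previous one. The other examples cover the intensity–response ranking
(`02`), dye-loading kinetics (`03`) and the full pipeline (`04`).

A thin CLI wraps the same functions:

```bash
conekinetics report --seed 1 --outdir out/   # full pipeline
conekinetics fit-poisson trace.tsv           # kernel fit on one trace
```

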