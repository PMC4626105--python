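"""Delayed negative-feedback model of the cone photoresponse.

The flash response of a dark-adapted cone, expressed as the fraction of
dark current suppressed versus time, is modelled in two stages:

* an *unregulated* response, the Poisson kernel

  .. math:: x_s(t) = A_s\\, t^3 e^{-t/\\tau},

  which describes the dim-flash response where Ca²⁺-dependent feedback is
  negligible;

* a *regulated* response produced by subtracting a delayed copy of the
  output from the input,

  .. math:: x_o(t) = H\\,[x_s(t) - G\\, x_o(t-\\Delta)],

  where ``H`` is the loop gain, ``G`` the feedback fraction (how much of
  the output is fed back), and ``Δ`` the delay that cytosolic Ca²⁺
  buffering imposes between a Ca²⁺ change and its detection by the
  Ca²⁺-sensor proteins.

Increasing Δ at fixed G morphs the recovery phase from a single kinetic
component, through a dual-component (shouldered) recovery, into damped
oscillations — the three phenotypes seen across cones with different
Ca²⁺-buffering capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import (
    AccuracyError,
    ClassificationError,
    MetricError,
    ParameterError,
)

__all__ = [
    "TimeGrid",
    "PoissonParams",
    "FeedbackParams",
    "ModelTrace",
    "RecoveryClassification",
    "poisson_response",
    "poisson_peak",
    "feedback_response",
    "delay_feedback_loop",
    "classify_recovery",
    "oscillation_metrics",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: ``t[i] = t_start + i * dt``."""

    t_start: float
    dt: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.n_points < 2:
            raise ParameterError(f"need at least 2 points, got {self.n_points}")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_points)

    @property
    def t_end(self) -> float:
        return self.t_start + self.dt * (self.n_points - 1)


@dataclass(frozen=True)
class PoissonParams:
    """Parameters of the unregulated kernel x_s(t) = A_s t³ exp(-t/τ).

    ``A_s`` sets the amplitude (response-units·s⁻³): dim-flash fits on
    raw current traces give values of a few hundred, while fits to
    normalized responses give values placing the peak near unity.
    ``tau`` (s) sets the kinetics; the kernel peaks at exactly 3·tau.
    """

    A_s: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.A_s > 0):
            raise ParameterError(f"A_s must be positive, got {self.A_s}")
        if not (self.tau > 0):
            raise ParameterError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class FeedbackParams:
    """Feedback-loop parameters: gain H, feedback fraction G, buffer delay Δ.

    ``scaled_down`` records whether H(1-G) < 1, i.e. whether the
    zero-delay regulated response is an attenuated copy of the input.
    ``loop_stable`` records whether |H·G| < 1, the condition for the
    delay recursion to damp rather than diverge.
    """

    G: float
    delta: float
    H: float = 1.0

    def __post_init__(self) -> None:
        if not (self.H > 0):
            raise ParameterError(f"H must be positive, got {self.H}")
        if not (0.0 <= self.G < 1.0):
            raise ParameterError(f"G must lie in [0, 1), got {self.G}")
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")

    @property
    def scaled_down(self) -> bool:
        return self.H * (1.0 - self.G) < 1.0

    @property
    def loop_stable(self) -> bool:
        return self.H * self.G < 1.0


@dataclass
class ModelTrace:
    """A model response sampled on a uniform grid.

    ``kind`` is ``"unregulated"`` for the Poisson kernel and
    ``"regulated"`` for the feedback-loop output.
    """

    grid: TimeGrid
    values: np.ndarray
    kind: str = "unregulated"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ParameterError(
                f"values length {self.values.shape} does not match grid "
                f"n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")


def _kernel(t: np.ndarray, params: PoissonParams) -> np.ndarray:
    tc = np.clip(t, 0.0, None)
    return params.A_s * tc**3 * np.exp(-tc / params.tau)


def poisson_response(params: PoissonParams, grid: TimeGrid) -> ModelTrace:
    """Sample the unregulated kernel x_s(t) = A_s t³ exp(-t/τ) on ``grid``.

    Values at t < 0 are zero (no response before the flash).
    """
    values = _kernel(grid.times, params)
    return ModelTrace(grid, values, kind="unregulated",
                      params={"A_s": params.A_s, "tau": params.tau})


def poisson_peak(params: PoissonParams) -> tuple[float, float]:
    """Analytic peak of the Poisson kernel.

    Returns ``(peak_time, peak_value)`` with ``peak_time = 3·tau`` and
    ``peak_value = A_s · 27 τ³ e⁻³`` (set t³e^(-t/τ) derivative to zero).
    """
    t_peak = 3.0 * params.tau
    v_peak = params.A_s * 27.0 * params.tau**3 * math.exp(-3.0)
    return t_peak, v_peak


def delay_feedback_loop(drive: np.ndarray, H: float, G: float, d: int) -> np.ndarray:
    """Run the explicit delay recursion x[i] = H·(drive[i] - G·x[i-d]).

    ``d`` is the delay in samples; history x[i<0] = 0 (dark-adapted
    baseline). ``d = 0`` returns the algebraic fixed point
    H·drive/(1 + H·G). Because the dependency reaches exactly ``d``
    samples back, the recursion is evaluated block-wise.
    """
    drive = np.asarray(drive, dtype=float)
    if d < 0:
        raise ParameterError(f"delay in samples must be >= 0, got {d}")
    if d == 0:
        return H * drive / (1.0 + H * G)
    if H * G >= 1.0:
        warnings.warn(
            f"H*G = {H * G:.3g} >= 1: the delay loop is unstable and the "
            "output will grow without bound",
            stacklevel=2,
        )
    n = drive.shape[0]
    out = np.empty(n, dtype=float)
    out[: min(d, n)] = H * drive[: min(d, n)]
    for start in range(d, n, d):
        stop = min(start + d, n)
        out[start:stop] = H * (drive[start:stop] - G * out[start - d : stop - d])
    return out


def feedback_response(
    pp: PoissonParams,
    fp: FeedbackParams,
    grid: TimeGrid,
    *,
    enforce_accuracy: bool = True,
) -> ModelTrace:
    """Regulated response x_o(t) = H·[x_s(t) - G·x_o(t-Δ)] on ``grid``.

    For Δ = 0 the algebraic solution H·x_s/(1 + H·G) is returned; for
    Δ > 0 the delay is rounded to the nearest integer number of samples
    (minimum 1) and the explicit recursion is run with zero history.

    With ``enforce_accuracy`` (default), a grid with dt > Δ/10 raises
    :class:`AccuracyError`; fitters relax this because candidate delays
    sweep down to a single sample.
    """
    if fp.delta > 0 and enforce_accuracy and grid.dt > fp.delta / 10.0:
        raise AccuracyError(
            f"dt = {grid.dt:g} s is too coarse for delta = {fp.delta:g} s; "
            "need dt <= delta/10"
        )
    xs = _kernel(grid.times, pp)
    d = 0 if fp.delta == 0 else max(1, round(fp.delta / grid.dt))
    values = delay_feedback_loop(xs, fp.H, fp.G, d)
    return ModelTrace(
        grid,
        values,
        kind="regulated",
        params={
            "A_s": pp.A_s, "tau": pp.tau,
            "H": fp.H, "G": fp.G, "delta": fp.delta, "delay_samples": d,
        },
    )


@dataclass
class RecoveryClassification:
    """Outcome of the recovery-phase classification.

    ``label`` is one of ``single``, ``dual``, ``oscillatory``.
    ``extrema`` lists post-peak extrema as (time, deviation-from-baseline)
    pairs beyond the noise floor. ``damping_ratio`` (geometric mean of
    successive extremum magnitude ratios) is defined only for
    oscillatory recoveries with at least two extrema. ``rebound`` is the
    decay-speed rebound factor used for the dual-vs-single decision.
    """

    label: str
    peak_time: float
    peak_value: float
    extrema: list[tuple[float, float]]
    damping_ratio: float | None
    rebound: float
    noise_floor: float


def _post_peak_extrema(
    times: np.ndarray, dev: np.ndarray, i_peak: int, noise_floor: float
) -> list[tuple[float, float]]:
    """Local extrema of the deviation after the peak, beyond the noise floor.

    Plateaus (from the piecewise-constant delay recursion) count once, at
    their midpoint.
    """
    post = dev[i_peak:]
    out: list[tuple[int, float]] = []
    for sign in (1.0, -1.0):
        idx, _ = find_peaks(sign * post, plateau_size=(1, None))
        out.extend((i, post[i]) for i in idx if abs(post[i]) > noise_floor)
    out.sort(key=lambda p: p[0])
    return [(times[i_peak + i], v) for i, v in out]


def classify_recovery(
    trace,
    noise_floor: float | None = None,
    *,
    baseline: float = 0.0,
    rebound_threshold: float = 1.5,
    floor_fraction: float = 0.05,
    slope_floor_fraction: float = 0.1,
    slope_smooth_s: float = 0.015,
) -> RecoveryClassification:
    """Classify a flash-response recovery as single, dual, or oscillatory.

    ``trace`` is any object with ``grid`` and ``values`` attributes
    (:class:`ModelTrace` or a measured trace). ``noise_floor`` is in
    response units; the default is 2% of the peak deviation.

    Decision rules, applied to the deviation from ``baseline``:

    * **oscillatory** — some post-peak extremum crosses the baseline by
      more than the noise floor (ringing/undershoot);
    * **dual** — no baseline crossing, but the post-peak decay speed
      (-d/dt of the deviation, Gaussian-smoothed over
      ``slope_smooth_s``) has an interior minimum followed by a rebound
      larger than ``rebound_threshold``: the shoulder that makes two
      kinetic components visible. The analysis is limited to the region
      where the deviation exceeds ``floor_fraction`` of the peak, and
      rebounds are measured against at least ``slope_floor_fraction`` of
      the maximum decay speed so that a near-zero trough cannot produce
      an unbounded ratio;
    * **single** — otherwise (monotone-rate recovery).

    Raises :class:`ClassificationError` when no peak rises above the
    noise floor.
    """
    times = trace.grid.times
    dt = trace.grid.dt
    dev = np.asarray(trace.values, dtype=float) - baseline

    i_peak = int(np.argmax(dev))
    peak = dev[i_peak]
    nf = 0.02 * peak if noise_floor is None else float(noise_floor)
    if not (peak > nf) or not (peak > 0):
        raise ClassificationError(
            f"no detectable peak: max deviation {peak:g} is not above the "
            f"noise floor {nf:g}"
        )

    extrema = _post_peak_extrema(times, dev, i_peak, nf)
    post = dev[i_peak:]

    if np.min(post) < -nf:
        mags = [abs(v) for _, v in extrema]
        damping = None
        if len(mags) >= 2:
            ratios = [mags[i + 1] / mags[i] for i in range(len(mags) - 1)]
            damping = float(np.exp(np.mean(np.log(ratios))))
        return RecoveryClassification(
            "oscillatory", times[i_peak], peak, extrema, damping, 0.0, nf
        )

    # Dual-vs-single: look for a shoulder in the decay speed. The search
    # region needs signal at least twice the noise floor: differentiation
    # amplifies noise, so the tail cannot be trusted as close to the floor
    # as the undershoot test can.
    floor = max(2.0 * nf, floor_fraction * peak)
    above = np.nonzero(post > floor)[0]
    lim = int(above[-1]) + 1 if above.size else post.shape[0]
    speed = -np.gradient(post[:lim], dt) / peak
    if slope_smooth_s > 0 and speed.shape[0] > 3:
        speed = gaussian_filter1d(speed, max(slope_smooth_s / dt, 1e-9),
                                  mode="nearest")
    rebound = 0.0
    if speed.shape[0] > 3:
        s_max = float(np.max(speed))
        # Troughs inside the last smoothing width of the analysis region are
        # edge artifacts of the smoothed derivative, not shoulders.
        edge = int(round(slope_smooth_s / dt))
        core = speed[: max(speed.shape[0] - edge, 4)]
        troughs, _ = find_peaks(-core)
        for i in troughs:
            later = float(np.max(core[i:]))
            rebound = max(rebound,
                          later / max(core[i], slope_floor_fraction * s_max))
    label = "dual" if rebound > rebound_threshold else "single"
    return RecoveryClassification(
        label, times[i_peak], peak, extrema, None, rebound, nf
    )


def oscillation_metrics(c: RecoveryClassification) -> tuple[float, float]:
    """Period and damping ratio of an oscillatory recovery.

    ``period`` is the mean spacing of successive same-sign extrema (one
    full cycle); ``damping_ratio`` is the geometric mean of successive
    extremum magnitude ratios. Requires an oscillatory classification
    with at least 3 extrema, else :class:`MetricError`. The period grows
    with the buffer delay Δ at fixed G.
    """
    if c.label != "oscillatory":
        raise MetricError(f"oscillation metrics undefined for label {c.label!r}")
    if len(c.extrema) < 3:
        raise MetricError(
            f"need at least 3 extrema, found {len(c.extrema)}"
        )
    times = np.array([t for t, _ in c.extrema])
    vals = np.array([v for _, v in c.extrema])
    spacings = []
    for sign in (1.0, -1.0):
        ts = times[np.sign(vals) == sign]
        if ts.size >= 2:
            spacings.extend(np.diff(ts))
    if not spacings:
        raise MetricError("no same-sign extremum pair to measure a period")
    period = float(np.mean(spacings))
    mags = np.abs(vals)
    damping = float(np.exp(np.mean(np.log(mags[1:] / mags[:-1]))))
    return period, damping
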