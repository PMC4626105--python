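"""Nonlinear least-squares estimation for every curve in the analysis.

All fitters use bounded trust-region least squares
(:func:`scipy.optimize.least_squares`). The delayed-feedback fit is
special: the buffer delay Δ enters the solver as an integer sample
shift, so the objective is piecewise constant in Δ and is profiled over
integer delays instead, with the smooth parameters re-optimised at each
candidate delay.

Intensity–response forms
------------------------
Hill:                    R(I) = I^m / (I^m + I0^m)
Exponential saturation:  R(I) = 1 - exp(-I / I0)

``I0`` is the half-saturating intensity for the Hill form and the
1 - 1/e intensity for the exponential-saturation form.

Dye loading
-----------
Fluorescence after intracellular injection follows
F(t) = A_f (1 - e^(-t/τ_f)) + A_s (1 - e^(-t/τ_s)) near the pipette,
degrading to a mono-exponential far from it where the fast component is
attenuated away; an onset delay of at most 5 s is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ParameterError
from .model import (
    FeedbackParams,
    PoissonParams,
    _kernel,
    delay_feedback_loop,
)

__all__ = [
    "HillParams",
    "ExpSatParams",
    "DyeLoadingParams",
    "FitResult",
    "IntensityResponseCurve",
    "hill_response",
    "expsat_response",
    "dye_loading_curve",
    "fit_poisson",
    "fit_feedback",
    "fit_intensity_response",
    "fit_dye_loading",
    "fit_recovery_exponentials",
    "recovery_harness",
]

DEFAULT_SEED = 20151029


@dataclass(frozen=True)
class HillParams:
    I0: float
    m: float = 1.0

    def __post_init__(self) -> None:
        if self.I0 <= 0 or self.m <= 0:
            raise ParameterError("Hill parameters must be positive")


@dataclass(frozen=True)
class ExpSatParams:
    I0: float

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ParameterError("I0 must be positive")


@dataclass(frozen=True)
class DyeLoadingParams:
    """Biexponential loading parameters; ``form='mono'`` uses only the slow pair."""

    A_f: float
    tau_f: float
    A_s: float
    tau_s: float
    onset_delay: float = 0.0
    form: str = "bi"

    def __post_init__(self) -> None:
        if min(self.A_f, self.A_s) < 0:
            raise ParameterError("amplitudes must be non-negative")
        if self.form == "bi" and not (self.tau_f < self.tau_s):
            raise ParameterError("tau_f must be smaller than tau_s")
        if not (0.0 <= self.onset_delay <= 5.0):
            raise ParameterError(
                f"onset delay must lie in [0, 5] s, got {self.onset_delay}"
            )

    @property
    def asymptote(self) -> float:
        return (self.A_f if self.form == "bi" else 0.0) + self.A_s


@dataclass
class FitResult:
    """Converged parameter estimates with the fit's provenance."""

    params: dict
    sse: float
    converged: bool
    n_iter: int
    init: dict
    bounds: dict
    model: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "sse": self.sse,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "init": dict(self.init),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }


@dataclass
class IntensityResponseCurve:
    """(intensity, normalized amplitude) points for intensity–response fits."""

    intensity: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.intensity.shape != self.amplitude.shape:
            raise ParameterError("intensity and amplitude must have equal length")
        if np.any(self.intensity <= 0):
            raise ParameterError("intensities must be positive")


def hill_response(I, I0: float, m: float = 1.0):
    I = np.asarray(I, dtype=float)
    return I**m / (I**m + I0**m)


def expsat_response(I, I0: float):
    I = np.asarray(I, dtype=float)
    return 1.0 - np.exp(-I / I0)


def dye_loading_curve(t, params: DyeLoadingParams):
    """Evaluate the loading time course; F = 0 before the onset delay."""
    t = np.asarray(t, dtype=float)
    ts = np.clip(t - params.onset_delay, 0.0, None)
    out = params.A_s * (1.0 - np.exp(-ts / params.tau_s))
    if params.form == "bi":
        out = out + params.A_f * (1.0 - np.exp(-ts / params.tau_f))
    return np.where(t >= params.onset_delay, out, 0.0)


def _ls(residual, x0, bounds, x_scale=None):
    kw = {"bounds": bounds, "method": "trf"}
    if x_scale is not None:
        kw["x_scale"] = x_scale
    res = least_squares(residual, x0, **kw)
    return res, float(np.sum(res.fun**2))


def fit_poisson(trace, init: PoissonParams | None = None) -> FitResult:
    """Fit x_s(t) = A_s t³ exp(-t/τ) to a dim-flash trace.

    On noiseless kernel data the generating (A_s, τ) are recovered to
    optimizer precision. The default initial guess is read off the trace
    peak (τ0 = t_peak/3, A0 from the analytic peak value).
    """
    t = trace.grid.times
    y = np.asarray(trace.values, dtype=float)
    if init is None:
        i_pk = int(np.argmax(y))
        tau0 = max(t[i_pk] / 3.0, trace.grid.dt)
        a0 = max(y[i_pk], 1e-12) / (27.0 * tau0**3 * np.exp(-3.0))
    else:
        a0, tau0 = init.A_s, init.tau

    def residual(p):
        return _kernel(t, PoissonParams(p[0], p[1])) - y

    lo, hi = [1e-12, 1e-6], [np.inf, np.inf]
    res, sse = _ls(residual, [a0, tau0], (lo, hi), x_scale=[a0, tau0])
    return FitResult(
        params={"A_s": float(res.x[0]), "tau": float(res.x[1])},
        sse=sse, converged=bool(res.success), n_iter=int(res.nfev),
        init={"A_s": a0, "tau": tau0},
        bounds={"A_s": (lo[0], hi[0]), "tau": (lo[1], hi[1])},
        model="poisson_kernel",
    )


def fit_feedback(
    trace,
    pp_fixed: PoissonParams,
    init: FeedbackParams | None = None,
    *,
    H: float = 1.0,
    fit_amplitude: bool = False,
    delta_max: float = 0.2,
    g_bounds: tuple[float, float] = (0.0, 0.99),
) -> FitResult:
    """Fit the delayed-feedback response for (G, Δ), with τ (and A_s) fixed.

    τ comes from the dim-flash fit; ``fit_amplitude=True`` adds a free
    multiplicative rescale of A_s (the stronger-flash response shares the
    kernel shape but a larger amplitude). Δ is profiled over integer
    sample delays from 0 to ``delta_max`` and G (and the amplitude) are
    re-optimised at each candidate; the best-SSE delay wins, with the
    smaller delay breaking ties.
    """
    t = trace.grid.times
    y = np.asarray(trace.values, dtype=float)
    dt = trace.grid.dt
    xs = _kernel(t, pp_fixed)
    g0 = init.G if init is not None else 0.3
    g0 = float(np.clip(g0, g_bounds[0] + 1e-6, g_bounds[1] - 1e-6))
    d_max = min(int(round(delta_max / dt)), t.size - 1)

    best = None
    total_nfev = 0
    for d in range(0, d_max + 1):
        if fit_amplitude:
            def residual(p, d=d):
                return p[1] * delay_feedback_loop(xs, H, p[0], d) - y
            x0 = [g0, 1.0]
            lo, hi = [g_bounds[0], 1e-9], [g_bounds[1], np.inf]
        else:
            def residual(p, d=d):
                return delay_feedback_loop(xs, H, p[0], d) - y
            x0 = [g0]
            lo, hi = [g_bounds[0]], [g_bounds[1]]
        res, sse = _ls(residual, x0, (lo, hi))
        total_nfev += int(res.nfev)
        if best is None or sse < best[1] - 1e-15:
            best = (d, sse, res)

    d, sse, res = best
    params = {"G": float(res.x[0]), "delta": d * dt, "H": H}
    if fit_amplitude:
        params["amplitude"] = float(res.x[1])
    return FitResult(
        params=params, sse=sse, converged=bool(res.success),
        n_iter=total_nfev,
        init={"G": g0, "delta": init.delta if init is not None else 0.0},
        bounds={"G": g_bounds, "delta": (0.0, d_max * dt)},
        model="delayed_feedback",
        extra={"delay_samples": d},
    )


def fit_intensity_response(
    points: IntensityResponseCurve, form: str = "expsat"
) -> FitResult:
    """Fit an intensity–response form: 'hill', 'hill_fixed_m' or 'expsat'.

    Amplitudes must be normalized to the saturating response; values
    above 1.05 indicate unnormalized input and raise
    :class:`ParameterError`.
    """
    I, R = points.intensity, points.amplitude
    if I.size < 3:
        raise ParameterError("need at least 3 intensity points")
    if np.max(R) > 1.05:
        raise ParameterError(
            f"amplitudes up to {np.max(R):.3g} look unnormalized; divide by "
            "the mean saturating-flash amplitude first"
        )
    # Initial I0: intensity where the curve crosses its half point.
    order = np.argsort(I)
    i0_init = float(np.interp(0.5, R[order], I[order],
                              left=I.min(), right=I.max()))
    lo_i, hi_i = I.min() / 100.0, I.max() * 100.0

    if form == "expsat":
        def residual(p):
            return expsat_response(I, p[0]) - R
        res, sse = _ls(residual, [i0_init], ([lo_i], [hi_i]), x_scale=[i0_init])
        params = {"I0": float(res.x[0])}
        init = {"I0": i0_init}
        bounds = {"I0": (lo_i, hi_i)}
    elif form == "hill_fixed_m":
        def residual(p):
            return hill_response(I, p[0], 1.0) - R
        res, sse = _ls(residual, [i0_init], ([lo_i], [hi_i]), x_scale=[i0_init])
        params = {"I0": float(res.x[0]), "m": 1.0}
        init = {"I0": i0_init, "m": 1.0}
        bounds = {"I0": (lo_i, hi_i)}
    elif form == "hill":
        def residual(p):
            return hill_response(I, p[0], p[1]) - R
        res, sse = _ls(residual, [i0_init, 1.0],
                       ([lo_i, 0.1], [hi_i, 10.0]), x_scale=[i0_init, 1.0])
        params = {"I0": float(res.x[0]), "m": float(res.x[1])}
        init = {"I0": i0_init, "m": 1.0}
        bounds = {"I0": (lo_i, hi_i), "m": (0.1, 10.0)}
    else:
        raise ParameterError(f"unknown form {form!r}")
    return FitResult(params, sse, bool(res.success), int(res.nfev),
                     init, bounds, model=form)


def _fit_loading_form(t, y, n_exp: int, allow_delay: bool):
    asym = float(np.mean(y[max(1, int(0.8 * y.size)):]))
    asym = max(asym, float(np.max(y)), 1e-9)
    crossing = np.nonzero(y >= (1 - np.exp(-1)) * asym)[0]
    tau0 = max(float(t[crossing[0]]) if crossing.size else t[-1] / 3.0,
               float(t[1] - t[0]))
    starts = [(0.5, 2.0)] if n_exp == 1 else [(0.2, 1.0), (0.1, 3.0), (1.0, 5.0)]
    best = None
    for f_fast, f_slow in starts:
        if n_exp == 1:
            x0 = [asym, tau0 * f_slow]
            lo, hi = [0.0, 1e-6], [np.inf, np.inf]
            def curve(p):
                return p[0] * (1.0 - np.exp(-np.clip(t - (p[2] if allow_delay else 0.0), 0, None) / p[1]))
        else:
            x0 = [asym / 2.0, tau0 * f_fast, asym / 2.0, tau0 * f_slow]
            lo, hi = [0.0, 1e-6, 0.0, 1e-6], [np.inf, np.inf, np.inf, np.inf]
            def curve(p):
                ts = np.clip(t - (p[4] if allow_delay else 0.0), 0.0, None)
                return (p[0] * (1.0 - np.exp(-ts / p[1]))
                        + p[2] * (1.0 - np.exp(-ts / p[3])))
        if allow_delay:
            x0 = x0 + [0.0]
            lo, hi = lo + [0.0], hi + [5.0]
        res, sse = _ls(lambda p: curve(p) - y, x0, (lo, hi))
        if best is None or sse < best[1]:
            best = (res, sse, x0, (lo, hi))
    return best


def fit_dye_loading(trace, allow_delay: bool = False,
                    mono_threshold: float = 0.05) -> FitResult:
    """Fit dye-loading fluorescence with bi- and mono-exponential forms.

    Both forms are fitted; the mono-exponential is selected when the
    biexponential's fast amplitude is below ``mono_threshold`` of the
    total — the regime of regions far from the pipette, where diffusion
    has filtered the fast component away. With ``allow_delay`` a free
    onset delay within [0, 5] s is included. Amplitudes are bounded at
    zero, so negative-amplitude solutions cannot occur.
    """
    t = trace.grid.times
    y = np.asarray(trace.values, dtype=float)
    res_b, sse_b, x0_b, bounds_b = _fit_loading_form(t, y, 2, allow_delay)
    res_m, sse_m, x0_m, bounds_m = _fit_loading_form(t, y, 1, allow_delay)

    a1, t1, a2, t2 = res_b.x[:4]
    if t1 > t2:  # order the components fast-first
        a1, t1, a2, t2 = a2, t2, a1, t1
    delay_b = float(res_b.x[4]) if allow_delay else 0.0
    delay_m = float(res_m.x[2]) if allow_delay else 0.0
    fast_fraction = a1 / max(a1 + a2, 1e-300)
    # A one-component curve makes the biexponential fit degenerate: the
    # amplitude lands in a single component or splits across two equal time
    # constants. Either way there is only one resolvable component.
    degenerate = (t2 / max(t1, 1e-300) < 2.0
                  or fast_fraction > 1.0 - mono_threshold)

    if fast_fraction < mono_threshold or degenerate:
        params = DyeLoadingParams(0.0, 0.0, float(res_m.x[0]),
                                  float(res_m.x[1]), delay_m, form="mono")
        sel, sse, x0 = res_m, sse_m, x0_m
    else:
        params = DyeLoadingParams(float(a1), float(t1), float(a2), float(t2),
                                  delay_b, form="bi")
        sel, sse, x0 = res_b, sse_b, x0_b
    return FitResult(
        params={"A_f": params.A_f, "tau_f": params.tau_f,
                "A_s": params.A_s, "tau_s": params.tau_s,
                "onset_delay": params.onset_delay, "form": params.form,
                "asymptote": params.asymptote},
        sse=sse, converged=bool(sel.success),
        n_iter=int(res_b.nfev + res_m.nfev),
        init={"x0": list(np.asarray(x0, dtype=float))},
        bounds={"amplitudes": (0.0, np.inf), "onset_delay": (0.0, 5.0)},
        model=f"dye_loading_{params.form}",
        extra={"sse_bi": sse_b, "sse_mono": sse_m,
               "fast_fraction": float(fast_fraction)},
    )


def fit_recovery_exponentials(t, y, n_exp: int = 1) -> FitResult:
    """Fit a decaying sum of ``n_exp`` exponentials A_i exp(-t/τ_i) to a recovery.

    Multi-start over time-constant splits; amplitudes bounded at zero.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2 * n_exp + 2:
        raise FitError("too few points for an exponential recovery fit")
    v0 = max(float(y[0]), 1e-12)
    below = np.nonzero(y < v0 / np.e)[0]
    tau0 = max(float(t[below[0]]) if below.size else float(t[-1]), 1e-6)
    starts = [(1.0,)] if n_exp == 1 else [(0.3, 1.0), (0.3, 3.0), (1.0, 5.0),
                                          (0.1, 1.0), (0.5, 10.0)]
    best = None
    for factors in starts:
        x0, lo, hi = [], [], []
        for f in factors:
            x0 += [v0 / n_exp, tau0 * f]
            lo += [0.0, 1e-9]
            hi += [np.inf, np.inf]

        def residual(p):
            out = np.zeros_like(t)
            for i in range(n_exp):
                out = out + p[2 * i] * np.exp(-t / p[2 * i + 1])
            return out - y

        res, sse = _ls(residual, x0, (lo, hi))
        if best is None or sse < best[1]:
            best = (res, sse, x0)
    res, sse, x0 = best
    params = {}
    order = np.argsort(res.x[1::2])
    for rank, i in enumerate(order, start=1):
        params[f"A{rank}"] = float(res.x[2 * i])
        params[f"tau{rank}"] = float(res.x[2 * i + 1])
    return FitResult(params, sse, bool(res.success), int(res.nfev),
                     {"x0": x0}, {"amplitudes": (0.0, np.inf)},
                     model=f"recovery_{n_exp}exp")


def recovery_harness(
    generate: Callable[[], object],
    fit: Callable[[object], FitResult],
    truth: dict,
    noise_sigma: float,
    n_reps: int,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Bias/RMSE table for a fitter on noisy replicates of its own model.

    ``generate`` returns a noiseless trace; white Gaussian noise with
    standard deviation ``noise_sigma`` x peak is added per replicate;
    ``fit`` maps the noisy trace to a :class:`FitResult`. Reproducible
    for a given ``seed``. The returned frame has one row per parameter
    in ``truth`` with columns truth / bias / rmse / rel_rmse.
    """
    if n_reps < 2:
        raise ParameterError(f"need at least 2 replicates, got {n_reps}")
    rng = np.random.default_rng(seed)
    clean = generate()
    peak = float(np.max(np.abs(clean.values)))
    estimates = {k: [] for k in truth}
    for _ in range(n_reps):
        noisy = clean.values + rng.normal(0.0, noise_sigma * peak,
                                          clean.values.shape)
        result = fit(clean.replace_values(noisy) if hasattr(clean, "replace_values")
                     else type(clean)(clean.grid, noisy, clean.kind))
        for k in truth:
            estimates[k].append(result.params[k])
    rows = []
    for k, true_val in truth.items():
        est = np.asarray(estimates[k])
        bias = float(np.mean(est) - true_val)
        rmse = float(np.sqrt(np.mean((est - true_val) ** 2)))
        rows.append({
            "param": k, "truth": true_val, "bias": bias, "rmse": rmse,
            "rel_rmse": rmse / abs(true_val) if true_val != 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("param")
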