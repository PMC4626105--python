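"""Alignment, averaging, smoothing and scalar metrics for recorded traces.

Mirrors the processing applied to whole-cell photoresponse recordings:
responses to the same flash are aligned on the flash time and averaged,
the average is smoothed with a 30 Hz local regression (or a 20 Hz
Gaussian filter for long, slow traces), and scalar metrics — fractional
suppression over a stable window, the normalized rising-phase slope, the
collecting-area estimate — are read off the processed trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .errors import FitError, FormatError, ParameterError
from .model import TimeGrid

__all__ = [
    "Trace",
    "SuppressionMetrics",
    "CollectingArea",
    "align_and_average",
    "smooth_local",
    "gaussian_lowpass",
    "fractional_suppression",
    "rising_slope",
    "estimate_collecting_area",
]

#: -3 dB calibration constants (see docs/methods.md):
#: a two-sided exponential kernel exp(-|t|/lam) has |H(f)| = 1/(1+(2πfλ)²),
#: a Gaussian kernel has |H(f)| = exp(-(2πfσ)²/2).
_EXP_LAMBDA_PER_HZ = math.sqrt(math.sqrt(2.0) - 1.0) / (2.0 * math.pi)
_GAUSS_SIGMA_PER_HZ = math.sqrt(math.log(2.0)) / (2.0 * math.pi)


@dataclass
class Trace:
    """A uniformly sampled recording (current in pA or fluorescence in a.u.).

    Current traces follow the suppression convention: values are the
    light-suppressed fraction of the dark current in pA, positive going,
    zero in darkness. ``stimulus`` optionally carries the stimulus event
    (a mapping with at least ``onset``).
    """

    grid: TimeGrid
    values: np.ndarray
    signal_kind: str = "current"
    stimulus: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ParameterError("values length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")

    def replace_values(self, values: np.ndarray) -> "Trace":
        return Trace(self.grid, values, self.signal_kind, self.stimulus,
                     dict(self.meta))


@dataclass(frozen=True)
class SuppressionMetrics:
    """Fraction of the dark current suppressed over a stated window."""

    dark_current: float
    fraction_suppressed: float
    window: tuple[float, float]


def _flash_onset(trace: Trace) -> float:
    stim = trace.stimulus
    if stim is None:
        raise FormatError("trace has no recorded flash time (stimulus missing)")
    if hasattr(stim, "onset"):
        return float(stim.onset)
    try:
        return float(stim["onset"])
    except (KeyError, TypeError) as exc:
        raise FormatError("stimulus metadata lacks an 'onset' field") from exc


def align_and_average(traces: list[Trace], flash_time: float = 0.0) -> Trace:
    """Align traces on their recorded flash times and average pointwise.

    Each trace is shifted so its flash time maps to ``flash_time``; the
    mean is taken over the overlapping window only (no extrapolation).
    All traces must share the same dt. Permutation-invariant.
    """
    if not traces:
        raise ParameterError("need at least one trace to average")
    dt = traces[0].grid.dt
    for tr in traces[1:]:
        if not math.isclose(tr.grid.dt, dt, rel_tol=1e-9):
            raise FormatError(
                f"mismatched sampling intervals: {tr.grid.dt} vs {dt}"
            )
    # Start/end of each trace relative to its own flash.
    rel_starts = [tr.grid.t_start - _flash_onset(tr) for tr in traces]
    rel_ends = [rs + dt * (tr.grid.n_points - 1)
                for rs, tr in zip(rel_starts, traces)]
    lo, hi = max(rel_starts), min(rel_ends)
    n = int(math.floor((hi - lo) / dt + 1e-9)) + 1
    if n < 1:
        raise ParameterError("traces have no overlapping window")
    stack = np.empty((len(traces), n))
    for row, (tr, rs) in enumerate(zip(traces, rel_starts)):
        k = round((lo - rs) / dt)
        stack[row] = tr.values[k : k + n]
    grid = TimeGrid(flash_time + lo, dt, n)
    first = traces[0]
    return Trace(grid, stack.mean(axis=0), first.signal_kind,
                 {"onset": flash_time, "n_averaged": len(traces)},
                 dict(first.meta))


def _check_cutoff(cutoff_hz: float, dt: float) -> None:
    nyquist = 0.5 / dt
    if not (0 < cutoff_hz < nyquist):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g} Hz)"
        )


def smooth_local(trace: Trace, cutoff_hz: float = 30.0) -> Trace:
    """Local degree-1 regression with negative-exponential weights.

    At each sample a straight line is fitted to the neighbourhood with
    weights exp(-|t - t0|/λ); λ is calibrated so the interior frequency
    response is -3 dB at ``cutoff_hz``. Degree-1 fitting reproduces
    constants and straight lines exactly (DC preserved); window
    truncation at the trace edges is handled by refitting, not padding.
    """
    _check_cutoff(cutoff_hz, trace.grid.dt)
    dt = trace.grid.dt
    lam = _EXP_LAMBDA_PER_HZ / cutoff_hz
    half = max(3, int(round(6.0 * lam / dt)))
    offs = np.arange(-half, half + 1)
    w = np.exp(-np.abs(offs) * dt / lam)

    y = trace.values
    ones = np.ones_like(y)
    # Weighted-moment convolutions; truncated windows at the edges are
    # handled by convolving the indicator, so each point gets an exact
    # weighted linear fit over its available neighbourhood.
    def conv(a: np.ndarray, kern: np.ndarray) -> np.ndarray:
        return np.convolve(a, kern[::-1], mode="same")

    s0 = conv(ones, w)
    s1 = conv(ones, w * offs)
    s2 = conv(ones, w * offs**2)
    t0 = conv(y, w)
    t1 = conv(y, w * offs)
    det = s0 * s2 - s1**2
    out = (s2 * t0 - s1 * t1) / det
    return trace.replace_values(out)


def gaussian_lowpass(trace: Trace, cutoff_hz: float = 20.0) -> Trace:
    """Gaussian FIR low-pass with -3 dB point at ``cutoff_hz``, unit DC gain."""
    _check_cutoff(cutoff_hz, trace.grid.dt)
    sigma = _GAUSS_SIGMA_PER_HZ / cutoff_hz / trace.grid.dt
    return trace.replace_values(
        gaussian_filter1d(trace.values, sigma, mode="nearest")
    )


def fractional_suppression(
    trace: Trace,
    dark_current: float,
    window: tuple[float, float] = (2.5, 6.0),
) -> SuppressionMetrics:
    """Mean suppressed current over ``window`` as a fraction of dark current.

    The default window (2.5–6 s after step onset) is where the
    step-response current is most stable. The fraction is clipped to
    [0, 1].
    """
    if dark_current <= 0:
        raise ParameterError(f"dark current must be positive, got {dark_current}")
    t = trace.grid.times
    lo, hi = window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ParameterError(
            f"window {window} not contained in trace span ({t[0]:g}, {t[-1]:g})"
        )
    mask = (t >= lo) & (t <= hi)
    frac = float(np.clip(np.mean(trace.values[mask]) / dark_current, 0.0, 1.0))
    return SuppressionMetrics(dark_current, frac, (lo, hi))


def rising_slope(
    trace: Trace,
    fit_fraction: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, float]:
    """Straight-line fit to the rising phase of a normalized response.

    The trace is normalized to peak 1 (making the result invariant to
    amplitude rescaling), and an ordinary least-squares line is fitted
    over the rising segment between the two normalized-amplitude
    fractions (default 10–90% of peak). Returns ``(slope, r)`` with the
    slope in s⁻¹ and ``r`` the Pearson correlation coefficient.
    """
    v = trace.values
    peak = float(np.max(v))
    if peak <= 0:
        raise FitError("trace has no positive peak to normalize by")
    v = v / peak
    i_peak = int(np.argmax(v))
    lo, hi = fit_fraction
    rising = v[: i_peak + 1]
    above_lo = np.nonzero(rising >= lo)[0]
    start = int(above_lo[0]) if above_lo.size else 0
    above_hi = np.nonzero(rising[start:] > hi)[0]
    stop = start + int(above_hi[0]) if above_hi.size else i_peak + 1
    seg = slice(start, max(stop, start))
    t_seg = trace.grid.times[seg]
    v_seg = v[seg]
    if t_seg.size < 4:
        raise FitError(
            f"only {t_seg.size} points in the rising segment; need >= 4"
        )
    slope, _ = np.polyfit(t_seg, v_seg, 1)
    r = float(pearsonr(t_seg, v_seg).statistic)
    return float(slope), r


@dataclass(frozen=True)
class CollectingArea:
    """Collecting-area estimate with the conventionally quoted rounding."""

    value: float
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def estimate_collecting_area(
    geometric_area: float, capture_ratio: float
) -> CollectingArea:
    """Collecting area = geometric outer-segment area x capture ratio.

    The capture ratio (collecting area / geometric area, ~0.062 from rod
    measurements) converts the measured geometrical area into an
    effective photon-collecting area. The full-precision product is kept
    in ``value``; ``label`` quotes it to a single leading figure
    (e.g. 15.3 μm² x 0.062 -> 0.949 -> "~1 μm²").
    """
    if geometric_area <= 0 or capture_ratio <= 0:
        raise ParameterError("geometric area and capture ratio must be positive")
    value = geometric_area * capture_ratio
    rounded = round(value) if value >= 0.5 else float(f"{value:.1g}")
    label = f"~{rounded:g} μm²"
    return CollectingArea(value, label)
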