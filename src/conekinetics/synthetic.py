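"""Synthetic whole-cell recordings and dye-loading curves.

Generates every input the analysis pipeline consumes, with the
statistical structure of the real recordings it stands in for: flash
responses shaped by the delayed-feedback model at the standard
ten-intensity ladder (1.14·10² – 3.76·10⁵ photons/μm²), a dark current
of ~18.7 pA, recording noise band-limited at 2 kHz, optional slow
baseline drift, step-of-light responses produced by driving the feedback
loop with a sustained input, and biexponential dye-loading fluorescence
whose fast component attenuates with distance from the pipette.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .fitting import DyeLoadingParams, ExpSatParams, dye_loading_curve, expsat_response
from .model import FeedbackParams, PoissonParams, TimeGrid, feedback_response
from .traceproc import Trace, gaussian_lowpass

__all__ = [
    "PAPER_INTENSITIES",
    "FLASH_DURATION_BREAK",
    "StimulusEvent",
    "StimulusProtocol",
    "CellSpec",
    "flash_duration",
    "make_protocol",
    "simulate_recording",
    "simulate_dye_loading",
]

#: The ten flash intensities of the standard ladder (photons/μm²).
PAPER_INTENSITIES = (
    1.14e2, 1.14e3, 1.16e3, 2.32e3, 4.49e3,
    8.68e3, 1.77e4, 9.55e4, 1.85e5, 3.76e5,
)

#: Flashes up to this intensity last 1 ms; stronger flashes last 10 ms.
FLASH_DURATION_BREAK = 1.77e4


def flash_duration(intensity: float) -> float:
    return 1e-3 if intensity <= FLASH_DURATION_BREAK else 1e-2


@dataclass(frozen=True)
class StimulusEvent:
    """A single light stimulus.

    ``intensity`` is in photons/μm² for flashes and photons/(μm²·s) for
    steps and backgrounds.
    """

    onset: float
    duration: float
    intensity: float
    kind: str = "flash"
    wavelength: float = 525.0

    def to_dict(self) -> dict:
        return {"onset": self.onset, "duration": self.duration,
                "intensity": self.intensity, "kind": self.kind,
                "wavelength": self.wavelength}


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered list of stimulus events; flash durations follow the
    intensity rule (1 ms up to 1.77·10⁴ photons/μm², 10 ms above)."""

    events: tuple

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.intensity <= 0:
                raise ParameterError(f"intensity must be positive: {ev}")
            if ev.kind == "flash":
                want = flash_duration(ev.intensity)
                if not np.isclose(ev.duration, want):
                    raise ParameterError(
                        f"flash at {ev.intensity:g} photons/μm² must last "
                        f"{want * 1e3:g} ms, got {ev.duration * 1e3:g} ms"
                    )

    def __len__(self) -> int:
        return len(self.events)


def make_protocol(
    intensities=None,
    repeats: int = 3,
    interval: float = 5.0,
    start: float = 1.0,
) -> StimulusProtocol:
    """Flashes of increasing intensity delivered in repeated groups.

    Default ladder is the standard ten intensities; each is delivered
    ``repeats`` times (triplets by default) spaced ``interval`` seconds.
    """
    if intensities is None:
        intensities = PAPER_INTENSITIES
    events = []
    onset = start
    for intensity in intensities:
        for _ in range(repeats):
            events.append(StimulusEvent(onset, flash_duration(intensity),
                                        float(intensity), "flash"))
            onset += interval
    return StimulusProtocol(tuple(events))


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of a simulated cone.

    ``feedback_scaling='saturation'`` scales the feedback fraction with
    the fractional activation, G_eff(I) = G·(1 - e^(-I/I0)), so dim
    flashes are quasi-unregulated (feedback grows with the light-driven
    Ca²⁺ decline); ``'none'`` applies G at every intensity.
    ``noise_sigma`` is the white-noise standard deviation (pA) before
    band-limiting at ``noise_bandwidth``. ``step_steady_fraction`` is
    the steady-state fraction of dark current suppressed by a step of
    light. Drift defaults to zero: baseline drift in the recordings
    arises in inner-segment channels, outside the transduction model.
    """

    poisson: PoissonParams
    feedback: FeedbackParams
    dark_current: float = 18.7
    irc: ExpSatParams = field(default_factory=lambda: ExpSatParams(3e3))
    drift_rate: float = 0.0            # pA per minute
    noise_sigma: float = 0.2           # pA, white, before band-limiting
    noise_bandwidth: float = 2000.0    # Hz
    step_steady_fraction: float = 0.83
    feedback_scaling: str = "saturation"

    def __post_init__(self) -> None:
        if self.dark_current <= 0:
            raise ParameterError("dark current must be positive")
        if self.feedback_scaling not in ("saturation", "none"):
            raise ParameterError(
                f"unknown feedback_scaling {self.feedback_scaling!r}"
            )

    def effective_feedback(self, intensity: float) -> FeedbackParams:
        if self.feedback_scaling == "none":
            return self.feedback
        g_eff = self.feedback.G * float(expsat_response(intensity, self.irc.I0))
        return replace(self.feedback, G=g_eff)


def _flash_values(cell: CellSpec, intensity: float, grid: TimeGrid) -> np.ndarray:
    fp = cell.effective_feedback(intensity)
    shape = feedback_response(cell.poisson, fp, grid).values
    peak = float(np.max(shape))
    amp = cell.dark_current * float(expsat_response(intensity, cell.irc.I0))
    return shape * (amp / peak)


def _step_values(cell: CellSpec, event: StimulusEvent, grid: TimeGrid) -> np.ndarray:
    from .model import delay_feedback_loop  # local to avoid cycle at import

    fp = cell.feedback
    target = cell.step_steady_fraction * cell.dark_current
    drive_level = target * (1.0 + fp.H * fp.G) / fp.H
    t = grid.times
    drive = np.where((t >= 0) & (t < event.duration), drive_level, 0.0)
    d = 0 if fp.delta == 0 else max(1, round(fp.delta / grid.dt))
    return delay_feedback_loop(drive, fp.H, fp.G, d)


def simulate_recording(
    cell: CellSpec,
    protocol: StimulusProtocol,
    grid: TimeGrid,
    seed: int,
) -> list[Trace]:
    """Simulate one suppression trace per stimulus event.

    ``grid`` is relative to each event (t = 0 at stimulus onset; use a
    negative ``t_start`` for a pre-stimulus baseline). Returned traces
    sit on absolute time with the event recorded in ``stimulus``. Values
    are suppressed current in pA (positive). Flash amplitudes follow the
    exponential-saturation intensity–response curve; noise is white
    Gaussian band-limited by a Gaussian filter at ``noise_bandwidth``;
    drift is linear in absolute time. Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    if cell.noise_sigma > 0 and cell.noise_bandwidth > 0.5 / grid.dt:
        raise ParameterError(
            f"noise bandwidth {cell.noise_bandwidth:g} Hz exceeds the grid "
            f"Nyquist frequency {0.5 / grid.dt:g} Hz"
        )
    traces = []
    for ev in protocol.events:
        if ev.kind == "flash":
            clean = _flash_values(cell, ev.intensity, grid)
        elif ev.kind in ("step", "background"):
            clean = _step_values(cell, ev, grid)
        else:
            raise ParameterError(f"unknown stimulus kind {ev.kind!r}")
        abs_grid = TimeGrid(ev.onset + grid.t_start, grid.dt, grid.n_points)
        values = clean
        if cell.drift_rate != 0.0:
            values = values + cell.drift_rate * abs_grid.times / 60.0
        if cell.noise_sigma > 0:
            noise = rng.normal(0.0, cell.noise_sigma, grid.n_points)
            carrier = Trace(abs_grid, noise, "current")
            values = values + gaussian_lowpass(carrier, cell.noise_bandwidth).values
        traces.append(Trace(abs_grid, values, "current", ev.to_dict(),
                            meta={"intensity": ev.intensity, "kind": ev.kind}))
    return traces


def simulate_dye_loading(
    params_per_region: list[DyeLoadingParams],
    duration: float = 50.0,
    seed: int | None = None,
    dt: float = 0.1,
    noise_cv: float = 0.0,
) -> list[Trace]:
    """Region-integrated fluorescence time courses after dye injection.

    The first entry conventionally describes the region next to the
    pipette (biexponential); distal regions carry mono-exponential
    parameters with the fast component already attenuated. Optional
    multiplicative Gaussian noise with coefficient of variation
    ``noise_cv``. F(0) = 0 in every region.
    """
    if not params_per_region:
        raise ParameterError("need at least one region")
    rng = np.random.default_rng(seed)
    grid = TimeGrid(0.0, dt, int(round(duration / dt)) + 1)
    out = []
    for i, params in enumerate(params_per_region):
        f = dye_loading_curve(grid.times, params)
        if noise_cv > 0:
            f = f * (1.0 + rng.normal(0.0, noise_cv, f.shape))
        out.append(Trace(grid, f, "fluorescence", None,
                         meta={"region": i, "form": params.form}))
    return out
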