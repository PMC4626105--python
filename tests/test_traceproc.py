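"""Tests for alignment, averaging, smoothing and scalar trace metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conekinetics import (
    FitError,
    FormatError,
    ParameterError,
    PoissonParams,
    TimeGrid,
    Trace,
    align_and_average,
    estimate_collecting_area,
    fractional_suppression,
    gaussian_lowpass,
    poisson_response,
    rising_slope,
    smooth_local,
)


def _trace(values, dt=1e-3, t_start=0.0, onset=None):
    grid = TimeGrid(t_start, dt, len(values))
    stim = {"onset": onset} if onset is not None else None
    return Trace(grid, np.asarray(values, dtype=float), "current", stim)


class TestAlignAndAverage:
    def test_mean_of_identical_traces_is_identity(self):
        v = np.sin(np.linspace(0, 3, 500))
        traces = [_trace(v, onset=0.0) for _ in range(3)]
        avg = align_and_average(traces)
        np.testing.assert_allclose(avg.values, v, rtol=1e-12, atol=1e-15)

    def test_alignment_uses_flash_tags(self):
        """Traces recorded at different absolute times coincide after
        alignment on their flash tags."""
        v = np.exp(-np.linspace(0, 5, 400))
        traces = []
        for onset in (0.1, 0.75, 2.0):
            grid = TimeGrid(onset - 0.05, 1e-3, 400)
            traces.append(Trace(grid, v, "current", {"onset": onset}))
        avg = align_and_average(traces, flash_time=0.0)
        np.testing.assert_allclose(avg.values, v)
        assert avg.grid.t_start == pytest.approx(-0.05)

    def test_noise_reduction_scales_with_replicates(self):
        rng = np.random.default_rng(11)
        clean = np.zeros(20000)
        traces = [_trace(clean + rng.normal(0, 1.0, clean.size), onset=0.0)
                  for _ in range(3)]
        avg = align_and_average(traces)
        assert np.std(avg.values) == pytest.approx(1.0 / np.sqrt(3), rel=0.1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        traces = [_trace(rng.normal(size=300), onset=0.0) for _ in range(4)]
        a = align_and_average(traces)
        b = align_and_average(traces[::-1])
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12, atol=1e-15)

    def test_mismatched_dt_rejected(self):
        with pytest.raises(FormatError):
            align_and_average([_trace(np.zeros(10), dt=1e-3, onset=0.0),
                               _trace(np.zeros(10), dt=2e-3, onset=0.0)])

    def test_missing_flash_tag_rejected(self):
        with pytest.raises(FormatError):
            align_and_average([_trace(np.zeros(10))])


class TestSmoothing:
    def test_constant_and_ramp_preserved_exactly(self):
        """Degree-1 local regression reproduces polynomials of degree <= 1,
        including at the trace edges."""
        grid = TimeGrid(0.0, 1e-4, 5000)
        for values in (np.full(5000, 3.7), 2.0 + 5.0 * grid.times):
            out = smooth_local(Trace(grid, values), 30.0)
            np.testing.assert_allclose(out.values, values, atol=1e-10)

    @pytest.mark.parametrize("smoother, cutoff",
                             [(smooth_local, 30.0), (gaussian_lowpass, 20.0)])
    def test_minus_3db_at_cutoff(self, smoother, cutoff):
        """A sinusoid at the cutoff frequency is attenuated to ~1/sqrt(2)."""
        grid = TimeGrid(0.0, 1e-4, 20000)
        tr = Trace(grid, np.sin(2 * np.pi * cutoff * grid.times))
        out = smoother(tr, cutoff)
        mid = slice(5000, 15000)
        att = np.sqrt(np.mean(out.values[mid] ** 2)
                      / np.mean(tr.values[mid] ** 2))
        assert att == pytest.approx(1.0 / np.sqrt(2), rel=0.05)

    def test_noise_attenuation_matches_impulse_response(self):
        """White-noise variance reduction equals the sum of squared effective
        weights read off the smoother's impulse response (the brute-force
        frequency-domain prediction)."""
        grid = TimeGrid(0.0, 1e-4, 40000)
        rng = np.random.default_rng(5)
        noisy = Trace(grid, rng.normal(0, 1.0, grid.n_points))
        out = smooth_local(noisy, 30.0)
        impulse = np.zeros(grid.n_points)
        impulse[grid.n_points // 2] = 1.0
        weights = smooth_local(Trace(grid, impulse), 30.0).values
        predicted = np.sqrt(np.sum(weights**2))
        measured = np.std(out.values[5000:-5000])
        assert measured == pytest.approx(predicted, rel=0.15)

    def test_smoothers_are_linear(self):
        grid = TimeGrid(0.0, 1e-4, 3000)
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=3000), rng.normal(size=3000)
        for fn in (smooth_local, gaussian_lowpass):
            combined = fn(Trace(grid, 2.0 * a + 3.0 * b), 25.0).values
            separate = (2.0 * fn(Trace(grid, a), 25.0).values
                        + 3.0 * fn(Trace(grid, b), 25.0).values)
            np.testing.assert_allclose(combined, separate, atol=1e-9)

    def test_gaussian_impulse_response_is_gaussian(self):
        grid = TimeGrid(0.0, 1e-3, 2001)
        impulse = np.zeros(2001)
        impulse[1000] = 1.0
        kernel = gaussian_lowpass(Trace(grid, impulse), 20.0).values
        sigma_s = np.sqrt(np.log(2.0)) / (2 * np.pi * 20.0)
        k = np.arange(2001) - 1000
        expected = np.exp(-0.5 * (k * grid.dt / sigma_s) ** 2)
        expected /= expected.sum()
        # the FIR truncates the analytic kernel's far tails (~1e-6)
        np.testing.assert_allclose(kernel, expected, atol=1e-5)

    def test_cutoff_beyond_nyquist_rejected(self):
        tr = _trace(np.zeros(100), dt=1e-3)  # Nyquist 500 Hz
        for fn in (smooth_local, gaussian_lowpass):
            with pytest.raises(ParameterError):
                fn(tr, 600.0)


class TestFractionalSuppression:
    def _step_trace(self, level):
        grid = TimeGrid(0.0, 1e-2, 801)
        values = np.where((grid.times >= 0.2) & (grid.times <= 7.5), level, 0.0)
        return Trace(grid, values)

    def test_full_and_absent_suppression(self):
        assert fractional_suppression(self._step_trace(18.7), 18.7) \
            .fraction_suppressed == pytest.approx(1.0)
        assert fractional_suppression(self._step_trace(0.0), 18.7) \
            .fraction_suppressed == 0.0

    def test_synthetic_step_suppressing_83_percent(self):
        """A simulated step of light reaching the standard steady state
        suppresses 83% of the dark current over the stable 2.5-6 s window."""
        from conekinetics import CellSpec, FeedbackParams, StimulusEvent, \
            StimulusProtocol, simulate_recording

        cell = CellSpec(PoissonParams(5200, 0.052), FeedbackParams(0.6, 0.06),
                        noise_sigma=0.0)
        proto = StimulusProtocol((StimulusEvent(0.0, 8.0, 1.8e5, "step"),))
        grid = TimeGrid(-0.5, 1e-2, 900)
        trace = simulate_recording(cell, proto, grid, seed=0)[0]
        m = fractional_suppression(trace, cell.dark_current)
        assert m.fraction_suppressed == pytest.approx(0.83, abs=0.01)

    @given(scale=st.floats(0.0, 1.0))
    def test_fraction_bounded(self, scale):
        tr = self._step_trace(scale * 18.7)
        frac = fractional_suppression(tr, 18.7).fraction_suppressed
        assert 0.0 <= frac <= 1.0

    def test_domain_errors(self):
        tr = self._step_trace(1.0)
        with pytest.raises(ParameterError):
            fractional_suppression(tr, 0.0)
        with pytest.raises(ParameterError):
            fractional_suppression(tr, 18.7, window=(2.5, 100.0))


class TestRisingSlope:
    def test_ramp_reaching_peak_in_one_sixtyfourth_second(self):
        grid = TimeGrid(0.0, 1e-5, 3000)
        values = np.clip(grid.times * 64.0, 0.0, 1.0)
        slope, r = rising_slope(Trace(grid, values))
        assert slope == pytest.approx(64.0, rel=1e-6)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_unit_ramp(self):
        grid = TimeGrid(0.0, 1e-3, 1100)
        values = np.clip(grid.times, 0.0, 1.0)
        slope, _ = rising_slope(Trace(grid, values))
        assert slope == pytest.approx(1.0, rel=1e-6)

    def test_kernel_slope_matches_secant_oracle(self):
        """OLS slope over the 10-90% rising segment agrees with the
        brute-force secant between the same amplitude fractions."""
        grid = TimeGrid(0.0, 1e-4, 5000)
        tr = poisson_response(PoissonParams(1100.0, 0.035), grid)
        v = tr.values / tr.values.max()
        slope, r = rising_slope(Trace(grid, v))
        i_peak = np.argmax(v)
        t10 = np.interp(0.1, v[: i_peak + 1], grid.times[: i_peak + 1])
        t90 = np.interp(0.9, v[: i_peak + 1], grid.times[: i_peak + 1])
        secant = 0.8 / (t90 - t10)
        assert slope == pytest.approx(secant, rel=0.1)
        assert r > 0.97

    def test_amplitude_rescaling_invariance(self):
        grid = TimeGrid(0.0, 1e-4, 5000)
        tr = poisson_response(PoissonParams(1100.0, 0.035), grid)
        s1, _ = rising_slope(Trace(grid, tr.values))
        s2, _ = rising_slope(Trace(grid, 7.3 * tr.values))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_too_few_points_rejected(self):
        grid = TimeGrid(0.0, 0.3, 5)
        with pytest.raises(FitError):
            rising_slope(Trace(grid, np.array([0, 0.2, 0.5, 1.0, 0.1])))


@pytest.mark.parametrize(
    "area, ratio, value, label",
    [
        (15.3, 0.062, 0.9486, "~1 μm²"),   # measured cone outer segment
        (1.0, 1.0, 1.0, "~1 μm²"),
        (16.13, 0.062, 1.00006, "~1 μm²"),
    ],
)
def test_collecting_area(area, ratio, value, label):
    est = estimate_collecting_area(area, ratio)
    assert est.value == pytest.approx(value, abs=1e-3)
    assert est.label == label


def test_collecting_area_domain():
    with pytest.raises(ParameterError):
        estimate_collecting_area(-1.0, 0.062)
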