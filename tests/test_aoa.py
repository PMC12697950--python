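"""Pulse isolation, TDoA estimation, and bearing inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seatag.aoa import (
    ArrayGeometry,
    DegeneratePairError,
    InfeasibleDelayError,
    PulseEvent,
    TdoaSet,
    bearing_for_event,
    default_l_array,
    estimate_tdoa,
    expected_angular_resolution,
    isolate_pulses,
    solve_bearing,
)
from seatag.audio import MultichannelAudio
from seatag.synth import ClickModel, click_waveform, propagate_to_array, synth_click_train

FS = 96_000.0
C = 1491.2


def _audio(channels: np.ndarray) -> MultichannelAudio:
    return MultichannelAudio(np.asarray(channels, dtype=np.int32), FS)


def _brute_force_lag(x, y, max_lag):
    """Independent time-domain scan: argmax over lags of sum x[n]*y[n+k],
    spec tie-breaking (smallest |lag|, then negative)."""
    best = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if lag >= 0:
            v = float(np.dot(x[: len(x) - lag], y[lag:]))
        else:
            v = float(np.dot(x[-lag:], y[: len(y) + lag]))
        if best is None or v > best[1]:
            best = (lag, v)
    return best[0]


class TestGeometry:
    def test_collinearity_flag(self):
        two = ArrayGeometry(np.array([[0.0, 0.0], [0.1, 0.0]]))
        line = ArrayGeometry(np.array([[0.0, 0.0], [0.1, 0.0], [0.25, 0.0]]))
        l_shape = default_l_array()
        assert two.collinear and line.collinear and not l_shape.collinear

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            ArrayGeometry(np.array([[0.0, 0.0], [0.0, 0.0]]))

    def test_predicted_delay_antisymmetry(self, geometry):
        for theta in (0.0, 45.0, 133.3):
            d = geometry.predicted_delays(theta)
            for (i, j), tau in d.items():
                assert tau == pytest.approx(
                    -float(
                        np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
                        @ (geometry.positions[j] - geometry.positions[i])
                    )
                    / geometry.sound_speed_m_s
                )


class TestIsolatePulses:
    def test_noise_only_yields_nothing(self, rng):
        noise = rng.normal(0, 100, (3, 96_000)).astype(np.int32)
        assert isolate_pulses(_audio(noise)) == []

    def test_constant_signal_yields_nothing(self):
        assert isolate_pulses(_audio(np.full((3, 48_000), 7))) == []

    def test_single_click_at_known_onset(self, geometry, rng):
        """One click at 20 dB SNR is found within 64 samples of its onset."""
        click = click_waveform(ClickModel(), FS)
        wave = np.zeros(96_000)
        wave[48_000 : 48_000 + click.size] = click
        audio, _ = propagate_to_array(wave, 30.0, 100.0, geometry, noise_spl_db=155.0, seed=4)
        events = isolate_pulses(audio)
        assert len(events) == 1
        assert abs(events[0].onset_sample - 48_000) <= 64

    def test_two_clicks_min_separation(self, geometry):
        click = click_waveform(ClickModel(), FS)
        wave = np.zeros(96_000)
        for onset in (20_000, 20_000 + 4800):  # 50 ms apart
            wave[onset : onset + click.size] += click
        audio, _ = propagate_to_array(wave, 0.0, 100.0, geometry, noise_spl_db=150.0, seed=5)
        events = isolate_pulses(audio, min_separation_s=10e-3)
        assert len(events) == 2
        assert events[0].onset_sample < events[1].onset_sample


class TestEstimateTdoa:
    def test_identical_channels_zero_lag_unit_peak(self, geometry, rng):
        sig = rng.normal(0, 1000, 4096).astype(np.int32)
        audio = _audio(np.vstack([sig, sig, sig]))
        event = PulseEvent(100, (0, 4096), 1.0)
        delay, peak = estimate_tdoa(audio, event, (0, 1), geometry)
        assert delay == 0.0
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_constructed_integer_shift(self, geometry, rng):
        sig = rng.normal(0, 1000, 4096)
        shifted = np.roll(sig, 7)
        audio = _audio(np.vstack([sig, shifted, sig]).astype(np.int32))
        event = PulseEvent(100, (0, 4096), 1.0)
        delay, _ = estimate_tdoa(audio, event, (0, 1), geometry)
        assert delay == pytest.approx(7 / FS)

    def test_antisymmetry(self, geometry, rng):
        for _ in range(20):
            block = rng.normal(0, 500, (3, 512)).astype(np.int32)
            audio = _audio(block)
            event = PulseEvent(10, (0, 512), 1.0)
            for i, j in geometry.pairs():
                dij, _ = estimate_tdoa(audio, event, (i, j), geometry)
                dji, _ = estimate_tdoa(audio, event, (j, i), geometry)
                assert dij == -dji

    def test_fft_equals_brute_force_scan(self, geometry, rng):
        """Frequency-domain argmax equals the exhaustive time-domain scan on
        200 random windows (exact lag agreement)."""
        for _ in range(200):
            n = int(rng.integers(64, 4096))
            block = rng.normal(0, 300, (3, n)).astype(np.int32)
            audio = _audio(block)
            event = PulseEvent(0, (0, n), 1.0)
            i, j = 0, 1
            delay, _ = estimate_tdoa(audio, event, (i, j), geometry)
            expected = _brute_force_lag(
                block[i].astype(float) - block[i].mean(),
                block[j].astype(float) - block[j].mean(),
                geometry.max_lag_samples(i, j),
            )
            assert delay == pytest.approx(expected / FS, abs=1e-15)

    def test_zero_energy_window_rejected(self, geometry):
        audio = _audio(np.zeros((3, 4096), dtype=np.int32))
        event = PulseEvent(10, (0, 4096), 0.0)
        with pytest.raises(ValueError, match="zero-energy"):
            estimate_tdoa(audio, event, (0, 1), geometry)

    def test_out_of_bounds_window_rejected(self, geometry, rng):
        audio = _audio(rng.normal(0, 100, (3, 1000)).astype(np.int32))
        event = PulseEvent(999, (900, 2000), 1.0)
        with pytest.raises(IndexError):
            estimate_tdoa(audio, event, (0, 1), geometry)


class TestSolveBearing:
    def test_exact_forward_model_inversion(self, geometry):
        for theta in (0.0, 90.0, 212.7):
            est = solve_bearing(TdoaSet(geometry.predicted_delays(theta)), geometry)
            err = abs(est.azimuth_deg - theta) % 360.0
            assert min(err, 360.0 - err) <= 0.05
            assert est.residual_s2 <= 1e-18
            assert not est.ambiguous

    def test_empty_tdoa_set_rejected(self, geometry):
        with pytest.raises(ValueError):
            solve_bearing(TdoaSet({}), geometry)

    def test_infeasible_delay_names_pair(self, geometry):
        delays = geometry.predicted_delays(10.0)
        delays[(0, 1)] = 1.0  # far beyond d/c
        with pytest.raises(InfeasibleDelayError, match=r"\(0, 1\)"):
            solve_bearing(TdoaSet(delays), geometry)

    @given(st.floats(min_value=-0.9, max_value=0.9), st.floats(min_value=0.0, max_value=179.0))
    @settings(deadline=None, max_examples=60)
    def test_two_hydrophone_mirror_ambiguity(self, delay_frac, baseline_deg):
        """Any feasible two-hydrophone delay yields exactly two bearings
        reflected about the line connecting the hydrophones."""
        d = 0.125
        angle = math.radians(baseline_deg)
        geom = ArrayGeometry(
            np.array([[0.0, 0.0], [d * math.cos(angle), d * math.sin(angle)]]), C, FS
        )
        tau = delay_frac * d / C
        est = solve_bearing(TdoaSet({(0, 1): tau}), geom)
        assert est.ambiguous
        assert est.mirror_azimuth_deg is not None
        # mirror image about the baseline: same predicted delay
        u = lambda t: np.array([math.cos(math.radians(t)), math.sin(math.radians(t))])
        p = geom.positions
        tau_main = float(u(est.azimuth_deg) @ (p[0] - p[1])) / C
        tau_mirror = float(u(est.mirror_azimuth_deg) @ (p[0] - p[1])) / C
        assert tau_main == pytest.approx(tau_mirror, abs=1e-9)
        assert tau_main == pytest.approx(tau, abs=2e-7)

    def test_quantized_sweep_within_resolution(self, geometry):
        """Integer-sample delay quantization over 360 bearings keeps the mean
        absolute azimuth error within the geometry's expected resolution."""
        res = expected_angular_resolution(geometry)
        fs = geometry.sample_rate_sps
        errors = []
        for theta in np.arange(0.0, 360.0):
            exact = geometry.predicted_delays(theta)
            quant = {p: round(t * fs) / fs for p, t in exact.items()}
            est = solve_bearing(TdoaSet(quant), geometry)
            err = abs(est.azimuth_deg - theta)
            errors.append(min(err, 360.0 - err))
        assert float(np.mean(errors)) <= res

    def test_rotational_equivariance(self):
        """Rotating array and source together leaves the quantized-delay
        error distribution unchanged (up to quantization-edge jitter)."""
        base = default_l_array()
        fs = base.sample_rate_sps

        def mean_error(geom, offset):
            errs = []
            for theta in np.arange(0.0, 360.0, 5.0):
                t = (theta + offset) % 360.0
                quant = {p: round(v * fs) / fs for p, v in geom.predicted_delays(t).items()}
                est = solve_bearing(TdoaSet(quant), geom)
                e = abs(est.azimuth_deg - t)
                errs.append(min(e, 360.0 - e))
            return float(np.mean(errs))

        reference = mean_error(base, 0.0)
        for rot in (30.0, 120.0, 275.0):
            a = math.radians(rot)
            r_mat = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
            rotated = ArrayGeometry(base.positions @ r_mat.T, C, fs)
            assert mean_error(rotated, rot) == pytest.approx(reference, abs=0.5)


class TestAngularResolution:
    def test_single_pair_enumeration_oracle(self):
        """Implementation against an independent enumeration for one pair."""
        d, fs = 0.125, 96_000.0
        geom = ArrayGeometry(np.array([[0.0, 0.0], [d, 0.0]]), C, fs)
        step = C / (fs * d)
        assert math.degrees(math.asin(step)) == pytest.approx(7.14, abs=0.005)
        angles = [
            math.degrees(math.asin(k * step))
            for k in range(-int(1 / step), int(1 / step) + 1)
        ]
        oracle = float(np.mean(np.abs(np.diff(angles))))
        assert expected_angular_resolution(geom) == pytest.approx(oracle, abs=1e-12)
        assert oracle > 7.14  # endfire steps dominate the mean

    def test_rate_scaling_monotonicity(self):
        d = 0.125
        lo = ArrayGeometry(np.array([[0.0, 0.0], [d, 0.0]]), C, 96_000.0)
        hi = ArrayGeometry(np.array([[0.0, 0.0], [d, 0.0]]), C, 192_000.0)
        assert expected_angular_resolution(hi) < expected_angular_resolution(lo)

    def test_degenerate_pair_named(self):
        geom = ArrayGeometry(np.array([[0.0, 0.0], [0.01, 0.0]]), C, 96_000.0)
        with pytest.raises(DegeneratePairError, match=r"\(0, 1\)"):
            expected_angular_resolution(geom)

    def test_default_array_value(self, geometry):
        # mean over the three pairs: two 0.125 m arms and the 0.177 m diagonal
        assert expected_angular_resolution(geometry) == pytest.approx(9.26, abs=0.01)


class TestNoisyRecovery:
    def test_bearing_recovery_at_snr_20(self, geometry):
        """Full signal-path recovery (clicks, noise, quantized sampling) stays
        within twice the geometry's single-sample resolution on average."""
        res = expected_angular_resolution(geometry)
        click = click_waveform(ClickModel(), geometry.sample_rate_sps)
        wave = np.zeros(4096)
        wave[1000 : 1000 + click.size] = click
        errors = []
        for k, theta in enumerate(np.arange(0.0, 360.0, 10.0)):
            audio, _ = propagate_to_array(
                wave, theta, 100.0, geometry, noise_spl_db=155.0, seed=100 + k
            )
            event = PulseEvent(1000, (0, 4096), 1.0)
            est = bearing_for_event(audio, event, geometry)
            err = abs(est.azimuth_deg - theta)
            errors.append(min(err, 360.0 - err))
        assert float(np.mean(errors)) <= 2 * res
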