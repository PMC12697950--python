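"""Synthetic deployments: click trains, geometry-consistent multichannel
audio, dive profiles, and correlated sensor streams.

The generator stands in for on-animal recordings so the whole toolkit can be
exercised without hardware.  Its defaults emulate the documented deployment
conditions: sperm whale clicks with a decaying multi-pulse structure
(three pulses, 4 ms inter-pulse interval — configuration values within the
plausible range for the species, carried into truth files rather than
asserted as biology), dominant spectral energy in the 5–10 kHz band with a
broadband edge extending past 40 kHz, dives of 40 ± 13 min reaching
645 ± 205 m, a ±300 Pa pressure sensor, and a −205 dB re FS/μPa, 16-bit,
96 kSPS, 3-channel acquisition chain.

Every operation is reproducible from (spec, seed), and every waveform is
written as exact ground truth alongside the data: onsets, per-pair delays,
dive tables and state transitions all land in a truth file for scoring.
Audio channels are sample-synchronous by construction, mirroring the
hardware's sub-sample synchronization guarantee.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chain as chain_mod
from .aoa import ArrayGeometry
from .audio import MultichannelAudio, write_audio
from .chain import AudioChainSpec
from .mission import MissionConfig, simulate_mission

__all__ = [
    "ClickModel",
    "DiveProfileSpec",
    "click_waveform",
    "synth_click_train",
    "propagate_to_array",
    "synth_dive_profile",
    "synth_sensor_streams",
    "synth_deployment_bundle",
]


@dataclass(frozen=True)
class ClickModel:
    """Parameters of one synthetic click.

    A click is ``n_pulses`` Gaussian-windowed tone bursts at
    ``center_freq_hz`` whose amplitudes decay by ``pulse_decay`` per pulse,
    separated by ``inter_pulse_interval_s`` — the decaying echo train caused
    by reflections inside the whale's head.  Each pulse also carries a short
    broadband transient (``transient_fraction`` of the pulse amplitude) so
    the spectrum keeps measurable energy well above the tonal band, as real
    clicks do.  ``peak_spl_db`` is the peak level at 1 m (dB re 1 μPa).
    """

    n_pulses: int = 3
    inter_pulse_interval_s: float = 4e-3
    pulse_decay: float = 0.6
    center_freq_hz: float = 7500.0
    bandwidth_hz: float = 5000.0
    peak_spl_db: float = 175.0
    transient_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not 0.0 < self.pulse_decay <= 1.0:
            raise ValueError("pulse_decay must lie in (0, 1]")
        if self.bandwidth_hz <= 0 or self.center_freq_hz <= 0:
            raise ValueError("center frequency and bandwidth must be positive")


@dataclass(frozen=True)
class DiveProfileSpec:
    """Dive statistics for profile synthesis.  Duration and depth defaults
    are the deployment averages (40 ± 13 min, 645 ± 205 m); the vertical
    rate and surface interval are generator choices at realistic scales."""

    n_dives: int = 2
    mean_duration_s: float = 40 * 60.0
    sd_duration_s: float = 13 * 60.0
    mean_max_depth_m: float = 645.0
    sd_max_depth_m: float = 205.0
    surface_interval_s: float = 600.0
    vertical_rate_m_s: float = 1.5
    sample_interval_s: float = 1.0
    start_epoch_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_max_depth_m < 0 or self.mean_duration_s <= 0:
            raise ValueError("depths must be >= 0 and durations > 0")


def click_waveform(model: ClickModel, fs: float) -> np.ndarray:
    """One click, peak-normalized to 1, at sample rate ``fs``.

    Raises if the tone would alias (center frequency at or above fs/2).
    """
    if model.center_freq_hz >= fs / 2:
        raise ValueError(
            f"center frequency {model.center_freq_hz} Hz aliases at fs {fs}"
        )
    # Gaussian envelope whose spectral FWHM matches the configured bandwidth
    sigma_t = 2.355 / (2.0 * math.pi * model.bandwidth_hz)
    sigma_transient = 5e-6  # broadband edge: ~30 kHz spectral std
    half = 4.0 * sigma_t
    ipi = model.inter_pulse_interval_s
    total = (model.n_pulses - 1) * ipi + 2 * half
    t = np.arange(int(round(total * fs)) + 1) / fs
    wave = np.zeros_like(t)
    for p in range(model.n_pulses):
        center = half + p * ipi
        amp = model.pulse_decay**p
        tt = t - center
        wave += amp * np.exp(-(tt**2) / (2 * sigma_t**2)) * np.sin(
            2 * math.pi * model.center_freq_hz * tt
        )
        wave += amp * model.transient_fraction * np.exp(-(tt**2) / (2 * sigma_transient**2))
    return wave / np.max(np.abs(wave))


def synth_click_train(
    model: ClickModel,
    rate_clicks_per_min: float,
    duration_s: float,
    fs: float,
    seed: int = 0,
    jitter_fraction: float = 0.2,
    poisson: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Single-channel click train (peak-normalized) plus exact truth onsets.

    Click onsets follow a regular point process at the configured rate with
    ±``jitter_fraction`` uniform jitter (seeded); a Poisson process is
    available as an option.  Onset indices mark the start of each click's
    first pulse.
    """
    if rate_clicks_per_min < 0:
        raise ValueError("rate must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    if rate_clicks_per_min == 0:
        return out, []
    rng = np.random.default_rng(seed)
    click = click_waveform(model, fs)
    spacing = 60.0 / rate_clicks_per_min
    onsets: list[int] = []
    if poisson:
        times, t = [], rng.exponential(spacing)
        while t < duration_s:
            times.append(t)
            t += rng.exponential(spacing)
    else:
        k = np.arange(int(duration_s / spacing))
        times = (0.5 + k) * spacing + rng.uniform(-jitter_fraction, jitter_fraction, k.size) * spacing
    for time in np.asarray(times):
        idx = int(round(time * fs))
        if idx < 0 or idx + click.size > n:
            continue
        out[idx : idx + click.size] += click
        onsets.append(idx)
    return out, onsets


def _fractional_delay(x: np.ndarray, delay_samples: float, n_taps: int = 32) -> np.ndarray:
    """Shift ``x`` later by ``delay_samples`` (possibly fractional/negative)
    using a windowed-sinc interpolator; output has the same length."""
    int_part = int(math.floor(delay_samples))
    frac = delay_samples - int_part
    half = n_taps // 2
    k = np.arange(-half, half + 1)
    taps = np.sinc(k - frac) * np.hanning(k.size + 2)[1:-1]
    y = np.convolve(x, taps, mode="same")
    if int_part > 0:
        y = np.concatenate([np.zeros(int_part), y[:-int_part]])
    elif int_part < 0:
        y = np.concatenate([y[-int_part:], np.zeros(-int_part)])
    return y


def propagate_to_array(
    waveform: np.ndarray,
    bearing_deg: float,
    range_m: float,
    geometry: ArrayGeometry,
    noise_spl_db: float,
    seed: int = 0,
    chain: AudioChainSpec | None = None,
    peak_spl_db: float = 175.0,
    plane_wave: bool = True,
    start_epoch_s: float = 0.0,
) -> tuple[MultichannelAudio, dict]:
    """Delay, attenuate, and digitize a source waveform onto the array.

    Under the plane-wave model (default) ``peak_spl_db`` is the incident
    peak level at the array (dB re 1 μPa); under the spherical model it is
    the source level referenced to 1 m and the amplitude scales by
    1/``range_m``.  Per-channel arrival times follow the chosen model;
    fractional sample delays are applied by windowed-sinc interpolation.  Independent
    Gaussian noise at ``noise_spl_db`` (RMS) is added per channel before
    conversion to integer counts via the chain's sensitivity.  Returns the
    audio and a truth dict with exact pairwise delays and a clipping flag.
    """
    if range_m <= 0:
        raise ValueError("range must be positive")
    chain = chain or AudioChainSpec()
    fs = geometry.sample_rate_sps
    rng = np.random.default_rng(seed)
    u = np.array([math.cos(math.radians(bearing_deg)), math.sin(math.radians(bearing_deg))])
    if plane_wave:
        arrivals = np.array([-(u @ p) / geometry.sound_speed_m_s for p in geometry.positions])
        amplitude = 1.0
    else:
        src = range_m * u
        arrivals = np.array(
            [np.linalg.norm(src - p) / geometry.sound_speed_m_s for p in geometry.positions]
        )
        amplitude = 1.0 / range_m
    rel = arrivals - arrivals[0]
    true_delays = {
        (i, j): float(arrivals[j] - arrivals[i]) for i, j in geometry.pairs()
    }

    fs_counts = chain.full_scale_counts
    counts_per_upa = fs_counts / 10.0 ** (chain.full_scale_spl_db / 20.0)
    peak_upa = 10.0 ** (peak_spl_db / 20.0)
    noise_rms_counts = fs_counts * 10.0 ** ((noise_spl_db - chain.full_scale_spl_db) / 20.0)

    channels = []
    clipped = False
    for ch in range(geometry.n_hydrophones):
        sig = _fractional_delay(waveform, rel[ch] * fs) * peak_upa * amplitude * counts_per_upa
        sig = sig + rng.normal(0.0, noise_rms_counts, sig.size)
        rounded = np.floor(sig + 0.5)
        if rounded.max() > fs_counts or rounded.min() < -fs_counts - 1:
            clipped = True
        channels.append(np.clip(rounded, -fs_counts - 1, fs_counts).astype(np.int32))
    audio = MultichannelAudio(
        np.vstack(channels),
        fs,
        chain.bit_depth,
        chain.sensitivity_db_re_fs_per_upa,
        start_epoch_s,
    )
    truth = {"delays": true_delays, "clipped": clipped, "bearing_deg": float(bearing_deg)}
    return audio, truth


def synth_dive_profile(spec: DiveProfileSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Piecewise descent–bottom–ascent dive series with surface intervals.

    Returns (profile, truth): the profile sampled at ``sample_interval_s``
    with columns ``epoch_s, depth_m``, starting and ending at the surface,
    and a per-dive truth table (start, duration, max depth).
    """
    rng = np.random.default_rng(spec.seed)
    knots_t = [spec.start_epoch_s]
    knots_z = [0.0]
    truth_rows = []
    t = spec.start_epoch_s + spec.surface_interval_s
    for d in range(spec.n_dives):
        duration = max(300.0, rng.normal(spec.mean_duration_s, spec.sd_duration_s)) if spec.sd_duration_s else spec.mean_duration_s
        depth = max(20.0, rng.normal(spec.mean_max_depth_m, spec.sd_max_depth_m)) if spec.sd_max_depth_m else spec.mean_max_depth_m
        # keep at least 10% of the dive as bottom time
        depth = min(depth, 0.45 * duration * spec.vertical_rate_m_s)
        travel = depth / spec.vertical_rate_m_s
        knots_t += [t, t + travel, t + duration - travel, t + duration]
        knots_z += [0.0, depth, depth, 0.0]
        truth_rows.append(
            {"dive": d, "start_epoch_s": t, "duration_s": duration, "max_depth_m": depth}
        )
        t += duration + spec.surface_interval_s
    knots_t.append(t)
    knots_z.append(0.0)
    epochs = np.arange(spec.start_epoch_s, t + spec.sample_interval_s / 2, spec.sample_interval_s)
    depths = np.interp(epochs, knots_t, knots_z)
    profile = pd.DataFrame({"epoch_s": epochs, "depth_m": depths})
    return profile, pd.DataFrame(truth_rows)


def synth_sensor_streams(
    dive_profile: pd.DataFrame,
    seed: int = 0,
    latitude_deg: float = 15.4,
    pressure_noise_pa: float = 300.0,
    surface_temp_c: float = 28.0,
    deep_temp_c: float = 4.7,
    thermocline_depth_m: float = 800.0,
    light_extinction_depth_m: float = 50.0,
    imu_rate_hz: float = 50.0,
    battery_rate_hz: float = 0.1,
    mission_config: MissionConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """CSV-ready sensor streams correlated with a dive profile.

    Pressure is the exact seawater inverse of the depth conversion at the
    configured latitude plus Gaussian sensor noise (±300 Pa class accuracy);
    light decays exponentially with depth; temperature follows a two-layer
    linear profile clamped to the deployment-experienced bounds; battery
    voltage comes from the mission simulator's energy proxy; IMU channels
    are white noise plus a per-axis bias around gravity.  All streams share
    the profile's epoch frame.
    """
    rng = np.random.default_rng(seed)
    epochs = np.asarray(dive_profile["epoch_s"], dtype=float)
    depths = np.asarray(dive_profile["depth_m"], dtype=float)

    pressure_bar = chain_mod.pressure_from_depth(depths, latitude_deg)
    pressure_bar = pressure_bar + rng.normal(0.0, pressure_noise_pa / 1e5, depths.size)
    pressure = pd.DataFrame({"epoch_s": epochs, "pressure_bar": pressure_bar})

    frac = np.minimum(depths, thermocline_depth_m) / thermocline_depth_m
    temp = surface_temp_c - (surface_temp_c - deep_temp_c) * frac
    temp = np.clip(temp + rng.normal(0.0, 0.05, depths.size), 4.7, 42.4)
    temperature = pd.DataFrame({"epoch_s": epochs, "temperature_c": temp})

    light_lux = 1000.0 * np.exp(-3.0 * depths / light_extinction_depth_m)
    light_lux = np.maximum(0.0, light_lux + rng.normal(0.0, 0.5, depths.size))
    light = pd.DataFrame({"epoch_s": epochs, "light_lux": light_lux})

    dt_imu = 1.0 / imu_rate_hz
    t_imu = np.arange(epochs[0], epochs[-1], dt_imu)
    bias = rng.normal(0.0, 0.1, 6)
    imu = pd.DataFrame(
        {
            "epoch_s": t_imu,
            "accel_x_m_s2": bias[0] + rng.normal(0.0, 0.5, t_imu.size),
            "accel_y_m_s2": bias[1] + rng.normal(0.0, 0.5, t_imu.size),
            "accel_z_m_s2": 9.81 + bias[2] + rng.normal(0.0, 0.5, t_imu.size),
            "gyro_x_deg_s": bias[3] + rng.normal(0.0, 2.0, t_imu.size),
            "gyro_y_deg_s": bias[4] + rng.normal(0.0, 2.0, t_imu.size),
            "gyro_z_deg_s": bias[5] + rng.normal(0.0, 2.0, t_imu.size),
        }
    )

    cfg = mission_config or MissionConfig()
    result = simulate_mission(cfg, dive_profile)
    t_batt = np.arange(epochs[0], epochs[-1] + 1e-9, 1.0 / battery_rate_hz)
    v = np.interp(t_batt, result.trajectory["epoch_s"], result.trajectory["voltage_v"])
    battery = pd.DataFrame({"epoch_s": t_batt, "battery_v": v})

    return {
        "pressure": pressure,
        "temperature": temperature,
        "light": light,
        "imu": imu,
        "battery": battery,
    }


def synth_deployment_bundle(
    outdir: str | Path,
    seed: int = 0,
    chain: AudioChainSpec | None = None,
    geometry: ArrayGeometry | None = None,
    mission_config: MissionConfig | None = None,
    click_model: ClickModel | None = None,
    dive_spec: DiveProfileSpec | None = None,
    bearing_deg: float = 135.0,
    source_range_m: float = 100.0,
    click_rate_per_min: float = 120.0,
    noise_spl_db: float = 155.0,
    audio_window_s: float = 60.0,
    segment_s: float = 300.0,
    audio_format: str = "wav",
    latitude_deg: float = 15.4,
    device_id: str = "synthtag-000",
) -> dict:
    """Generate and write a complete synthetic deployment bundle.

    The bundle directory holds five-minute-convention audio segments
    (one segment at the default 60 s window), sensor stream CSVs, the
    mission event log, a manifest, and a truth file recording every click
    onset, pairwise delay, dive, and state transition.  Identical arguments
    and seed reproduce the bundle byte for byte.
    """
    from .bundle import write_bundle  # local import to avoid a cycle

    chain = chain or AudioChainSpec()
    geometry = geometry or _default_geometry()
    mission_config = mission_config or MissionConfig()
    click_model = click_model or ClickModel()
    dive_spec = dive_spec or DiveProfileSpec(seed=seed)
    fs = geometry.sample_rate_sps
    if abs(fs - chain.odr_sps) > 1e-6:
        raise ValueError(
            f"geometry sample rate {fs} differs from the chain ODR {chain.odr_sps}"
        )

    seeds = np.random.SeedSequence(seed).spawn(4)
    seed_train, seed_prop, seed_sensors, _ = (int(s.generate_state(1)[0] % 2**31) for s in seeds)

    profile, dive_truth = synth_dive_profile(dive_spec)
    start_epoch = float(profile["epoch_s"].iloc[0])

    train, onsets = synth_click_train(
        click_model, click_rate_per_min, audio_window_s, fs, seed=seed_train
    )
    audio, audio_truth = propagate_to_array(
        train,
        bearing_deg,
        source_range_m,
        geometry,
        noise_spl_db,
        seed=seed_prop,
        chain=chain,
        peak_spl_db=click_model.peak_spl_db,
        start_epoch_s=start_epoch,
    )
    streams = synth_sensor_streams(
        profile, seed=seed_sensors, latitude_deg=latitude_deg, mission_config=mission_config
    )
    mission = simulate_mission(mission_config, profile)

    truth = {
        "bearing_deg": float(bearing_deg),
        "click_onsets_samples": [int(o) for o in onsets],
        "click_onsets_epoch_s": [start_epoch + o / fs for o in onsets],
        "pair_delays_s": {f"{i}-{j}": d for (i, j), d in audio_truth["delays"].items()},
        "clipped": audio_truth["clipped"],
        "dives": dive_truth.to_dict(orient="records"),
        "transitions": mission.event_log.to_dict(orient="records"),
        "click_model": asdict(click_model),
        "dive_spec": asdict(dive_spec),
        "seed": int(seed),
    }
    return write_bundle(
        outdir,
        device_id=device_id,
        audio=audio,
        streams=streams,
        event_log=mission.event_log,
        truth=truth,
        chain=chain,
        geometry=geometry,
        segment_s=segment_s,
        audio_format=audio_format,
    )


def _default_geometry() -> ArrayGeometry:
    from .aoa import default_l_array

    return default_l_array()
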