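"""Closed-form calibration math for the bio-logger's acoustic acquisition chain.

The acquisition chain maps underwater acoustic pressure (dB re 1 μPa) to
integer ADC counts through an end-to-end sensitivity expressed in
dB re FS/μPa: a sensitivity of −205 dB means that a 205 dB re 1 μPa peak
drives the converter exactly to positive full scale.  The functions here are
the closed-form design relations of that chain — full-scale count mapping,
the analog RC high-pass, the oscillator/divider clock tree of the sigma-delta
ADC, the wideband digital filter cutoff — plus the environmental conversions
needed to interpret the sensor streams: pure-water sound speed (Marczak 1997
fifth-order polynomial) and latitude-dependent seawater pressure-to-depth
(Leroy & Parthiot 1998).

All raw operations return unrounded values; ``round_half_up`` is provided for
reporting at the precision conventionally printed (integer Hz, 0.1 kHz,
0.1 m/s, nearest metre, 0.1 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AudioChainSpec",
    "AcousticEnvironment",
    "ClockChain",
    "DetectionRange",
    "counts_from_spl",
    "spl_from_counts",
    "dynamic_range_db",
    "dynamic_range_db_rounded",
    "rc_highpass_cutoff",
    "clock_chain",
    "wideband_cutoff",
    "nyquist_min_rate",
    "sound_speed_pure_water",
    "depth_from_pressure",
    "pressure_from_depth",
    "far_field_min_freq",
    "detection_range",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimal places.

    Printed-value comparisons use this convention rather than banker's
    rounding so that e.g. 62.5 Hz would report as 63 Hz.
    """
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class AudioChainSpec:
    """Electrical and digital parameters of the audio acquisition chain.

    Defaults reproduce the deployed configuration: −205 dB re FS/μPa
    sensitivity, 16-bit samples, a 98.304 MHz oscillator divided 4/8/32 down
    to a 96 kSPS output data rate, wideband digital filtering at 0.4×ODR,
    and three active hydrophone channels.  Analog gain and the antialias
    cutoff are carried as metadata only; no analog waveform simulation
    depends on them.
    """

    sensitivity_db_re_fs_per_upa: float = -205.0
    bit_depth: int = 16
    input_resistance: float = 374e3  # ohm
    hydrophone_capacitance: float = 6.8e-9  # farad
    analog_gain_db: float = 12.0
    antialias_cutoff_hz: float = 100e3
    oscillator_hz: float = 98_304_000.0
    master_clock_divider: int = 4
    modulator_divider: int = 8
    decimation_factor: int = 32
    digital_filter_fraction: float = 0.4
    n_channels: int = 3

    def __post_init__(self) -> None:
        if self.bit_depth not in (16, 24):
            raise ValueError(f"bit_depth must be 16 or 24, got {self.bit_depth}")
        if self.sensitivity_db_re_fs_per_upa >= 0:
            raise ValueError("sensitivity must be negative (dB re FS/μPa)")
        for name in ("master_clock_divider", "modulator_divider", "decimation_factor"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.digital_filter_fraction < 0.5:
            raise ValueError("digital_filter_fraction must lie in (0, 0.5)")
        if not 1 <= self.n_channels <= 4:
            raise ValueError("n_channels must be between 1 and 4")

    @property
    def full_scale_counts(self) -> int:
        """Largest positive code of the signed converter output."""
        return 2 ** (self.bit_depth - 1) - 1

    @property
    def full_scale_spl_db(self) -> float:
        """SPL (dB re 1 μPa peak) that drives the chain to full scale."""
        return -self.sensitivity_db_re_fs_per_upa

    @property
    def odr_sps(self) -> float:
        return clock_chain(self).odr_sps


@dataclass(frozen=True)
class AcousticEnvironment:
    """Water conditions used for sound-speed and depth conversions.

    Defaults match the deployment region (eastern Caribbean, ~15.4° N) and
    the tank characterization temperature of 23 °C.
    """

    temperature_c: float = 23.0
    latitude_deg: float = 15.4
    water_type: str = "sea"
    sound_speed_m_s: float | None = None
    absorption_db_per_km: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError("latitude must lie in [-90, 90] degrees")
        if self.water_type not in ("fresh", "sea"):
            raise ValueError("water_type must be 'fresh' or 'sea'")
        if self.sound_speed_m_s is not None and not 1000.0 < self.sound_speed_m_s < 2000.0:
            raise ValueError("sound_speed override must lie in (1000, 2000) m/s")

    def sound_speed(self) -> float:
        """Sound speed: explicit override, else the pure-water polynomial.

        The pure-water value is an approximation for seawater (salinity adds
        of order 1%); pass an override when that matters.
        """
        if self.sound_speed_m_s is not None:
            return self.sound_speed_m_s
        return sound_speed_pure_water(self.temperature_c)


def counts_from_spl(spec: AudioChainSpec, spl_peak: float) -> int:
    """ADC output counts for a peak SPL, clipped to the converter range.

    A signal at the chain's full-scale SPL (the negated sensitivity) maps to
    ``2**(bit_depth-1) - 1`` counts; levels above that clip by definition.
    ``spl_peak = -inf`` (zero pressure) maps to 0.
    """
    fs_counts = spec.full_scale_counts
    if spl_peak == -math.inf:
        return 0
    raw = fs_counts * 10.0 ** ((spl_peak - spec.full_scale_spl_db) / 20.0)
    return int(min(max(round_half_up(raw), 0), fs_counts))


def spl_from_counts(spec: AudioChainSpec, counts: float) -> float:
    """Peak SPL (dB re 1 μPa) corresponding to an ADC count value."""
    if counts <= 0:
        raise ValueError(f"SPL undefined for counts <= 0 (got {counts})")
    if counts > spec.full_scale_counts:
        raise ValueError(f"counts {counts} exceed full scale {spec.full_scale_counts}")
    return spec.full_scale_spl_db + 20.0 * math.log10(counts / spec.full_scale_counts)


def dynamic_range_db(bit_depth: int) -> float:
    """Ideal dynamic range of a ``bit_depth``-bit converter, 20·log10(2^B)."""
    if bit_depth < 1:
        raise ValueError("bit_depth must be >= 1")
    return 20.0 * bit_depth * math.log10(2.0)


def dynamic_range_db_rounded(bit_depth: int) -> int:
    """`dynamic_range_db` rounded to the nearest integer dB for reporting."""
    return int(round_half_up(dynamic_range_db(bit_depth)))


def rc_highpass_cutoff(input_resistance: float, hydrophone_capacitance: float) -> float:
    """First-order high-pass corner 1/(2πRC) formed by the hydrophone
    capacitance against the front-end input resistance."""
    if input_resistance <= 0 or hydrophone_capacitance <= 0:
        raise ValueError("R and C must both be positive")
    return 1.0 / (2.0 * math.pi * input_resistance * hydrophone_capacitance)


class ClockChain(NamedTuple):
    master_clock_hz: float
    modulator_clock_hz: float
    odr_sps: float


def clock_chain(spec: AudioChainSpec) -> ClockChain:
    """Derive the ADC clock tree from the oscillator and its dividers.

    oscillator → (÷master_clock_divider) master clock → (÷modulator_divider)
    sigma-delta modulator clock → (÷decimation_factor) output data rate.
    Every division must be exact: a sigma-delta converter cannot run on a
    fractional clock, so a non-integer result is a configuration error.
    """
    osc = Fraction(spec.oscillator_hz).limit_denominator(10**9)
    master = osc / spec.master_clock_divider
    modulator = master / spec.modulator_divider
    odr = modulator / spec.decimation_factor
    for name, value in (("master clock", master), ("modulator clock", modulator), ("ODR", odr)):
        if value.denominator != 1:
            raise ValueError(f"{name} = {float(value)} Hz is not an exact division of the oscillator")
    return ClockChain(float(master), float(modulator), float(odr))


def wideband_cutoff(odr_sps: float, fraction: float = 0.4) -> float:
    """Nominal cutoff of the ADC's wideband digital filter, fraction × ODR."""
    if odr_sps <= 0:
        raise ValueError("ODR must be positive")
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    return fraction * odr_sps


def nyquist_min_rate(f_max_hz: float) -> float:
    """Minimum sampling rate capturing content up to ``f_max_hz``: 2·f_max."""
    if f_max_hz <= 0:
        raise ValueError("f_max must be positive")
    return 2.0 * f_max_hz


# Marczak (1997) pure-water sound-speed polynomial, valid 0–95 °C.
_MARCZAK = (1402.385, 5.038813, -5.799136e-2, 3.287156e-4, -1.398845e-6, 2.787860e-9)


def sound_speed_pure_water(temperature_c: float) -> float:
    """Speed of sound in pure water (m/s) from the fifth-order polynomial in
    temperature; raises outside the 0–95 °C validity range."""
    if not 0.0 <= temperature_c <= 95.0:
        raise ValueError(f"temperature {temperature_c} °C outside polynomial validity [0, 95]")
    acc = 0.0
    for coef in reversed(_MARCZAK):
        acc = acc * temperature_c + coef
    return acc


def _gravity(latitude_deg: float) -> float:
    s2 = math.sin(math.radians(latitude_deg)) ** 2
    return 9.780318 * (1.0 + 5.2788e-3 * s2 + 2.36e-5 * s2 * s2)


def depth_from_pressure(gauge_pressure_bar, latitude_deg: float = 15.4):
    """Seawater depth (m) from gauge pressure (bar) at a given latitude.

    Standard-ocean conversion with latitude-dependent gravity:
    with P in MPa, Z = (9.72659e2·P − 2.2512e−1·P² + 2.279e−4·P³
    − 1.82e−7·P⁴) / (g(φ) + 1.092e−4·P).  Accepts scalars or arrays.
    """
    p_bar = np.asarray(gauge_pressure_bar, dtype=float)
    if np.any(p_bar < 0):
        raise ValueError("gauge pressure must be non-negative")
    p = p_bar * 0.1  # bar -> MPa
    num = p * (9.72659e2 + p * (-2.2512e-1 + p * (2.279e-4 + p * -1.82e-7)))
    z = num / (_gravity(latitude_deg) + 1.092e-4 * p)
    return float(z) if np.isscalar(gauge_pressure_bar) else z


def pressure_from_depth(depth_m, latitude_deg: float = 15.4):
    """Inverse of `depth_from_pressure`: gauge pressure (bar) at depth (m).

    Solved by bracketed root finding on the monotone forward conversion;
    scalars and arrays accepted (arrays use a dense interpolation table,
    accurate to well under 0.01 m over the 0–1200 m range).
    """
    scalar = np.isscalar(depth_m)
    z = np.atleast_1d(np.asarray(depth_m, dtype=float))
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    zmax = float(z.max(initial=0.0))
    # forward model is within a few percent of 0.1007 bar/m near the surface
    p_hi = max(1.0, 0.12 * zmax + 1.0)
    if z.size <= 4:
        out = np.array(
            [
                0.0
                if zi == 0.0
                else brentq(lambda p: depth_from_pressure(p, latitude_deg) - zi, 0.0, p_hi, xtol=1e-10)
                for zi in z
            ]
        )
    else:
        grid_p = np.linspace(0.0, p_hi, 4096)
        grid_z = depth_from_pressure(grid_p, latitude_deg)
        out = np.interp(z, grid_z, grid_p)
    return float(out[0]) if scalar else out


def far_field_min_freq(separation_m: float, sound_speed_m_s: float, n_wavelengths: int = 5) -> float:
    """Lowest frequency for which ``separation_m`` spans ``n_wavelengths``
    wavelengths — the far-field validity bound of a calibration setup."""
    if separation_m <= 0:
        raise ValueError("separation must be positive")
    if n_wavelengths < 1:
        raise ValueError("n_wavelengths must be >= 1")
    return n_wavelengths * sound_speed_m_s / separation_m


class DetectionRange(NamedTuple):
    range_m: float
    capped: bool


def detection_range(
    source_spl_db: float,
    floor_spl_db: float,
    absorption_db_per_km: float = 1.0,
    r_max_m: float = 100e3,
) -> DetectionRange:
    """Range at which a source just reaches the capture floor.

    Solves source − 20·log10(r) − α·r/1000 = floor for r > 0 (spherical
    spreading plus linear absorption).  With α = 0 the closed form
    10^((source−floor)/20) is returned directly.  If no solution exists
    below ``r_max_m`` the result is capped and flagged.
    """
    if source_spl_db <= floor_spl_db:
        raise ValueError("source level must exceed the floor")
    if absorption_db_per_km < 0:
        raise ValueError("absorption must be non-negative")
    if absorption_db_per_km == 0.0:
        r = 10.0 ** ((source_spl_db - floor_spl_db) / 20.0)
        return DetectionRange(min(r, r_max_m), r > r_max_m)

    def excess(r: float) -> float:
        return source_spl_db - 20.0 * math.log10(r) - absorption_db_per_km * r / 1000.0 - floor_spl_db

    if excess(r_max_m) > 0:
        return DetectionRange(r_max_m, True)
    r = brentq(excess, 1e-6, r_max_m, xtol=1e-6)
    return DetectionRange(float(r), False)
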