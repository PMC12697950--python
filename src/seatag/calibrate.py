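"""Derived-quantity report for a loaded configuration.

Collects every closed-form value of the acquisition chain and mission
budget — full-scale counts, filter corners, the clock tree, dynamic range,
Nyquist bound, battery runtime, sound speed, far-field bound, and the
reference depth conversion — rounded at the precision conventionally
printed for each (integer counts/dB/Hz, 0.1 kHz, 0.001 MHz, 0.1 m/s,
nearest metre, 0.1 h).
"""

from __future__ import annotations

from . import chain as c
from .config import Config
from .mission import Mode

__all__ = ["calibration_report"]


def calibration_report(cfg: Config) -> dict[str, float | int]:
    spec = cfg.chain
    env = cfg.environment
    refs = cfg.calibration
    clocks = c.clock_chain(spec)
    sound_speed = env.sound_speed()
    runtime_h = cfg.mission.battery_energy_wh / cfg.mission.draw_w(Mode.SURFACE_RECORD, True)
    detect = c.detection_range(
        refs.detection_source_spl_db,
        refs.detection_floor_spl_db,
        refs.detection_absorption_db_per_km,
    )
    return {
        "full_scale_counts": c.counts_from_spl(spec, spec.full_scale_spl_db),
        "rc_highpass_cutoff_hz": int(
            c.round_half_up(c.rc_highpass_cutoff(spec.input_resistance, spec.hydrophone_capacitance))
        ),
        "wideband_cutoff_khz": c.round_half_up(
            c.wideband_cutoff(clocks.odr_sps, spec.digital_filter_fraction) / 1e3, 1
        ),
        "master_clock_mhz": c.round_half_up(clocks.master_clock_hz / 1e6, 3),
        "modulator_clock_mhz": c.round_half_up(clocks.modulator_clock_hz / 1e6, 3),
        "odr_ksps": int(c.round_half_up(clocks.odr_sps / 1e3)),
        "dynamic_range_db": c.dynamic_range_db_rounded(spec.bit_depth),
        "nyquist_min_khz": int(
            c.round_half_up(c.nyquist_min_rate(refs.max_signal_freq_hz) / 1e3)
        ),
        "battery_runtime_h": c.round_half_up(runtime_h, 1),
        "sound_speed_m_s": c.round_half_up(sound_speed, 1),
        "far_field_min_khz": c.round_half_up(
            c.far_field_min_freq(
                refs.far_field_separation_m, sound_speed, refs.far_field_n_wavelengths
            )
            / 1e3,
            1,
        ),
        "depth_from_reference_pressure_m": int(
            c.round_half_up(
                c.depth_from_pressure(refs.reference_pressure_bar, env.latitude_deg)
            )
        ),
        "detection_range_m": c.round_half_up(detect.range_m, 1),
    }
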