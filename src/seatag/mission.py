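"""Discrete-time simulator of the logger's adaptive deployment controller.

The deployment controller is a finite-state machine driven by depth and
battery voltage.  Shallower than 3 m the logger records with the recovery
system enabled and polls GPS once a minute; deeper than 5 m it records with
all wireless disabled; between the two thresholds the mode is retained
(hysteresis).  A release countdown starts at the first detected dive and is
persisted, so it survives power cycles; its expiry — or the battery falling
below 6.4 V, or an optional depth-safety bound — fires the burnwire exactly
once.  Below 6.2 V all data acquisition stops to devote the remaining energy
to recovery; below 6.0 V the logger powers off.

Energy is integrated from a per-subsystem power budget (watts) against the
pack capacity (two cells in series, 5 Ah at 7.4 V nominal ≈ 37 Wh).  The
controller's thresholds are in volts while the budget is in watts; the
bridging model is a voltage proxy linear in remaining energy from the full
voltage (8.4 V) down to the power-off voltage (6.0 V).  It is deliberately
isolated in `voltage_from_energy` so a measured discharge curve can replace
it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "MissionConfig",
    "LoggerState",
    "MissionResult",
    "step_state",
    "simulate_mission",
    "simulate_recovery_comms",
    "voltage_from_energy",
]


class Mode(Enum):
    INIT = "INIT"
    SURFACE_RECORD = "SURFACE_RECORD"
    DIVE_RECORD = "DIVE_RECORD"
    BURNWIRE = "BURNWIRE"
    CRITICAL_SHUTDOWN = "CRITICAL_SHUTDOWN"
    OFF = "OFF"


#: modes in which audio and sensor data accrue
RECORDING_MODES = {Mode.SURFACE_RECORD, Mode.DIVE_RECORD, Mode.BURNWIRE}


def _default_power_budget() -> dict[str, float]:
    # Placeholder per-subsystem wattages summing to 2.2 W at surface
    # recording; the real breakdown is device-specific and user-configurable.
    return {
        "compute": 1.0,
        "audio": 0.55,
        "sensors": 0.25,
        "gps": 0.15,
        "recovery_tx": 0.25,
    }


@dataclass(frozen=True)
class MissionConfig:
    """Thresholds, battery model, power budget, and data-rate parameters."""

    surface_depth_m: float = 3.0
    dive_depth_m: float = 5.0
    burnwire_voltage_v: float = 6.4
    critical_voltage_v: float = 6.2
    poweroff_voltage_v: float = 6.0
    mission_duration_s: float = 8 * 3600.0
    gps_poll_interval_s: float = 60.0
    depth_safety_release_m: float | None = 1000.0
    battery_capacity_mah: float = 5000.0
    cells_in_series: int = 2
    nominal_voltage_v: float = 7.4
    full_voltage_v: float = 8.4
    power_budget: dict[str, float] = field(default_factory=_default_power_budget)
    audio_channels: int = 3
    bytes_per_sample: int = 2
    sample_rate: float = 96_000.0
    compression_ratio: float = 0.15
    sensor_bytes_per_hour: float = 41e6

    def __post_init__(self) -> None:
        if not self.poweroff_voltage_v < self.critical_voltage_v < self.burnwire_voltage_v < self.nominal_voltage_v < self.full_voltage_v:
            raise ValueError("voltage thresholds must satisfy poweroff < critical < burnwire < nominal < full")
        if not self.surface_depth_m < self.dive_depth_m:
            raise ValueError("surface_depth must be below dive_depth")
        if any(w < 0 for w in self.power_budget.values()):
            raise ValueError("power budget entries must be non-negative")

    @property
    def battery_energy_wh(self) -> float:
        """Pack energy at nominal voltage (cells in series share one capacity)."""
        return self.battery_capacity_mah / 1000.0 * self.nominal_voltage_v

    @property
    def audio_bytes_per_s(self) -> float:
        """Stored audio rate: raw PCM scaled by the lossless compression ratio."""
        return self.audio_channels * self.bytes_per_sample * self.sample_rate * self.compression_ratio

    def draw_w(self, mode: Mode, wireless_enabled: bool) -> float:
        """Total draw (W) of the subsystems active in a mode."""
        b = self.power_budget
        if mode is Mode.OFF:
            return 0.0
        w = b.get("compute", 0.0)
        if mode in RECORDING_MODES:
            w += b.get("audio", 0.0) + b.get("sensors", 0.0)
        if wireless_enabled and mode is not Mode.DIVE_RECORD:
            w += b.get("gps", 0.0) + b.get("recovery_tx", 0.0)
        return w


@dataclass(frozen=True)
class LoggerState:
    """Controller state.  ``countdown_started_epoch_s``, ``burnwire_fired``
    and ``wifi_disabled`` model values kept on persistent storage: they
    survive simulated restarts."""

    mode: Mode = Mode.INIT
    wireless_enabled: bool = True
    wifi_enabled: bool = True
    countdown_started_epoch_s: float | None = None
    burnwire_fired: bool = False
    energy_remaining_wh: float = 37.0
    data_written_bytes: float = 0.0
    last_gps_poll_epoch_s: float | None = None


def voltage_from_energy(energy_wh: float, config: MissionConfig) -> float:
    """Linear voltage proxy: full voltage at full energy, power-off voltage
    at zero; an exhausted pack reads 0.1 V below cutoff (cell collapse).
    Replace with a measured discharge curve when available."""
    if energy_wh <= 0.0:
        return config.poweroff_voltage_v - 0.1
    frac = min(1.0, energy_wh / config.battery_energy_wh)
    return config.poweroff_voltage_v + (config.full_voltage_v - config.poweroff_voltage_v) * frac


def step_state(
    state: LoggerState,
    depth_m: float,
    voltage_v: float,
    epoch_s: float,
    config: MissionConfig,
) -> tuple[LoggerState, list[str]]:
    """Advance the controller one observation; returns the new state and the
    actions emitted (transitions, burnwire firing, GPS polls, faults).

    Threshold comparisons are strict, exactly as specified: depth < 3 m is
    surface, depth > 5 m is dive, and the 3–5 m band retains the mode.
    """
    actions: list[str] = []
    if math.isnan(depth_m) or math.isnan(voltage_v):
        return state, ["sensor_fault"]
    if state.mode is Mode.OFF:
        return state, actions

    new = state

    # battery protection dominates everything else
    if voltage_v < config.poweroff_voltage_v:
        if new.mode is not Mode.OFF:
            actions.append("poweroff")
        return replace(new, mode=Mode.OFF, wireless_enabled=False, wifi_enabled=False), actions
    if voltage_v < config.critical_voltage_v:
        if new.mode is not Mode.CRITICAL_SHUTDOWN:
            actions.append("critical_shutdown")
        surfaced = depth_m < config.surface_depth_m
        return replace(new, mode=Mode.CRITICAL_SHUTDOWN, wireless_enabled=surfaced), actions

    # burnwire: countdown expiry, low battery, or depth-safety release
    if not new.burnwire_fired:
        cause = None
        if (
            new.countdown_started_epoch_s is not None
            and epoch_s - new.countdown_started_epoch_s >= config.mission_duration_s
        ):
            cause = "countdown_expired"
        elif voltage_v < config.burnwire_voltage_v:
            cause = "low_battery"
        elif (
            config.depth_safety_release_m is not None
            and depth_m >= config.depth_safety_release_m
        ):
            cause = "depth_safety"
        if cause is not None:
            actions.append(f"burnwire_fired:{cause}")
            # countdown is cleared from persistent storage once fired
            new = replace(
                new, mode=Mode.BURNWIRE, burnwire_fired=True, countdown_started_epoch_s=None
            )

    # depth-driven behavior
    if depth_m > config.dive_depth_m:
        if new.mode in (Mode.INIT, Mode.SURFACE_RECORD):
            actions.append("dive_detected")
            new = replace(new, mode=Mode.DIVE_RECORD)
            if new.countdown_started_epoch_s is None and not new.burnwire_fired:
                actions.append("countdown_started")
                new = replace(new, countdown_started_epoch_s=epoch_s)
        # Wi-Fi stays off for the rest of the mission after the first dive
        new = replace(new, wireless_enabled=False, wifi_enabled=False)
    elif depth_m < config.surface_depth_m:
        if new.mode in (Mode.INIT, Mode.DIVE_RECORD):
            actions.append("surfaced")
            new = replace(new, mode=Mode.SURFACE_RECORD)
        new = replace(new, wireless_enabled=True)
    # else: hysteresis band, mode retained

    if new.wireless_enabled and new.mode in (Mode.SURFACE_RECORD, Mode.BURNWIRE, Mode.INIT):
        last = new.last_gps_poll_epoch_s
        if last is None or epoch_s - last >= config.gps_poll_interval_s:
            actions.append("gps_poll")
            new = replace(new, last_gps_poll_epoch_s=epoch_s)

    return new, actions


@dataclass
class MissionResult:
    event_log: pd.DataFrame
    trajectory: pd.DataFrame
    final_state: LoggerState


def simulate_mission(
    config: MissionConfig,
    dive_profile: pd.DataFrame,
    seed: int = 0,
    restart_epochs: Sequence[float] = (),
    initial_state: LoggerState | None = None,
) -> MissionResult:
    """Run the controller over a depth time series sampled at a fixed step.

    ``dive_profile`` needs columns ``epoch_s`` (fixed-step, increasing) and
    ``depth_m``.  ``restart_epochs`` injects simulated power cycles: volatile
    state resets while the persisted countdown and burnwire flag survive.
    The run is fully deterministic for a given (config, profile, seed).
    """
    epochs = np.asarray(dive_profile["epoch_s"], dtype=float)
    depths = np.asarray(dive_profile["depth_m"], dtype=float)
    if epochs.size == 0:
        raise ValueError("empty dive profile")
    steps = np.diff(epochs)
    if epochs.size > 1 and (steps.min() <= 0 or np.ptp(steps) > 1e-9):
        raise ValueError("dive profile must be sampled at a fixed positive step")
    dt = float(steps[0]) if epochs.size > 1 else 1.0

    state = initial_state or LoggerState(energy_remaining_wh=config.battery_energy_wh)
    restarts = sorted(set(restart_epochs))
    log: list[dict] = [
        {"epoch_s": float(epochs[0]), "transition": "INIT", "cause": "startup",
         "depth_m": float(depths[0]), "voltage_v": voltage_from_energy(state.energy_remaining_wh, config)}
    ]
    traj = {k: [] for k in ("epoch_s", "depth_m", "voltage_v", "energy_wh", "data_bytes", "mode")}

    for epoch, depth in zip(epochs, depths):
        while restarts and epoch >= restarts[0]:
            restarts.pop(0)
            # persisted values (countdown, burnwire flag, Wi-Fi lockout)
            # survive; volatile state reinitializes
            state = replace(
                state, mode=Mode.INIT, wireless_enabled=True, last_gps_poll_epoch_s=None
            )
            log.append({"epoch_s": float(epoch), "transition": "INIT", "cause": "restart",
                        "depth_m": float(depth), "voltage_v": voltage_from_energy(state.energy_remaining_wh, config)})

        voltage = voltage_from_energy(state.energy_remaining_wh, config)
        prev_mode = state.mode
        state, actions = step_state(state, float(depth), voltage, float(epoch), config)
        for action in actions:
            if action == "gps_poll":
                continue  # polls are routine; keep the log to transitions/faults
            log.append({"epoch_s": float(epoch), "transition": state.mode.value,
                        "cause": action, "depth_m": float(depth), "voltage_v": voltage})
        if state.mode is not prev_mode and not actions:
            log.append({"epoch_s": float(epoch), "transition": state.mode.value,
                        "cause": "mode_change", "depth_m": float(depth), "voltage_v": voltage})

        draw = config.draw_w(state.mode, state.wireless_enabled)
        energy = max(0.0, state.energy_remaining_wh - draw * dt / 3600.0)
        data = state.data_written_bytes
        if state.mode in RECORDING_MODES:
            data += (config.audio_bytes_per_s + config.sensor_bytes_per_hour / 3600.0) * dt
        state = replace(state, energy_remaining_wh=energy, data_written_bytes=data)

        traj["epoch_s"].append(float(epoch))
        traj["depth_m"].append(float(depth))
        traj["voltage_v"].append(voltage)
        traj["energy_wh"].append(state.energy_remaining_wh)
        traj["data_bytes"].append(state.data_written_bytes)
        traj["mode"].append(state.mode.value)

    return MissionResult(pd.DataFrame(log), pd.DataFrame(traj), state)


def simulate_recovery_comms(
    n_attempts: int,
    success_prob: float,
    seed: int = 0,
    gps_lock_prob: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Stochastic model of the recovery message channel.

    Each attempt first needs a GPS lock (Bernoulli ``gps_lock_prob``); a
    locked attempt broadcasts a message carrying an incrementing
    transmission index, which is received with probability ``success_prob``
    (independent Bernoulli, as observed for relayed recovery messages).
    Returns per-attempt outcomes and the received fraction among
    transmissions.
    """
    if not 0.0 <= success_prob <= 1.0:
        raise ValueError("success_prob must lie in [0, 1]")
    if not 0.0 <= gps_lock_prob <= 1.0:
        raise ValueError("gps_lock_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    locks = rng.random(n_attempts) < gps_lock_prob
    received = np.where(locks, rng.random(n_attempts) < success_prob, False)
    tx_index = np.where(locks, np.cumsum(locks) - 1, -1)
    df = pd.DataFrame(
        {"attempt": np.arange(n_attempts), "gps_lock": locks, "tx_index": tx_index,
         "received": received}
    )
    n_tx = int(locks.sum())
    fraction = float(received.sum() / n_tx) if n_tx else 0.0
    return df, fraction
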