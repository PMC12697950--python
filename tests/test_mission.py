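"""Deployment state machine, energy/data budgets, and recovery channel."""

import math

import numpy as np
import pandas as pd
import pytest

from seatag.mission import (
    LoggerState,
    MissionConfig,
    Mode,
    simulate_mission,
    simulate_recovery_comms,
    step_state,
    voltage_from_energy,
)
from seatag.synth import DiveProfileSpec, synth_dive_profile


def _flat_profile(hours: float, depth: float = 0.0, dt: float = 1.0) -> pd.DataFrame:
    t = np.arange(0.0, hours * 3600.0, dt)
    return pd.DataFrame({"epoch_s": t, "depth_m": np.full_like(t, depth)})


def _small_dive_spec(seed: int) -> DiveProfileSpec:
    """Short random dive profiles keep the 100-profile sweeps fast."""
    return DiveProfileSpec(
        n_dives=2, mean_duration_s=600.0, sd_duration_s=150.0,
        mean_max_depth_m=150.0, sd_max_depth_m=60.0, surface_interval_s=120.0,
        seed=seed,
    )


class TestStepState:
    CFG = MissionConfig()

    def _surface_state(self):
        return LoggerState(mode=Mode.SURFACE_RECORD, energy_remaining_wh=37.0)

    def test_dive_disables_wireless(self):
        new, actions = step_state(self._surface_state(), 10.0, 8.0, 100.0, self.CFG)
        assert new.mode is Mode.DIVE_RECORD
        assert not new.wireless_enabled and not new.wifi_enabled
        assert "dive_detected" in actions and "countdown_started" in actions
        assert new.countdown_started_epoch_s == 100.0

    def test_hysteresis_band_retains_mode(self):
        diving = LoggerState(mode=Mode.DIVE_RECORD, wireless_enabled=False)
        new, _ = step_state(diving, 4.0, 8.0, 0.0, self.CFG)
        assert new.mode is Mode.DIVE_RECORD
        surfaced = self._surface_state()
        new, _ = step_state(surfaced, 4.0, 8.0, 0.0, self.CFG)
        assert new.mode is Mode.SURFACE_RECORD

    def test_voltage_ladder(self):
        state = self._surface_state()
        state, actions = step_state(state, 0.0, 6.1, 0.0, self.CFG)
        assert state.mode is Mode.CRITICAL_SHUTDOWN and "critical_shutdown" in actions
        state, actions = step_state(state, 0.0, 5.9, 1.0, self.CFG)
        assert state.mode is Mode.OFF and "poweroff" in actions
        # OFF is terminal
        state, actions = step_state(state, 0.0, 8.4, 2.0, self.CFG)
        assert state.mode is Mode.OFF and actions == []

    def test_burnwire_on_low_battery_fires_once(self):
        state = self._surface_state()
        state, actions = step_state(state, 0.0, 6.3, 0.0, self.CFG)
        assert state.mode is Mode.BURNWIRE and state.burnwire_fired
        assert any(a.startswith("burnwire_fired") for a in actions)
        state, actions = step_state(state, 0.0, 6.3, 1.0, self.CFG)
        assert not any(a.startswith("burnwire_fired") for a in actions)

    def test_burnwire_on_countdown_expiry_clears_countdown(self):
        state = LoggerState(
            mode=Mode.DIVE_RECORD, wireless_enabled=False,
            countdown_started_epoch_s=0.0,
        )
        state, actions = step_state(state, 10.0, 8.0, self.CFG.mission_duration_s, self.CFG)
        assert state.burnwire_fired
        assert state.countdown_started_epoch_s is None

    def test_depth_safety_release(self):
        state = LoggerState(mode=Mode.DIVE_RECORD, wireless_enabled=False)
        state, actions = step_state(state, 1005.0, 8.0, 0.0, self.CFG)
        assert state.burnwire_fired
        assert "burnwire_fired:depth_safety" in actions

    def test_nan_sensor_fault_keeps_mode(self):
        state = self._surface_state()
        new, actions = step_state(state, math.nan, 8.0, 0.0, self.CFG)
        assert new.mode is Mode.SURFACE_RECORD and actions == ["sensor_fault"]
        new, actions = step_state(state, 0.0, math.nan, 0.0, self.CFG)
        assert actions == ["sensor_fault"]

    def test_wifi_stays_off_after_first_dive(self):
        state = self._surface_state()
        state, _ = step_state(state, 10.0, 8.0, 0.0, self.CFG)
        state, _ = step_state(state, 1.0, 8.0, 100.0, self.CFG)
        assert state.mode is Mode.SURFACE_RECORD
        assert state.wireless_enabled and not state.wifi_enabled


class TestSimulateMission:
    def test_constant_draw_depletes_at_expected_runtime(self):
        """37 Wh at a constant 2.2 W lasts 16.8 h (one-step tolerance)."""
        cfg = MissionConfig(
            power_budget={"compute": 2.2}, mission_duration_s=1e12,
            depth_safety_release_m=None,
        )
        result = simulate_mission(cfg, _flat_profile(18.0))
        off = result.trajectory[result.trajectory["mode"] == "OFF"]
        assert len(off) > 0
        t_off_h = off["epoch_s"].iloc[0] / 3600.0
        expected = cfg.battery_energy_wh / 2.2
        assert abs(t_off_h - expected) <= 1.5 / 3600.0

    def test_zero_power_budget_is_inert(self):
        cfg = MissionConfig(power_budget={}, mission_duration_s=1e12, depth_safety_release_m=None)
        result = simulate_mission(cfg, _flat_profile(1.0))
        assert result.trajectory["energy_wh"].nunique() == 1
        assert not any(
            c.startswith(("critical", "poweroff", "burnwire")) for c in result.event_log["cause"]
        )

    def test_countdown_persists_across_restart(self):
        """Set countdown, inject a restart, fire on schedule — exactly once."""
        cfg = MissionConfig(mission_duration_s=2 * 3600.0, depth_safety_release_m=None)
        t = np.arange(0.0, 3.0 * 3600.0, 1.0)
        depth = np.where((t > 1800) & (t < 2400), 50.0, 0.0)  # dive at t=30 min
        profile = pd.DataFrame({"epoch_s": t, "depth_m": depth})
        result = simulate_mission(cfg, profile, restart_epochs=[3600.0])
        fires = result.event_log[result.event_log["cause"].str.startswith("burnwire_fired")]
        assert len(fires) == 1
        assert fires["cause"].iloc[0] == "burnwire_fired:countdown_expired"
        # 30 min first dive + 2 h countdown = 2 h 30 min
        assert fires["epoch_s"].iloc[0] == pytest.approx(1800.0 + 2 * 3600.0, abs=2.0)
        restarts = result.event_log[result.event_log["cause"] == "restart"]
        assert len(restarts) == 1

    def test_invariants_over_seeded_profiles(self):
        """Burnwire at most once; energy and voltage non-increasing; no data
        accrual below the critical voltage; wireless off whenever submerged;
        across 100 random dive profiles."""
        for seed in range(100):
            profile, _ = synth_dive_profile(_small_dive_spec(seed))
            cfg = MissionConfig(mission_duration_s=900.0)
            result = simulate_mission(cfg, profile, seed=seed)
            fires = result.event_log["cause"].str.startswith("burnwire_fired").sum()
            assert fires <= 1
            traj = result.trajectory
            assert (np.diff(traj["energy_wh"]) <= 1e-12).all()
            assert (np.diff(traj["voltage_v"]) <= 1e-12).all()
            assert (np.diff(traj["data_bytes"]) >= 0).all()
            submerged = traj["depth_m"] > cfg.dive_depth_m
            assert not (submerged & (traj["mode"] == "SURFACE_RECORD")).any()
            dead = traj["mode"].isin(["CRITICAL_SHUTDOWN", "OFF"])
            if dead.any():
                assert np.diff(traj.loc[dead, "data_bytes"]).sum() == 0

    def test_no_data_below_critical_voltage(self):
        # tiny battery so the ladder is crossed within the profile
        cfg = MissionConfig(battery_capacity_mah=30.0, mission_duration_s=1e12,
                            depth_safety_release_m=None)
        result = simulate_mission(cfg, _flat_profile(1.0))
        traj = result.trajectory
        below = traj["voltage_v"] < cfg.critical_voltage_v
        assert below.any()
        assert np.allclose(np.diff(traj.loc[below, "data_bytes"]), 0.0)

    def test_reproducible_event_log(self):
        profile, _ = synth_dive_profile(_small_dive_spec(7))
        cfg = MissionConfig()
        a = simulate_mission(cfg, profile, seed=3).event_log.to_csv(index=False)
        b = simulate_mission(cfg, profile, seed=3).event_log.to_csv(index=False)
        assert a == b

    def test_data_rate_matches_config(self):
        cfg = MissionConfig(mission_duration_s=1e12, depth_safety_release_m=None)
        result = simulate_mission(cfg, _flat_profile(1.0))
        expected = (cfg.audio_bytes_per_s + cfg.sensor_bytes_per_hour / 3600.0) * 3600.0
        assert result.final_state.data_written_bytes == pytest.approx(expected, rel=1e-3)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            simulate_mission(MissionConfig(), pd.DataFrame({"epoch_s": [], "depth_m": []}))

    def test_irregular_step_rejected(self):
        profile = pd.DataFrame({"epoch_s": [0.0, 1.0, 3.0], "depth_m": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            simulate_mission(MissionConfig(), profile)


class TestVoltageProxy:
    def test_endpoints(self):
        cfg = MissionConfig()
        assert voltage_from_energy(cfg.battery_energy_wh, cfg) == pytest.approx(8.4)
        assert voltage_from_energy(0.0, cfg) < cfg.poweroff_voltage_v

    def test_monotone(self):
        cfg = MissionConfig()
        e = np.linspace(0.0, cfg.battery_energy_wh, 50)
        v = [voltage_from_energy(x, cfg) for x in e]
        assert (np.diff(v) >= 0).all()


class TestRecoveryComms:
    def test_certainty_and_impossibility(self):
        df, frac = simulate_recovery_comms(100, 1.0, seed=0)
        assert frac == 1.0 and df["received"].all()
        df, frac = simulate_recovery_comms(100, 0.0, seed=0)
        assert frac == 0.0 and not df["received"].any()

    def test_received_fraction_within_binomial_interval(self):
        """p=0.25, n=10000: fraction inside the 99% binomial interval."""
        _, frac = simulate_recovery_comms(10_000, 0.25, seed=42)
        half = 2.576 * math.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac - 0.25) <= half

    def test_tx_index_increments_only_on_lock(self):
        df, _ = simulate_recovery_comms(1000, 0.5, seed=1, gps_lock_prob=0.3)
        locked = df[df["gps_lock"]]
        assert (locked["tx_index"].to_numpy() == np.arange(len(locked))).all()
        assert (df.loc[~df["gps_lock"], "tx_index"] == -1).all()
        assert not df.loc[~df["gps_lock"], "received"].any()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MissionConfig(poweroff_voltage_v=6.5)
        with pytest.raises(ValueError):
            MissionConfig(surface_depth_m=6.0)
        with pytest.raises(ValueError):
            simulate_recovery_comms(10, 1.5)
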