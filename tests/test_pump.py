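"""Insulin-pump state machine: configuration bounds, delivery, mode logic."""

import numpy as np
import pytest

from mcpsim.engine import run_scenario
from mcpsim.pump import (
    ALERT_EMPTY,
    ALERT_LOW,
    ALERT_OK,
    CartridgeStatus,
    DeliveryCommand,
    InsulinPump,
    PumpConfig,
    PumpMode,
    PumpState,
    Strategy,
    administer_dose,
    check_cartridge_level,
    get_strategy_adm_insulin,
    pump_step,
    pump_transition,
)


def run_pump_day(config, horizon=1440.0, start_level=None):
    state = PumpState(
        mode=PumpMode.EXECUTING,
        initial_level=config.capacity if start_level is None else start_level,
        status=CartridgeStatus.FULL,
    )
    history = []
    t = 0.0
    while t <= horizon:
        state, out = pump_step(state, config, t)
        history.append((t, out))
        t += 1.0
    return state, history


class TestPumpConfig:
    def test_default_cartridge_holds_315_units(self):
        assert PumpConfig().capacity == pytest.approx(315.0)

    def test_basal_rate_bounds_enforced(self):
        with pytest.raises(ValueError, match="25.0"):
            PumpConfig(basal_rate=30.0)
        with pytest.raises(ValueError, match="0.1"):
            PumpConfig(basal_rate=0.05)

    def test_bolus_bound(self):
        with pytest.raises(ValueError):
            PumpConfig(standard_bolus=26.0)

    def test_customized_profile_needs_24_rates(self):
        with pytest.raises(ValueError, match="24"):
            PumpConfig(basal_profile="customized", basal_rates=(1.0,) * 12)


class TestCheckCartridgeLevel:
    CFG = PumpConfig()

    def test_empty(self):
        assert check_cartridge_level(0.0, self.CFG) == (CartridgeStatus.EMPTY, ALERT_EMPTY)

    def test_full_at_capacity(self):
        assert check_cartridge_level(315.0, self.CFG) == (CartridgeStatus.FULL, ALERT_OK)

    def test_low_boundary_inclusive(self):
        status, alert = check_cartridge_level(self.CFG.low_threshold, self.CFG)
        assert status is CartridgeStatus.LOW and alert == ALERT_LOW

    def test_normal_between(self):
        assert check_cartridge_level(100.0, self.CFG)[0] is CartridgeStatus.NORMAL

    def test_out_of_range_is_corruption(self):
        with pytest.raises(Exception, match="outside"):
            check_cartridge_level(-1.0, self.CFG)


class TestStrategy:
    def test_standard_basal_dose_is_rate_over_20(self):
        cfg = PumpConfig(basal_rate=1.2)
        cmd = get_strategy_adm_insulin(6.0, cfg)
        assert cmd.strategy is Strategy.BASAL
        assert cmd.dose == pytest.approx(1.2 / 20.0)

    def test_corrective_preempts(self):
        cfg = PumpConfig(corrective_bolus=2.5)
        cmd = get_strategy_adm_insulin(6.0, cfg, corrective_requested=True)
        assert cmd.strategy is Strategy.CORREC_BOLUS and cmd.dose == 2.5

    def test_scheduled_bolus(self):
        cfg = PumpConfig(standard_bolus=4.0, bolus_times=(480.0,))
        assert get_strategy_adm_insulin(480.0, cfg).strategy is Strategy.STAND_BOLUS

    def test_off_slot_is_idle(self):
        assert get_strategy_adm_insulin(7.0, PumpConfig()) is None

    def test_standard_profile_issues_480_commands_per_day(self):
        cfg = PumpConfig()
        cmds = [get_strategy_adm_insulin(float(t), cfg) for t in range(1441)]
        assert sum(c is not None and c.strategy is Strategy.BASAL for c in cmds) == 480

    def test_customized_profile_issues_24_commands_per_day(self):
        cfg = PumpConfig(basal_profile="customized", basal_rates=(1.0,) * 24)
        cmds = [get_strategy_adm_insulin(float(t), cfg) for t in range(1441)]
        assert sum(c is not None for c in cmds) == 24


class TestAdminister:
    def _exec_state(self, level):
        return PumpState(mode=PumpMode.EXECUTING, initial_level=level)

    def test_subtracts_dose(self):
        state, delivered = administer_dose(self._exec_state(315.0), DeliveryCommand(Strategy.BASAL, 0.06))
        assert state.level == pytest.approx(314.94)
        assert state.cumulative == pytest.approx(0.06)
        assert delivered == 0.06

    def test_insufficient_level_refuses_and_stops(self):
        state, delivered = administer_dose(self._exec_state(0.04), DeliveryCommand(Strategy.BASAL, 0.06))
        assert state.level == 0.04
        assert delivered == 0.0
        assert state.mode is PumpMode.STOP

    def test_480_doses_arithmetic(self):
        state = self._exec_state(315.0)
        for _ in range(480):
            state, _ = administer_dose(state, DeliveryCommand(Strategy.BASAL, 0.06))
        assert state.level == pytest.approx(286.2)
        assert state.cumulative == pytest.approx(28.8)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            administer_dose(self._exec_state(10.0), DeliveryCommand(Strategy.BASAL, -1.0))


class TestTransition:
    def test_run_accepted_when_normal(self):
        s = PumpState(mode=PumpMode.STOP, initial_level=100.0, status=CartridgeStatus.NORMAL)
        assert pump_transition(s, "Run").mode is PumpMode.EXECUTING

    def test_run_refused_when_low(self):
        s = PumpState(mode=PumpMode.STOP, initial_level=10.0, status=CartridgeStatus.LOW)
        assert pump_transition(s, "Run").mode is PumpMode.STOP

    def test_stop_always_accepted(self):
        s = PumpState(mode=PumpMode.EXECUTING, initial_level=100.0, status=CartridgeStatus.NORMAL)
        assert pump_transition(s, "Stop").mode is PumpMode.STOP

    def test_executing_stops_when_status_empty(self):
        s = PumpState(mode=PumpMode.EXECUTING, initial_level=0.0, status=CartridgeStatus.EMPTY)
        assert pump_transition(s).mode is PumpMode.STOP

    def test_warn_only_keeps_running_on_low(self):
        cfg = PumpConfig(warn_only_on_low=True)
        s = PumpState(mode=PumpMode.EXECUTING, initial_level=10.0, status=CartridgeStatus.LOW)
        assert pump_transition(s, config=cfg).mode is PumpMode.EXECUTING


class TestPumpStep:
    def test_full_day_cumulative_closed_form(self):
        cfg = PumpConfig(basal_rate=1.2)
        state, _ = run_pump_day(cfg)
        assert state.cumulative == pytest.approx(480 * 1.2 / 20.0)

    def test_conservation_identity(self):
        cfg = PumpConfig(basal_rate=2.4)
        state, history = run_pump_day(cfg)
        # the level is maintained as initial - cumulative, bitwise
        assert state.level == state.initial_level - state.cumulative
        # and the cumulative equals the re-accumulated per-tick deliveries
        acc = 0.0
        for _, out in history:
            acc += out["administered"]
        assert acc == state.cumulative

    def test_low_cartridge_warns_and_stops(self):
        """Default policy: the pump stops once the cartridge goes LOW."""
        cfg = PumpConfig(cartridge_ml=0.2, basal_rate=1.25)  # 20 U, LOW at 2
        state, history = run_pump_day(cfg)
        assert state.mode is PumpMode.STOP
        assert ALERT_LOW in state.alerts
        stop_t = next(t for t, out in history if out["insulinPumpStatus"] == "STOP")
        assert all(out["administered"] == 0 for t, out in history if t > stop_t)

    def test_runout_produces_empty_alert_then_stop_next_tick(self):
        """With warn-only LOW, a cartridge sized to run dry mid-day empties
        (exactly: 20 U / 0.0625 U per slot = 320 doses), alerts, and the
        mode transition to STOP lands one tick after the status change."""
        cfg = PumpConfig(cartridge_ml=0.2, basal_rate=1.25, warn_only_on_low=True)
        state, history = run_pump_day(cfg)
        by_time = {t: out for t, out in history}
        empty_t = next(t for t, out in history if out["cartridgeStatus"] == "EMPTY")
        assert by_time[empty_t]["insulinPumpStatus"] == "EXECUTING"
        assert by_time[empty_t + 1.0]["insulinPumpStatus"] == "STOP"
        assert state.status is CartridgeStatus.EMPTY
        assert ALERT_EMPTY in state.alerts
        assert state.level == 0.0
        assert all(out["administered"] == 0 for t, out in history if t > empty_t)

    def test_determinism_of_consumption_history(self):
        cfg = PumpConfig(basal_rate=1.0, standard_bolus=4.0, bolus_times=(480.0, 720.0))
        _, h1 = run_pump_day(cfg)
        _, h2 = run_pump_day(cfg)
        assert [(t, o["administered"]) for t, o in h1] == [(t, o["administered"]) for t, o in h2]


class TestPumpComponent:
    def test_engine_run_matches_direct_stepping(self):
        cfg = PumpConfig(basal_rate=1.2)
        pump = InsulinPump("pump", cfg)
        trace = run_scenario([pump], [], horizon=1440, dt=1, seed=0)
        direct_state, _ = run_pump_day(cfg)
        assert pump.state.cumulative == pytest.approx(direct_state.cumulative)
        basal = [d for d in pump.delivery_log if d["strategy"] == "BASAL"]
        assert len(basal) == 480

    def test_reachable_states_safe(self):
        """Level never negative; EMPTY iff level == 0, over a randomized run."""
        rng = np.random.default_rng(17)
        cfg = PumpConfig(cartridge_ml=0.5, basal_rate=1.5, corrective_bolus=2.0)
        state = PumpState(mode=PumpMode.EXECUTING, initial_level=cfg.capacity)
        for t in range(1441):
            inputs = {"corrective": bool(rng.random() < 0.01)}
            state, _ = pump_step(state, cfg, float(t), inputs)
            assert state.level >= 0
            assert (state.status is CartridgeStatus.EMPTY) == (state.level == 0)
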