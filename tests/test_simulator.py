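"""Event-driven metabolic/DOT simulator: rates, events, conservation."""

import numpy as np
import pytest

import dotpulse as dp
from dotpulse.simulator import (STATE_I, STATE_II, STATE_III, STATE_IV,
                                SolverOptions, _rates_raw)


class TestAdaptationTime:
    def test_maximum_at_reference_concentrations(self, adapt):
        assert dp.adaptation_time(0.5, 25.0, adapt) == pytest.approx(60.0)

    def test_worked_value(self, adapt):
        # CA and Cx both halved: the two factors cancel
        assert dp.adaptation_time(0.25, 12.5, adapt) == pytest.approx(60.0)

    def test_zero_acetate_gives_zero(self, adapt):
        assert dp.adaptation_time(0.0, 10.0, adapt) == 0.0

    def test_zero_biomass_rejected(self, adapt):
        with pytest.raises(ValueError):
            dp.adaptation_time(0.2, 0.0, adapt)

    def test_constant_and_none_modes(self):
        const = dp.AdaptationParams(mode="constant", dt_const_s=15.0)
        assert dp.adaptation_time(0.4, 10.0, const) == 15.0
        off = dp.AdaptationParams(mode="none")
        assert dp.adaptation_time(0.4, 10.0, off) == 0.0


class TestRates:
    def test_static_state_all_zero(self, adapt):
        cell = dp.CellParams()
        state = dp.SimState(cs=1.0, ca=1.0, cx=10, dot=50, state=STATE_IV)
        r = dp.rates(state, cell, adapt)
        assert (r.qs_ox, r.qs_of, r.qa_ox, r.qo2, r.mu) == (0, 0, 0, 0, 0)

    def test_overflow_split_at_saturating_glucose(self, adapt):
        cell = dp.CellParams(qs_max=2.5)
        state = dp.SimState(cs=50.0, ca=0, cx=10, dot=100, state=STATE_I)
        r = dp.rates(state, cell, adapt)
        assert r.qs_ox == pytest.approx(0.16 / 0.075, rel=1e-3)
        assert r.qs_of == pytest.approx(2.5 * 50 / 50.02 - 0.16 / 0.075,
                                        rel=1e-2)
        assert r.qo2 == pytest.approx(0.16, rel=1e-3)

    def test_full_pause_zeroes_everything(self, cell):
        adapt = dp.AdaptationParams(rt=1.0)
        state = dp.SimState(cs=0.0, ca=0.4, cx=10, dot=50, state=STATE_II)
        r = dp.rates(state, cell, adapt)
        assert r.qo2 == 0.0 and r.qa_ox == 0.0

    def test_acetate_oxidation_capped_at_critical(self, cell, adapt):
        state = dp.SimState(cs=0.0, ca=5.0, cx=10, dot=100, state=STATE_III)
        r = dp.rates(state, cell, adapt)
        assert r.qa_ox <= cell.qa_ox_critical + 1e-12
        assert r.qo2 == pytest.approx(cell.qo2_max, rel=1e-2)

    def test_overflow_requires_capacity_margin(self):
        with pytest.raises(ValueError):
            dp.CellParams(qs_max=1.0)  # below qO2max/YO2S


class TestEventSequences:
    def test_large_bolus_visits_adaptation_state(self, single_pulse_sim):
        res, _ = single_pulse_sim
        seq = [(e.from_state, e.to_state) for e in res.events]
        assert seq == [(STATE_IV, STATE_I), (STATE_I, STATE_II),
                       (STATE_II, STATE_III), (STATE_III, STATE_IV)]
        times = [e.t_s for e in res.events]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_small_bolus_skips_adaptation(self, cell, adapt, reactor, sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(60.0, 3.0, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=700.0)
        seq = [(e.from_state, e.to_state) for e in res.events]
        assert seq == [(STATE_IV, STATE_I), (STATE_I, STATE_III),
                       (STATE_III, STATE_IV)]

    def test_pure_reoxygenation(self, cell, adapt, reactor, sensor):
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=50.0, dotm=50.0)
        res = dp.simulate_experiment(dp.FeedSchedule([]), init, cell, adapt,
                                     reactor, sensor, t_end_s=100.0)
        expect = 100.0 - 50.0 * np.exp(-reactor.kla_per_h / 3600.0
                                       * res.time_s)
        np.testing.assert_allclose(res.dot, expect, atol=1e-6)
        assert np.all(res.cs == 0) and np.all(res.ca == 0)

    def test_empty_schedule_constant_at_saturation(self, cell, adapt,
                                                   reactor, sensor):
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(dp.FeedSchedule([]), init, cell, adapt,
                                     reactor, sensor, t_end_s=60.0)
        np.testing.assert_allclose(res.dot, 100.0, atol=1e-9)

    def test_step_events_single_fragment(self, cell, adapt, reactor, sensor):
        state = dp.SimState(cs=0.3, ca=0.0, cx=10.0, v_ml=8.0, dot=100.0,
                            dotm=100.0, state=STATE_I)
        frag, new_state, event = dp.step_events(state, cell, adapt, reactor,
                                                sensor, t_until_s=600.0)
        assert event is not None and event.trigger == "glucose_depleted"
        assert new_state.cs == 0.0
        assert frag["time_s"].iloc[-1] <= event.t_s


class TestConservation:
    @pytest.mark.parametrize("volume", [3.0, 5.5, 9.0])
    def test_mass_balances_close(self, volume, cell, adapt, reactor, sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(60.0, volume, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=1000.0)
        rep = dp.conservation_report(res, cell)
        assert abs(rep["glucose_rel_err"]) < 1e-6
        assert abs(rep["acetate_rel_err"]) < 1e-6
        assert abs(dp.oxygen_balance_error(res, cell, reactor)) < 1e-6

    def test_multi_pulse_with_growth(self, cell, adapt, reactor, sensor):
        spec = dp.ExperimentSpec(plan="E", horizon_h=0.5, seed=0,
                                 noise_sigma_pct=0.0)
        schedule = dp.build_schedule(spec)
        init = dp.SimState(cs=0, ca=0, cx=8.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=1800.0, growth=True)
        rep = dp.conservation_report(res, cell)
        assert abs(rep["glucose_rel_err"]) < 1e-6
        assert abs(rep["acetate_rel_err"]) < 1e-6
        assert abs(dp.oxygen_balance_error(res, cell, reactor)) < 1e-6
        assert res.cx[-1] > res.cx[0]  # biomass actually grew

    def test_state_bounds(self, single_pulse_sim, reactor):
        res, _ = single_pulse_sim
        assert np.all(res.cs >= -1e-9) and np.all(res.ca >= -1e-9)
        assert np.all(res.dot >= -1e-6)
        assert np.all(res.dot <= reactor.dotstar + 1e-6)

    def test_probe_lags_dot_by_tau(self, single_pulse_sim, sensor):
        res, _ = single_pulse_sim
        a = res.dot - res.dot.mean()
        b = res.dotm - res.dotm.mean()
        lags = np.arange(0, 120)
        cc = [float(np.dot(a[:a.size - k], b[k:])) for k in lags]
        peak = lags[int(np.argmax(cc))]
        # the probe trails by a delay on the order of tau (the exact peak
        # position depends on the pulse spectrum)
        assert sensor.tau_s / 3 <= peak <= 2 * sensor.tau_s
        assert np.argmin(res.dotm) > np.argmin(res.dot)

    def test_oxygen_limited_run_stays_nonnegative(self, cell, adapt, reactor,
                                                  sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(60.0, 9.0, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=14.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=900.0)
        assert res.dot.min() >= -1e-6


class TestDeterminism:
    def test_identical_inputs_identical_event_logs(self, cell, adapt,
                                                   reactor, sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(60.0, 6.5, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        r1 = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                    sensor, t_end_s=700.0)
        r2 = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                    sensor, t_end_s=700.0)
        assert [e.t_s for e in r1.events] == [e.t_s for e in r2.events]
        np.testing.assert_array_equal(r1.dot, r2.dot)
        np.testing.assert_array_equal(r1.dotm, r2.dotm)


def naive_fixed_step(schedule, init, cell, adapt, reactor, sensor, t_end_s,
                     dt=0.01, sample_every=100):
    """Independent fixed-step (explicit Euler) oracle for the hybrid model.

    Events are handled at step resolution: the same state logic as the
    event-driven integrator, but located only to within dt.
    """
    opts = SolverOptions()
    h = reactor.h_pct_l_per_g
    kla = reactor.kla_per_h
    tau = sensor.tau_s
    feeds = sorted(schedule.events, key=lambda e: e.time_s)
    cs, ca, cx, v = init.cs, init.ca, init.cx, init.v_ml
    dot, dotm = init.dot, init.dotm
    state = STATE_IV
    deadline = None
    fi = 0
    out_t, out_dot = [], []
    n = int(round(t_end_s / dt))
    dth = dt / 3600.0
    for i in range(n + 1):
        t = i * dt
        if fi < len(feeds) and t >= feeds[fi].time_s:
            f = feeds[fi]
            dv = f.volume_ul * 1e-3
            cs = (cs * v + f.mass_mg) / (v + dv)
            ca *= v / (v + dv)
            cx *= v / (v + dv)
            v += dv
            state = STATE_I
            deadline = None
            fi += 1
        if state == STATE_I and cs <= opts.cs_event_mg_ml:
            cs = 0.0
            if adapt.mode != "none" and ca > adapt.ca_threshold:
                state = STATE_II
                deadline = t + dp.adaptation_time(ca, cx, adapt)
            elif ca > opts.ca_event_mg_ml:
                state = STATE_III
            else:
                ca, state = 0.0, STATE_IV
        if state == STATE_II and deadline is not None and t >= deadline:
            state = STATE_III if ca > opts.ca_event_mg_ml else STATE_IV
            deadline = None
        if state == STATE_III and ca <= opts.ca_event_mg_ml:
            ca, state = 0.0, STATE_IV
        qs_ox, qs_of, qa_ox, qo2, mu = _rates_raw(state, cs, ca, dot, cell,
                                                  adapt)
        if i % sample_every == 0:
            out_t.append(t)
            out_dot.append(dot)
        cs += -(qs_ox + qs_of) * cx * dth
        ca += (qs_of * cell.yas - qa_ox) * cx * dth
        ddot = (reactor.dotstar - dot) * kla - qo2 * h * cx
        dot += ddot * dth
        dotm += (dot - dotm) / tau * dt
    return np.array(out_t), np.array(out_dot)


class TestFixedStepOracle:
    def test_event_driven_matches_naive_integration(self, cell, adapt,
                                                    reactor, sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(30.0, 9.0, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=400.0)
        t_ref, dot_ref = naive_fixed_step(schedule, init, cell, adapt,
                                          reactor, sensor, 400.0)
        dot_edm = np.interp(t_ref, res.time_s, res.dot)
        rms = np.sqrt(np.mean((dot_edm - dot_ref) ** 2))
        assert rms < 0.1


class TestThresholdSweep:
    def test_no_pause_means_no_fourth_segment(self, cell, reactor):
        res = dp.find_segment_threshold(np.arange(5.0, 9.1, 2.0), 10.0, cell,
                                        dp.AdaptationParams(rt=0.0), reactor)
        assert res.threshold_ul is None

    def test_unreachable_acetate_threshold(self, cell, reactor):
        res = dp.find_segment_threshold(np.arange(5.0, 9.1, 2.0), 10.0, cell,
                                        dp.AdaptationParams(ca_threshold=1e6),
                                        reactor)
        assert res.threshold_ul is None

    def test_no_adaptation_mode_gives_two_segments(self, cell, reactor,
                                                   sensor):
        schedule = dp.FeedSchedule([dp.FeedEvent(60.0, 9.0, 600.0)])
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell,
                                     dp.AdaptationParams(mode="none"),
                                     reactor, sensor, t_end_s=900.0)
        pulses = dp.segment_run(res.trace_dotm(), schedule)
        assert pulses[0].n_segments == 2
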