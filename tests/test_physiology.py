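"""Parameter retrieval: KLa, qO2/qO2max, yields, and the full workflow."""

import math

import numpy as np
import pytest

import dotpulse as dp
from dotpulse.errors import (DegeneratePulseError, NotApplicableError,
                             SingularRecoveryError)
from dotpulse.physiology import kla_from_endpoints
from dotpulse.segmentation import S1, S3, S4, Pulse, Segment

from conftest import recovery_run


def _segment(label, t0, t1, d0, d1, dotstar=100.0):
    dur = t1 - t0
    area = 0.5 * (d0 + d1) * dur
    return Segment(label, t0, t1, d0, d1, area, dotstar * dur - area)


def _pulse(segments, feed=dp.FeedEvent(0.0, 5.0, 600.0), baseline=100.0,
           flags=()):
    return Pulse(feed, segments[0].t_start, segments[-1].t_end,
                 list(segments), baseline,
                 min(s.dot_start for s in segments), set(flags))


class TestKlaClosedForm:
    def test_printed_evaluation(self):
        # recovery from 20 % to 90 % of a 100 % saturation in 36 s
        kla = kla_from_endpoints(100.0, 20.0, 90.0, 36.0)
        assert kla == pytest.approx(-math.log(10 / 80) / 0.01, rel=1e-12)
        assert kla == pytest.approx(207.94, abs=0.01)

    def test_unit_case(self):
        # depression ratio e^-1 over one hour -> KLa = 1/h
        kla = kla_from_endpoints(100.0, 20.0, 100.0 - 80.0 / math.e, 3600.0)
        assert kla == pytest.approx(1.0)

    def test_singular_recovery(self):
        with pytest.raises(SingularRecoveryError):
            kla_from_endpoints(100.0, 20.0, 100.0, 36.0)

    def test_non_rising_segment(self):
        with pytest.raises(DegeneratePulseError):
            kla_from_endpoints(100.0, 90.0, 85.0, 36.0)

    def test_truncated_pulse_not_applicable(self):
        p = _pulse([_segment(S1, 0, 30, 100, 40),
                    _segment(S4, 30, 60, 40, 80)], flags={"truncated"})
        with pytest.raises(NotApplicableError):
            dp.estimate_kla(p, 100.0)

    def test_simulated_recovery_recovered_within_two_percent(self):
        # pure reoxygenation generated at KLa = 250/h, no noise
        reactor = dp.ReactorParams()
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=20.0, dotm=20.0)
        res = dp.simulate_experiment(dp.FeedSchedule([]), init,
                                     dp.CellParams(), dp.AdaptationParams(),
                                     reactor, dp.SensorModel(0.0),
                                     t_end_s=120.0)
        trace = res.trace_dot()
        i95 = int(np.argmax(trace.dot >= 95.0))
        p = _pulse([_segment(S1, 0.0, 1.0, 100.0, 20.0),
                    _segment(S4, 1.0, trace.time[i95], 20.0,
                             float(trace.dot[i95]))])
        kla = dp.estimate_kla(p, 100.0, trace)
        assert kla == pytest.approx(reactor.kla_per_h, rel=0.02)


class TestQo2:
    def _trace(self, value, n=61):
        t = np.arange(float(n))
        return dp.DotTrace(t, np.full(n, value))

    def test_steady_depression_closed_form(self):
        # DOT pinned at 80 %: qO2 = 20*200/(H*Cx), OUR = qO2*Cx
        reactor = dp.ReactorParams(kla_per_h=200.0)
        p = _pulse([_segment(S1, 0, 60, 80, 80),
                    _segment(S4, 60, 61, 80, 95)])
        qo2, our = dp.estimate_qo2(p, self._trace(80.0), cx=10.0,
                                   kla_per_h=200.0, reactor=reactor)
        assert qo2 == pytest.approx(20 * 200 / (reactor.h_pct_l_per_g * 10),
                                    rel=1e-9)
        assert qo2 == pytest.approx(0.028, abs=1e-4)
        assert our == pytest.approx(0.28, abs=1e-3)

    def test_no_depression_means_zero_uptake(self):
        p = _pulse([_segment(S1, 0, 60, 100, 100),
                    _segment(S4, 60, 61, 100, 100)])
        qo2, our = dp.estimate_qo2(p, self._trace(100.0), cx=10.0,
                                   kla_per_h=200.0,
                                   reactor=dp.ReactorParams())
        assert qo2 == 0.0 and our == 0.0

    def test_missing_biomass_rejected(self):
        p = _pulse([_segment(S1, 0, 60, 80, 80)])
        with pytest.raises(ValueError):
            dp.estimate_qo2(p, self._trace(80.0), cx=0.0, kla_per_h=200.0,
                            reactor=dp.ReactorParams())


class TestQo2Max:
    def test_max_of_estimates(self):
        qmax, agg = dp.estimate_qo2max([0.10, 0.16, 0.12])
        assert qmax == 0.16
        assert agg.mean == pytest.approx(0.12666, abs=1e-4)

    def test_single_estimate(self):
        qmax, _ = dp.estimate_qo2max([0.11])
        assert qmax == 0.11

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dp.estimate_qo2max([])


class TestYo2s:
    def test_rectangular_depression_closed_form(self):
        # 20 % depression held for 0.05 h; 5 uL x 600 mg/mL = 3 mg glucose
        reactor = dp.ReactorParams(kla_per_h=200.0)
        t = np.arange(0.0, 181.0)
        trace = dp.DotTrace(t, np.full(t.size, 80.0))
        p = _pulse([_segment(S1, 0, 90, 100, 80),
                    _segment(S4, 90, 180, 80, 95)])
        y = dp.estimate_yo2s(p, trace, kla_per_h=200.0, reactor=reactor)
        assert y == pytest.approx(0.112e-3 / 3e-3, rel=1e-3)
        assert y == pytest.approx(0.0373, abs=2e-4)

    def test_zero_depression(self):
        t = np.arange(0.0, 181.0)
        trace = dp.DotTrace(t, np.full(t.size, 100.0))
        p = _pulse([_segment(S1, 0, 90, 100, 100),
                    _segment(S4, 90, 180, 100, 95)])
        assert dp.estimate_yo2s(p, trace, 200.0, dp.ReactorParams()) == 0.0

    def test_four_segment_pulse_rejected(self):
        segs = [_segment(S1, 0, 30, 100, 40), _segment("S2", 30, 50, 40, 60),
                _segment(S3, 50, 80, 60, 30), _segment(S4, 80, 120, 30, 95)]
        t = np.arange(0.0, 121.0)
        trace = dp.DotTrace(t, np.full(t.size, 80.0))
        with pytest.raises(NotApplicableError):
            dp.estimate_yo2s(_pulse(segs), trace, 200.0, dp.ReactorParams())

    def test_unreturned_baseline_rejected(self):
        p = _pulse([_segment(S1, 0, 90, 100, 60),
                    _segment(S4, 90, 180, 60, 80)])
        t = np.arange(0.0, 181.0)
        trace = dp.DotTrace(t, np.full(t.size, 80.0))
        with pytest.raises(NotApplicableError):
            dp.estimate_yo2s(p, trace, 200.0, dp.ReactorParams())


class TestYo2a:
    def test_two_segment_pulse_rejected(self):
        p = _pulse([_segment(S1, 0, 30, 100, 40),
                    _segment(S4, 30, 60, 40, 95)])
        t = np.arange(0.0, 61.0)
        trace = dp.DotTrace(t, np.full(t.size, 80.0))
        with pytest.raises(NotApplicableError):
            dp.estimate_yo2a(p, trace, 200.0, dp.ReactorParams(), 2.1,
                             0.667, 10.0)

    def test_zero_third_segment_depression(self):
        segs = [_segment(S1, 0, 30, 100, 100), _segment("S2", 30, 50, 100, 100),
                _segment(S3, 50, 80, 100, 100), _segment(S4, 80, 120, 100, 100)]
        t = np.arange(0.0, 121.0)
        trace = dp.DotTrace(t, np.full(t.size, 100.0))
        y = dp.estimate_yo2a(_pulse(segs), trace, 200.0, dp.ReactorParams(),
                             qs_ox_max=0.1, yas=0.667, cx=10.0)
        assert y == 0.0

    def test_nonpositive_acetate_mass_degenerate(self):
        # qs_ox_max so large that the whole bolus is oxidised within S1
        segs = [_segment(S1, 0, 300, 100, 40), _segment("S2", 300, 320, 40, 60),
                _segment(S3, 320, 350, 60, 30), _segment(S4, 350, 400, 30, 95)]
        t = np.arange(0.0, 401.0)
        trace = dp.DotTrace(t, np.full(t.size, 80.0))
        with pytest.raises(DegeneratePulseError):
            dp.estimate_yo2a(_pulse(segs), trace, 200.0, dp.ReactorParams(),
                             qs_ox_max=50.0, yas=0.667, cx=10.0)


class TestWorkflow:
    def test_no_samples_gives_kla_only(self):
        exp, _ = recovery_run(2)
        wf = dp.run_workflow(exp.trace, exp.feeds, None, dp.ReactorParams())
        assert wf.estimate.kla.n > 0
        assert wf.estimate.qo2.n == 0
        assert math.isnan(wf.estimate.qo2max)
        assert any("qO2 skipped" in d or "neighbourhood" in d
                   for d in wf.estimate.diagnostics)

    def test_all_truncated_yields_empty_estimate(self, cell, adapt, reactor,
                                                 sensor):
        # boluses every 45 s never allow recovery before the next feed
        events = [dp.FeedEvent(60.0 + 45.0 * k, 6.5, 600.0) for k in range(8)]
        schedule = dp.FeedSchedule(events)
        init = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100, dotm=100)
        res = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                     sensor, t_end_s=480.0)
        wf = dp.run_workflow(res.trace_dotm(), schedule, None, reactor)
        assert wf.estimate.kla.n == 0
        assert wf.estimate.diagnostics

    def test_kla_robust_to_noise(self):
        # estimates with and without sigma = 0.5 % noise agree within 5 %
        quiet = dp.run_workflow(*_run_inputs(seed=4, sigma=0.0))
        noisy = dp.run_workflow(*_run_inputs(seed=4, sigma=0.5))
        assert noisy.estimate.kla.mean == pytest.approx(
            quiet.estimate.kla.mean, rel=0.05)

    def test_qs_ox_critical_matches_generator_switch(self):
        _, wf = recovery_run(1)
        truth = dp.CellParams().qs_ox_critical
        assert wf.estimate.qs_ox_critical == pytest.approx(truth, rel=0.10)

    def test_kla_plausibility_warning(self):
        with pytest.warns(UserWarning, match="outside plausible range"):
            kla = kla_from_endpoints(100.0, 99.0, 99.5, 3600.0)
            from dotpulse.physiology import _warn_kla
            _warn_kla(kla)


def _run_inputs(seed, sigma):
    spec = dp.plan_e_recovery_spec(seed=seed, noise_sigma_pct=sigma)
    exp = dp.generate_experiment(spec)
    return exp.trace, exp.feeds, exp.samples, dp.ReactorParams()
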