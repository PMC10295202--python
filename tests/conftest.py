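"""Shared fixtures: model defaults, constructed pulses, cached synthetic runs."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import dotpulse as dp


@pytest.fixture(scope="session")
def cell():
    return dp.CellParams()


@pytest.fixture(scope="session")
def adapt():
    return dp.AdaptationParams()


@pytest.fixture(scope="session")
def reactor():
    return dp.ReactorParams()


@pytest.fixture(scope="session")
def sensor():
    return dp.SensorModel()


def make_piecewise_pulse(slopes, durations, noise_sigma=0.0, seed=7,
                         pre_s=15.0, post_s=30.0, dt=1.0, baseline=100.0):
    """A DOT trace holding one constructed piecewise-linear pulse.

    Returns (trace, feeds, segment_start_times): the designed segment
    boundaries include the pulse end, so ``len == len(slopes) + 1``.
    """
    rng = np.random.default_rng(seed)
    tcur, dcur = 0.0, baseline
    pts_t, pts_d = [tcur], [dcur]
    tcur += pre_s
    pts_t.append(tcur)
    pts_d.append(dcur)
    bounds = []
    for s, dur in zip(slopes, durations):
        bounds.append(tcur)
        tcur += dur
        dcur += s * dur
        pts_t.append(tcur)
        pts_d.append(dcur)
    bounds.append(tcur)
    pts_t.append(tcur + post_s)
    pts_d.append(dcur)
    grid = np.arange(0.0, pts_t[-1] + dt, dt)
    dot = np.interp(grid, pts_t, pts_d)
    if noise_sigma > 0:
        dot = dot + rng.normal(0.0, noise_sigma, grid.size)
    trace = dp.DotTrace(grid, dot)
    feeds = dp.FeedSchedule([dp.FeedEvent(pre_s, 6.5, 600.0)])
    return trace, feeds, bounds


@lru_cache(maxsize=8)
def _recovery_run(seed: int, sigma: float = 0.3):
    spec = dp.plan_e_recovery_spec(seed=seed, noise_sigma_pct=sigma)
    exp = dp.generate_experiment(spec)
    wf = dp.run_workflow(exp.trace, exp.feeds, exp.samples,
                         dp.ReactorParams())
    return exp, wf


def recovery_run(seed: int, sigma: float = 0.3):
    """Generated plan-E-style run plus its workflow result (cached)."""
    return _recovery_run(seed, sigma)


@pytest.fixture(scope="session")
def single_pulse_sim():
    """One 9 µL bolus at Cx = 10 mg/mL: the canonical four-segment case."""
    schedule = dp.FeedSchedule([dp.FeedEvent(60.0, 9.0, 600.0)])
    initial = dp.SimState(cs=0, ca=0, cx=10.0, v_ml=8.0, dot=100.0,
                          dotm=100.0)
    return dp.simulate_experiment(schedule, initial, dp.CellParams(),
                                  dp.AdaptationParams(), dp.ReactorParams(),
                                  dp.SensorModel(), t_end_s=1100.0), schedule
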