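"""Retrieval of reactor and cell-physiological parameters from DOT pulses.

The segments of a DOT pulse are each dominated by one process, so simple
closed forms recover the governing parameters:

* S4 (recovery) is transfer-dominated, dDOT/dt = (DOT* - DOT)·KLa, whose
  analytic solution gives the volumetric transfer coefficient

      KLa = -ln[(DOT* - DOT_end)/(DOT* - DOT_min)] / dT4.

* S1 (glucose decline) obeys the oxygen balance dDOT/dt = OTR - OUR, so
  the biomass-specific uptake rate is

      qO2 = [(DOT* - DOT)·KLa - dDOT/dt] / (H·Cx),

  evaluated with segment means on the delay-corrected signal.  Its maximum
  over pulses is qO2max, and OUR = qO2·Cx.

* A two-segment pulse whose endpoints match delivers all of its oxygen to
  a known glucose mass, giving the yield YO2/S (oxygen per substrate).

* In a four-segment pulse the third segment's oxygen, integrated until the
  signal regains its pre-segment level, relates to the acetate formed by
  overflow, giving YO2/A.

DOT percentages convert to dissolved-oxygen mass through the Henry-derived
constant H = DOT*/C*_O2,sat [%·L/g]; KLa is reported per hour, segment
times are seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePulseError, NotApplicableError, SingularRecoveryError
from .segmentation import (S1, S3, S4, Pulse, SegmentationConfig,
                           segment_run)
from .trace import (DotTrace, FeedSchedule, SampleTable, SensorModel,
                    SECONDS_PER_HOUR, invert_sensor_delay, resample_uniform,
                    smooth)

KLA_PLAUSIBLE = (20.0, 1440.0)  # 1/h envelope for minibioreactors


@dataclass(frozen=True)
class ReactorParams:
    """Reactor configuration.

    v_ml : working volume [mL]
    dotstar : saturation DOT [%]
    c_o2_sat_g_per_l : dissolved-oxygen concentration at saturation [g/L]
    kla_per_h : volumetric oxygen transfer coefficient [1/h]
    """

    v_ml: float = 8.0
    dotstar: float = 100.0
    c_o2_sat_g_per_l: float = 0.007
    kla_per_h: float = 250.0

    def __post_init__(self):
        for name in ("v_ml", "dotstar", "c_o2_sat_g_per_l", "kla_per_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def h_pct_l_per_g(self) -> float:
        """Henry-derived conversion: % air saturation per (g O2 / L)."""
        return self.dotstar / self.c_o2_sat_g_per_l

    @property
    def v_l(self) -> float:
        return self.v_ml * 1e-3


@dataclass
class ParamAggregate:
    """Per-run aggregate of per-pulse estimates: mean ± one s.d."""

    values: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else math.nan

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return 0.0 if self.values else math.nan
        return float(np.std(self.values, ddof=1))

    @property
    def lo(self) -> float:
        return self.mean - self.sd

    @property
    def hi(self) -> float:
        return self.mean + self.sd

    @property
    def max(self) -> float:
        return float(np.max(self.values)) if self.values else math.nan


@dataclass
class PhysioEstimate:
    """Retrieved parameters for one run, with ±σ ranges."""

    kla: ParamAggregate = field(default_factory=ParamAggregate)
    qo2: ParamAggregate = field(default_factory=ParamAggregate)
    our: ParamAggregate = field(default_factory=ParamAggregate)
    yo2s: ParamAggregate = field(default_factory=ParamAggregate)
    yo2a: ParamAggregate = field(default_factory=ParamAggregate)
    yas: float = 0.667
    diagnostics: list[str] = field(default_factory=list)

    @property
    def qo2max(self) -> float:
        """Maximum S1-based specific oxygen uptake rate [g/(g·h)]."""
        return self.qo2.max

    @property
    def qs_ox_critical(self) -> float:
        """Overflow switching threshold qO2max / YO2S [g/(g·h)]."""
        if self.qo2.n and self.yo2s.n:
            return self.qo2max / self.yo2s.mean
        return math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, agg, unit in (
                ("KLa", self.kla, "1/h"),
                ("qO2", self.qo2, "g/(g.h)"),
                ("OUR", self.our, "g/(L.h)"),
                ("YO2S", self.yo2s, "g/g"),
                ("YO2A", self.yo2a, "g/g")):
            rows.append({"param": name, "unit": unit, "mean": agg.mean,
                         "sd": agg.sd, "lo": agg.lo, "hi": agg.hi,
                         "n": agg.n})
        rows.append({"param": "qO2max", "unit": "g/(g.h)",
                     "mean": self.qo2max, "sd": math.nan, "lo": math.nan,
                     "hi": math.nan, "n": self.qo2.n})
        rows.append({"param": "qs_ox_critical", "unit": "g/(g.h)",
                     "mean": self.qs_ox_critical, "sd": math.nan,
                     "lo": math.nan, "hi": math.nan, "n": self.qo2.n})
        return pd.DataFrame(rows)


def _warn_kla(kla: float) -> None:
    lo, hi = KLA_PLAUSIBLE
    if not (lo <= kla <= hi):
        warnings.warn(f"KLa = {kla:.1f} 1/h outside plausible range "
                      f"[{lo}, {hi}] 1/h")


# ---------------------------------------------------------------------------
# per-pulse estimators
# ---------------------------------------------------------------------------

def kla_from_endpoints(dotstar: float, dot_min: float, dot_end: float,
                       dt4_s: float) -> float:
    """Closed-form KLa [1/h] from two points of a free recovery."""
    if dot_end >= dotstar:
        raise SingularRecoveryError(
            f"recovery endpoint {dot_end:.2f} >= DOT* = {dotstar}")
    if dot_min >= dot_end:
        raise DegeneratePulseError("recovery segment does not rise")
    ratio = (dotstar - dot_end) / (dotstar - dot_min)
    return -math.log(ratio) / (dt4_s / SECONDS_PER_HOUR)


def estimate_kla(pulse: Pulse, dotstar: float = 100.0,
                 trace: DotTrace | None = None,
                 burn_in_fraction: float = 0.25,
                 recovery_fraction: float = 0.95,
                 smooth_window: int = 11, smooth_polyorder: int = 2) -> float:
    """KLa [1/h] from the recovery segment's analytic solution.

    The recovery endpoint sits at the configured baseline-return fraction,
    keeping the log term away from its saturation singularity.  When the
    (delay-corrected) trace is given, the lower anchor is moved a fraction
    of the way up the recovery: the first samples after the pulse bottom
    still carry residual substrate uptake, which otherwise biases the
    estimate low.  Without a trace the raw segment endpoints are used.
    """
    if "truncated" in pulse.flags:
        raise NotApplicableError("truncated pulse: free recovery required")
    s4 = pulse.segment(S4)
    if s4 is None:
        raise DegeneratePulseError("pulse has no recovery segment")
    if trace is None:
        kla = kla_from_endpoints(dotstar, s4.dot_start, s4.dot_end,
                                 s4.duration)
        _warn_kla(kla)
        return kla
    # fit the same analytic law, ln(DOT* - DOT) linear in t, over all
    # recovery samples past the burn-in point: unlike an endpoint pair this
    # is insensitive to where noise places the recovery threshold crossing
    sm = smooth(trace, smooth_window, smooth_polyorder)
    i0 = int(np.searchsorted(sm.time, s4.t_start - 1e-9))
    i1 = int(np.searchsorted(sm.time, s4.t_end + 1e-9)) - 1
    # stop at the first baseline-return crossing: under noise the detected
    # window can run on into the saturation plateau, which carries no
    # transfer information
    hi_target = recovery_fraction * pulse.baseline
    returned = np.nonzero(sm.dot[i0:i1 + 1] >= hi_target)[0]
    if returned.size:
        i1 = min(i1, i0 + int(returned[0]))
    target = s4.dot_start + burn_in_fraction * (s4.dot_end - s4.dot_start)
    risen = np.nonzero(sm.dot[i0:i1 + 1] >= target)[0]
    if risen.size:
        i0 = i0 + int(risen[0])
    dep = dotstar - sm.dot[i0:i1 + 1]
    tt = sm.time[i0:i1 + 1]
    ok = dep > 0.5  # stay away from the saturation singularity
    if ok.sum() < 3:
        kla = kla_from_endpoints(dotstar, s4.dot_start, s4.dot_end,
                                 s4.duration)
        _warn_kla(kla)
        return kla
    # two-pass inverse-variance weighting: additive noise of variance s² on
    # DOT has variance s²/dep² on ln(dep), so the weights should be ∝ dep —
    # taken from the first-pass fit, not the data, to avoid correlating
    # weights with residuals
    sl0, ic0 = np.polyfit(tt[ok], np.log(dep[ok]), 1)
    w = np.exp(ic0 + sl0 * tt[ok])
    slope = np.polyfit(tt[ok], np.log(dep[ok]), 1, w=w)[0]
    if slope >= 0:
        raise DegeneratePulseError("recovery segment does not rise")
    kla = -float(slope) * SECONDS_PER_HOUR
    _warn_kla(kla)
    return kla


def _segment_on(trace: DotTrace, t0: float, t1: float):
    i0 = int(np.searchsorted(trace.time, t0 - 1e-9))
    i1 = int(np.searchsorted(trace.time, t1 + 1e-9)) - 1
    return trace.time[i0:i1 + 1], trace.dot[i0:i1 + 1]


def estimate_qo2(pulse: Pulse, trace: DotTrace, cx: float,
                 kla_per_h: float, reactor: ReactorParams,
                 segment_label: str = S1,
                 use_segment_mean: bool = True) -> tuple[float, float]:
    """Specific oxygen uptake rate qO2 [g/(g·h)] and OUR [g/(L·h)].

    Evaluates the oxygen balance on the delay-corrected trace over the
    chosen segment.  ``use_segment_mean`` selects the time-averaged DOT in
    the transfer term (default, less noise-sensitive); otherwise the
    segment-end value is used.
    """
    if cx <= 0:
        raise ValueError("Cx must be positive")
    seg = pulse.segment(segment_label)
    if seg is None:
        raise NotApplicableError(f"pulse has no {segment_label} segment")
    t, dot = _segment_on(trace, seg.t_start, seg.t_end)
    if t.size < 2:
        raise DegeneratePulseError("segment shorter than 2 samples")
    if use_segment_mean:
        dot_ref = float(np.trapezoid(dot, t) / (t[-1] - t[0]))
    else:
        dot_ref = seg.dot_end
    # endpoint slope on the actual signal: the time-mean of dDOT/dt, which
    # is what the averaged oxygen balance requires
    slope_per_h = (dot[-1] - dot[0]) / (t[-1] - t[0]) * SECONDS_PER_HOUR
    qo2 = ((reactor.dotstar - dot_ref) * kla_per_h - slope_per_h) \
        / (reactor.h_pct_l_per_g * cx)
    qo2 = max(qo2, 0.0)
    return qo2, qo2 * cx


def estimate_qo2max(qo2_values: list[float]) -> tuple[float, ParamAggregate]:
    """Maximum of the S1-based qO2 estimates, plus their mean ± σ."""
    if not qo2_values:
        raise ValueError("no qO2 estimates available")
    agg = ParamAggregate(list(qo2_values))
    return agg.max, agg


def estimate_yo2s(pulse: Pulse, trace: DotTrace, kla_per_h: float,
                  reactor: ReactorParams, endpoint_tol_pct: float = 2.0,
                  baseline_return_fraction: float = 0.95) -> float:
    """Oxygen-per-glucose yield YO2/S [g/g] from a two-segment pulse.

    Applicable only when the whole bolus was oxidised within one pulse that
    returned to its baseline: the transferred-oxygen integral over the
    pulse window then equals the oxygen consumed, and the glucose mass is
    the known bolus mass.
    """
    if pulse.n_segments != 2:
        raise NotApplicableError(
            "YO2/S needs a two-segment pulse; use the YO2/A path for "
            "four-segment pulses")
    if "truncated" in pulse.flags:
        raise NotApplicableError("truncated pulse")
    s1, s4 = pulse.segment(S1), pulse.segment(S4)
    expected_end = baseline_return_fraction * pulse.baseline
    if abs(s4.dot_end - expected_end) > endpoint_tol_pct:
        raise NotApplicableError(
            f"pulse did not return to baseline (end {s4.dot_end:.1f}, "
            f"expected ~{expected_end:.1f})")
    t, dot = _segment_on(trace, pulse.t_start, pulse.t_end)
    depression_pct_h = float(np.trapezoid(reactor.dotstar - dot, t)) \
        / SECONDS_PER_HOUR
    o2_g = reactor.v_l * kla_per_h * depression_pct_h / reactor.h_pct_l_per_g
    feed_g = pulse.feed.mass_mg * 1e-3
    return o2_g / feed_g


def estimate_yo2a(pulse: Pulse, trace: DotTrace, kla_per_h: float,
                  reactor: ReactorParams, qs_ox_max: float, yas: float,
                  cx: float) -> float:
    """Oxygen-per-acetate yield YO2/A [g/g] from a four-segment pulse.

    The third segment's transferred oxygen is integrated from its start
    until the signal regains the segment's starting level during the
    recovery (so the dissolved-oxygen inventory cancels and the integral
    equals the oxygen spent on acetate).  The acetate mass is the overflow
    share of the bolus: fed glucose minus the amount oxidised during S1 at
    the critical uptake rate, times the acetate-per-glucose yield.
    """
    if pulse.n_segments != 4:
        raise NotApplicableError("YO2/A needs a four-segment pulse")
    if cx <= 0:
        raise ValueError("Cx must be positive")
    s1, s3 = pulse.segment(S1), pulse.segment(S3)
    # integration window: S3 start until DOT recovers to its S3-start level
    i0 = int(np.searchsorted(trace.time, s3.t_start - 1e-9))
    i_end_pulse = int(np.searchsorted(trace.time, pulse.t_end + 1e-9)) - 1
    i3e = int(np.searchsorted(trace.time, s3.t_end - 1e-9))
    level = min(float(trace.dot[i0]), float(trace.dot[i_end_pulse]))
    after = np.nonzero(trace.dot[i3e:i_end_pulse + 1] >= level)[0]
    i1 = i3e + int(after[0]) if after.size else i_end_pulse
    t = trace.time[i0:i1 + 1]
    dot = trace.dot[i0:i1 + 1]
    depression_pct_h = float(np.trapezoid(reactor.dotstar - dot, t)) \
        / SECONDS_PER_HOUR
    o2_g = reactor.v_l * kla_per_h * depression_pct_h / reactor.h_pct_l_per_g
    feed_g = pulse.feed.mass_mg * 1e-3
    oxidised_g = qs_ox_max * cx * reactor.v_l * (s1.duration / SECONDS_PER_HOUR)
    acetate_g = max(feed_g - oxidised_g, 0.0) * yas
    if acetate_g <= 0:
        raise DegeneratePulseError(
            "non-positive acetate mass: pulse should not have four segments")
    return o2_g / acetate_g


# ---------------------------------------------------------------------------
# workflow
# ---------------------------------------------------------------------------

@dataclass
class WorkflowResult:
    estimate: PhysioEstimate
    per_pulse: pd.DataFrame
    pulses: list[Pulse]
    corrected: DotTrace


def run_workflow(measured: DotTrace, feeds: FeedSchedule,
                 samples: SampleTable | None, reactor: ReactorParams,
                 sensor: SensorModel = SensorModel(),
                 config: SegmentationConfig | None = None,
                 yas: float = 0.667,
                 sample_neighbourhood_s: float = 900.0,
                 resample_dt_s: float | None = None) -> WorkflowResult:
    """Full retrieval pipeline on one run.

    Delay-corrects the measured trace, segments every feed response, then
    estimates KLa from untruncated recoveries, qO2/qO2max from first
    segments near biomass samples, YO2/S from two-segment pulses and YO2/A
    from four-segment pulses.  Stage failures are recorded per pulse and
    the workflow continues.
    """
    config = config or SegmentationConfig()
    trace = measured
    if not trace.is_uniform or resample_dt_s is not None:
        dt = resample_dt_s or float(np.median(np.diff(trace.time)))
        trace = resample_uniform(trace, dt)
    corrected = invert_sensor_delay(trace, sensor, config.window,
                                    config.polyorder)
    pulses = segment_run(corrected, feeds, config)
    est = PhysioEstimate(yas=yas)
    rows = []
    # stage 1: KLa
    kla_by_pulse: dict[int, float] = {}
    for i, p in enumerate(pulses):
        try:
            kla_by_pulse[i] = estimate_kla(p, reactor.dotstar, corrected)
            est.kla.values.append(kla_by_pulse[i])
        except Exception as e:  # noqa: BLE001 - stage failures are data
            est.diagnostics.append(f"pulse {i}: KLa skipped ({e})")
    if not est.kla.values:
        est.diagnostics.append("no untruncated recoveries: no KLa estimate")
        return WorkflowResult(est, pd.DataFrame(), pulses, corrected)
    kla = est.kla.mean

    # stage 2: qO2 / qO2max near biomass samples
    cx_by_pulse: dict[int, float] = {}
    for i, p in enumerate(pulses):
        cx = (samples.nearest_cx(p.feed.time_s, sample_neighbourhood_s)
              if samples is not None else None)
        if cx is None:
            est.diagnostics.append(f"pulse {i}: no biomass sample in "
                                   "neighbourhood, qO2 skipped")
            continue
        cx_by_pulse[i] = cx
        try:
            qo2, our = estimate_qo2(p, corrected, cx, kla, reactor)
            est.qo2.values.append(qo2)
            est.our.values.append(our)
        except Exception as e:  # noqa: BLE001
            est.diagnostics.append(f"pulse {i}: qO2 skipped ({e})")

    # stage 3: YO2/S from two-segment pulses
    for i, p in enumerate(pulses):
        if p.n_segments != 2:
            continue
        try:
            est.yo2s.values.append(estimate_yo2s(
                p, corrected, kla, reactor,
                baseline_return_fraction=config.baseline_return_fraction))
        except NotApplicableError as e:
            est.diagnostics.append(f"pulse {i}: YO2/S skipped ({e})")

    # stage 4: YO2/A from four-segment pulses (needs qs_ox_critical)
    qs_ox_max = est.qs_ox_critical
    if math.isfinite(qs_ox_max):
        for i, p in enumerate(pulses):
            if p.n_segments != 4 or i not in cx_by_pulse:
                continue
            try:
                est.yo2a.values.append(estimate_yo2a(
                    p, corrected, kla, reactor, qs_ox_max, yas,
                    cx_by_pulse[i]))
            except (NotApplicableError, DegeneratePulseError) as e:
                est.diagnostics.append(f"pulse {i}: YO2/A skipped ({e})")
    else:
        est.diagnostics.append("qs_ox_critical unavailable: YO2/A skipped")

    for i, p in enumerate(pulses):
        rows.append({"pulse_id": i, "feed_time_s": p.feed.time_s,
                     "n_segments": p.n_segments,
                     "kla_per_h": kla_by_pulse.get(i, math.nan),
                     "cx_mg_ml": cx_by_pulse.get(i, math.nan),
                     "flags": ",".join(sorted(p.flags))})
    return WorkflowResult(est, pd.DataFrame(rows), pulses, corrected)
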