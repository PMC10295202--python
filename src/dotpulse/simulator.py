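"""Event-driven simulation of glucose/acetate metabolism and DOT dynamics.

The culture response to a glucose bolus is modelled as a piecewise-
continuous ODE system with four metabolic states:

* **I — glucose oxidation with overflow.** Total uptake follows Monod
  kinetics, qs = qs_max·Cs/(Cs+Ks); the oxidative share is capped at the
  critical rate qO2max/YO2S and the excess is excreted as acetate with
  yield YA/S.
* **II — adaptation.** After glucose depletion, if enough acetate has
  accumulated (above ``ca_threshold``), all rates are scaled by (1 − Rt)
  for an adaptation interval Δt; with the default Rt = 1 the metabolism
  pauses completely.  Δt is either a constant or the acetate/biomass
  relation Δt = t_adap_max · (CA/CA_max) · (Cx_max/Cx).
* **III — acetate oxidation.** Acetate is oxidised at up to the critical
  rate qO2max/YO2A.
* **IV — static.** No metabolic activity; DOT relaxes to saturation.

Dissolved oxygen obeys dDOT/dt = OTR − OUR = (DOT* − DOT)·KLa −
(YO2S·qs_ox + YO2A·qA_ox)·H·Cx, and the probe reading DOTm follows DOT
with a first-order lag τ.  State switches are located exactly by the
integrator's event detection and the sub-model is restarted, so the event
log gives the precise metabolic switching times.  Feeds are instantaneous
jumps in Cs and V with dilution of the other concentrations.

Internal time unit is hours (rate constants are per hour); the public
interface speaks seconds.  Depletion events fire at small positive
concentrations (Monod tails reach zero only asymptotically); the truncated
residuals are tracked in the mass bookkeeping so conservation checks close
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError
from .physiology import ReactorParams
from .segmentation import SegmentationConfig, segment_run
from .trace import DotTrace, FeedEvent, FeedSchedule, SensorModel, SECONDS_PER_HOUR

STATE_I, STATE_II, STATE_III, STATE_IV = "I", "II", "III", "IV"


@dataclass(frozen=True)
class CellParams:
    """Kinetic and stoichiometric cell parameters.

    Defaults reproduce a low-acetate *E. coli* BL21-like strain in an
    8 mL minibioreactor: qO2max and the yields are reactor-E midpoints of
    the retrieval analysis, and qs_max is calibrated so that a single
    bolus into 8 mL at Cx = 10 mg/mL acquires the adaptation segment just
    above 5 µL.

    qo2_max : maximum specific oxygen uptake rate [g O2/(g DCW·h)]
    qs_max : maximum total glucose uptake capacity [g/(g·h)]
    ks, ka : Monod affinities for glucose and acetate [g/L]
    ko : optional oxygen Monod constant [% DOT]; None disables the
        oxygen-limitation factor DOT/(DOT+KO) on oxidative rates
    yo2s, yo2a : oxygen yields on glucose / acetate [g/g]
    yas : acetate yield on overflowed glucose [g/g]
    yxs, yxa : biomass yields on glucose / acetate [g/g] (used only when
        growth is enabled)
    qa_max : maximum acetate uptake rate [g/(g·h)]; None means full
        oxidative capacity qO2max/YO2A
    """

    qo2_max: float = 0.16
    qs_max: float = 4.2
    ks: float = 0.02
    ka: float = 0.001
    ko: float | None = None
    yo2s: float = 0.075
    yo2a: float = 0.15
    yas: float = 0.667
    yxs: float = 0.5
    yxa: float = 0.4
    qa_max: float | None = None

    def __post_init__(self):
        for name in ("qo2_max", "qs_max", "ks", "ka", "yo2s", "yo2a",
                     "yas", "yxs", "yxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qs_max <= self.qs_ox_critical:
            raise ValueError(
                "qs_max must exceed qO2max/YO2S so overflow is possible")

    @property
    def qs_ox_critical(self) -> float:
        """Maximum oxidative glucose uptake [g/(g·h)]."""
        return self.qo2_max / self.yo2s

    @property
    def qa_ox_critical(self) -> float:
        """Maximum oxidative acetate uptake [g/(g·h)]."""
        return self.qo2_max / self.yo2a

    @property
    def qa_cap(self) -> float:
        return self.qa_max if self.qa_max is not None else self.qa_ox_critical


@dataclass(frozen=True)
class AdaptationParams:
    """Adaptation-state (metabolic pause) configuration.

    mode : 'none', 'constant' (Δt = dt_const_s) or 'variable'
        (Δt = t_adap_max·(CA/CA_max)·(Cx_max/Cx))
    rt : fraction by which rates are reduced during the pause (1 = full stop)
    ca_threshold : acetate concentration [mg/mL] above which the pause is
        entered at glucose depletion
    """

    mode: str = "variable"
    dt_const_s: float = 30.0
    rt: float = 1.0
    t_adap_max_s: float = 60.0
    ca_max: float = 0.5
    cx_max: float = 25.0
    ca_threshold: float = 0.1

    def __post_init__(self):
        if self.mode not in ("none", "constant", "variable"):
            raise ValueError(f"unknown adaptation mode {self.mode!r}")
        if not (0.0 <= self.rt <= 1.0):
            raise ValueError("rt must be in [0, 1]")
        for name in ("dt_const_s", "t_adap_max_s", "ca_max", "cx_max",
                     "ca_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimState:
    """Instantaneous simulator state (concentrations in mg/mL, t in hours)."""

    t_h: float = 0.0
    cs: float = 0.0
    ca: float = 0.0
    cx: float = 10.0
    v_ml: float = 8.0
    dot: float = 100.0
    dotm: float = 100.0
    state: str = STATE_IV
    adaptation_deadline_h: float | None = None


@dataclass(frozen=True)
class Rates:
    """Specific rates [g/(g·h)]: uptake splits, oxygen, growth."""

    qs_ox: float
    qs_of: float
    qa_ox: float
    qo2: float
    mu: float


@dataclass(frozen=True)
class SimEvent:
    t_s: float
    from_state: str
    to_state: str
    trigger: str


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the event-driven integration."""

    cs_event_mg_ml: float = 1e-3
    ca_event_mg_ml: float = 1e-5
    rtol: float = 1e-9
    atol: float = 1e-12
    method: str = "LSODA"


@dataclass
class SimResult:
    """Dense trajectory plus the metabolic-state event log."""

    time_s: np.ndarray
    cs: np.ndarray
    ca: np.ndarray
    cx: np.ndarray
    v_ml: np.ndarray
    dot: np.ndarray
    dotm: np.ndarray
    state: np.ndarray  # array of state labels
    events: list[SimEvent]
    bookkeeping: dict
    dotstar: float = 100.0

    def trace_dotm(self, reactor_id: str = "sim") -> DotTrace:
        return DotTrace(self.time_s, self.dotm, reactor_id=reactor_id,
                        dotstar=self.dotstar, note="simulated DOTm")

    def trace_dot(self, reactor_id: str = "sim") -> DotTrace:
        return DotTrace(self.time_s, self.dot, reactor_id=reactor_id,
                        dotstar=self.dotstar, note="simulated DOT")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "cs_mg_ml": self.cs,
                             "ca_mg_ml": self.ca, "cx_mg_ml": self.cx,
                             "v_ml": self.v_ml, "dot_pct": self.dot,
                             "dotm_pct": self.dotm, "state": self.state})

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"time_s": e.t_s, "from": e.from_state,
                              "to": e.to_state, "trigger": e.trigger}
                             for e in self.events])


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def adaptation_time(ca: float, cx: float, params: AdaptationParams) -> float:
    """Adaptation-state duration Δt [s].

    Variable mode: Δt = t_adap_max · (CA/CA_max) · (Cx_max/Cx); acetate
    prolongs the pause, biomass shortens it.  Constant mode returns the
    configured constant; mode 'none' returns 0.
    """
    if params.mode == "none":
        return 0.0
    if params.mode == "constant":
        return params.dt_const_s
    if cx <= 0:
        raise ValueError("Cx must be positive for the variable adaptation time")
    return params.t_adap_max_s * (ca / params.ca_max) * (params.cx_max / cx)


def rates(state: SimState, cell: CellParams,
          adapt: AdaptationParams) -> Rates:
    """Specific rates for the current metabolic state."""
    q = _rates_raw(state.state, state.cs, state.ca, state.dot, cell, adapt)
    return Rates(*q)


# Smooth oxygen-availability clamp: oxidative uptake vanishes as DOT -> 0,
# which keeps the DOT trajectory non-negative without a discontinuous floor
# (a hard floor stalls the stiff integrator).  Small enough (0.01 % DOT) to
# be invisible at the depressions the calibrated model reaches.
DOT_FLOOR_PCT = 0.01


def _o2_factor(dot: float, cell: CellParams) -> float:
    d = max(dot, 0.0)
    f = d / (d + DOT_FLOOR_PCT)
    if cell.ko is not None:
        f *= d / (d + cell.ko)
    return f


def _rates_raw(label: str, cs: float, ca: float, dot: float,
               cell: CellParams, adapt: AdaptationParams):
    """(qs_ox, qs_of, qa_ox, qo2, mu); all clamped at zero."""
    cs, ca = max(cs, 0.0), max(ca, 0.0)
    fo2 = _o2_factor(dot, cell)
    qs_ox = qs_of = qa_ox = 0.0
    if label == STATE_I:
        qs = cell.qs_max * cs / (cs + cell.ks) if cs > 0 else 0.0
        qs_ox = min(qs, cell.qs_ox_critical) * fo2
        qs_of = qs - qs_ox
    elif label in (STATE_II, STATE_III):
        qa = cell.qa_cap * ca / (ca + cell.ka) if ca > 0 else 0.0
        qa_ox = min(qa, cell.qa_ox_critical) * fo2
        if label == STATE_II:
            qa_ox *= (1.0 - adapt.rt)
    # STATE_IV: everything stays zero
    qo2 = cell.yo2s * qs_ox + cell.yo2a * qa_ox
    mu = cell.yxs * qs_ox + cell.yxa * qa_ox
    return qs_ox, qs_of, qa_ox, qo2, mu


# ---------------------------------------------------------------------------
# event-driven integration
# ---------------------------------------------------------------------------

# y = [cs, ca, cx, dot, dotm, m_glu_ox, m_glu_of, m_ace_ox, m_otr]
_N_Y = 9


def _make_rhs(label: str, cell: CellParams, adapt: AdaptationParams,
              reactor: ReactorParams, v_ml: float, tau_h: float,
              growth: bool):
    h_const = reactor.h_pct_l_per_g
    kla = reactor.kla_per_h
    dotstar = reactor.dotstar

    def rhs(t, y):
        cs, ca, cx, dot, dotm = y[0], y[1], y[2], y[3], y[4]
        qs_ox, qs_of, qa_ox, qo2, mu = _rates_raw(label, cs, ca, dot,
                                                  cell, adapt)
        dcs = -(qs_ox + qs_of) * cx
        dca = qs_of * cell.yas * cx - qa_ox * cx
        dcx = mu * cx if growth else 0.0
        otr = (dotstar - dot) * kla
        ddot = otr - qo2 * h_const * cx
        if dot <= 0.0 and ddot < 0.0:
            ddot = 0.0  # hard floor: no oxygen left to take up
        ddotm = (dot - dotm) / tau_h if tau_h > 0 else ddot
        return [dcs, dca, dcx, ddot, ddotm,
                qs_ox * cx * v_ml, qs_of * cx * v_ml, qa_ox * cx * v_ml,
                otr * v_ml / h_const]

    return rhs


def _fragment_events(label: str, adapt: AdaptationParams,
                     opts: SolverOptions):
    evts = []
    if label == STATE_I:
        def glucose_gone(t, y):
            return y[0] - opts.cs_event_mg_ml
        glucose_gone.terminal = True
        glucose_gone.direction = -1
        glucose_gone.trigger = "glucose_depleted"
        evts.append(glucose_gone)
    if label == STATE_III or (label == STATE_II and adapt.rt < 1.0):
        def acetate_gone(t, y):
            return y[1] - opts.ca_event_mg_ml
        acetate_gone.terminal = True
        acetate_gone.direction = -1
        acetate_gone.trigger = "acetate_depleted"
        evts.append(acetate_gone)
    return evts


def step_events(state: SimState, cell: CellParams, adapt: AdaptationParams,
                reactor: ReactorParams, sensor: SensorModel,
                t_until_s: float, growth: bool = False,
                opts: SolverOptions = SolverOptions(),
                output_dt_s: float = 1.0):
    """Integrate from ``state`` until the next metabolic event or t_until.

    Returns (trajectory DataFrame fragment, new SimState, SimEvent or
    None).  The fragment covers grid points in [t, t_event) at the output
    step; the returned state sits exactly at the event/stop time.
    """
    frames, events, state = _advance(state, cell, adapt, reactor, sensor,
                                     t_until_s / SECONDS_PER_HOUR, growth,
                                     opts, output_dt_s, {},
                                     single_step=True)
    frag = _assemble_fragment(frames)
    return frag, state, (events[0] if events else None)


def _advance(state: SimState, cell, adapt, reactor, sensor, t_stop_h,
             growth, opts, output_dt_s, book, single_step=False):
    """March the hybrid system until t_stop_h (no feeds in this span)."""
    tau_h = sensor.tau_s / SECONDS_PER_HOUR
    dt_h = output_dt_s / SECONDS_PER_HOUR
    frames = []
    events: list[SimEvent] = []
    guard = 0
    while state.t_h < t_stop_h - 1e-15:
        guard += 1
        if guard > 10000:
            raise IntegrationError("event loop did not converge", state)
        # immediate (zero-length) transitions
        if state.state == STATE_I and state.cs <= opts.cs_event_mg_ml:
            state, ev = _leave_state_i(state, cell, adapt, opts, book)
            events.append(ev)
            if single_step:
                return frames, events, state
            continue
        if state.state == STATE_III and state.ca <= opts.ca_event_mg_ml:
            state, ev = _exhaust_acetate(state, opts, book)
            events.append(ev)
            if single_step:
                return frames, events, state
            continue
        t_end = t_stop_h
        deadline_hit = False
        if state.state == STATE_II and state.adaptation_deadline_h is not None:
            if state.adaptation_deadline_h <= state.t_h + 1e-15:
                state, ev = _end_adaptation(state, opts, book)
                events.append(ev)
                if single_step:
                    return frames, events, state
                continue
            if state.adaptation_deadline_h < t_end:
                t_end = state.adaptation_deadline_h
                deadline_hit = True
        y0 = [state.cs, state.ca, state.cx, state.dot, state.dotm,
              0.0, 0.0, 0.0, 0.0]
        rhs = _make_rhs(state.state, cell, adapt, reactor, state.v_ml,
                        tau_h, growth)
        evts = _fragment_events(state.state, adapt, opts)
        sol = solve_ivp(rhs, (state.t_h, t_end), y0, method=opts.method,
                        events=evts or None, rtol=opts.rtol, atol=opts.atol,
                        dense_output=True)
        if sol.status < 0:
            raise IntegrationError(f"integration failed: {sol.message}", state)
        t_frag_end = float(sol.t[-1])
        # sample the dense solution on the output grid
        i0 = int(np.ceil(round(state.t_h / dt_h, 6)))
        i1 = int(np.floor(round(t_frag_end / dt_h, 6)))
        tg = np.arange(i0, i1 + 1) * dt_h
        tg = tg[(tg >= state.t_h - 1e-12) & (tg <= t_frag_end + 1e-12)]
        if tg.size:
            yg = sol.sol(tg)
            frames.append((tg, yg, state.state, state.v_ml))
        y_end = sol.y[:, -1] if sol.status == 0 else sol.sol(t_frag_end)
        # accumulate mass bookkeeping
        book["glu_ox_mg"] = book.get("glu_ox_mg", 0.0) + float(y_end[5])
        book["glu_of_mg"] = book.get("glu_of_mg", 0.0) + float(y_end[6])
        book["ace_ox_mg"] = book.get("ace_ox_mg", 0.0) + float(y_end[7])
        book["otr_mg"] = book.get("otr_mg", 0.0) + float(y_end[8])
        state = replace(state, t_h=t_frag_end, cs=float(y_end[0]),
                        ca=float(y_end[1]), cx=float(y_end[2]),
                        dot=float(y_end[3]), dotm=float(y_end[4]))
        triggered = None
        if sol.status == 1:
            for f, te in zip(evts, sol.t_events):
                if te.size:
                    triggered = f.trigger
                    break
        if triggered == "glucose_depleted":
            state, ev = _leave_state_i(state, cell, adapt, opts, book)
            events.append(ev)
            if single_step:
                return frames, events, state
        elif triggered == "acetate_depleted":
            from_ii = state.state == STATE_II
            state, ev = _exhaust_acetate(state, opts, book)
            events.append(ev)
            if single_step:
                return frames, events, state
        elif deadline_hit and abs(t_frag_end - t_end) < 1e-12:
            state, ev = _end_adaptation(state, opts, book)
            events.append(ev)
            if single_step:
                return frames, events, state
    return frames, events, state


def _leave_state_i(state: SimState, cell, adapt, opts, book):
    """Glucose depleted: route to adaptation, acetate oxidation or rest."""
    book["glu_residual_mg"] = book.get("glu_residual_mg", 0.0) \
        + max(state.cs, 0.0) * state.v_ml
    t_s = state.t_h * SECONDS_PER_HOUR
    if adapt.mode != "none" and state.ca > adapt.ca_threshold:
        dt_s = adaptation_time(state.ca, state.cx, adapt)
        new = replace(state, cs=0.0, state=STATE_II,
                      adaptation_deadline_h=state.t_h + dt_s / SECONDS_PER_HOUR)
        return new, SimEvent(t_s, STATE_I, STATE_II, "glucose_depleted")
    if state.ca > opts.ca_event_mg_ml:
        new = replace(state, cs=0.0, state=STATE_III,
                      adaptation_deadline_h=None)
        return new, SimEvent(t_s, STATE_I, STATE_III, "glucose_depleted")
    book["ace_residual_mg"] = book.get("ace_residual_mg", 0.0) \
        + max(state.ca, 0.0) * state.v_ml
    new = replace(state, cs=0.0, ca=0.0, state=STATE_IV,
                  adaptation_deadline_h=None)
    return new, SimEvent(t_s, STATE_I, STATE_IV, "glucose_depleted")


def _end_adaptation(state: SimState, opts, book):
    t_s = state.t_h * SECONDS_PER_HOUR
    if state.ca > opts.ca_event_mg_ml:
        new = replace(state, state=STATE_III, adaptation_deadline_h=None)
        return new, SimEvent(t_s, STATE_II, STATE_III, "adaptation_elapsed")
    book["ace_residual_mg"] = book.get("ace_residual_mg", 0.0) \
        + max(state.ca, 0.0) * state.v_ml
    new = replace(state, ca=0.0, state=STATE_IV, adaptation_deadline_h=None)
    return new, SimEvent(t_s, STATE_II, STATE_IV, "adaptation_elapsed")


def _exhaust_acetate(state: SimState, opts, book):
    book["ace_residual_mg"] = book.get("ace_residual_mg", 0.0) \
        + max(state.ca, 0.0) * state.v_ml
    t_s = state.t_h * SECONDS_PER_HOUR
    new = replace(state, ca=0.0, state=STATE_IV, adaptation_deadline_h=None)
    return new, SimEvent(t_s, state.state, STATE_IV, "acetate_depleted")


def _assemble_fragment(frames):
    if not frames:
        return pd.DataFrame(columns=["time_s", "cs_mg_ml", "ca_mg_ml",
                                     "cx_mg_ml", "v_ml", "dot_pct",
                                     "dotm_pct", "state"])
    parts = []
    for tg, yg, label, v in frames:
        parts.append(pd.DataFrame({
            "time_s": tg * SECONDS_PER_HOUR, "cs_mg_ml": yg[0],
            "ca_mg_ml": yg[1], "cx_mg_ml": yg[2], "v_ml": v,
            "dot_pct": yg[3], "dotm_pct": yg[4], "state": label}))
    return pd.concat(parts, ignore_index=True)


def _apply_feed(state: SimState, feed: FeedEvent, book,
                h_pct_l_per_g: float) -> SimState:
    dv = feed.volume_ul * 1e-3  # mL
    v_new = state.v_ml + dv
    dilution = state.v_ml / v_new
    cs = (state.cs * state.v_ml + feed.mass_mg) / v_new
    book["fed_mg"] = book.get("fed_mg", 0.0) + feed.mass_mg
    # DOT is left unchanged across the jump, so the added volume carries
    # dissolved oxygen with it; book it as a source for the O2 balance.
    book["o2_fed_mg"] = book.get("o2_fed_mg", 0.0) \
        + state.dot * dv / h_pct_l_per_g
    return replace(state, cs=cs, ca=state.ca * dilution,
                   cx=state.cx * dilution, v_ml=v_new, state=STATE_I,
                   adaptation_deadline_h=None)


def simulate_experiment(schedule: FeedSchedule, initial: SimState,
                        cell: CellParams, adapt: AdaptationParams,
                        reactor: ReactorParams,
                        sensor: SensorModel = SensorModel(),
                        t_end_s: float | None = None,
                        output_dt_s: float = 1.0, growth: bool = False,
                        opts: SolverOptions = SolverOptions()) -> SimResult:
    """Chain the event-driven integration across all feed events.

    ``initial`` supplies concentrations and volume at t = 0 (its metabolic
    state is re-derived from the concentrations).  The horizon defaults to
    one mean feed interval past the last feed, or can be given explicitly.
    """
    feeds = sorted(schedule.events, key=lambda e: e.time_s)
    if t_end_s is None:
        if not feeds:
            raise ValueError("give t_end_s when the schedule is empty")
        gap = (feeds[-1].time_s - feeds[0].time_s) / max(len(feeds) - 1, 1)
        t_end_s = feeds[-1].time_s + max(gap, 600.0)
    t_end_h = t_end_s / SECONDS_PER_HOUR
    label = (STATE_I if initial.cs > opts.cs_event_mg_ml else
             STATE_III if initial.ca > opts.ca_event_mg_ml else STATE_IV)
    state = replace(initial, t_h=0.0, state=label)
    book: dict = {"fed_mg": 0.0, "initial": (state.cs, state.ca, state.cx,
                                             state.v_ml, state.dot)}
    frames = []
    events: list[SimEvent] = []
    for feed in feeds:
        tf_h = feed.time_s / SECONDS_PER_HOUR
        if tf_h > t_end_h:
            break
        f, e, state = _advance(state, cell, adapt, reactor, sensor, tf_h,
                               growth, opts, output_dt_s, book)
        frames += f
        events += e
        pre = state.state
        state = _apply_feed(state, feed, book, reactor.h_pct_l_per_g)
        events.append(SimEvent(feed.time_s, pre, STATE_I, "feed"))
    f, e, state = _advance(state, cell, adapt, reactor, sensor, t_end_h,
                           growth, opts, output_dt_s, book)
    frames += f
    events += e
    book["final"] = (state.cs, state.ca, state.cx, state.v_ml, state.dot)
    traj = _assemble_fragment(frames)
    # final grid point (the horizon itself) if not already sampled
    if traj.empty or traj["time_s"].iloc[-1] < t_end_s - 1e-9:
        traj = pd.concat([traj, pd.DataFrame({
            "time_s": [state.t_h * SECONDS_PER_HOUR],
            "cs_mg_ml": [state.cs], "ca_mg_ml": [state.ca],
            "cx_mg_ml": [state.cx], "v_ml": [state.v_ml],
            "dot_pct": [state.dot], "dotm_pct": [state.dotm],
            "state": [state.state]})], ignore_index=True)
    traj = traj.drop_duplicates(subset="time_s", keep="last")
    return SimResult(
        time_s=traj["time_s"].to_numpy(), cs=traj["cs_mg_ml"].to_numpy(),
        ca=traj["ca_mg_ml"].to_numpy(), cx=traj["cx_mg_ml"].to_numpy(),
        v_ml=traj["v_ml"].to_numpy(), dot=traj["dot_pct"].to_numpy(),
        dotm=traj["dotm_pct"].to_numpy(), state=traj["state"].to_numpy(),
        events=events, bookkeeping=book, dotstar=reactor.dotstar)


def conservation_report(result: SimResult, cell: CellParams) -> dict:
    """Relative closure errors of the glucose/acetate/oxygen balances.

    Includes the depletion-event residuals that the integrator truncates,
    so a correct simulation closes to the solver tolerance.
    """
    b = result.bookkeeping
    cs0, ca0, cx0, v0, dot0 = b["initial"]
    cs1, ca1, cx1, v1, dot1 = b["final"]
    fed = b.get("fed_mg", 0.0)
    glu_ox = b.get("glu_ox_mg", 0.0)
    glu_of = b.get("glu_of_mg", 0.0)
    ace_ox = b.get("ace_ox_mg", 0.0)
    glu_res = b.get("glu_residual_mg", 0.0)
    ace_res = b.get("ace_residual_mg", 0.0)
    otr = b.get("otr_mg", 0.0)
    glu_in = fed + cs0 * v0
    glu_out = glu_ox + glu_of + glu_res + cs1 * v1
    ace_in = ca0 * v0 + cell.yas * glu_of
    ace_out = ace_ox + ace_res + ca1 * v1
    scale_g = max(glu_in, 1e-12)
    scale_a = max(ace_in, 1e-12)
    return {
        "glucose_rel_err": (glu_in - glu_out) / scale_g,
        "acetate_rel_err": (ace_in - ace_out) / scale_a,
        "glucose_fed_mg": fed, "glucose_oxidised_mg": glu_ox,
        "glucose_overflowed_mg": glu_of, "acetate_oxidised_mg": ace_ox,
        "oxygen_transferred_mg": otr,
    }


def oxygen_balance_error(result: SimResult, cell: CellParams,
                         reactor: ReactorParams) -> float:
    """Relative error of ∫OUR·V dt vs the stoichiometric oxygen demand.

    OUR is inferred from the DOT equation: ∫OUR·V = ∫OTR·V − Δ(DOT·V)/H,
    which must equal YO2S·(glucose oxidised) + YO2A·(acetate oxidised).
    """
    b = result.bookkeeping
    cs0, ca0, cx0, v0, dot0 = b["initial"]
    cs1, ca1, cx1, v1, dot1 = b["final"]
    h = reactor.h_pct_l_per_g
    inventory = (dot1 * v1 - dot0 * v0) / h  # mg
    our_int = b.get("otr_mg", 0.0) + b.get("o2_fed_mg", 0.0) - inventory
    demand = cell.yo2s * b.get("glu_ox_mg", 0.0) \
        + cell.yo2a * b.get("ace_ox_mg", 0.0)
    return (our_int - demand) / max(demand, 1e-12)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    threshold_ul: float | None
    table: pd.DataFrame  # columns: volume_ul, n_segments


def find_segment_threshold(volumes_ul, cx_mg_ml: float, cell: CellParams,
                           adapt: AdaptationParams, reactor: ReactorParams,
                           sensor: SensorModel = SensorModel(),
                           conc_mg_ml: float = 600.0,
                           feed_time_s: float = 60.0,
                           horizon_s: float = 900.0,
                           output_dt_s: float = 1.0,
                           config: SegmentationConfig | None = None
                           ) -> ThresholdResult:
    """Smallest bolus volume whose measured pulse has four segments.

    Simulates one bolus per volume into a resting culture at the given
    biomass, segments the simulated probe signal DOTm, and reports the
    segment count per volume plus the smallest four-segment volume (None
    if the sweep never produces one).
    """
    rows = []
    threshold = None
    for v in volumes_ul:
        schedule = FeedSchedule([FeedEvent(feed_time_s, float(v), conc_mg_ml)])
        initial = SimState(cs=0.0, ca=0.0, cx=cx_mg_ml, v_ml=reactor.v_ml,
                           dot=reactor.dotstar, dotm=reactor.dotstar)
        res = simulate_experiment(schedule, initial, cell, adapt, reactor,
                                  sensor, t_end_s=feed_time_s + horizon_s,
                                  output_dt_s=output_dt_s)
        pulses = segment_run(res.trace_dotm(), schedule, config)
        n = pulses[0].n_segments if pulses else 0
        rows.append({"volume_ul": float(v), "n_segments": n})
        if n == 4 and threshold is None:
            threshold = float(v)
    return ThresholdResult(threshold, pd.DataFrame(rows))
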