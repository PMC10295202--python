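"""Data model and I/O for dissolved-oxygen-tension (DOT) traces.

A DOT trace is a timestamped series of oxygen saturation values (% air
saturation) logged by an optical probe in a minibioreactor.  This module
holds the in-memory containers (trace, bolus feed schedule, at-line sample
table, first-order sensor model), CSV readers for the plain tabular files
these loggers produce, and the signal-conditioning primitives every
downstream step relies on: uniform resampling, local-polynomial smoothing
and derivative estimation, and inversion of the probe's first-order lag

    DOT(t) = tau * dDOTm/dt + DOTm(t)

which recovers the actual liquid-phase DOT from the measured signal DOTm.

Time is seconds everywhere in this module; rate constants quoted per hour
are converted at the API boundary (see :func:`per_hour_to_per_second`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import EmptyTraceError, FormatError, NonUniformError

SECONDS_PER_HOUR = 3600.0


def per_hour_to_per_second(x: float) -> float:
    """Convert a first-order rate constant from 1/h to 1/s."""
    return x / SECONDS_PER_HOUR


def per_second_to_per_hour(x: float) -> float:
    """Convert a first-order rate constant from 1/s to 1/h."""
    return x * SECONDS_PER_HOUR


@dataclass
class DotTrace:
    """One reactor run's DOT measurement series.

    Parameters
    ----------
    time : array of float
        Seconds from run start; strictly increasing, at least 2 points.
    dot : array of float
        % air saturation.  Values outside [0, dotstar] are kept (they are
        measurement noise, and clipping would bias slope estimates) but
        counted in :attr:`n_out_of_range`.
    reactor_id : str
        Label of the reactor/run the trace belongs to.
    dotstar : float
        Saturation value DOT* in % air saturation.
    """

    time: np.ndarray
    dot: np.ndarray
    reactor_id: str = ""
    dotstar: float = 100.0
    note: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.dot = np.asarray(self.dot, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.dot.shape:
            raise FormatError("time and dot must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise EmptyTraceError(f"trace needs >= 2 points, got {self.time.size}")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.dot)):
            raise FormatError("time and dot must be finite")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")
        if np.any(self.time < 0):
            raise FormatError("time must be non-negative")

    @property
    def n_out_of_range(self) -> int:
        """Number of samples below 0 or above DOT* (flagged, never clipped)."""
        return int(np.sum((self.dot < 0.0) | (self.dot > self.dotstar)))

    @property
    def dt(self) -> float | None:
        """Sampling interval in seconds if uniform, else None."""
        steps = np.diff(self.time)
        if np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            return float(steps[0])
        return None

    @property
    def is_uniform(self) -> bool:
        return self.dt is not None

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    def replace_dot(self, dot: np.ndarray, note: str | None = None) -> "DotTrace":
        return DotTrace(self.time.copy(), np.asarray(dot, dtype=float),
                        reactor_id=self.reactor_id, dotstar=self.dotstar,
                        note=self.note if note is None else note)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "dot_pct": self.dot})


@dataclass(frozen=True)
class FeedEvent:
    """One bolus: injection time [s], volume [µL], glucose conc [mg/mL]."""

    time_s: float
    volume_ul: float
    conc_mg_ml: float = 600.0

    def __post_init__(self):
        if self.volume_ul <= 0:
            raise FormatError(f"feed volume must be > 0, got {self.volume_ul}")
        if self.conc_mg_ml <= 0:
            raise FormatError(f"feed concentration must be > 0, got {self.conc_mg_ml}")

    @property
    def mass_mg(self) -> float:
        """Glucose mass delivered by the bolus [mg]."""
        return self.volume_ul * 1e-3 * self.conc_mg_ml


@dataclass
class FeedSchedule:
    """Ordered bolus feed events for one run."""

    events: list[FeedEvent] = field(default_factory=list)

    def __post_init__(self):
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise FormatError("feed event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_s for e in self.events])

    @property
    def total_volume_ul(self) -> float:
        return float(sum(e.volume_ul for e in self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": [e.time_s for e in self.events],
             "volume_ul": [e.volume_ul for e in self.events],
             "conc_mg_ml": [e.conc_mg_ml for e in self.events]})


@dataclass
class SampleTable:
    """At-line samples: biomass Cx, glucose Cs, acetate CA [mg/mL].

    Missing analytes are NaN.  Concentrations must be >= 0 when present.
    """

    time_s: np.ndarray
    cx_mg_ml: np.ndarray | None = None
    cs_mg_ml: np.ndarray | None = None
    ca_mg_ml: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = self.time_s.size
        for name in ("cx_mg_ml", "cs_mg_ml", "ca_mg_ml"):
            v = getattr(self, name)
            if v is None:
                v = np.full(n, np.nan)
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise FormatError(f"{name} length must match time")
            if np.any(v[np.isfinite(v)] < 0):
                raise FormatError(f"{name} must be >= 0 where present")
            setattr(self, name, v)

    def __len__(self) -> int:
        return self.time_s.size

    def nearest_cx(self, t: float, max_distance_s: float) -> float | None:
        """Biomass of the sample closest to time t, if within the window."""
        finite = np.isfinite(self.cx_mg_ml)
        if not finite.any():
            return None
        times, cx = self.time_s[finite], self.cx_mg_ml[finite]
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) <= max_distance_s:
            return float(cx[i])
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "cx_mg_ml": self.cx_mg_ml,
                             "cs_mg_ml": self.cs_mg_ml, "ca_mg_ml": self.ca_mg_ml})


@dataclass(frozen=True)
class SensorModel:
    """First-order optical-probe lag, time constant tau [s] (default 36)."""

    tau_s: float = 36.0

    def __post_init__(self):
        if self.tau_s < 0:
            raise FormatError("sensor time constant must be >= 0")


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_trace(path, time_col: str = "time_s", dot_col: str = "dot_pct",
               delimiter: str = ",", time_unit: str = "s",
               reactor_id: str = "", dotstar: float = 100.0) -> DotTrace:
    """Read a DOT trace from a delimited text file with a header row.

    Duplicate timestamps are collapsed by their mean; rows with non-finite
    values are dropped (a warning reports the count).  ``time_unit`` may be
    's', 'min' or 'h' and is converted to seconds.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    for col in (time_col, dot_col):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in {path} "
                              f"(have {list(df.columns)})")
    sub = df[[time_col, dot_col]].apply(pd.to_numeric, errors="coerce")
    n_bad = int(sub.isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} row(s) with non-finite values")
        sub = sub.dropna()
    factor = {"s": 1.0, "min": 60.0, "h": 3600.0}[time_unit]
    sub = sub.groupby(time_col, as_index=False).mean().sort_values(time_col)
    if len(sub) < 2:
        raise EmptyTraceError(f"{path}: fewer than 2 valid rows")
    return DotTrace(sub[time_col].to_numpy() * factor, sub[dot_col].to_numpy(),
                    reactor_id=reactor_id, dotstar=dotstar)


def read_feeds(path, time_col: str = "time_s", volume_col: str = "volume_ul",
               conc_col: str = "conc_mg_ml", delimiter: str = ",") -> FeedSchedule:
    """Read a bolus feed log (time [s], volume [µL], concentration [mg/mL])."""
    df = pd.read_csv(path, delimiter=delimiter)
    for col in (time_col, volume_col):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in {path}")
    conc = df[conc_col] if conc_col in df.columns else pd.Series(600.0, index=df.index)
    events = [FeedEvent(float(t), float(v), float(c))
              for t, v, c in zip(df[time_col], df[volume_col], conc)]
    events.sort(key=lambda e: e.time_s)
    return FeedSchedule(events)


def read_samples(path, delimiter: str = ",") -> SampleTable:
    """Read an at-line sample table; optional analytes may be blank."""
    df = pd.read_csv(path, delimiter=delimiter)
    if "time_s" not in df.columns:
        raise FormatError(f"column 'time_s' not found in {path}")
    def col(name):
        return df[name].to_numpy(dtype=float) if name in df.columns else None
    return SampleTable(df["time_s"].to_numpy(dtype=float),
                       cx_mg_ml=col("cx_mg_ml"), cs_mg_ml=col("cs_mg_ml"),
                       ca_mg_ml=col("ca_mg_ml"))


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------

def resample_uniform(trace: DotTrace, dt: float) -> DotTrace:
    """Linearly interpolate onto a uniform grid spanning the trace.

    Endpoints are preserved; if the span is not an exact multiple of ``dt``
    the final point is appended so the last timestamp survives.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if trace.span < dt:
        raise ValueError(f"dt={dt} exceeds trace span {trace.span}")
    n = int(np.floor(trace.span / dt + 1e-9))
    grid = trace.time[0] + dt * np.arange(n + 1)
    if grid[-1] < trace.time[-1] - 1e-9 * dt:
        grid = np.append(grid, trace.time[-1])
    dot = np.interp(grid, trace.time, trace.dot)
    return DotTrace(grid, dot, reactor_id=trace.reactor_id,
                    dotstar=trace.dotstar, note=trace.note)


def _require_uniform(trace: DotTrace) -> float:
    dt = trace.dt
    if dt is None:
        raise NonUniformError(
            "trace is not uniformly sampled; call resample_uniform first")
    return dt


def _check_window(n: int, window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < 3 or window > n:
        raise ValueError(f"window must be odd and in [3, {n}], got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")


def smooth(trace: DotTrace, window: int = 11, polyorder: int = 2) -> DotTrace:
    """Savitzky-Golay smoothed copy of the trace (endpoints: one-sided fits)."""
    _require_uniform(trace)
    _check_window(trace.time.size, window, polyorder)
    sm = savgol_filter(trace.dot, window, polyorder, mode="interp")
    return trace.replace_dot(sm)


def smooth_derivative(trace: DotTrace, window: int = 11,
                      polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay first derivative dDOT/dt in %/s, same length as input.

    Requires uniform sampling; endpoints use the one-sided polynomial fits
    of the boundary windows ('interp' mode).
    """
    dt = _require_uniform(trace)
    _check_window(trace.time.size, window, polyorder)
    return savgol_filter(trace.dot, window, polyorder, deriv=1, delta=dt,
                         mode="interp")


def invert_sensor_delay(measured: DotTrace, sensor: SensorModel,
                        window: int = 11, polyorder: int = 2) -> DotTrace:
    """Recover the actual DOT from the measured trace.

    Applies DOT = tau * dDOTm/dt + DOTm with a smoothed derivative.  With
    tau = 0 the input is returned unchanged.
    """
    if sensor.tau_s == 0:
        return measured
    ddt = smooth_derivative(measured, window=window, polyorder=polyorder)
    return measured.replace_dot(measured.dot + sensor.tau_s * ddt,
                                note="delay-corrected")


def apply_sensor_delay(trace: DotTrace, sensor: SensorModel,
                       dotm0: float | None = None) -> DotTrace:
    """Forward-simulate the first-order probe on an actual-DOT trace.

    Integrates dDOTm/dt = (DOT - DOTm)/tau exactly on each sampling
    interval under linear interpolation of DOT.  Used as the independent
    oracle for the inversion round trip.
    """
    if sensor.tau_s == 0:
        return trace
    t, x = trace.time, trace.dot
    y = np.empty_like(x)
    y[0] = x[0] if dotm0 is None else dotm0
    tau = sensor.tau_s
    for i in range(1, t.size):
        h = t[i] - t[i - 1]
        a = np.exp(-h / tau)
        slope = (x[i] - x[i - 1]) / h
        # exact response to a linear input segment
        y[i] = x[i] - slope * tau + (y[i - 1] - x[i - 1] + slope * tau) * a
    return trace.replace_dot(y, note="sensor-delayed")
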