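"""Feed-pulse detection and four-segment labelling of DOT traces.

Each glucose bolus in an intermittently fed culture produces a negative
DOT pulse.  Visually a pulse has up to four segments:

* S1 - sharp decline: glucose oxidation at full capacity plus overflow,
* S2 - plateau or slight rise: the metabolic adaptation pause between
  glucose exhaustion and full-capacity acetate oxidation,
* S3 - second, gentler decline: oxidation of the accumulated acetate,
* S4 - recovery to the saturation value, transfer-dominated.

Small boluses produce only S1 and S4.  The classifier works on the
Savitzky-Golay smoothed slope: samples are labelled steep-down, moderate-
down, flat or up against per-run thresholds, run-length encoded, and the
runs are mapped onto the canonical S1(,S2,S3),S4 structure.  The slope
thresholds are trained per run from the distribution of each feed
interval's steepest decline, so the same configuration adapts to reactors
with different transfer rates and biomass loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePulseError, UndefinedCorrelationError
from .trace import DotTrace, FeedEvent, FeedSchedule, smooth_derivative, smooth

# slope classes
_STEEP, _MOD, _FLAT, _UP = 0, 1, 2, 3
_DOWN_CLASSES = (_STEEP, _MOD)

S1, S2, S3, S4 = "S1", "S2", "S3", "S4"


@dataclass
class SegmentationConfig:
    """Tuning parameters of the segmentation state machine.

    steep_slope_quantile
        Quantile of the per-feed-interval steepest-decline distribution
        used as the steep threshold (the "training" step).
    flat_band_fraction
        Half-width of the flat band as a fraction of |steep threshold|.
    min_segment_duration
        Runs shorter than this [s] are merged into a neighbour.
    s2_min_duration
        Minimum duration [s] of the non-declining interlude accepted as an
        adaptation segment; must be at least the smoothing support so that
        genuine pauses are separated from the brief glucose-to-acetate
        handoff rounding.
    baseline_return_fraction
        A pulse ends when DOT recovers to this fraction of its pre-feed
        baseline (sustained until the next feed).
    bottom_epsilon
        Tolerance [%] used to place the recovery start at the end of the
        flat pulse bottom rather than its first sample.
    """

    steep_slope_quantile: float = 0.5
    flat_band_fraction: float = 0.15
    min_segment_duration: float = 4.0
    s2_min_duration: float = 10.0
    baseline_return_fraction: float = 0.95
    bottom_epsilon: float = 0.5
    s3_min_drop_fraction: float = 0.2
    window: int = 11
    polyorder: int = 2
    response_horizon_s: float = 120.0
    baseline_lookback_s: float = 10.0

    def __post_init__(self):
        if not (0 < self.steep_slope_quantile < 1):
            raise ValueError("steep_slope_quantile must be in (0, 1)")
        if not (0 < self.flat_band_fraction < 1):
            raise ValueError("flat_band_fraction must be in (0, 1)")
        if not (0 < self.baseline_return_fraction < 1):
            raise ValueError("baseline_return_fraction must be in (0, 1)")
        if self.min_segment_duration <= 0:
            raise ValueError("min_segment_duration must be > 0")


@dataclass(frozen=True)
class SlopeThresholds:
    """Per-run trained slope thresholds [%/s]; steep < 0 < flat."""

    steep: float
    flat: float


@dataclass
class PulseWindow:
    """A candidate feed-response window (indices into the run trace)."""

    feed: FeedEvent
    i_start: int
    i_end: int  # inclusive
    baseline: float
    no_response: bool = False
    truncated: bool = False

    @property
    def n(self) -> int:
        return self.i_end - self.i_start + 1


@dataclass
class Segment:
    """One labelled sub-interval of a pulse with its descriptive metrics.

    slope is the endpoint slope (DOT_end - DOT_start)/duration [%/s];
    area_under is the trapezoidal integral of DOT over the segment [%.s];
    area_depression integrates (DOT* - DOT) instead, so the two always sum
    to DOT* times the duration.
    """

    label: str
    t_start: float
    t_end: float
    dot_start: float
    dot_end: float
    area_under: float
    area_depression: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def slope(self) -> float:
        return (self.dot_end - self.dot_start) / self.duration


@dataclass
class Pulse:
    """A segmented feed-response pulse."""

    feed: FeedEvent
    t_start: float
    t_end: float
    segments: list[Segment]
    baseline: float
    dot_min: float
    flags: set[str] = field(default_factory=set)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def segment(self, label: str) -> Segment | None:
        for s in self.segments:
            if s.label == label:
                return s
        return None

    @property
    def area_under(self) -> float:
        return float(sum(s.area_under for s in self.segments))

    @property
    def area_depression(self) -> float:
        return float(sum(s.area_depression for s in self.segments))

    def validate(self) -> set[str]:
        """Soft consistency checks; returns (and records) warning flags."""
        warn = set()
        s1, s3, s4 = self.segment(S1), self.segment(S3), self.segment(S4)
        if s1 is not None and s1.slope >= 0:
            warn.add("s1-slope-nonnegative")
        if s4 is not None and s4.slope <= 0:
            warn.add("s4-slope-nonpositive")
        if s3 is not None:
            if s3.slope >= 0:
                warn.add("s3-slope-nonnegative")
            if s1 is not None and s1.slope >= s3.slope:
                warn.add("s1-not-steeper-than-s3")
        self.flags |= warn
        return warn


# ---------------------------------------------------------------------------
# training and detection
# ---------------------------------------------------------------------------

def train_thresholds(trace: DotTrace, feeds: FeedSchedule,
                     config: SegmentationConfig) -> SlopeThresholds:
    """Estimate per-run slope thresholds from the feed-interval declines.

    For every feed interval the steepest smoothed slope is collected; the
    configured quantile of that (negative) distribution becomes the steep
    threshold and the flat band is a fraction of its magnitude.
    """
    sdot = smooth_derivative(trace, config.window, config.polyorder)
    t = trace.time
    bounds = list(feeds.times) + [t[-1] + 1.0]
    steepest = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        m = (t >= t0) & (t < t1)
        if m.sum() >= 2:
            steepest.append(float(np.min(sdot[m])))
    if not steepest:
        raise DegeneratePulseError("no feed intervals overlap the trace")
    steep = float(np.quantile(steepest, config.steep_slope_quantile))
    if steep >= 0:
        steep = min(steepest)  # run with no real declines; keep sign sane
    flat = config.flat_band_fraction * abs(steep)
    return SlopeThresholds(steep=steep, flat=flat)


def detect_pulses(trace: DotTrace, feeds: FeedSchedule,
                  config: SegmentationConfig | None = None,
                  thresholds: SlopeThresholds | None = None) -> list[PulseWindow]:
    """Locate one feed-response window per bolus.

    A window opens at the last sample before the post-feed decline onset
    and closes at sustained baseline recovery (DOT back above the
    configured fraction of the pre-feed baseline, and staying there until
    the next feed) or at the next feed event, whichever is earlier.  Feeds
    without a detectable decline are flagged ``no_response``.
    """
    config = config or SegmentationConfig()
    if len(feeds) == 0:
        raise ValueError("feed schedule is empty")
    if thresholds is None:
        thresholds = train_thresholds(trace, feeds, config)
    t = trace.time
    dt = trace.dt
    sdot = smooth_derivative(trace, config.window, config.polyorder)
    dot_sm = smooth(trace, config.window, config.polyorder).dot
    n_back = max(1, int(round(config.baseline_lookback_s / dt)))
    windows: list[PulseWindow] = []
    feed_idx = np.searchsorted(t, feeds.times)
    for k, feed in enumerate(feeds):
        i_feed = int(feed_idx[k])
        if i_feed >= t.size:
            continue
        limit = int(feed_idx[k + 1]) if k + 1 < len(feeds) else t.size
        limit = min(limit, t.size)
        baseline = float(np.median(trace.dot[max(0, i_feed - n_back):i_feed + 1]))
        horizon = min(limit, i_feed + int(round(config.response_horizon_s / dt)) + 1)
        decline = np.nonzero(sdot[i_feed:horizon] < -thresholds.flat)[0]
        if decline.size == 0:
            windows.append(PulseWindow(feed, i_feed, min(horizon, t.size) - 1,
                                       baseline, no_response=True))
            continue
        onset = i_feed + int(decline[0])
        i_start = max(i_feed, onset - 1)
        thresh = config.baseline_return_fraction * baseline
        recovered = dot_sm[onset:limit] >= thresh
        truncated = False
        if recovered.size and recovered[-1]:
            # first sample of the final sustained-recovery block
            below = np.nonzero(~recovered)[0]
            i_end = onset + (int(below[-1]) + 1 if below.size else 0)
        else:
            i_end = limit - 1
            truncated = True
        windows.append(PulseWindow(feed, i_start, i_end, baseline,
                                   truncated=truncated))
    return windows


# ---------------------------------------------------------------------------
# segmentation state machine
# ---------------------------------------------------------------------------

def _classify(sdot: np.ndarray, th: SlopeThresholds) -> np.ndarray:
    cls = np.full(sdot.shape, _FLAT, dtype=int)
    cls[sdot < th.steep] = _STEEP
    cls[(sdot >= th.steep) & (sdot < -th.flat)] = _MOD
    cls[sdot > th.flat] = _UP
    return cls


def _runs(cls: np.ndarray) -> list[list[int]]:
    """Run-length encode into [class, i0, i1) triples."""
    out = []
    i0 = 0
    for i in range(1, cls.size + 1):
        if i == cls.size or cls[i] != cls[i0]:
            out.append([int(cls[i0]), i0, i])
            i0 = i
    return out


def _merge_short_runs(runs: list[list[int]], min_samples: int) -> list[list[int]]:
    """Absorb runs shorter than min_samples into their longer neighbour."""
    runs = [r[:] for r in runs]
    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_samples:
            break
        left = runs[shortest - 1] if shortest > 0 else None
        right = runs[shortest + 1] if shortest < len(runs) - 1 else None
        if left is not None and (right is None or
                                 (left[2] - left[1]) >= (right[2] - right[1])):
            left[2] = runs[shortest][2]
            del runs[shortest]
        else:
            right[1] = runs[shortest][1]
            del runs[shortest]
        # coalesce identical neighbours
        i = 0
        while i < len(runs) - 1:
            if runs[i][0] == runs[i + 1][0]:
                runs[i][2] = runs[i + 1][2]
                del runs[i + 1]
            else:
                i += 1
    return runs


def _down_blocks(runs: list[list[int]]) -> list[tuple[int, int]]:
    """Merge adjacent declining runs into maximal [i0, i1) blocks."""
    blocks = []
    for cls, i0, i1 in runs:
        if cls in _DOWN_CLASSES:
            if blocks and blocks[-1][1] == i0:
                blocks[-1] = (blocks[-1][0], i1)
            else:
                blocks.append((i0, i1))
    return blocks


def _refine_boundary(sdot: np.ndarray, b: int, lo_limit: int, hi_limit: int,
                     span: int) -> int:
    """Move a provisional boundary onto the local slope-midpoint crossing.

    Slope-class changes fire where the smoothed derivative crosses a fixed
    band edge, which for unequal neighbouring slopes is systematically off
    the true corner.  The crossing of the midpoint between the slopes just
    left and just right of the boundary is centred on it; local medians
    (rather than whole-segment ones) keep curved segments - e.g. a decline
    that flattens onto its transfer-limited quasi-steady level - from
    dragging the reference away from the corner.
    """
    left_lo = max(lo_limit, b - 2 * span)
    right_hi = min(hi_limit, b + 2 * span)
    if b - left_lo < 2 or right_hi - b < 2:
        return b
    ml = float(np.median(sdot[left_lo:b]))
    mr = float(np.median(sdot[b:right_hi]))
    if ml == mr:
        return b
    target = 0.5 * (ml + mr)
    lo = max(lo_limit + 1, b - span)
    hi = min(hi_limit - 1, b + span)
    if hi <= lo:
        return b
    seg = sdot[lo:hi + 1]
    hits = np.nonzero(seg >= target)[0] if mr > ml else np.nonzero(seg <= target)[0]
    return lo + int(hits[0]) if hits.size else b


def _make_segment(label: str, t: np.ndarray, dot_raw: np.ndarray,
                  dot_sm: np.ndarray, i0: int, i1: int, dotstar: float,
                  fit_ends: bool = False, trim: int = 0) -> Segment:
    """Segment over samples [i0, i1] (inclusive, shared boundaries).

    With ``fit_ends`` the boundary DOT values are evaluated from a line
    fitted to the segment interior (corner rounding from the smoothing
    window then cancels out of the endpoint slope, which is exact for
    linear phases).  The recovery segment keeps plain smoothed reads
    because it is strongly curved.
    """
    au = float(np.trapezoid(dot_raw[i0:i1 + 1], t[i0:i1 + 1]))
    dur = float(t[i1] - t[i0])
    v0, v1 = float(dot_sm[i0]), float(dot_sm[i1])
    if fit_ends and (i1 - trim) - (i0 + trim) >= 3:
        core = slice(i0 + trim, i1 - trim + 1)
        coef = np.polyfit(t[core], dot_sm[core], 1)
        v0 = float(np.polyval(coef, t[i0]))
        v1 = float(np.polyval(coef, t[i1]))
    return Segment(label=label, t_start=float(t[i0]), t_end=float(t[i1]),
                   dot_start=v0, dot_end=v1,
                   area_under=au, area_depression=dotstar * dur - au)


def segment_pulse(trace: DotTrace, window: PulseWindow,
                  config: SegmentationConfig | None = None,
                  thresholds: SlopeThresholds | None = None) -> Pulse:
    """Label the segments of one detected pulse window.

    Samples are classified by smoothed slope, run-length encoded, short
    runs merged, and the declining blocks mapped onto the canonical
    structure: the leading decline is S1; if a non-declining interlude of
    at least ``s2_min_duration`` separates it from a second decline, the
    pair becomes S2 and S3; the remainder from the pulse bottom onward is
    S4.  Without a qualifying interlude the pulse has two segments.
    """
    config = config or SegmentationConfig()
    if window.no_response:
        raise DegeneratePulseError("cannot segment a no-response window")
    dt = trace.dt
    if window.n < 2 * max(2, int(round(config.min_segment_duration / dt))):
        p = Pulse(window.feed, trace.time[window.i_start],
                  trace.time[window.i_end], [], window.baseline,
                  float(np.min(trace.dot[window.i_start:window.i_end + 1])),
                  flags={"degenerate"})
        return p
    if thresholds is None:
        # standalone use: train on this window alone
        sd_all = smooth_derivative(trace, config.window, config.polyorder)
        steep0 = float(np.min(sd_all[window.i_start:window.i_end + 1]))
        q = config.steep_slope_quantile
        thresholds = SlopeThresholds(steep=q * steep0,
                                     flat=config.flat_band_fraction * abs(steep0))
    t = trace.time
    dot_raw = trace.dot
    dot_sm = smooth(trace, config.window, config.polyorder).dot
    sdot = smooth_derivative(trace, config.window, config.polyorder)
    a, b = window.i_start, window.i_end
    cls = _classify(sdot[a:b + 1], thresholds)
    min_samples = max(2, int(round(config.min_segment_duration / dt)))
    runs = _merge_short_runs(_runs(cls), min_samples)
    s2_min_samples = max(min_samples, int(round(config.s2_min_duration / dt)))
    # declines separated by less than a resolvable adaptation interlude are
    # one decline phase (noise or the glucose-to-acetate handoff rounding)
    blocks_rel = _down_blocks(runs)
    coalesced: list[tuple[int, int]] = []
    for blk in blocks_rel:
        if coalesced and blk[0] - coalesced[-1][1] < s2_min_samples:
            coalesced[-1] = (coalesced[-1][0], blk[1])
        else:
            coalesced.append(blk)
    blocks = [(a + i0, a + i1) for i0, i1 in coalesced]
    flags = set()
    if window.truncated:
        flags.add("truncated")
    if not blocks:
        return Pulse(window.feed, t[a], t[b], [], window.baseline,
                     float(np.min(dot_sm[a:b + 1])), flags | {"degenerate"})

    # S3 candidate: the first later decline that is long enough, separated
    # from the leading decline by a resolvable interlude, and that actually
    # descends a meaningful fraction of the pulse depression (this rejects
    # both noise runs and the small glucose-to-acetate handoff bump).
    depression = window.baseline - float(np.min(dot_sm[a:b + 1]))
    min_drop = config.s3_min_drop_fraction * max(depression, 0.0)
    s3_block = None
    for blk in blocks[1:]:
        if blk[0] - blocks[0][1] < s2_min_samples:
            continue
        if blk[1] - blk[0] < min_samples:
            continue
        drop = float(dot_sm[blk[0]] - np.min(dot_sm[blk[0]:blk[1]]))
        if drop >= min_drop:
            s3_block = blk
            break
    four = s3_block is not None
    segments: list[Segment] = []
    if four:
        # S1/S2 boundary: where the pause's rise begins.  A transfer-limited
        # decline flattens at its quasi-steady depression while glucose is
        # still being consumed, so the end of the declining run underestimates
        # the first segment; the first rising run inside the interlude (or,
        # failing that, the interlude's minimum) marks the metabolic pause.
        lo, hi = blocks[0][1] - a, s3_block[0] - a  # interlude, window-rel
        b1 = None
        for cls_r, i0, i1 in runs:
            if i0 >= lo and i1 <= hi and cls_r == _UP:
                b1 = a + i0
                break
        if b1 is None:
            rel = int(np.argmin(dot_sm[a + lo:a + hi + 1]))
            b1 = a + lo + rel
        b2 = s3_block[0]             # S2/S3 boundary: start of second decline
        span = config.window
        b1 = _refine_boundary(sdot, b1, a, b2, span)
        b2 = _refine_boundary(sdot, b2, b1, s3_block[1], span)
        # S3/S4 boundary: end of the flat pulse bottom after the 2nd decline
        region = slice(s3_block[0], b + 1)
        m = float(np.min(dot_sm[region]))
        at_bottom = np.nonzero(dot_sm[region] <= m + config.bottom_epsilon)[0]
        b3 = s3_block[0] + int(at_bottom[-1])
        b3 = max(b3, b2 + 1)
        if not (a < b1 < b2 < b3 < b):
            four = False
        else:
            trim = config.window // 2
            segments = [
                _make_segment(S1, t, dot_raw, dot_sm, a, b1, trace.dotstar,
                              fit_ends=True, trim=trim),
                _make_segment(S2, t, dot_raw, dot_sm, b1, b2, trace.dotstar,
                              fit_ends=True, trim=trim),
                _make_segment(S3, t, dot_raw, dot_sm, b2, b3, trace.dotstar,
                              fit_ends=True, trim=trim),
                _make_segment(S4, t, dot_raw, dot_sm, b3, b, trace.dotstar),
            ]
    if not four:
        region = slice(blocks[0][0], b + 1)
        m = float(np.min(dot_sm[region]))
        at_bottom = np.nonzero(dot_sm[region] <= m + config.bottom_epsilon)[0]
        b1 = blocks[0][0] + int(at_bottom[-1])
        b1 = min(max(b1, a + 1), b - 1)
        segments = [
            _make_segment(S1, t, dot_raw, dot_sm, a, b1, trace.dotstar,
                          fit_ends=True, trim=config.window // 2),
            _make_segment(S4, t, dot_raw, dot_sm, b1, b, trace.dotstar),
        ]
    pulse = Pulse(window.feed, t[a], t[b], segments, window.baseline,
                  float(np.min(dot_sm[a:b + 1])), flags)
    pulse.validate()
    return pulse


def segment_run(trace: DotTrace, feeds: FeedSchedule,
                config: SegmentationConfig | None = None) -> list[Pulse]:
    """Train thresholds, detect windows and segment every responsive pulse."""
    config = config or SegmentationConfig()
    thresholds = train_thresholds(trace, feeds, config)
    pulses = []
    for w in detect_pulses(trace, feeds, config, thresholds):
        if w.no_response:
            continue
        pulses.append(segment_pulse(trace, w, config, thresholds))
    return pulses


# ---------------------------------------------------------------------------
# metrics and correlations
# ---------------------------------------------------------------------------

def compute_metrics(pulse: Pulse, dotstar: float = 100.0) -> dict:
    """Flat record of the per-segment and whole-pulse descriptive metrics."""
    rec: dict = {
        "feed_time_s": pulse.feed.time_s,
        "feed_volume_ul": pulse.feed.volume_ul,
        "n_segments": pulse.n_segments,
        "pulse_duration_s": pulse.duration,
        "dot_min": pulse.dot_min,
        "pulse_area_under": pulse.area_under,
        "pulse_area_depression": pulse.area_depression,
        "flags": ",".join(sorted(pulse.flags)),
    }
    for s in pulse.segments:
        k = s.label.lower()
        rec[f"{k}_duration_s"] = s.duration
        rec[f"{k}_slope_pct_per_s"] = s.slope
        rec[f"{k}_area_under"] = s.area_under
        rec[f"{k}_area_depression"] = s.area_depression
    return rec


def metrics_table(pulses: list[Pulse], dotstar: float = 100.0) -> pd.DataFrame:
    return pd.DataFrame([compute_metrics(p, dotstar) for p in pulses])


def pulses_to_frame(pulses: list[Pulse]) -> pd.DataFrame:
    """One row per segment, the CSV layout of the ``segment`` subcommand."""
    rows = []
    for i, p in enumerate(pulses):
        for s in p.segments:
            rows.append({"pulse_id": i, "feed_time_s": p.feed.time_s,
                         "label": s.label, "t_start": s.t_start,
                         "t_end": s.t_end, "duration_s": s.duration,
                         "slope_pct_per_s": s.slope,
                         "area_under": s.area_under,
                         "area_depression": s.area_depression,
                         "flags": ",".join(sorted(p.flags))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    degenerate: bool = False


def correlate_metrics(metric: np.ndarray, covariate: np.ndarray) -> CorrelationResult:
    """Least-squares line, Pearson r and R² between a metric and a covariate.

    Pairs with non-finite entries are dropped; at least 3 pairs required.
    A zero-variance covariate is an error; a zero-variance metric yields a
    flagged r = 0 result.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(metric, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("covariate has zero variance")
    if np.ptp(y) == 0:
        return CorrelationResult(0.0, float(y[0]), 0.0, 0.0, int(x.size),
                                 degenerate=True)
    res = stats.linregress(x, y)
    return CorrelationResult(float(res.slope), float(res.intercept),
                             float(res.rvalue), float(res.rvalue ** 2),
                             int(x.size))


def dilution_ratio(volume_ul: float, working_volume_ml: float) -> float:
    """Bolus volume per working volume [µL/mL]."""
    if volume_ul <= 0:
        raise ValueError("bolus volume must be > 0")
    if working_volume_ml <= 0:
        raise ValueError("working volume must be > 0")
    return volume_ul / working_volume_ml
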