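"""Synthetic minibioreactor experiments: schedules, noise, ground truth.

Emulates an intermittently fed 8 mL *E. coli* cultivation: a bolus plan
from the eight-reactor design (volumes 5-8.5 µL every 4-30 min, 600 mg/mL
glucose), a mechanistic simulation of the culture, the probe's 36 s
first-order lag, ~1 s sampling and additive Gaussian sensor noise, plus a
small at-line sample table (five samples per run).  The generating
parameters are written next to the data so retrieval pipelines can be
scored against ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .physiology import ReactorParams
from .simulator import (AdaptationParams, CellParams, SimResult, SimState,
                        simulate_experiment)
from .trace import (DotTrace, FeedEvent, FeedSchedule, SampleTable,
                    SensorModel)

#: Table of the eight bolus feeding plans: volume [µL], interval [min].
FEEDING_PLANS: dict[str, tuple[float, float]] = {
    "A": (5.0, 30.0), "B": (5.5, 20.0), "C": (6.5, 12.0), "D": (6.5, 9.0),
    "E": (6.5, 9.0), "F": (8.5, 9.0), "G": (6.0, 4.0), "H": (7.5, 4.0),
}


@dataclass
class ExperimentSpec:
    """Specification of one synthetic run.

    Either name a ``plan`` (A-H) or give ``pulse_volume_ul`` and
    ``interval_min`` directly.  ``probe_every``/``probe_volume_ul``
    optionally replace every n-th bolus with a small probe bolus, so a run
    contains both two- and four-segment pulses (as real runs do).
    """

    plan: str | None = "E"
    pulse_volume_ul: float | None = None
    interval_min: float | None = None
    conc_mg_ml: float = 600.0
    horizon_h: float = 11.7
    v0_ml: float = 8.0
    cx0_mg_ml: float = 8.0
    cs0_mg_ml: float = 0.0
    ca0_mg_ml: float = 0.0
    noise_sigma_pct: float = 0.3
    dt_s: float = 1.0
    seed: int = 0
    n_samples: int = 5
    probe_every: int = 0
    probe_volume_ul: float = 2.0
    volume_jitter_ul: float = 0.0
    interval_jitter_s: float = 0.0

    def __post_init__(self):
        if self.plan is not None:
            if self.plan not in FEEDING_PLANS:
                raise ValueError(f"unknown plan {self.plan!r}; "
                                 f"choose from {sorted(FEEDING_PLANS)}")
            vol, interval = FEEDING_PLANS[self.plan]
            if self.pulse_volume_ul is None:
                self.pulse_volume_ul = vol
            if self.interval_min is None:
                self.interval_min = interval
        if self.pulse_volume_ul is None or self.interval_min is None:
            raise ValueError("give a plan or pulse_volume_ul + interval_min")
        if self.interval_min <= 0:
            raise ValueError("interval must be positive")
        if self.noise_sigma_pct < 0:
            raise ValueError("noise sigma must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def build_schedule(spec: ExperimentSpec,
                   rng: np.random.Generator | None = None) -> FeedSchedule:
    """Equidistant bolus events from t = 0 up to (and including) the horizon.

    Optional jitter perturbs volumes and intervals to emulate scheduling
    conflicts with sampling and titration tasks (off by default).
    """
    interval_s = spec.interval_min * 60.0
    horizon_s = spec.horizon_h * 3600.0
    times = np.arange(0.0, horizon_s + 1e-6, interval_s)
    volumes = np.full(times.size, float(spec.pulse_volume_ul))
    if spec.probe_every > 1:
        idx = np.arange(times.size)
        volumes[(idx + 1) % spec.probe_every == 0] = spec.probe_volume_ul
    if rng is not None and (spec.volume_jitter_ul > 0
                            or spec.interval_jitter_s > 0):
        if spec.interval_jitter_s > 0:
            times = times + rng.normal(0, spec.interval_jitter_s, times.size)
            times[0] = max(times[0], 0.0)
            times = np.sort(times)
        if spec.volume_jitter_ul > 0:
            volumes = np.maximum(
                volumes + rng.normal(0, spec.volume_jitter_ul, times.size),
                0.5)
    return FeedSchedule([FeedEvent(float(t), float(v), spec.conc_mg_ml)
                         for t, v in zip(times, volumes)])


@dataclass
class SynthExperiment:
    """A generated run: noisy measured trace, inputs, and ground truth."""

    trace: DotTrace
    feeds: FeedSchedule
    samples: SampleTable
    truth: dict
    result: SimResult
    spec: ExperimentSpec


def generate_experiment(spec: ExperimentSpec,
                        cell: CellParams = CellParams(),
                        adapt: AdaptationParams = AdaptationParams(),
                        reactor: ReactorParams = ReactorParams(),
                        sensor: SensorModel = SensorModel(),
                        growth: bool = True) -> SynthExperiment:
    """Simulate a run and emit its noisy measured trace plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    feeds = build_schedule(spec, rng)
    initial = SimState(cs=spec.cs0_mg_ml, ca=spec.ca0_mg_ml,
                       cx=spec.cx0_mg_ml, v_ml=spec.v0_ml,
                       dot=reactor.dotstar, dotm=reactor.dotstar)
    result = simulate_experiment(feeds, initial, cell, adapt, reactor,
                                 sensor, t_end_s=spec.horizon_h * 3600.0,
                                 output_dt_s=spec.dt_s, growth=growth)
    dotm = result.dotm.copy()
    if spec.noise_sigma_pct > 0:
        dotm = dotm + rng.normal(0.0, spec.noise_sigma_pct, dotm.size)
    trace = DotTrace(result.time_s, dotm, reactor_id=spec.plan or "custom",
                     dotstar=reactor.dotstar, note="synthetic measured DOT")
    # five at-line samples spread over the horizon, read off the truth
    frac = np.linspace(0.08, 0.95, spec.n_samples)
    sample_t = frac * spec.horizon_h * 3600.0
    idx = np.searchsorted(result.time_s, sample_t).clip(0, result.time_s.size - 1)
    samples = SampleTable(result.time_s[idx], cx_mg_ml=result.cx[idx],
                          cs_mg_ml=result.cs[idx], ca_mg_ml=result.ca[idx])
    truth = {
        "kla_per_h": reactor.kla_per_h,
        "qo2_max": cell.qo2_max,
        "yo2s": cell.yo2s,
        "yo2a": cell.yo2a,
        "yas": cell.yas,
        "qs_ox_critical": cell.qs_ox_critical,
        "qs_max": cell.qs_max,
        "tau_s": sensor.tau_s,
        "v0_ml": spec.v0_ml,
        "cx0_mg_ml": spec.cx0_mg_ml,
        "noise_sigma_pct": spec.noise_sigma_pct,
        "seed": spec.seed,
    }
    return SynthExperiment(trace, feeds, samples, truth, result, spec)


def plan_e_recovery_spec(seed: int = 0, horizon_h: float = 3.6,
                         noise_sigma_pct: float = 0.3) -> ExperimentSpec:
    """The designed parameter-recovery experiment.

    Reference plan (6.5 µL every 9 min) with every third bolus replaced by
    a 2 µL probe, so each run contains four-segment pulses (for KLa, qO2,
    YO2/A) and clean two-segment pulses (for YO2/S), mirroring the
    observation that both pulse types occur in every real run.
    """
    return ExperimentSpec(plan="E", horizon_h=horizon_h, seed=seed,
                          noise_sigma_pct=noise_sigma_pct, probe_every=3,
                          probe_volume_ul=2.0)


# ---------------------------------------------------------------------------
# on-disk form + manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to regenerate a synthetic run byte-identically."""

    files: dict = field(default_factory=dict)  # name -> sha256
    seed: int = 0
    config_hash: str = ""
    spec: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_experiment(exp: SynthExperiment, outdir,
                     cell: CellParams = CellParams(),
                     adapt: AdaptationParams = AdaptationParams(),
                     reactor: ReactorParams = ReactorParams()) -> RunManifest:
    """Write trace/feeds/samples CSVs, truth YAML and a manifest."""
    import dotpulse
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace.csv": exp.trace.to_frame(),
        "feeds.csv": exp.feeds.to_frame(),
        "samples.csv": exp.samples.to_frame(),
    }
    for name, df in paths.items():
        df.to_csv(out / name, index=False, float_format="%.10g")
    truth = dict(exp.truth)
    truth.update({"cell": asdict(cell), "adaptation": asdict(adapt),
                  "reactor": asdict(reactor)})
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    config = {"spec": exp.spec.to_dict(), "cell": asdict(cell),
              "adaptation": asdict(adapt), "reactor": asdict(reactor)}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    files = {name: _sha256(out / name)
             for name in [*paths, "truth.yaml"]}
    manifest = RunManifest(files=files, seed=exp.spec.seed,
                           config_hash=config_hash, spec=exp.spec.to_dict(),
                           versions={"dotpulse": dotpulse.__version__,
                                     "numpy": np.__version__})
    (out / "manifest.yaml").write_text(manifest.to_yaml())
    return manifest
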