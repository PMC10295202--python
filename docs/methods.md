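# Methods

`dotpulse` analyses the dissolved-oxygen-tension (DOT) signal of
intermittently fed *E. coli* minibioreactor cultivations.  Each glucose
bolus produces a negative DOT pulse; the package (i) segments those pulses,
(ii) retrieves reactor and cell-physiological parameters from the segments,
and (iii) simulates the pulses with a piecewise-continuous metabolic model
whose hallmark is an *adaptation state* — a brief pause of metabolic
activity between glucose exhaustion and full-capacity acetate oxidation
that produces a second signal segment.  A synthetic-experiment generator
closes the loop so the whole pipeline can be scored against known ground
truth without laboratory data.

## Signal model and units

DOT is expressed in % air saturation with saturation value DOT\*
(default 100 %).  The oxygen balance of the liquid phase is

    dDOT/dt = OTR − OUR
            = (DOT* − DOT)·KLa − (Y_O2/S·qs_ox + Y_O2/A·qA_ox)·H·Cx

where KLa [1/h] is the volumetric transfer coefficient, Cx [g/L] the
biomass, qs_ox and qA_ox [g/(g·h)] the oxidative glucose and acetate
uptake rates, Y_O2/S and Y_O2/A [g/g] the oxygen yields, and
H = DOT\*/C\*_O2,sat [%·L/g] converts dissolved-oxygen mass concentration
to saturation percent.  C\*_O2,sat defaults to 0.007 g/L (air-saturated
medium near cultivation temperature), giving H ≈ 14 286 %·L/g.  The probe
reads a first-order-lagged copy of the signal,

    dDOTm/dt = (DOT − DOTm)/τ,      τ = 36 s,

and the analysis inverts this lag with DOT = τ·dDOTm/dt + DOTm, using a
Savitzky–Golay derivative (default window 11 samples at 1 s sampling,
polynomial order 2; endpoints use the one-sided boundary fits).  Signal
processing works in seconds; the simulator works in hours internally and
converts at its interface.

## Metabolic model

Four states, switched exactly by event location inside the stiff
integrator (LSODA, rtol 1e-9, atol 1e-12):

* **I — glucose oxidation with overflow.**  Total uptake
  qs = qs_max·Cs/(Cs+Ks); the oxidative share is capped at the critical
  rate qs_ox ≤ qO2max/Y_O2/S and the excess is excreted as acetate with
  yield Y_A/S.
* **II — adaptation.**  Entered at glucose depletion when accumulated
  acetate exceeds `ca_threshold` (0.1 mg/mL).  All rates are scaled by
  (1 − Rt); the default Rt = 1 is a complete pause.  Duration is either a
  constant or the variable relation
  Δt = t_adap_max·(CA/CA_max)·(Cx_max/Cx) with t_adap_max = 60 s,
  CA_max = 0.5 mg/mL, Cx_max = 25 mg/mL: acetate prolongs the pause,
  biomass shortens it.
* **III — acetate oxidation** at up to qO2max/Y_O2/A with Monod affinity
  KA.
* **IV — static**: no uptake; DOT relaxes to saturation at rate KLa.

Feeds are instantaneous: Cs jumps by the bolus mass over the new volume,
other concentrations dilute by V/(V+ΔV), and the state resets to I.
Biomass growth (yields Y_X/S, Y_X/A) is integrated only when enabled; for
single-pulse analyses the biomass change over one pulse is negligible and
growth is off by default.

Numerical choices worth knowing:

* Depletion events fire at small positive concentrations
  (Cs: 1e-3 mg/mL, CA: 1e-5 mg/mL) because Monod tails reach zero only
  asymptotically; waiting for ~0 would insert a long zero-uptake interval
  inside state I that looks like a false adaptation segment.  The truncated
  residuals are tracked explicitly in the mass bookkeeping, so the
  glucose/acetate/oxygen balances close to the solver tolerance (checked to
  1e-6 relative in the tests).
* Oxidative rates carry a smooth oxygen-availability clamp
  DOT/(DOT + 0.01 %): uptake vanishes as DOT → 0, which keeps the
  trajectory non-negative under oxygen limitation without a discontinuous
  floor that stalls the integrator.  An optional Monod factor
  DOT/(DOT+KO) can be enabled via `CellParams.ko` for sensitivity studies;
  it is off by default because the analysis is insensitive to it at the
  depressions the calibrated model reaches.
* Cumulative masses (glucose oxidised/overflowed, acetate oxidised,
  oxygen transferred) are integrated as additional ODE states, so
  conservation checks are solver-accurate rather than quadrature-limited.

### Default parameters

| parameter | value | unit | rationale |
|---|---|---|---|
| KLa | 250 | 1/h | mid-range retrieval result for the reference reactor |
| qO2max | 0.16 | g O2/(g·h) | reference-reactor midpoint |
| Y_O2/S | 0.075 | g/g | reference-reactor midpoint |
| Y_O2/A | 0.15 | g/g | reference-reactor midpoint |
| Y_A/S | 0.667 | g/g | stoichiometry of glucose → 2 acetate |
| qs_max | 4.2 | g/(g·h) | calibrated: see below |
| Ks | 0.02 | g/L | high glucose affinity; keeps the overflow share volume-dependent |
| KA | 0.001 | g/L | near-zero-order acetate uptake: the third segment ends in a sharp corner, leaving the recovery transfer-dominated |
| Y_X/S, Y_X/A | 0.5, 0.4 | g/g | typical aerobic yields |
| τ | 36 | s | optical-probe response time |
| V, DOT\* | 8 mL, 100 % | | working volume and saturation |

qs_max is the one deliberately calibrated constant: it sets the overflow
fraction and therefore how much acetate a bolus of a given size leaves
behind.  It is chosen so that, at Cx = 10 mg/mL in 8 mL, a single bolus
crosses the adaptation threshold (CA > 0.1 mg/mL at glucose depletion)
just above 5 µL — the observed onset of four-segment pulses.  With
Ks = 0.02 g/L the overflow integral gives CA(5.0 µL) ≈ 0.097 and
CA(5.5 µL) ≈ 0.108 mg/mL at qs_max = 4.2, so the sweep flips between 5.0
and 5.5 µL.

## Segmentation

Up to four segments per pulse: S1 sharp decline (glucose oxidation +
overflow), S2 plateau/slight rise (adaptation pause), S3 second decline
(acetate oxidation), S4 recovery.

The classifier works on the smoothed slope of the (optionally
delay-corrected) signal.  Thresholds are trained per run: the steep
threshold is a quantile (default 0.5) of each feed interval's steepest
decline, and the flat band is a fraction (default 0.15) of its magnitude,
so the same configuration adapts across reactors.  Samples are classed
steep-down / moderate-down / flat / up, run-length encoded, and runs
shorter than `min_segment_duration` (4 s) merged into their longer
neighbour.

Pulse windows open at the last sample before the post-feed decline onset
and close at *sustained* recovery — the final contiguous block at or above
`baseline_return_fraction` (0.95) of the pre-feed baseline — or at the
next feed, in which case the pulse is flagged `truncated` and excluded
from transfer-rate estimation.

Mapping runs to segments:

* Declining blocks separated by less than `s2_min_duration` (10 s, about
  the smoothing support) are one decline phase.  This absorbs both noise
  runs and the small glucose-to-acetate handoff bump that is not an
  adaptation pause.
* The S3 candidate is the first later declining block that is separated
  from the leading decline by a resolvable interlude, lasts at least the
  minimum duration, and actually descends at least
  `s3_min_drop_fraction` (0.2) of the pulse depression.  Without a
  qualifying candidate the pulse has two segments, split at the end of
  the flat pulse bottom (`bottom_epsilon` = 0.5 %).
* The S1/S2 boundary is placed where the pause's rise begins (a
  transfer-limited decline flattens onto its quasi-steady level while
  glucose is still being consumed, so the end of the declining run would
  systematically underestimate S1).  Internal boundaries are then refined
  to the crossing of the midpoint between the local slopes on either
  side, which centres them on the true corner; on noise-free
  piecewise-linear pulses the recovered boundaries are within ±2 samples
  and endpoint slopes within a few percent of construction.
* Segment endpoint values for S1–S3 are evaluated from a line fitted to
  the segment interior (corner rounding from the smoothing window then
  cancels out of the endpoint slope); the strongly curved S4 keeps plain
  smoothed reads.

Segment metrics are the duration, the endpoint slope
(DOT_end − DOT_start)/ΔT, and the trapezoidal areas under DOT and under
the depression DOT\* − DOT (the two always sum to DOT\*·ΔT).  Both areas
are reported because the duration-weighted depression, not the raw area,
is what links to deposited oxygen.

## Parameter retrieval

Executed in the order KLa → qO2/qO2max → Y_O2/S → Y_O2/A; stage failures
are recorded per pulse and the workflow continues.

* **KLa** from S4, where dDOT/dt = (DOT\* − DOT)·KLa, i.e.
  KLa = −ln[(DOT\*−DOT_end)/(DOT\*−DOT_min)]/ΔT4.  The production
  estimator evaluates this law as a weighted least-squares fit of
  ln(DOT\* − DOT) against time over the recovery samples — identical in
  model, but insensitive to where noise places the endpoint crossings.
  The fit starts a quarter of the way up the recovery (the first seconds
  after the pulse bottom still carry residual substrate uptake) and stops
  at the baseline-return crossing (the saturation plateau carries no
  transfer information).  Weights come from a first-pass fit (inverse
  variance of the log of a noisy depression), not from the data, to avoid
  correlating weights with residuals.
* **qO2** from the oxygen balance over S1 on the delay-corrected signal:
  qO2 = [(DOT\*−DOT)·KLa − dDOT/dt]/(H·Cx), with the segment-mean DOT in
  the transfer term (an endpoint variant is available) and the endpoint
  slope of the actual signal — the exact time average of the balance.
  Only pulses within ±15 min of a biomass sample are evaluated;
  OUR = qO2·Cx and qO2max = max over S1-based estimates.  The sign
  convention is the physical balance (transfer minus accumulation); the
  equivalent "slope plus depression" form with a negative slope is the
  same quantity.
* **Y_O2/S** from two-segment pulses that returned to baseline: all
  transferred oxygen over the pulse window went into a known glucose
  mass, Y_O2/S = V·KLa·∫(DOT\*−DOT)dt / (H·Fs·Cs,in).  "Returned to
  baseline" means the pulse end lies within 2 % (of DOT\*) of
  `baseline_return_fraction` times the pre-feed baseline.
* **Y_O2/A** from four-segment pulses: the third segment's oxygen is
  integrated from the S3 start until the signal regains the S3-start
  level during the recovery.  With equal window-endpoint DOT values the
  dissolved-oxygen inventory cancels and the transfer integral equals the
  oxygen consumed inside the window, essentially all of it on acetate.
  The acetate mass is the overflow share of the bolus,
  (Fs·Cs,in − qs_ox,crit·Cx·V·ΔT1)·Y_A/S with
  qs_ox,crit = qO2max/Y_O2/S taken from the earlier stages.
* Aggregates are per-run mean ± one standard deviation.  KLa estimates
  outside the plausibility envelope 20–1440 1/h raise warnings, never
  errors.

The oxygen-percent integrals of the yield equations are converted to mass
through 1/H; without it the expressions are dimensionally open.

## Synthetic experiments

The generator emulates the laboratory setup: 8 mL initial volume,
600 mg/mL glucose feed, the eight bolus plans (5–8.5 µL every 4–30 min),
1 s sampling of the lagged probe signal, additive i.i.d. Gaussian sensor
noise (default σ = 0.3 % DOT), five at-line samples per run, and biomass
growth across the horizon.  The generating parameters are written next to
the data (`truth.yaml`), and a manifest with file hashes makes every run
byte-reproducible from its seed.

The designed *recovery experiment* (`plan_e_recovery_spec`) is the
reference plan with every third bolus replaced by a 2 µL probe, over a
3.6 h window (26 boluses).  Under the calibrated kinetics every 6.5 µL
bolus yields a four-segment pulse, so a pure reference-plan run would
contain no two-segment pulses and the Y_O2/S estimator (which needs them)
would have nothing to work on; the probes supply clean two-segment
pulses, mirroring the observation that both pulse types occur in every
real run.  The 3.6 h window is the package's chosen test scale — long
enough to average estimator noise over ~25 pulses, a deliberate
scale-down from full ~12 h cultivations.

What the generator does **not** emulate: end-of-run baseline drift
(viscosity-driven KLa decline), pH/titration events and their scheduling
conflicts with feeding (a jitter option exists but is off by default),
sampling-volume removal, sensor drift or calibration error, and analytical
noise on the at-line samples (they are exact).  Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artefact of real cultivations.

## Verification summary

The test suite checks, among others: exact mass/oxygen conservation
(1e-6 relative, with event residuals tracked); agreement of the
event-driven integration with a 10 ms fixed-step oracle (RMS < 0.1 % DOT);
lag-inversion round trips (<1 % RMS); segmentation boundary recovery on
constructed pulses (±3 samples); the 5–5.5 µL four-segment threshold; the
monotone growth of the adaptation segment with bolus volume and its
shrinkage with biomass; and recovery of KLa, qO2max, Y_O2/S and Y_O2/A on
seeded synthetic runs within 2 %, 15 %, 10 % and 20 % respectively.

## Known limitations

* The adaptation pause is all-or-nothing by default (Rt = 1); partial
  reductions are supported but untested against data.
* Y_O2/S from two-segment pulses inherits a small positive bias because
  even small boluses overflow a little and oxidising that acetate costs
  more oxygen per gram of glucose than the direct route; at the 2 µL probe
  volume this is a few percent.
* ΔT1-based acetate mass assumes uptake at the critical rate for the whole
  first segment; the Monod tail near depletion makes this a slight
  overestimate, partially offset by the estimated critical rate.
* Segment slopes of real (curved) phases are descriptive numbers, not
  model fits; only the S4 log-linear law and the S1 balance are used
  quantitatively.
* KLa is assumed constant within a run; viscosity-driven drift is out of
  scope.
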