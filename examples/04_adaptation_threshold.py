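"""Where does the adaptation segment appear, and how long does it last?

Sweeps single-bolus volumes at constant biomass and reports the smallest
volume whose simulated measured pulse carries the second and third
segments; then shows how the adaptation-segment length moves with bolus
volume and biomass, following Δt = t_max (CA/CA_max)(Cx_max/Cx).
"""

import numpy as np

import dotpulse as dp

cell, adapt, reactor = dp.CellParams(), dp.AdaptationParams(), dp.ReactorParams()

res = dp.find_segment_threshold(np.arange(1.0, 10.01, 0.5), 10.0, cell,
                                adapt, reactor)
print("bolus volume sweep at Cx = 10 mg/mL:")
print("  volumes [uL]:", " ".join(f"{v:g}" for v in res.table.volume_ul))
print("  segments:    ", " ".join(f"{n}" for n in res.table.n_segments))
print(f"  four-segment threshold: {res.threshold_ul:g} uL\n")


def s2_duration(volume, cx):
    schedule = dp.FeedSchedule([dp.FeedEvent(60.0, volume, 600.0)])
    init = dp.SimState(cs=0, ca=0, cx=cx, v_ml=8.0, dot=100, dotm=100)
    sim = dp.simulate_experiment(schedule, init, cell, adapt, reactor,
                                 dp.SensorModel(), t_end_s=1100.0)
    pulse = dp.segment_run(sim.trace_dotm(), schedule)[0]
    s2 = pulse.segment("S2")
    return s2.duration if s2 else 0.0


print("adaptation-segment duration [s]:")
for v in (3.0, 6.0, 9.0):
    print(f"  {v:3.0f} uL at Cx = 10 mg/mL: {s2_duration(v, 10.0):5.1f}")
for cx in (8.0, 10.0, 12.0):
    print(f"  9 uL at Cx = {cx:4.1f} mg/mL: {s2_duration(9.0, cx):5.1f}")

print("\nworked adaptation-time values from the relation itself:")
for ca, cx in ((0.5, 25.0), (0.25, 12.5), (0.1, 10.0)):
    print(f"  CA = {ca:4.2f} mg/mL, Cx = {cx:4.1f} mg/mL -> "
          f"dt = {dp.adaptation_time(ca, cx, adapt):5.1f} s")
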