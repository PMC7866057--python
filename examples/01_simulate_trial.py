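"""Generate a synthetic TUG trial and inspect its ground truth.

The simulator emulates the 3 m Timed Up and Go layout: sit, stand up,
walk out, turn 180 degrees, walk back, sit down — as seen simultaneously
by a 5 Hz UWB radar (range to the subject) and a 100 Hz instrumented
insole (anteroposterior acceleration + 3 FSR force channels).
"""

from tugkit import SimulationParams, simulate_tug

params = SimulationParams(seed=42)
radar, insole, truth = simulate_tug(params)

print(f"radar:  {len(radar)} samples at {params.radar_rate_hz:.0f} Hz, "
      f"range {radar.distance.min():.2f}-{radar.distance.max():.2f} m")
print(f"insole: {len(insole)} samples at {params.insole_rate_hz:.0f} Hz, "
      f"{insole.n_channels} FSR channels")
print()
print("ground-truth transition points (s):")
for name, t in zip(["t0", "t1", "t2", "t3", "t4", "t5"], truth.event_times):
    print(f"  {name} = {t:6.2f}")
print()
print(f"{truth.n_strides} strides ({truth.stride_labels}):")
for sl, st, lab in zip(truth.stride_lengths, truth.stride_times, truth.stride_labels):
    print(f"  {lab:<13} SL = {sl:.3f} m   ST = {st:.3f} s")

# t0..t5 bound the five activities (sit-to-stand, walk forward, turn,
# walk back, stand-to-sit); stride lengths sum to the walkway distance
# minus the standing offset in each direction.
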