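"""Detect strides from the insole's y-acceleration and validate with force.

The z-scored acceleration is median + zero-phase Butterworth filtered;
zero crossings set the locking period; each candidate peak is screened by
its drops to the flanking toe-off/heel-strike minima (PL, PR) and by the
admissible inter-peak gap.  Strides = valid peaks - 1.  The FSR total
force independently counts stance/swing cycles and locates the
sit-to-stand / stand-to-sit force ramps.
"""

from tugkit import (
    SimulationParams, detect_stride_peaks, detect_sts_phases, locking_period,
    lowpass_ay, normalize_recording, simulate_tug, validate_with_force,
)

_, insole, truth = simulate_tug(SimulationParams(seed=42))

norm = normalize_recording(insole)
ay = lowpass_ay(norm.ay, norm.sample_rate_hz)
crossings, lockp = locking_period(ay, norm.sample_rate_hz)
print(f"locking period: {lockp:.3f} s "
      f"(mean stride time / 4 = {truth.stride_times.mean() / 4:.3f} s)")

events = detect_stride_peaks(ay, norm.sample_rate_hz, lockp)
print(f"valid peaks: {int(events.valid.sum())}  ->  "
      f"{events.n_strides} strides (truth: {truth.n_strides})")
print("peak times vs true heel strikes (s):")
for p, hs in zip(events.valid_times, truth.heel_strikes):
    print(f"  {p:6.2f}   {hs:6.2f}")

check = validate_with_force(norm.total_force, events, norm.sample_rate_hz)
print(f"\nforce stance/swing cycles: {check.force_cycles}, "
      f"agreement with acceleration: {check.agreement}")

s2st, st2s = detect_sts_phases(norm.total_force, norm.sample_rate_hz)
print(f"sit-to-stand (force): {s2st[0]:.2f}-{s2st[1]:.2f} s, "
      f"stand-to-sit: {st2s[0]:.2f}-{st2s[1]:.2f} s")
# the force channel confirms the stride count and brackets the chair
# transfers without using the radar at all
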