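"""Score the risk of falling against a personal gait baseline.

A baseline (per-parameter mean and SD over all strides of several prior
trials) anchors the deviation scores: Sk = 100 - 10 * |z|, clamped at 0.
Equal-weighted parameter scores give the composite 0-100 TUG score,
read out in five risk bands.
"""

from tugkit import (
    SimulationParams, build_baseline, score_trial, simulate_tug,
    trial_parameters,
)

# baseline: five healthy trials of the same subject
tables = [
    trial_parameters(*simulate_tug(SimulationParams(seed=s))[:2])
    for s in range(5)
]
baseline = build_baseline(tables)
print("baseline (pooled over 5 trials):")
for name, entry in baseline.parameters.items():
    print(f"  {name:<20} mean {entry.mean:7.3f}  sd {entry.sd:.3f}")

# a normal follow-up trial vs a markedly slowed one
normal = trial_parameters(*simulate_tug(SimulationParams(seed=50))[:2])
slow = trial_parameters(*simulate_tug(SimulationParams(
    seed=51, stride_length_m=1.0, stride_time_s=1.5))[:2])

for label, trial in (("normal trial", normal), ("slowed trial", slow)):
    result = score_trial(trial, baseline)
    print(f"\n{label}: TUG score {result.tug_score:.1f} -> {result.risk_band} risk")
    for name, sk in result.parameter_scores.items():
        print(f"  {name:<20} Sk = {sk:6.1f}")
# shorter, slower strides push every parameter several SDs from baseline,
# dropping the composite score and the risk band accordingly
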