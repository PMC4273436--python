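"""Reciprocal-design performance indices.

Shows why reciprocal training matters: an innate odor bias alone yields a
zero performance index (it cancels between the two swapped-CS+ groups),
while a true learning effect survives the averaging.
"""

from flyvalence import (
    GroupCounts,
    ReciprocalExperiment,
    TmazeParams,
    simulate_tmaze,
    tmaze_pi,
    ymaze_pi,
)

# hand-built count table: group 1 had OCT paired with shock, group 2 MCH
exp = ReciprocalExperiment(
    group1=GroupCounts(cs_plus="OCT", counts={"OCT": 10, "MCH": 30}),
    group2=GroupCounts(cs_plus="MCH", counts={"OCT": 30, "MCH": 10}),
)
out = tmaze_pi(exp)
print(f"T-maze group indices {out['group_indices']}, PI = {out['pi']:+.2f}")

bias_only = simulate_tmaze(TmazeParams(n_flies=5000, bias=0.4, delta=0.0, seed=1))
print(f"bias 0.4 without learning -> PI = {tmaze_pi(bias_only)['pi']:+.3f} "
      "(innate bias cancels)")

learned = simulate_tmaze(TmazeParams(n_flies=5000, bias=0.4, delta=0.3, seed=2))
print(f"bias 0.4 with learning effect 0.3 -> PI = {tmaze_pi(learned)['pi']:+.3f} "
      "(the learning effect is what remains)")

y = ymaze_pi([(22, 8), (13, 17)])
idx = ", ".join(f"{v:+.3f}" for v in y["trial_indices"])
print(f"Y-maze reciprocal trials with indices ({idx}) -> "
      f"conditioned PI = {y['pi']:+.3f}")
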