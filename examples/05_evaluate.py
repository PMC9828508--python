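"""S-curves, true-vs-predicted tables and trajectory superposition.

After an active-learning run, per-configuration total prediction errors are
summarized as cumulative error curves: summing |atomic errors| gives the
pessimistic no-cancellation curve, while summing signed errors first lets
atomic mistakes offset (what a simulation consuming totals experiences).
"""

import numpy as np

from atomgpr import (ALConfig, ToyPESOracle, compute_alf, get_system,
                     run_active_learning, s_curve, superpose_trajectory,
                     total_prediction_error, true_vs_predicted)
from atomgpr.oracle import SamplerConfig, sample_configurations
from atomgpr.pso import SwarmConfig

geom, pes = get_system("water")
traj = sample_configurations(SamplerConfig(
    seed_geometry=geom, temperature=300.0, n_frames=400, seed=3))
oracle = ToyPESOracle(traj, pes)
result = run_active_learning(traj, oracle, ALConfig(
    mode="per_atom", batch_size=5, max_train=35, seed=3,
    swarm=SwarmConfig(n_particles=20, max_iter=60)))

alf = compute_alf(traj[0])
valid = result.states[(0,)].valid_idx
table = true_vs_predicted(result.models, traj, valid, oracle, alf)

atomic_err = np.column_stack(
    [table[f"true_atom_{a}"] - table[f"pred_atom_{a}"] for a in range(3)])
no_cancel = s_curve([total_prediction_error(r) for r in atomic_err])
cancel = s_curve([total_prediction_error(r, "cancellation")
                  for r in atomic_err], mode="cancellation")

print(f"validation configurations: {len(table)}")
for thresh in (0.01, 0.1, 1.0):
    print(f"  errors below {thresh:>5} kJ/mol: "
          f"no-cancellation {no_cancel.percentile_below(thresh):5.1f}%  "
          f"cancellation {cancel.percentile_below(thresh):5.1f}%")
r = np.corrcoef(table["true_total"], table["predicted_total"])[0, 1]
print(f"true vs predicted total energy: Pearson r = {r:.5f}")

sup = superpose_trajectory(traj, subset=[0, 1, 2])
spread = sup.coordinates().std(axis=0).max()
print(f"largest per-coordinate spread after Kabsch superposition: "
      f"{spread:.3f} A")
# The cancellation curve always sits at or left of the no-cancellation
# curve; the superposed spread visualizes how much configuration space the
# sampled trajectory covers.
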