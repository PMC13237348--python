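"""Behavioral costs and the connectivity-to-behavior validation layer.

Computes restart costs (first minus third post-cue target) and the switch
cost (first post-switch minus first post-repeat) from the simulated trial
table, then checks that the planted edge couplings predict first-target
reaction times: ranked Pearson correlations and a stepwise regression of
z-scored RTs on z-scored edge ground-truth gains.
"""

import numpy as np

from acgfc.behavior import compute_costs, rank_edge_rt_correlations, stepwise_regression
from acgfc.synth import default_study_config, make_connectome, simulate_epochs, simulate_trials

cfg = default_study_config(seed=5)
conn = make_connectome(cfg.n_nodes, cfg.n_edges, cfg.rewire_prob, seed=cfg.seed)
epochs, truth = simulate_epochs(conn, cfg)
trials, rt1 = simulate_trials(truth)

costs = compute_costs(trials)
print("behavioral costs (group means, paired tests across subjects):")
for key in ("restart_rt_repeat", "restart_rt_switch", "switch_rt_cost"):
    g = costs.group[key]
    print(f"  {key}: {g['mean']:.1f} ms (t={g['t']:.2f}, p={g['p']:.2g})")

# edge-level validation: realized gain per epoch on switch trials vs RT
sel = truth.labels == 1
gains = truth.realized_gain[sel][:, None] * np.ones((1, 3))
gains[:, 1:] += np.random.default_rng(0).normal(0, 0.3, gains[:, 1:].shape)  # decoys
ranked = rank_edge_rt_correlations(gains, rt1[sel])
print("\nedge-RT correlations (descending |r|):")
for _, row in ranked.iterrows():
    print(f"  candidate {row['edge']}: r = {row['r']:.3f}")

report = stepwise_regression(gains, rt1[sel], names=["planted", "decoy1", "decoy2"])
final = report.steps[-1]
print(f"\nstepwise regression selected {final['variables']} "
      f"(adjusted R^2 = {final['adj_r2']:.3f})")
print("the planted-gain regressor should rank first and be selected: the RT"
      " model ties behavior to the same couplings the attribution recovers.")
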