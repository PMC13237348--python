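"""Attribute the classifier's decision onto structural edges and test them.

Integrated Gradients treats each structural edge's adjacency entry as a
continuous input and integrates the decision-logit gradient from an
all-edges-zero baseline to the full template. Per epoch, scores are min-max
normalized across edges; the common-edge test (AP I) then asks which edges
carry systematically high values against a within-epoch reshuffling null,
and the differential test (AP II) asks which edges differ between switch
and repeat epochs under a label-permutation null. Both control FDR at 0.05.

This is the full pipeline at study scale; it takes a few minutes on one CPU.
"""

from acgfc.attribution import ap2_differential, attribute_epochs
from acgfc.experiments import planted_recovery_study

run = planted_recovery_study(seed=0, train_epochs=15, ig_steps=32, n_perm=2000)

print(f"held-out accuracy {run['accuracy']:.3f}, AUROC {run['auroc']:.3f}")
planted = set(run["truth"].planted_edges)
print(f"planted edges: {sorted(planted)}")

# AP II attributes the model's own decision (label-free target)
attr_pred = attribute_epochs(run["folds"], run["epochs"], run["connectome"],
                             steps=32, target="pred")
res2 = ap2_differential(attr_pred, n_perm=2000, seed=0)
labels = run["connectome"].atlas.labels
print(f"\ncommon edges recovered by AP I: {run['n_recovered']} "
      f"(precision {run['precision']:.2f}, recall {run['recall']:.2f})")

n_sig = int(res2.significant.sum())
planted_hits = [(i, j) for (i, j), d in zip(res2.edge_index, res2.direction)
                if d != 0 and (i, j) in planted]
print(f"\ndifferential edges flagged by AP II: {n_sig} of {len(res2.edge_index)}")
print(f"planted edges among them, with the correct 'switch > repeat' sign: "
      f"{len(planted_hits)} of {len(planted)}")
for i, j in planted_hits:
    print(f"  {labels[i]} - {labels[j]}")
# Precision/recall compare the recovered edge set against the planted one:
# the framework's core claim is that decision-relevant structural pathways
# can be read back out of the trained network, and AP I is the instrument
# that localizes them. AP II behaves diffusely in this extreme regime
# (coupling in one condition only): a planted edge's normalized value
# swings between ~1 and ~0 with the model's per-epoch decision — a
# high-variance signature the permutation test does not rank as extreme —
# while the min-max normalization spreads small but consistent shifts over
# the remaining edges, which do reach significance. Under a genuine null
# AP II holds its nominal 5% level (see the validation studies).
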