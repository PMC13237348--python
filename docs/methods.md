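# Methods

## Problem setting

Cued task-switching data: per trial, a cue announces whether the
stimulus–response rule repeats or switches, and the preparatory (cue-locked)
EEG interval carries condition-specific neural dynamics. After source
reconstruction, each epoch is a matrix of N ROI time courses. The package
consumes (a) a binary undirected structural connectome over the same ROIs,
(b) epoched ROI signals with binary condition labels and subject IDs, and
(c) a behavioral trial table. The scientific question is which structural
connections carry the condition-discriminating dynamics.

## The classifier

Per time step the node-feature matrix X_t is filtered with a K-order
Chebyshev expansion of the scaled graph Laplacian; the filtered features
pass a pointwise nonlinearity and drive a GRU whose weights are shared
across nodes; the final hidden states of all nodes are flattened into one
vector and mapped to two logits by a dense layer.

Choices that were genuinely open, and why they were made:

* **Self-loops before normalization** (Â = A + I): keeps isolated nodes
  well defined and is the standard stabilization for spectral filters.
* **Nonlinearity σ(z) = z² (default; ReLU available).** Band-limited
  oscillations carry condition information in second-order statistics
  (variances and cross-node covariances), not in means: squaring the
  spatially filtered signal makes a covariance difference linearly readable
  by the recurrent integrator, exactly as the square-then-average step in
  CSP-style oscillation decoding. With ReLU the same information is only
  accessible through saturation effects and training stalls near chance on
  covariance-coded data.
* **Flatten readout, not mean pooling.** Mean pooling over nodes makes the
  decision function node-permutation invariant but also blind to
  node-localized effects: with a handful of informative edges the pooled
  effect size caps held-out accuracy near 0.65 regardless of training,
  while the flattened readout reaches ~0.87 under identical conditions.
  The network up to the readout remains permutation *equivariant*; the
  equivariance is tested by permuting nodes and the readout blocks
  together.
* **Hyper-parameters not fixed by the problem**: K = 2, 16 filter
  channels, GRU width 16, AdaDelta (ρ = 0.95, ε = 10⁻⁶, lr 1.0), 15
  training epochs by default. Dropout 0.2 on the flattened representation,
  L2 weight decay λ = 5·10⁻⁴ applied to weight matrices (not biases) as
  (λ/2m)Σ‖W‖², mini-batch 32. All exposed in `TrainConfig`.
* **Numerics**: float32 parameters and activations by default (a `dtype`
  argument selects float64, used by the finite-difference gradient tests);
  gradients are hand-derived and verified against central differences to
  ~10⁻⁷ relative error.

Cross-validation is grouped by subject (shuffle subjects under the seed,
chunk into folds; ten folds of two subjects each at the default study
size), so reported metrics always measure generalization to unseen
participants. Baselines: a structure-free GRU consuming all node signals
as one flat vector, and a per-class MAR(1) model X_{t+1} = A_c X_t + ε
whose transition matrix is least-squares fitted only on structurally
connected pairs plus the diagonal, classified by Gaussian log-likelihood.

## Edge attribution

Each structural edge's adjacency entry is treated as a continuous input
w_e ∈ [0,1] scaling the off-diagonal entries of Â, with the degree
normalization and λ_max frozen at their full-template values; the scaled
Laplacian is then affine in w, so the gradient of any logit with respect
to w_e is a fixed linear functional of its gradient with respect to the
L̃ matrix (computed in the same hand-written backward pass). Integrated
Gradients integrates that gradient along the straight path from w = 0
(all edges absent) to w = 1 (full template) with a midpoint Riemann sum
(64 steps in pipelines, 256 in axiom checks; completeness holds to <1%
relative at 256 steps, and attribution is exactly closed-form for models
linear in L̃).

**The attributed logit differs between the two processes.** The
common-edge analysis (AP I) attributes the epoch's *true*-class logit: its
permutation null shuffles values across edges within an epoch and never
touches labels, and the true-class functional localizes planted edges far
more sharply (precision 0.88 vs 0.58 with the predicted-class target on
identical trained models — misclassified epochs otherwise attribute the
wrong logit and drag informative edges toward the low end of the per-epoch
min–max). The differential analysis (AP II) instead attributes the
*predicted*-class logit, a pure function of the input: a label-dependent
attribution would break the exchangeability its label-permutation null
relies on (measured type-I inflation ~15% vs. 5% nominal with the
true-class target). Attribution magnitude (|α|) was evaluated as a third
variant and rejected: it carries strong graph-position structure that
floods the common-edge test with false positives. Per epoch, raw edge
scores are min–max normalized to [0,1]; constant-score epochs normalize to
all zeros with a warning.

Significance:

* **AP I (common)**: statistic = per-edge mean value over all epochs;
  null = independent reshuffling of each epoch's values across template
  edges; one-sided p = (1 + #{null ≥ obs})/(n_perm + 1); BH-FDR.
* **AP II (differential)**: statistic = mean(switch) − mean(repeat);
  null = condition-label permutation with group sizes preserved;
  two-sided p; BH-FDR; sign reported on significant edges. A rank variant
  (edge values replaced by ranks across epochs before the same
  permutation) is provided; the mean-difference form is the default
  because the two condition groups are unpaired and of unequal size, which
  a signed-rank pairing cannot represent.

Each epoch is attributed with the model of the cross-validation fold that
held it out, so attribution never reflects a model that saw the epoch in
training.

## Conventional FC, masking, and network comparison

PLV = |mean e^{iΔφ}| and the unbiased PPC = (n·PLV² − 1)/(n − 1) are
computed from mirror-padded zero-phase band-pass (Butterworth order 4,
band 2–13 Hz by default) plus Hilbert phases; Coh and |ImCoh| are Welch
cross-spectra (segments T/2, 50% overlap, Hann) averaged over the band.
FC is estimated per epoch over the analysis window and averaged. Common-FC
significance uses circular-time-shift surrogates (each node shifted by an
independent random offset per epoch — autostructure preserved, cross-node
alignment destroyed); differential FC uses the same label-permutation
machinery as AP II. ACM-FC retains the significant pairs that are template
edges. PLI is available but off by default.

Network similarity: Jaccard on edge sets; Frobenius distance (for binary
symmetric zero-diagonal matrices FD = √(2·|AΔB|), so FD² is an even
integer); spectral distance as the Euclidean distance between
descending-sorted adjacency eigenvalue spectra (Laplacian spectra via an
option). The SPD null draws equal-size edge sets uniformly from the
template (a free-null variant samples all pairs); sparse draws are often
isospectral, and the output flags the fraction of the null mass sitting on
one value.

## GFP and behavior

GFP(t) is the spatial standard deviation across channels. Conditions are
compared with a paired t-test across subject-mean GFP curves at each time
point (the two conditions come from the same participants), BH-FDR over
time points, and maximal runs of significant samples are reported as
half-open [start, end) windows in ms. Behavioral costs follow the standard
definitions: restart cost = first − third post-cue target (RT and error
rate, per cue), switch cost = first post-switch − first post-repeat;
"correct" responses faster than 200 ms count as errors, and RT means use
correct trials only. Edge–behavior validation ranks Pearson correlations
between per-epoch edge values and first-target RT (pooling subjects'
trials) and runs stepwise regression (entry p ≤ 0.05, removal p ≥ 0.10,
classical defaults) on z-scored variables.

## The synthetic-study generator

The generator emulates the statistical structure the framework assumes,
with every planted quantity recorded as ground truth:

* **Connectome**: connected Watts–Strogatz graph at the nearest feasible
  even lattice degree, rewiring probability 0.1, then random edge
  additions/removals (avoiding bridges) to hit the exact edge count —
  default 68 nodes / 248 edges, density 0.109, small-world (σ > 1 against
  edge-matched random graphs).
* **Signals**: each node sums unit sinusoids at 3, 6 and 10 Hz (inside the
  2–13 Hz band) sampled at 100 Hz, with phases = subject-specific offset +
  per-epoch Gaussian jitter (sd 2.0 rad), plus white noise (sd 0.5).
  Trial-varying phase mirrors the partial phase locking of cue-locked
  oscillations; it is also what prevents a classifier from memorizing
  subject waveforms instead of learning the planted couplings.
* **Couplings**: for a planted edge (i, j) with gain g, the target node
  receives the variance-preserving mixture
  x_j ← (x_j + g·lag(x_i))/√(1+g²) (lag 2 samples by default). Variance
  preservation keeps node marginals uninformative, so condition
  information lives strictly in the pairwise dependence the edge carries —
  the premise the attribution method is supposed to detect. The injected
  variance share is g²/(1+g²). Differential edges use per-condition gains
  (default 2.0 in 'switch', 0.0 in 'repeat') with per-epoch gain jitter
  (sd 0.2); the canonical study plants 8 such edges.
* **Behavior**: first-target RT = 560 ms − 100·(gain fluctuation around
  the condition mean) + 75 ms switch cost + noise (sd 40 ms); positions 2
  and 3 relax toward the intercept minus a 60 ms restart cost; 4% errors.
  Tying the slope to the within-condition fluctuation keeps mean RTs
  governed by the switch cost while trial-level RT variability tracks the
  realized coupling strength.

What the generator does **not** emulate: volume conduction and field
spread, 1/f background spectra, non-stationary artifacts, biophysical
neural-mass dynamics, or subject-level gain heterogeneity. Passing tests
therefore show that the pipeline recovers planted linear lagged couplings
under realistic phase variability — not that it is robust to every
property of real source-reconstructed EEG.

## Validation studies and problem sizes

The validation suite (and `scripts/acceptance.py`) runs, per seed: the
canonical recovery study (68/248 template, 20 subjects × 20 epochs,
T = 30, ten-fold grouped CV, 15 training epochs, IG with 24-32 steps, AP I
with 2,000 permutations — median precision and recall of the recovered
vs. planted edge set across 5 seeds); the structural-prior comparison
(same data, three folds, 10 training epochs, T-GCN vs. GRU over 5 seeds);
differential-test type-I error (a model trained on one null study
attributes 100 freshly simulated null datasets, AP II at 999
permutations); GFP window recovery (amplitude gain 1.6 in 500–800 ms,
full −200..1200 ms epochs); SPD null calibration (uniformity of the
permutation p under the null, KS test over 200 repetitions of 499 null
draws); MAR(1) recovery (max-abs transition error at noise sd 0.01,
two-system classification at sd 0.1); and the FC / distance / FDR closed
forms. The pytest suite runs the same studies at reduced repetition counts
(three recovery seeds, 30 type-I repetitions) with identical thresholds.

## Known limitations

* Tractography, source reconstruction, and artifact removal are out of
  scope: the connectome and the epochs are consumed as given.
* The permutation null of AP I (values exchangeable across edges within an
  epoch) is a strong assumption on real data, where attribution magnitude
  may covary with graph position; on synthetic data it calibrates cleanly.
* The per-epoch min-max normalization couples edges, which limits the
  differential test's specificity under strong one-sided planting: a
  planted edge's normalized value swings between ~1 and ~0 with the
  model's per-epoch decision (a high-variance signature the permutation
  test does not rank as extreme), while small but consistent compression
  shifts on the remaining edges do reach significance. Its type-I error
  under a genuine null is exactly at the nominal level; on data where both
  conditions engage couplings (differences of degree rather than
  presence/absence) the statistic is better behaved. The common-edge test
  is the instrument that localizes planted pathways.
* The attribution path scales all edges jointly from the common zero
  baseline; per-edge conditional baselines (rewiring one edge at a time)
  would cost one integral per edge and are not implemented.
* The MAR(1) baseline assumes Gaussian residuals and a shared sampling
  grid; it is a reference model, not a serious competitor on oscillatory
  data.
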