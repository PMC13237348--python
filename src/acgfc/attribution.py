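"""Integrated-Gradients edge attribution and its significance procedures.

The trained classifier's decision is attributed back onto individual
structural edges by treating each edge's adjacency entry as a continuous
input in [0, 1] and integrating the gradient of the decision logit (the
model's predicted class by default) along the straight path from the
all-edges-zero baseline to the full template (midpoint Riemann sum). Because every time step's graph convolution
uses the same Laplacian, gradients accumulate over the whole epoch
automatically. Per epoch, raw attributions are min-max normalized across
edges to the [0, 1] "ACG-FC value" scale.

Two group-level procedures follow:

* Attribution Process I (common edges): per-edge mean value across all
  epochs, tested against a null that reshuffles each epoch's values across
  the template edges (10,000 permutations by default), one-sided, BH-FDR.
* Attribution Process II (differential edges): per-edge mean difference
  switch - repeat, tested by condition-label permutation with group sizes
  preserved, two-sided, BH-FDR, with the sign reported on significant edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import Connectome, EpochSet
from .models.laplacian import ScaledLaplacian, scaled_laplacian
from .models.nn import TGCN
from .models.train import FoldResult, _epochs_to_model_input
from .stats import EdgeTestResult, fdr_bh, perm_mean_diff, perm_mean_high

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionResult",
    "ig_edge_attribution",
    "normalize_epoch",
    "attribute_epochs",
    "ap1_common",
    "ap2_differential",
    "fdr_bh",
]


@dataclass
class AttributionResult:
    """Per-epoch, per-structural-edge attribution; ``values`` in [0, 1]."""

    values: np.ndarray  # (epochs, edges), min-max normalized per epoch
    raw: np.ndarray  # (epochs, edges), unnormalized integrated gradients
    edge_index: list[tuple[int, int]]
    labels: np.ndarray
    subjects: np.ndarray
    ig_steps: int
    baseline: str = "zero-edges"

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def mean_values(self) -> np.ndarray:
        return self.values.mean(axis=0)


def ig_edge_attribution(
    model: TGCN,
    X: np.ndarray,
    slap: ScaledLaplacian,
    steps: int = 64,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Raw integrated-gradient attribution per structural edge.

    X is a batch (B, T, N, F); ``targets`` gives the logit to attribute per
    sample (default: the model's predicted class). Returns (B, n_edges);
    the (i, j) and (j, i) adjacency gradients are summed into one undirected
    edge score.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    B = X.shape[0]
    if targets is None:
        probs = model.predict_proba(X, slap.Lt)
        targets = probs.argmax(axis=1)
    targets = np.asarray(targets, dtype=int)
    ones = np.ones(slap.n_edges)
    acc = np.zeros((B, slap.n_edges))
    onehot = np.zeros((B, 2))
    onehot[np.arange(B), targets] = 1.0
    for s in range(steps):
        a = (s + 0.5) / steps
        Lt_a = slap.with_edge_weights(a * ones)
        _, cache = model.forward(X, Lt_a)
        _, dLt = model.backward(cache, onehot, need_edge_grad=True)
        acc += slap.edge_gradient(dLt)
    return acc / steps  # path length is 1 per edge (from 0 to 1)


def normalize_epoch(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize each row to [0, 1]; constant rows map to all zeros."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] <= 0
    if flat.any():
        logger.warning("%d epoch(s) with constant attribution normalized to zeros", int(flat.sum()))
    span[flat] = 1.0
    v = (raw - lo) / span
    v[flat] = 0.0
    return v


def attribute_epochs(
    fold_results: list[FoldResult],
    epochs: EpochSet,
    connectome: Connectome,
    steps: int = 64,
    batch: int = 64,
    target: str = "pred",
) -> AttributionResult:
    """Attribute every epoch with the model of the fold that held it out.

    ``target='pred'`` (default) integrates the logit of the model's own
    decision — label-free, so attribution values stay exchangeable under
    label permutation when the conditions are; ``target='true'`` uses the
    epoch's true-class logit.
    """
    slap = scaled_laplacian(connectome)
    X = _epochs_to_model_input(epochs)
    raw = np.zeros((epochs.n_epochs, slap.n_edges))
    covered = np.zeros(epochs.n_epochs, dtype=bool)
    for fr in fold_results:
        idx = np.nonzero(fr.test_mask)[0]
        for s in range(0, len(idx), batch):
            sel = idx[s : s + batch]
            tgt = epochs.labels[sel].astype(int) if target == "true" else None
            raw[sel] = ig_edge_attribution(fr.model, X[sel], slap, steps, targets=tgt)
        covered[idx] = True
    if not covered.all():
        raise ValueError("fold held-out masks do not cover all epochs")
    values = normalize_epoch(raw)
    return AttributionResult(values, raw, list(slap.edges), epochs.labels.copy(),
                             epochs.subjects.copy(), steps)


def ap1_common(
    attr: AttributionResult,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EdgeTestResult:
    """Common-edge detection: is an edge's mean value across all epochs higher
    than expected when values are randomly reassigned across template edges
    within each epoch?"""
    if attr.values.shape[0] < 2:
        raise ValueError("AP I needs at least 2 epochs")
    rng = np.random.default_rng(seed)
    observed, p_raw = perm_mean_high(attr.values, n_perm, rng)
    significant, p_adj = fdr_bh(p_raw, alpha)
    direction = np.zeros(attr.n_edges, dtype=int)
    return EdgeTestResult(attr.edge_index, observed, p_raw, p_adj, significant,
                          direction, alpha, n_perm, kind="ap1-common")


def ap2_differential(
    attr: AttributionResult,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> EdgeTestResult:
    """Differential-edge detection between switch and repeat epochs.

    ``statistic='mean_diff'`` permutes condition labels on the raw values;
    ``statistic='rank'`` first replaces each edge's values by their ranks
    across epochs (a rank-sum-style variant). Two-sided p, BH-FDR, and the
    sign of delta on significant edges.
    """
    labels = attr.labels.astype(int)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("AP II needs at least 2 epochs per condition")
    vals = attr.values
    if statistic == "rank":
        vals = rankdata(vals, axis=0)
    elif statistic != "mean_diff":
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    delta, p_raw = perm_mean_diff(vals, labels, n_perm, rng)
    if statistic == "rank":
        # report delta on the original value scale, test on ranks
        delta = attr.values[labels == 1].mean(0) - attr.values[labels == 0].mean(0)
    significant, p_adj = fdr_bh(p_raw, alpha)
    direction = np.where(significant, np.sign(delta).astype(int), 0)
    return EdgeTestResult(attr.edge_index, delta, p_raw, p_adj, significant,
                          direction, alpha, n_perm, kind="ap2-differential")
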