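"""Structure-constrained MAR(1) baseline.

X_{t+1} = A_c X_t + eps, fitted separately per condition c with the
transition matrix masked to structurally connected ROI pairs plus the
diagonal. Classification assigns a test epoch to the class whose model
yields the higher Gaussian log-likelihood of the observed transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..data import Connectome, EpochSet

logger = logging.getLogger(__name__)

__all__ = ["MARModel", "fit_mar1", "classify_mar1", "mar_loglik"]


@dataclass
class MARModel:
    transition: dict[int, np.ndarray]  # class -> (N, N), zero off the structural mask
    resid_var: dict[int, np.ndarray]  # class -> (N,)
    mask: np.ndarray  # (N, N) boolean, structural edges + diagonal

    def __post_init__(self):
        for A in self.transition.values():
            if np.any(A[~self.mask] != 0):
                raise AssertionError("transition entries outside the structural mask")


def _stack_transitions(data: np.ndarray):
    """(E, N, T) -> predictors (E*(T-1), N) at t and targets at t+1."""
    X_t = data[:, :, :-1]  # (E, N, T-1)
    X_next = data[:, :, 1:]
    prev = np.transpose(X_t, (0, 2, 1)).reshape(-1, data.shape[1])
    nxt = np.transpose(X_next, (0, 2, 1)).reshape(-1, data.shape[1])
    return prev, nxt


def fit_mar1(epochs: EpochSet, connectome: Connectome, ridge: float = 0.0) -> MARModel:
    """Masked least squares per class and per target node.

    For node i only its structural neighbors (and i itself) enter the
    regression. A singular design falls back to a small ridge with a logged
    jitter.
    """
    data = epochs.data if epochs.data.ndim == 3 else epochs.data[..., 0]
    N = connectome.n_nodes
    mask = connectome.adjacency.astype(bool) | np.eye(N, dtype=bool)
    transition, resid_var = {}, {}
    for c in (0, 1):
        sel = epochs.labels == c
        if sel.sum() == 0:
            raise ValueError(f"no epochs for class {c}")
        prev, nxt = _stack_transitions(data[sel])
        if prev.shape[0] < N:
            raise ValueError(f"class {c}: need at least N={N} transition samples")
        A = np.zeros((N, N))
        sig2 = np.zeros(N)
        for i in range(N):
            cols = np.nonzero(mask[i])[0]
            D = prev[:, cols]
            target = nxt[:, i]
            gram = D.T @ D
            lam = ridge
            try:
                coef = np.linalg.solve(gram + lam * np.eye(len(cols)), D.T @ target)
            except np.linalg.LinAlgError:
                lam = max(ridge, 1e-8) * (1.0 + np.trace(gram) / len(cols))
                logger.warning("singular design for node %d; ridge jitter %g applied", i, lam)
                coef = np.linalg.solve(gram + lam * np.eye(len(cols)), D.T @ target)
            A[i, cols] = coef
            resid = target - D @ coef
            sig2[i] = max(float(resid.var()), 1e-12)
        transition[c] = A
        resid_var[c] = sig2
    return MARModel(transition, resid_var, mask)


def mar_loglik(model: MARModel, epoch: np.ndarray, cls: int) -> float:
    """Gaussian log-likelihood of one epoch (N, T) under class ``cls``."""
    A = model.transition[cls]
    sig2 = model.resid_var[cls]
    pred = A @ epoch[:, :-1]
    resid = epoch[:, 1:] - pred
    T1 = resid.shape[1]
    ll = -0.5 * T1 * np.sum(np.log(2 * np.pi * sig2))
    ll -= 0.5 * np.sum(resid**2 / sig2[:, None])
    return float(ll)


def classify_mar1(model: MARModel, epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Argmax log-likelihood labels and class-1 posterior scores."""
    data = epochs.data if epochs.data.ndim == 3 else epochs.data[..., 0]
    n = data.shape[0]
    labels = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    for e in range(n):
        ll0 = mar_loglik(model, data[e], 0)
        ll1 = mar_loglik(model, data[e], 1)
        labels[e] = int(ll1 > ll0)
        # stable posterior from the log-likelihood gap
        scores[e] = 1.0 / (1.0 + np.exp(np.clip(ll0 - ll1, -500, 500)))
    return labels, scores
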