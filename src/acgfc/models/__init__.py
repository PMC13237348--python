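from .laplacian import ScaledLaplacian, scaled_laplacian
from .nn import AdaDelta, GRUBaseline, TGCN, cross_entropy, softmax
from .train import (
    FoldResult,
    MetricsReport,
    TrainConfig,
    evaluate,
    subject_folds,
    train_model,
)
from .mar import MARModel, classify_mar1, fit_mar1, mar_loglik

import numpy as np


def cheb_conv(X: np.ndarray, Lt: np.ndarray, theta: np.ndarray, activation=None) -> np.ndarray:
    """One spatial filtering step: sum_k T_k(Lt) X theta_k, then activation.

    X is (N, F), theta is (K+1, F, C); T_k follows the Chebyshev recursion
    T_0 = I, T_1 = Lt, T_k = 2 Lt T_{k-1} - T_{k-2}. Default activation ReLU.
    """
    K = theta.shape[0] - 1
    if K < 0:
        raise ValueError("theta must contain at least the order-0 filter")
    P = [X]
    if K >= 1:
        P.append(Lt @ X)
    for _ in range(2, K + 1):
        P.append(2.0 * Lt @ P[-1] - P[-2])
    Z = sum(p @ theta[k] for k, p in enumerate(P))
    if activation is None:
        return np.maximum(Z, 0.0)
    return activation(Z)


def tgcn_forward(model: TGCN, epoch: np.ndarray, Lt: np.ndarray) -> np.ndarray:
    """Logits for a single epoch given as (N, F, T) (or (N, T) with F=1)."""
    if epoch.ndim == 2:
        epoch = epoch[:, None, :]
    X = np.transpose(epoch, (2, 0, 1))[None]  # (1, T, N, F)
    logits, _ = model.forward(X, Lt)
    return logits[0]


__all__ = [
    "ScaledLaplacian", "scaled_laplacian", "AdaDelta", "GRUBaseline", "TGCN",
    "cross_entropy", "softmax", "FoldResult", "MetricsReport", "TrainConfig",
    "evaluate", "subject_folds", "train_model", "MARModel", "classify_mar1",
    "fit_mar1", "mar_loglik", "cheb_conv", "tgcn_forward",
]
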