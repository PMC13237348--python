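"""Training loop, subject-grouped cross-validation, and evaluation metrics.

Folds are built on subjects, never on epochs: every held-out fold contains
all epochs of a disjoint subject group (default ten folds, two subjects per
fold with twenty subjects), so evaluation always reflects generalization to
unseen participants. The loss is mean cross-entropy plus an L2 weight-decay
penalty (lambda / 2m) * sum ||W||^2 over weight matrices, minimized with
AdaDelta on mini-batches of 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from ..data import Connectome, EpochSet
from .laplacian import ScaledLaplacian, scaled_laplacian
from .nn import AdaDelta, GRUBaseline, TGCN, cross_entropy, softmax

__all__ = ["TrainConfig", "MetricsReport", "evaluate", "subject_folds", "train_model", "FoldResult"]


@dataclass
class TrainConfig:
    cheb_order: int = 2
    cheb_channels: int = 16
    hidden: int = 16
    activation: str = "square"
    dropout: float = 0.2
    weight_decay: float = 0.0005
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1.0
    optimizer: str = "adadelta"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def evaluate(y_true: np.ndarray, scores: np.ndarray) -> dict:
    """Five metrics from class-1 probabilities: accuracy, cross-entropy loss,
    F1 (positive class = switch), MCC (0 on zero denominator), AUROC (None
    when only one class is present)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= 0.5).astype(int)
    p = np.clip(np.where(y_true == 1, scores, 1.0 - scores), 1e-12, 1.0)
    out = {
        "accuracy": float((y_pred == y_true).mean()),
        "loss": float(-np.log(p).mean()),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
    }
    out["auroc"] = float(roc_auc_score(y_true, scores)) if len(np.unique(y_true)) == 2 else None
    return out


@dataclass
class MetricsReport:
    per_fold: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        keys = ("accuracy", "loss", "f1", "mcc", "auroc")
        out = {}
        for k in keys:
            vals = [f[k] for f in self.per_fold if f.get(k) is not None]
            out[k] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        return out

    def mean(self, key: str) -> float:
        return self.summary()[key]["mean"]


def subject_folds(subjects: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle subjects under the seed and chunk them into n_folds groups;
    returns per-fold boolean epoch masks for the held-out set."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects for {n_folds} folds, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    chunks = np.array_split(uniq[order], n_folds)
    return [np.isin(subjects, chunk) for chunk in chunks]


@dataclass
class FoldResult:
    fold: int
    model: object
    test_mask: np.ndarray
    metrics: dict
    train_losses: list[float]


def _epochs_to_model_input(epochs: EpochSet) -> np.ndarray:
    """(E, N, T[, F]) -> (E, T, N, F)."""
    d = epochs.data
    if d.ndim == 3:
        d = d[..., None]
    return np.transpose(d, (0, 2, 1, 3))


def _fit_one(model, X, y, config: TrainConfig, Lt, rng) -> list[float]:
    opt = AdaDelta(model.params, lr=config.learning_rate)
    n = X.shape[0]
    m = config.batch_size
    losses = []
    weight_keys = [k for k in model.params if k.startswith("W") or k == "theta"]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, m):
            idx = order[s : s + m]
            xb, yb = X[idx], y[idx]
            logits, cache = model.forward(xb, Lt, train=True, dropout=config.dropout, rng=rng)
            probs = softmax(logits)
            loss = cross_entropy(probs, yb)
            if config.weight_decay > 0:
                loss += config.weight_decay / (2 * len(idx)) * sum(
                    float((model.params[k] ** 2).sum()) for k in weight_keys
                )
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads, _ = model.backward(cache, dlogits)
            if config.weight_decay > 0:
                for k in weight_keys:
                    grads[k] = grads[k] + config.weight_decay / len(idx) * model.params[k]
            opt.step(model.params, grads)
            ep_loss += loss * len(idx)
        losses.append(ep_loss / n)
    return losses


def train_model(
    epochs: EpochSet,
    connectome: Connectome | None,
    config: TrainConfig,
    architecture: str = "tgcn",
) -> tuple[list[FoldResult], MetricsReport]:
    """Subject-grouped cross-validated training.

    ``architecture`` selects the structural model ('tgcn') or the
    structure-free GRU control ('gru'). Returns per-fold fitted models with
    their held-out masks and the metrics report.
    """
    X = _epochs_to_model_input(epochs)
    y = epochs.labels.astype(int)
    if architecture == "tgcn":
        if connectome is None:
            raise ValueError("the T-GCN needs a structural connectome")
        Lt = scaled_laplacian(connectome).Lt
    else:
        Lt = None
    folds = subject_folds(epochs.subjects, config.n_folds, config.seed)
    results, report = [], MetricsReport()
    for f, test_mask in enumerate(folds):
        train_mask = ~test_mask
        y_tr = y[train_mask]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {f}: training split lacks one class")
        rng = np.random.default_rng(config.seed * 10007 + f)
        if architecture == "tgcn":
            model = TGCN(epochs.n_nodes, X.shape[-1], config.cheb_order,
                         config.cheb_channels, config.hidden, seed=config.seed * 613 + f,
                         activation=config.activation)
        elif architecture == "gru":
            model = GRUBaseline(epochs.n_nodes, X.shape[-1], config.hidden,
                                seed=config.seed * 613 + f)
        else:
            raise ValueError(f"unknown architecture {architecture!r}")
        losses = _fit_one(model, X[train_mask], y_tr, config, Lt, rng)
        scores = model.predict_proba(X[test_mask], Lt)[:, 1]
        metrics = evaluate(y[test_mask], scores)
        results.append(FoldResult(f, model, test_mask, metrics, losses))
        report.per_fold.append(metrics)
    return results, report
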