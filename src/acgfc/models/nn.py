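"""Recurrent graph network in plain numpy with analytic gradients.

Two classifiers share one GRU core:

* :class:`TGCN` — per time step, node features are spatially filtered by a
  K-order Chebyshev expansion of the scaled structural Laplacian, passed
  through ReLU, and fed to a GRU whose hidden state is shared across nodes;
  the final state is mean-pooled over nodes and mapped to two logits.
* :class:`GRUBaseline` — the structure-free control: the same GRU consumes
  the raw node signals as one flat feature vector per time step.

Backpropagation is written out by hand (the package does not depend on an
autodiff framework), which also yields the gradient of any logit with
respect to the scaled Laplacian matrix — the quantity the Integrated
Gradients edge attribution integrates along its path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TGCN", "GRUBaseline", "AdaDelta", "softmax", "cross_entropy"]


def _sigmoid(x):
    # numerically stable via tanh, single vectorized pass
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.log(p).mean())


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# shared GRU core: inputs (B, T, M, C) with a node axis M and hidden size H
# ---------------------------------------------------------------------------

def _gru_forward(Hc: np.ndarray, params: dict, hidden: int):
    """Inputs (B, T, M, C). The input-side projections of all three gates are
    hoisted out of the recurrence into single large matrix products."""
    B, T, M, C = Hc.shape
    H = hidden
    Wu, bu = params["Wu"], params["bu"]
    Wr, br = params["Wr"], params["br"]
    Wh, bh = params["Wh"], params["bh"]
    # time-major 2-D layout (T, B*M, H): one GEMM per gate per step
    tm = np.ascontiguousarray(Hc.transpose(1, 0, 2, 3)).reshape(T, B * M, C)
    flat = tm.reshape(-1, C)
    Xu = (flat @ Wu[:C] + bu).reshape(T, B * M, H)
    Xr = (flat @ Wr[:C] + br).reshape(T, B * M, H)
    Xh = (flat @ Wh[:C] + bh).reshape(T, B * M, H)
    Wu_h, Wr_h, Wh_h = Wu[C:], Wr[C:], Wh[C:]
    dt = Hc.dtype
    u_a = np.empty((T, B * M, H), dt)
    r_a = np.empty((T, B * M, H), dt)
    hc_a = np.empty((T, B * M, H), dt)
    hp_a = np.empty((T, B * M, H), dt)
    h = np.zeros((B * M, H), dt)
    for t in range(T):
        u = _sigmoid(Xu[t] + h @ Wu_h)
        r = _sigmoid(Xr[t] + h @ Wr_h)
        hc = np.tanh(Xh[t] + (r * h) @ Wh_h)
        u_a[t], r_a[t], hc_a[t], hp_a[t] = u, r, hc, h
        h = u * h + (1.0 - u) * hc
    cache = {"u": u_a, "r": r_a, "hc": hc_a, "h_prev": hp_a, "Hc_tm": tm,
             "shape": (B, T, M)}
    return h.reshape(B, M, H), cache


def _gru_backward(cache: dict, params: dict, dh: np.ndarray, C: int):
    Wu, Wr, Wh = params["Wu"], params["Wr"], params["Wh"]
    Wu_h, Wr_h, Wh_h = Wu[C:], Wr[C:], Wh[C:]
    u_a, r_a, hc_a, hp_a = cache["u"], cache["r"], cache["hc"], cache["h_prev"]
    tm = cache["Hc_tm"]
    B, T, M = cache["shape"]
    H = u_a.shape[-1]
    dt = u_a.dtype
    dh = dh.reshape(B * M, H).astype(dt, copy=False)
    dau_a = np.empty((T, B * M, H), dt)
    dar_a = np.empty((T, B * M, H), dt)
    dah_a = np.empty((T, B * M, H), dt)
    for t in range(T - 1, -1, -1):
        u, r, hc, h_prev = u_a[t], r_a[t], hc_a[t], hp_a[t]
        du = dh * (h_prev - hc)
        dah = (dh * (1.0 - u)) * (1.0 - hc * hc)
        drh = dah @ Wh_h.T
        dr = drh * h_prev
        dau = du * u * (1.0 - u)
        dar = dr * r * (1.0 - r)
        dau_a[t], dar_a[t], dah_a[t] = dau, dar, dah
        dh = dh * u + drh * r + dau @ Wu_h.T + dar @ Wr_h.T
    flat_in = tm.reshape(-1, tm.shape[-1])
    flat_hp = hp_a.reshape(-1, H)
    flat_rh = (r_a * hp_a).reshape(-1, H)
    fau = dau_a.reshape(-1, H)
    far = dar_a.reshape(-1, H)
    fah = dah_a.reshape(-1, H)
    grads = {
        "Wu": np.vstack([flat_in.T @ fau, flat_hp.T @ fau]),
        "bu": fau.sum(axis=0),
        "Wr": np.vstack([flat_in.T @ far, flat_hp.T @ far]),
        "br": far.sum(axis=0),
        "Wh": np.vstack([flat_in.T @ fah, flat_rh.T @ fah]),
        "bh": fah.sum(axis=0),
    }
    dHc_tm = (fau @ Wu[:C].T + far @ Wr[:C].T + fah @ Wh[:C].T).reshape(T, B, M, C)
    dHc = np.ascontiguousarray(dHc_tm.transpose(1, 0, 2, 3))
    return dHc, grads


class _RecurrentClassifier:
    """GRU classifier scaffold shared by both models: the final hidden states
    of all nodes are flattened and mapped to two logits by one fully
    connected layer (node identity is preserved into the readout)."""

    hidden: int
    params: dict

    def _head_forward(self, h_last, train, dropout, rng):
        B = h_last.shape[0]
        flat = h_last.reshape(B, -1)  # (B, M*H)
        mask = None
        if train and dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            mask = ((rng.random(flat.shape) >= dropout) / (1.0 - dropout)).astype(flat.dtype)
            flat = flat * mask
        logits = flat @ self.params["Wo"] + self.params["bo"]
        return logits, flat, mask

    def _head_backward(self, dlogits, flat, mask, n_pool):
        grads = {
            "Wo": flat.T @ dlogits,
            "bo": dlogits.sum(axis=0),
        }
        dflat = dlogits @ self.params["Wo"].T
        if mask is not None:
            dflat = dflat * mask
        dh = dflat.reshape(dlogits.shape[0], n_pool, -1)
        return grads, dh


class TGCN(_RecurrentClassifier):
    """Chebyshev graph convolution + GRU condition classifier.

    Parameters
    ----------
    n_nodes, in_features : graph size N and node feature dimension F.
    cheb_order : K; the filter aggregates up to K-hop structural neighbors.
    cheb_channels : spatial filter output channels C.
    hidden : GRU state size per node.
    """

    def __init__(self, n_nodes: int, in_features: int = 1, cheb_order: int = 2,
                 cheb_channels: int = 16, hidden: int = 16, seed: int = 0,
                 activation: str = "square", dtype=np.float32):
        if cheb_order < 0:
            raise ValueError("cheb_order must be >= 0")
        if activation not in ("square", "abs", "relu"):
            raise ValueError("activation must be 'square', 'abs' or 'relu'")
        self.activation = activation
        self.n_nodes = n_nodes
        self.in_features = in_features
        self.K = cheb_order
        self.C = cheb_channels
        self.hidden = hidden
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        C, H, F = cheb_channels, hidden, in_features
        dt = self.dtype
        self.params = {
            "theta": _glorot(rng, (self.K + 1, F, C), dt),
            "Wu": _glorot(rng, (C + H, H), dt), "bu": np.zeros(H, dt),
            "Wr": _glorot(rng, (C + H, H), dt), "br": np.zeros(H, dt),
            "Wh": _glorot(rng, (C + H, H), dt), "bh": np.zeros(H, dt),
            "Wo": _glorot(rng, (n_nodes * H, 2), dt), "bo": np.zeros(2, dt),
        }

    # -- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, Lt: np.ndarray, train: bool = False,
                dropout: float = 0.0, rng: np.random.Generator | None = None):
        """X: (B, T, N, F); Lt: (N, N). Returns (logits, cache)."""
        if np.isnan(X).any():
            raise ValueError("NaN in input epochs")
        X = X.astype(self.dtype, copy=False)
        Lt = Lt.astype(self.dtype, copy=False)
        B, T, N, F = X.shape
        P = [X]
        if self.K >= 1:
            P.append(np.einsum("nm,btmf->btnf", Lt, X))
        for k in range(2, self.K + 1):
            P.append(2.0 * np.einsum("nm,btmf->btnf", Lt, P[-1]) - P[-2])
        Z = np.einsum("kbtnf,kfc->btnc", np.stack(P), self.params["theta"])
        if self.activation == "square":
            Hc = Z * Z
        elif self.activation == "abs":
            Hc = np.abs(Z)
        else:
            Hc = np.maximum(Z, 0.0)
        h_last, gru_cache = _gru_forward(Hc, self.params, self.hidden)
        logits, pooled, mask = self._head_forward(h_last, train, dropout, rng)
        cache = {"P": P, "Z": Z, "gru": gru_cache, "pooled": pooled,
                 "mask": mask, "Lt": Lt}
        return logits, cache

    # -- backward -----------------------------------------------------------
    def backward(self, cache: dict, dlogits: np.ndarray, need_edge_grad: bool = False):
        """Gradients of a scalar loss with logit gradients ``dlogits``.

        Returns (grads, dLt) where dLt is the per-sample gradient w.r.t. the
        scaled Laplacian, shape (B, N, N), or None when not requested.
        """
        P, Z = cache["P"], cache["Z"]
        grads, dh = self._head_backward(dlogits, cache["pooled"], cache["mask"], self.n_nodes)
        dHc, gru_grads = _gru_backward(cache["gru"], self.params, dh, self.C)
        grads.update(gru_grads)
        if self.activation == "square":
            dZ = dHc * (2.0 * Z)
        elif self.activation == "abs":
            dZ = dHc * np.sign(Z)
        else:
            dZ = dHc * (Z > 0)
        grads["theta"] = np.einsum("kbtnf,btnc->kfc", np.stack(P), dZ)
        dLt = None
        if need_edge_grad and self.K >= 1:
            Lt = cache["Lt"]
            g = [np.einsum("btnc,fc->btnf", dZ, self.params["theta"][k])
                 for k in range(self.K + 1)]
            B = dZ.shape[0]
            dLt = np.zeros((B, self.n_nodes, self.n_nodes))
            for k in range(self.K, 1, -1):
                dLt += 2.0 * np.einsum("btnf,btmf->bnm", g[k], P[k - 1])
                g[k - 1] = g[k - 1] + 2.0 * np.einsum("nm,btmf->btnf", Lt, g[k])
                g[k - 2] = g[k - 2] - g[k]
            dLt += np.einsum("btnf,btmf->bnm", g[1], P[0])
        elif need_edge_grad:
            dLt = np.zeros((dZ.shape[0], self.n_nodes, self.n_nodes))
        return grads, dLt

    def predict_proba(self, X: np.ndarray, Lt: np.ndarray, batch: int = 128) -> np.ndarray:
        out = []
        for s in range(0, X.shape[0], batch):
            logits, _ = self.forward(X[s : s + batch], Lt)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


class GRUBaseline(_RecurrentClassifier):
    """Structure-free control: the GRU sees all node signals as one vector."""

    def __init__(self, n_nodes: int, in_features: int = 1, hidden: int = 16, seed: int = 0,
                 dtype=np.float32):
        self.n_nodes = n_nodes
        self.in_features = in_features
        self.C = n_nodes * in_features
        self.hidden = hidden
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        D, H = self.C, hidden
        dt = self.dtype
        self.params = {
            "Wu": _glorot(rng, (D + H, H), dt), "bu": np.zeros(H, dt),
            "Wr": _glorot(rng, (D + H, H), dt), "br": np.zeros(H, dt),
            "Wh": _glorot(rng, (D + H, H), dt), "bh": np.zeros(H, dt),
            "Wo": _glorot(rng, (H, 2), dt), "bo": np.zeros(2, dt),
        }

    def forward(self, X: np.ndarray, Lt=None, train: bool = False,
                dropout: float = 0.0, rng: np.random.Generator | None = None):
        if np.isnan(X).any():
            raise ValueError("NaN in input epochs")
        X = X.astype(self.dtype, copy=False)
        B, T, N, F = X.shape
        Hc = X.reshape(B, T, 1, N * F)
        h_last, gru_cache = _gru_forward(Hc, self.params, self.hidden)
        logits, pooled, mask = self._head_forward(h_last, train, dropout, rng)
        return logits, {"gru": gru_cache, "pooled": pooled, "mask": mask}

    def backward(self, cache: dict, dlogits: np.ndarray, need_edge_grad: bool = False):
        grads, dh = self._head_backward(dlogits, cache["pooled"], cache["mask"], 1)
        _, gru_grads = _gru_backward(cache["gru"], self.params, dh, self.C)
        grads.update(gru_grads)
        return grads, None

    def predict_proba(self, X: np.ndarray, Lt=None, batch: int = 128) -> np.ndarray:
        out = []
        for s in range(0, X.shape[0], batch):
            logits, _ = self.forward(X[s : s + batch])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


class AdaDelta:
    """AdaDelta with accumulators per parameter (rho=0.95, eps=1e-6)."""

    def __init__(self, params: dict, rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.rho, self.eps, self.lr = rho, eps, lr
        self.Eg = {k: np.zeros_like(v) for k, v in params.items()}
        self.Ex = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            self.Eg[k] = self.rho * self.Eg[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.Ex[k] + self.eps) / np.sqrt(self.Eg[k] + self.eps) * g
            self.Ex[k] = self.rho * self.Ex[k] + (1 - self.rho) * dx * dx
            params[k] += self.lr * dx
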