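"""Scaled graph Laplacian for Chebyshev spectral filtering.

The filter operates on L-tilde = 2 L / lambda_max - I with
L = I - D^(-1/2) (A + I) D^(-1/2); self-loops are added before
normalization so isolated nodes stay well defined, and the spectrum of
L-tilde lies in [-1, 1].

For edge attribution the off-diagonal adjacency entries are treated as
continuous inputs in [0, 1]. The degree normalization and lambda_max are
frozen at their full-template values, which makes L-tilde an affine function
of the edge weights: the gradient of any model output with respect to an
edge weight is then a fixed linear functional of its gradient with respect
to the L-tilde matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import Connectome

__all__ = ["ScaledLaplacian", "scaled_laplacian"]

_EPS = 1e-12


@dataclass(frozen=True)
class ScaledLaplacian:
    Lt: np.ndarray  # (N, N) scaled Laplacian of the full template
    lambda_max: float
    dinv_sqrt: np.ndarray  # (N,) frozen D^(-1/2) of A + I
    edges: tuple[tuple[int, int], ...]

    @property
    def n_nodes(self) -> int:
        return self.Lt.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def with_edge_weights(self, w: np.ndarray) -> np.ndarray:
        """L-tilde for adjacency with off-diagonal entries scaled by ``w``.

        ``w`` has one entry per template edge; w = 1 recovers ``Lt``.
        Normalization constants stay frozen, so the map is affine in w.
        """
        n = self.n_nodes
        Aw = np.eye(n)
        for e, (i, j) in enumerate(self.edges):
            Aw[i, j] = Aw[j, i] = w[e]
        S = self.dinv_sqrt[:, None] * Aw * self.dinv_sqrt[None, :]
        L = np.eye(n) - S
        return 2.0 * L / self.lambda_max - np.eye(n)

    def edge_gradient(self, dLt: np.ndarray) -> np.ndarray:
        """Map gradients w.r.t. L-tilde, shape (..., N, N), onto edge weights.

        The (i, j) and (j, i) entries are summed, matching the symmetrized
        per-edge attribution.
        """
        scale = -2.0 / self.lambda_max
        iu = np.array([i for i, _ in self.edges])
        ju = np.array([j for _, j in self.edges])
        coef = scale * self.dinv_sqrt[iu] * self.dinv_sqrt[ju]
        return coef * (dLt[..., iu, ju] + dLt[..., ju, iu])


def scaled_laplacian(connectome: Connectome) -> ScaledLaplacian:
    A = connectome.adjacency.astype(np.float64)
    n = A.shape[0]
    A_hat = A + np.eye(n)
    d = A_hat.sum(axis=1)
    dinv_sqrt = 1.0 / np.sqrt(d)
    S = dinv_sqrt[:, None] * A_hat * dinv_sqrt[None, :]
    L = np.eye(n) - S
    lam = float(np.linalg.eigvalsh(L).max())
    lam = max(lam, _EPS)
    Lt = 2.0 * L / lam - np.eye(n)
    return ScaledLaplacian(Lt, lam, dinv_sqrt, tuple(connectome.edges))
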