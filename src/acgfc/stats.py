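"""Shared inferential machinery: BH-FDR and the two permutation nulls used by
the attribution and functional-connectivity tests.

Both permutation schemes return valid p-values with minimum attainable value
1 / (n_perm + 1) (the observed statistic is counted as one member of the
null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["fdr_bh", "EdgeTestResult", "perm_mean_high", "perm_mean_diff"]


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (rejected mask, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return rejected, adj


@dataclass
class EdgeTestResult:
    """Per-edge test outcome shared by attribution and FC significance tests.

    ``direction`` is sign(delta) on significant edges for differential tests
    and 0 elsewhere.
    """

    edge_index: list[tuple[int, int]]
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    direction: np.ndarray
    alpha: float
    n_perm: int
    kind: str = ""

    def __post_init__(self):
        if np.any(self.p_adj + 1e-12 < self.p_raw):
            raise AssertionError("adjusted p must be >= raw p")

    @property
    def significant_edges(self) -> list[tuple[int, int]]:
        return [e for e, s in zip(self.edge_index, self.significant) if s]

    def to_frame(self, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        rows = {
            "source": [labels[i] if labels else i for i, _ in self.edge_index],
            "target": [labels[j] if labels else j for _, j in self.edge_index],
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "significant": self.significant.astype(int),
            "direction": self.direction.astype(int),
        }
        return pd.DataFrame(rows)


def perm_mean_high(
    values: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided permutation test for 'mean across rows is high for a column'.

    The null reassigns each row's values uniformly across columns (independent
    permutations per row), matching exchangeability of a feature's identity
    within each observation. Returns (observed column means, raw p).
    """
    values = np.asarray(values, dtype=np.float64)
    n_rows, n_cols = values.shape
    observed = values.mean(axis=0)
    exceed = np.zeros(n_cols, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # (b, n_rows, n_cols): independent column-permutation per row per draw
        tiled = np.broadcast_to(values, (b, n_rows, n_cols)).copy()
        null_means = rng.permuted(tiled, axis=2).mean(axis=1)
        exceed += (null_means >= observed[None, :]).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, p


def perm_mean_diff(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided label-permutation test on mean(group 1) - mean(group 0).

    Group sizes are preserved under permutation. Returns (observed delta,
    raw two-sided p) per column.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    n_rows, n_cols = values.shape
    if labels.shape[0] != n_rows:
        raise ValueError("labels length does not match values rows")
    n1 = int((labels == 1).sum())
    n0 = n_rows - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("each condition needs at least 2 observations")
    total = values.sum(axis=0)
    observed = values[labels == 1].mean(axis=0) - values[labels == 0].mean(axis=0)
    abs_obs = np.abs(observed)
    exceed = np.zeros(n_cols, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = np.argsort(rng.random((b, n_rows)), axis=1)
        ind = np.zeros((b, n_rows))
        np.put_along_axis(ind, order[:, :n1], 1.0, axis=1)
        sum1 = ind @ values  # (b, n_cols)
        delta = sum1 / n1 - (total[None, :] - sum1) / n0
        exceed += (np.abs(delta) >= abs_obs[None, :]).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, p
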