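"""Topological similarity between edge sets: Jaccard similarity (JS),
Frobenius distance (FD), spectral distance (SPD), and the random-network
null test on SPD.

SPD is the Euclidean distance between descending-sorted adjacency
eigenvalue spectra (configurable to Laplacian spectra); for binary symmetric
zero-diagonal matrices FD equals sqrt(2 |A xor B|). The SPD null draws
networks uniformly from the structural template's edge set with the same
edge count as the observed network, matching the shuffle domain of the
common-edge attribution test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import Connectome

logger = logging.getLogger(__name__)

__all__ = ["NetworkComparison", "jaccard", "frobenius_distance", "spectral_distance",
           "edges_to_adjacency", "spd_null_test"]

Edge = tuple[int, int]


def _norm_edges(edges) -> set[Edge]:
    out = set()
    for i, j in edges:
        if i == j:
            raise ValueError("self-loops are not valid edges")
        out.add((min(i, j), max(i, j)))
    return out


def jaccard(edges_a, edges_b) -> float:
    """|A intersect B| / |A union B|; 1 when both sets are empty (logged)."""
    a, b = _norm_edges(edges_a), _norm_edges(edges_b)
    if not a and not b:
        logger.warning("Jaccard of two empty edge sets defined as 1")
        return 1.0
    return len(a & b) / len(a | b)


def edges_to_adjacency(edges, n_nodes: int) -> np.ndarray:
    A = np.zeros((n_nodes, n_nodes))
    for i, j in _norm_edges(edges):
        A[i, j] = A[j, i] = 1.0
    return A


def frobenius_distance(A: np.ndarray, B: np.ndarray) -> float:
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("adjacency matrices must share a shape")
    return float(np.linalg.norm(A - B))


def spectral_distance(A: np.ndarray, B: np.ndarray, basis: str = "adjacency") -> float:
    """Euclidean distance between descending-sorted eigenvalue spectra."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("matrices must share a shape")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("spectral distance requires symmetric matrices")
    if basis == "laplacian":
        A = np.diag(A.sum(axis=1)) - A
        B = np.diag(B.sum(axis=1)) - B
    elif basis != "adjacency":
        raise ValueError(f"unknown basis {basis!r}")
    ea = np.sort(np.linalg.eigvalsh(A))[::-1]
    eb = np.sort(np.linalg.eigvalsh(B))[::-1]
    return float(np.linalg.norm(ea - eb))


@dataclass
class NetworkComparison:
    js: float
    spd: float
    fd: float
    null_spd: np.ndarray
    p_one_sided: float
    n_null: int
    null_mean: float
    pct_below_null_mean: float
    isospectral_fraction: float
    constraint: str = "template-constrained"
    spd_basis: str = "adjacency"


def spd_null_test(
    acg_edges,
    fc_edges,
    template: Connectome,
    n_null: int = 5000,
    seed: int = 0,
    spd_basis: str = "adjacency",
    free_null: bool = False,
) -> NetworkComparison:
    """Convergence test: is the observed SPD between the attribution-derived
    network and an FC network smaller than for random equal-size networks?

    Null networks draw |acg_edges| edges uniformly without replacement from
    the template edge set (or from all node pairs with ``free_null``);
    one-sided p = (1 + #{null SPD <= observed}) / (n_null + 1). Heavy ties
    in the null (isospectral sparse draws) are reported as a fraction.
    """
    n = template.n_nodes
    acg = _norm_edges(acg_edges)
    if len(acg) < 1:
        raise ValueError("the attribution-derived edge set is empty")
    pool = [tuple(e) for e in (template.edges if not free_null else
                               zip(*[x.tolist() for x in np.triu_indices(n, k=1)]))]
    if len(acg) > len(pool):
        raise ValueError("observed network has more edges than the sampling pool")
    A_fc = edges_to_adjacency(fc_edges, n)
    A_acg = edges_to_adjacency(acg, n)
    observed = spectral_distance(A_acg, A_fc, spd_basis)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    k = len(acg)
    pool_arr = np.arange(len(pool))
    for b in range(n_null):
        pick = rng.choice(pool_arr, size=k, replace=False)
        A_rand = edges_to_adjacency([pool[i] for i in pick], n)
        null[b] = spectral_distance(A_rand, A_fc, spd_basis)
    p = (1.0 + np.sum(null <= observed)) / (n_null + 1.0)
    null_mean = float(null.mean())
    uniq, counts = np.unique(np.round(null, 10), return_counts=True)
    iso_frac = float(counts.max() / n_null) if len(uniq) else 0.0
    if iso_frac > 0.25:
        logger.warning("null SPD distribution is highly degenerate "
                       "(%.0f%% of draws share one value): isospectral sparse networks", 100 * iso_frac)
    pct_below = 100.0 * (null_mean - observed) / null_mean if null_mean > 0 else 0.0
    return NetworkComparison(
        js=jaccard(acg, fc_edges), spd=observed,
        fd=frobenius_distance(A_acg, A_fc), null_spd=null,
        p_one_sided=float(p), n_null=n_null, null_mean=null_mean,
        pct_below_null_mean=float(pct_below), isospectral_fraction=iso_frac,
        constraint="free" if free_null else "template-constrained",
        spd_basis=spd_basis,
    )
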