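"""Conventional functional-connectivity metrics and their significance tests.

Phase metrics (PLV, PPC) come from the band-limited analytic-signal phase;
coherence metrics (Coh, ImCoh) from Welch cross-spectra averaged over the
band. FC is estimated per epoch over the analysis window and averaged across
epochs. Common FCs are tested against circular-time-shift surrogates (which
preserve each node's autostructure while destroying cross-node alignment);
differential FCs use the condition-label permutation shared with the
attribution tests. ACM-FC is the post-hoc structural masking of a
significant FC set to template edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data import Connectome, EpochSet
from .signal import analytic_phase, bandpass_mirror
from .stats import EdgeTestResult, fdr_bh, perm_mean_diff

logger = logging.getLogger(__name__)

__all__ = [
    "FCMatrix",
    "fc_metric",
    "fc_matrix",
    "common_fc_test",
    "differential_fc_test",
    "acm_mask",
    "METRICS",
]

METRICS = ("plv", "ppc", "coh", "imcoh", "pli")


@dataclass
class FCMatrix:
    matrix: np.ndarray  # (N, N) symmetric
    metric: str
    band: tuple[float, float]


def _pair_index(n: int) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


# -- single-pair scalar metrics ---------------------------------------------

def fc_metric(a: np.ndarray, b: np.ndarray, metric: str,
              fs: float | None = None, band: tuple[float, float] | None = None,
              is_phase: bool = False) -> float:
    """Scalar connectivity between two equal-length series.

    For 'plv'/'ppc'/'pli' the inputs are phase series when ``is_phase`` else
    raw signals filtered into ``band``. 'coh'/'imcoh' always consume raw
    signals (Welch segments: length T//2, 50% overlap, Hann).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    n = a.shape[0]
    if metric in ("plv", "ppc", "pli"):
        if not is_phase:
            if fs is None or band is None:
                raise ValueError("raw-signal phase metrics need fs and band")
            a = analytic_phase(a[None], band, fs)[0]
            b = analytic_phase(b[None], band, fs)[0]
        dphi = a - b
        z = np.exp(1j * dphi)
        plv = float(np.abs(z.mean()))
        if metric == "plv":
            return plv
        if metric == "ppc":
            if n < 2:
                raise ValueError("PPC needs at least 2 samples")
            return float((n * plv**2 - 1.0) / (n - 1.0))
        return float(np.abs(np.mean(np.sign(np.sin(dphi)))))  # pli
    if metric in ("coh", "imcoh"):
        if fs is None or band is None:
            raise ValueError("coherence metrics need fs and band")
        return float(_coherency_matrix(np.vstack([a, b]), fs, band, metric)[0, 1])
    raise ValueError(f"unknown FC metric {metric!r}")


# -- epoch-level all-pairs matrices -----------------------------------------

def _phase_matrix(data: np.ndarray, fs: float, band, metric: str) -> np.ndarray:
    """(N, T) signals -> (N, N) PLV/PPC/PLI matrix."""
    phases = analytic_phase(data, band, fs)
    z = np.exp(1j * phases)  # (N, T)
    T = z.shape[1]
    if metric == "pli":
        dsin = np.sin(phases[:, None, :] - phases[None, :, :])
        M = np.abs(np.sign(dsin).mean(axis=2))
    else:
        plv = np.abs(z @ z.conj().T) / T
        M = plv if metric == "plv" else (T * plv**2 - 1.0) / (T - 1.0)
    np.fill_diagonal(M, 0.0 if metric == "pli" else 1.0)
    return M


def _coherency_matrix(data: np.ndarray, fs: float, band, metric: str) -> np.ndarray:
    """(N, T) signals -> band-averaged Coh or |ImCoh| matrix via Welch."""
    N, T = data.shape
    nperseg = max(8, T // 2)
    noverlap = nperseg // 2
    win = sps.get_window("hann", nperseg)
    step = nperseg - noverlap
    starts = range(0, T - nperseg + 1, step)
    segs = np.stack([data[:, s : s + nperseg] * win for s in starts])  # (S, N, L)
    F = np.fft.rfft(segs, axis=-1)  # (S, N, nf)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        sel = np.zeros_like(sel)
        sel[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    Fb = F[:, :, sel]
    S = np.einsum("snf,smf->nmf", Fb, Fb.conj())  # cross-spectra, seg-summed
    auto = np.sqrt(np.abs(np.einsum("nnf->nf", S)))
    denom = auto[:, None, :] * auto[None, :, :]
    denom[denom == 0] = np.inf
    coherency = S / denom
    if metric == "coh":
        M = np.abs(coherency).mean(axis=2)
        np.fill_diagonal(M, 1.0)
    else:
        M = np.abs(coherency.imag).mean(axis=2)
        np.fill_diagonal(M, 0.0)
    return M


def fc_matrix(data: np.ndarray, fs: float, band: tuple[float, float], metric: str) -> FCMatrix:
    """All-pairs FC for one epoch (N, T)."""
    if metric in ("plv", "ppc", "pli"):
        M = _phase_matrix(data, fs, band, metric)
    elif metric in ("coh", "imcoh"):
        M = _coherency_matrix(data, fs, band, metric)
    else:
        raise ValueError(f"unknown FC metric {metric!r}")
    return FCMatrix(M, metric, tuple(band))


def _per_epoch_pair_values(epochs: EpochSet, metric: str, band) -> np.ndarray:
    data = epochs.data if epochs.data.ndim == 3 else epochs.data[..., 0]
    n = epochs.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    out = np.zeros((epochs.n_epochs, len(iu)))
    for e in range(epochs.n_epochs):
        out[e] = fc_matrix(data[e], epochs.fs, band, metric).matrix[iu, ju]
    return out


def common_fc_test(
    epochs: EpochSet,
    metric: str,
    band: tuple[float, float] = (2.0, 13.0),
    n_surrogate: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> EdgeTestResult:
    """Significant common FCs over all node pairs, all epochs pooled.

    The null circularly time-shifts every node's signal by an independent
    random offset per epoch before re-estimating FC, one-sided p, BH-FDR.
    """
    if epochs.n_epochs < 2:
        raise ValueError("common FC test needs at least 2 epochs")
    if n_surrogate < 100:
        warnings.warn("fewer than 100 surrogates gives a coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)
    data = epochs.data if epochs.data.ndim == 3 else epochs.data[..., 0]
    E, N, T = data.shape
    iu, ju = np.triu_indices(N, k=1)
    observed = _per_epoch_pair_values(epochs, metric, band).mean(axis=0)
    exceed = np.zeros_like(observed, dtype=np.int64)
    if metric in ("plv", "ppc", "pli"):
        # shift the band-limited phase factors directly: much cheaper than
        # re-filtering, identical in intent (alignment is destroyed, each
        # node's autostructure preserved)
        z = np.exp(1j * analytic_phase(data, band, epochs.fs))  # (E, N, T)
        base_idx = np.arange(T)[None, None, :]
        for _ in range(n_surrogate):
            offs = rng.integers(1, T, size=(E, N))
            idx = (base_idx + offs[:, :, None]) % T
            zs = np.take_along_axis(z, idx, axis=2)
            if metric == "pli":
                dphi = np.angle(zs[:, :, None, :] * zs[:, None, :, :].conj())
                M = np.abs(np.sign(dphi).mean(axis=3))
            else:
                plv = np.abs(np.einsum("ent,emt->enm", zs, zs.conj())) / T
                M = plv if metric == "plv" else (T * plv**2 - 1.0) / (T - 1.0)
            null_mean = M.mean(axis=0)[iu, ju]
            exceed += null_mean >= observed
    else:
        for _ in range(n_surrogate):
            shifted = np.empty_like(data)
            for e in range(E):
                offs = rng.integers(1, T, size=N)
                for i, o in enumerate(offs):
                    shifted[e, i] = np.roll(data[e, i], int(o))
            null_mean = np.stack([
                _coherency_matrix(shifted[e], epochs.fs, band, metric)[iu, ju]
                for e in range(E)
            ]).mean(axis=0)
            exceed += null_mean >= observed
    p_raw = (1.0 + exceed) / (n_surrogate + 1.0)
    significant, p_adj = fdr_bh(p_raw, alpha)
    pairs = _pair_index(epochs.n_nodes)
    return EdgeTestResult(pairs, observed, p_raw, p_adj, significant,
                          np.zeros(len(pairs), dtype=int), alpha, n_surrogate,
                          kind=f"common-fc-{metric}")


def differential_fc_test(
    epochs: EpochSet,
    metric: str,
    band: tuple[float, float] = (2.0, 13.0),
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EdgeTestResult:
    """Condition differences in FC per pair: label-permutation test on
    mean(switch) - mean(repeat), two-sided, BH-FDR, signed on significance."""
    values = _per_epoch_pair_values(epochs, metric, band)
    rng = np.random.default_rng(seed)
    delta, p_raw = perm_mean_diff(values, epochs.labels.astype(int), n_perm, rng)
    significant, p_adj = fdr_bh(p_raw, alpha)
    direction = np.where(significant, np.sign(delta).astype(int), 0)
    pairs = _pair_index(epochs.n_nodes)
    return EdgeTestResult(pairs, delta, p_raw, p_adj, significant, direction,
                          alpha, n_perm, kind=f"differential-fc-{metric}")


def acm_mask(fc_result: EdgeTestResult, connectome: Connectome) -> EdgeTestResult:
    """Anatomically masked FC: keep only significant pairs that are template
    edges (the post-hoc structural-constraint baseline)."""
    n = connectome.n_nodes
    if any(i >= n or j >= n for i, j in fc_result.edge_index):
        raise ValueError("FC pair indices exceed the connectome's node count")
    template = set(connectome.edges)
    keep = np.array([e in template for e in fc_result.edge_index])
    sig = fc_result.significant & keep
    logger.info("ACM mask: %d of %d significant pairs on-template",
                int(sig.sum()), int(fc_result.significant.sum()))
    return EdgeTestResult(
        fc_result.edge_index, fc_result.statistic, fc_result.p_raw,
        fc_result.p_adj, sig, np.where(sig, fc_result.direction, 0),
        fc_result.alpha, fc_result.n_perm, kind=fc_result.kind + "-acm",
    )
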