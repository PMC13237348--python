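"""Global field power and condition-difference window detection.

GFP(t) is the spatial standard deviation across channels at each time point
(Lehmann-Skrandies convention): the spatial mean is removed, so GFP is
invariant to a common offset and scales linearly with channel-wise scaling.
Condition differences are assessed with a paired t-test across subject-mean
GFP curves at every time point, BH-FDR corrected; maximal contiguous runs of
significant samples are reported as half-open [start, end) windows in ms on
the epoch clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .data import EpochSet
from .stats import fdr_bh

__all__ = ["GFPResult", "compute_gfp", "detect_windows"]


@dataclass
class GFPResult:
    times_ms: np.ndarray
    mean: dict[int, np.ndarray]  # condition -> mean GFP curve across subjects
    ci95: dict[int, np.ndarray]  # condition -> (2, T) lower/upper bounds
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    windows_ms: list[tuple[float, float]]
    alpha: float


def compute_gfp(epochs: EpochSet) -> np.ndarray:
    """Per-epoch GFP time series, shape (epochs, samples)."""
    data = epochs.data if epochs.data.ndim == 3 else epochs.data[..., 0]
    if data.shape[1] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return data.std(axis=1, ddof=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def detect_windows(epochs: EpochSet, alpha: float = 0.05) -> GFPResult:
    """Paired per-timepoint comparison of subject-mean GFP between conditions.

    Every subject must contribute epochs of both conditions; fewer than three
    subjects is rejected (the paired test would have fewer than two degrees
    of freedom).
    """
    gfp = compute_gfp(epochs)
    subjects = np.asarray(epochs.subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 3:
        raise ValueError("window detection needs at least 3 subjects")
    per_subj = {0: [], 1: []}
    for s in uniq:
        for c in (0, 1):
            sel = (subjects == s) & (epochs.labels == c)
            if sel.sum() == 0:
                raise ValueError(f"subject {s!r} lacks condition {c} epochs")
            per_subj[c].append(gfp[sel].mean(axis=0))
    curves = {c: np.asarray(per_subj[c]) for c in (0, 1)}  # (S, T)
    n_subj = len(uniq)
    mean = {c: curves[c].mean(axis=0) for c in (0, 1)}
    ci95 = {}
    tcrit = sst.t.ppf(0.975, n_subj - 1)
    for c in (0, 1):
        sem = curves[c].std(axis=0, ddof=1) / np.sqrt(n_subj)
        ci95[c] = np.vstack([mean[c] - tcrit * sem, mean[c] + tcrit * sem])
    t_stat, p_raw = sst.ttest_rel(curves[1], curves[0], axis=0)
    # identical condition curves yield 0/0 -> NaN; no evidence of a difference
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    significant, p_adj = fdr_bh(p_raw, alpha)
    t = epochs.times_ms
    dt = 1000.0 / epochs.fs
    windows = [(float(t[a]), float(t[b - 1] + dt)) for a, b in _runs(significant)]
    return GFPResult(t, mean, ci95, np.asarray(t_stat), p_raw, p_adj,
                     significant, windows, alpha)
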