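"""Synthetic study generator with known ground truth.

Emulates the statistical structure of the cued task-switching study this
toolkit targets: a small-world binary structural connectome (default 68
nodes, 248 edges, density ~0.11), band-limited (2-13 Hz) oscillatory node
signals at 100 Hz for 20 subjects with balanced two-class cue-locked epochs,
condition-dependent lagged couplings planted on a known subset of structural
edges, and first-target reaction times linearly tied to the realized planted
coupling strength.

Coupling model: for a planted edge (i, j) with gain g the target node's
signal is the variance-preserving mixture

    x_j <- (x_j + g * lag(x_i)) / sqrt(1 + g^2)

so that condition information lives in the inter-node dependence carried by
the structural edge rather than in any node's marginal amplitude. The
injected component's variance share is g^2 / (1 + g^2), monotone in g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .data import Connectome, EpochSet, ROIAtlas, TrialTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_connectome",
    "simulate_epochs",
    "simulate_trials",
    "default_study_config",
]

#: Oscillatory components (Hz) summed at every node; all inside the 2-13 Hz
#: modeling band (delta/theta/low-alpha).
OSC_FREQS = (3.0, 6.0, 10.0)


@dataclass
class SimulationConfig:
    n_nodes: int = 68
    n_edges: int = 248
    rewire_prob: float = 0.1
    n_subjects: int = 20
    epochs_per_subject: int = 20
    class_ratio: float = 0.5
    n_samples: int = 30
    fs: float = 100.0
    t0_ms: float = 500.0
    osc_band: tuple[float, float] = (2.0, 13.0)
    phase_jitter_sd: float = 2.0  # rad; trial-to-trial phase variability
    noise_sd: float = 0.5
    # planted couplings: edge indices into the connectome's edge list
    planted_common_edges: tuple[int, ...] = ()
    common_gain: float = 0.0
    planted_diff_edges: tuple[int, ...] = ()
    diff_gains: tuple[float, float] = (2.0, 0.0)  # (g_switch, g_repeat)
    gain_jitter_sd: float = 0.2
    coupling_lag: int = 2
    # behavioral model for the first post-cue target
    rt_intercept_ms: float = 560.0
    rt_slope_ms: float = -100.0  # ms per unit gain fluctuation
    rt_noise_sd_ms: float = 40.0
    switch_cost_ms: float = 75.0
    restart_cost_ms: float = 60.0
    error_rate: float = 0.04
    # optional condition-specific amplitude modulation (for field-power tests)
    gfp_window_ms: tuple[float, float] | None = None
    gfp_gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.class_ratio < 1.0):
            raise ValueError("class_ratio must lie in (0, 1)")
        if self.common_gain < 0 or min(self.diff_gains) < 0:
            raise ValueError("coupling gains must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: edges, per-epoch realized gains, and the seed."""

    planted_common: list[tuple[int, int]]
    planted_diff: list[tuple[int, int]]
    realized_gain: np.ndarray  # (epochs,) mean realized planted gain per epoch
    expected_gain: np.ndarray  # (epochs,) configured condition-mean gain
    labels: np.ndarray
    config: SimulationConfig

    @property
    def planted_edges(self) -> list[tuple[int, int]]:
        return sorted(set(self.planted_common) | set(self.planted_diff))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_common": [list(e) for e in self.planted_common],
            "planted_diff": [list(e) for e in self.planted_diff],
            "realized_gain": self.realized_gain.tolist(),
            "expected_gain": self.expected_gain.tolist(),
            "labels": self.labels.tolist(),
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self.config).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_connectome(
    n_nodes: int,
    n_edges: int,
    rewire_prob: float = 0.1,
    seed: int = 0,
    atlas: ROIAtlas | None = None,
) -> Connectome:
    """Small-world connectome with an exact edge count.

    A connected Watts-Strogatz graph at the nearest feasible even lattice
    degree is rewired, then edges are added or removed at random (avoiding
    bridges on removal) until exactly ``n_edges`` remain.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (n_nodes <= n_edges <= max_edges):
        raise ValueError(f"cannot place {n_edges} edges on {n_nodes} nodes as a connected small-world graph")
    rng = np.random.default_rng(seed)
    k = max(2, int(2 * n_edges // n_nodes) // 2 * 2)
    G = nx.connected_watts_strogatz_graph(n_nodes, k, rewire_prob, seed=int(rng.integers(2**31)))
    while G.number_of_edges() < n_edges:
        i, j = rng.integers(n_nodes, size=2)
        if i != j and not G.has_edge(i, j):
            G.add_edge(int(i), int(j))
    while G.number_of_edges() > n_edges:
        edges = sorted(G.edges())
        bridges = set(nx.bridges(G))
        removable = [e for e in edges if e not in bridges and (e[1], e[0]) not in bridges]
        if not removable:
            raise RuntimeError("cannot reach edge count without disconnecting the graph")
        e = removable[int(rng.integers(len(removable)))]
        G.remove_edge(*e)
    A = nx.to_numpy_array(G, nodelist=range(n_nodes), dtype=np.int8)
    return Connectome(A, atlas or ROIAtlas.generic(n_nodes))


def _epoch_oscillation(cfg: SimulationConfig, subject_offset: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """One epoch's node oscillations, (N, T).

    Each node sums unit-amplitude sinusoids at OSC_FREQS. Phases combine a
    subject-specific offset (the only subject-level random effect) with
    per-epoch Gaussian phase jitter, mimicking cue-locked oscillations that
    are only partially phase-locked across trials.
    """
    t = np.arange(cfg.n_samples) / cfg.fs
    jitter = rng.normal(0.0, cfg.phase_jitter_sd, size=subject_offset.shape)
    phases = subject_offset + jitter
    out = np.zeros((cfg.n_nodes, cfg.n_samples))
    for c, f in enumerate(OSC_FREQS):
        out += np.sin(2 * np.pi * f * t[None, :] + phases[:, c : c + 1])
    return out


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """Circularly lag the last axis by ``lag`` samples."""
    return np.roll(x, lag, axis=-1)


def simulate_epochs(
    connectome: Connectome, config: SimulationConfig
) -> tuple[EpochSet, GroundTruth]:
    """Generate condition-labelled epochs on a structural connectome.

    Reproducible under ``config.seed``; planted edges must belong to the
    structural edge set (they are given as indices into ``connectome.edges``).
    """
    cfg = config
    edges = connectome.edges
    for idx in tuple(cfg.planted_common_edges) + tuple(cfg.planted_diff_edges):
        if not (0 <= idx < len(edges)):
            raise ValueError(f"planted edge index {idx} outside the structural edge set (E={len(edges)})")
    rng = np.random.default_rng(cfg.seed)
    subject_offsets = rng.uniform(0, 2 * np.pi,
                                  size=(cfg.n_subjects, cfg.n_nodes, len(OSC_FREQS)))

    n_total = cfg.n_subjects * cfg.epochs_per_subject
    labels = (rng.random(n_total) < cfg.class_ratio).astype(np.int8)
    subjects = np.repeat([f"sub{c + 1:02d}" for c in range(cfg.n_subjects)], cfg.epochs_per_subject)

    planted_common = [edges[i] for i in cfg.planted_common_edges]
    planted_diff = [edges[i] for i in cfg.planted_diff_edges]

    data = np.empty((n_total, cfg.n_nodes, cfg.n_samples))
    realized = np.zeros(n_total)
    expected = np.zeros(n_total)
    for e in range(n_total):
        s = e // cfg.epochs_per_subject
        osc = _epoch_oscillation(cfg, subject_offsets[s], rng)
        x = osc.copy()
        gains_this = []
        g_cond = cfg.diff_gains[0] if labels[e] == 1 else cfg.diff_gains[1]
        for (i, j), g0 in [((i, j), cfg.common_gain) for i, j in planted_common] + [
            ((i, j), g_cond) for i, j in planted_diff
        ]:
            g = g0
            if g > 0 and cfg.gain_jitter_sd > 0:
                g = max(0.0, g + rng.normal(0, cfg.gain_jitter_sd))
            if g > 0:
                x[j] = (x[j] + g * _lagged(osc[i], cfg.coupling_lag)) / np.sqrt(1 + g * g)
            gains_this.append(g)
        if cfg.noise_sd > 0:
            x = x + rng.normal(0, cfg.noise_sd, size=x.shape)
        if cfg.gfp_window_ms is not None and labels[e] == 1 and cfg.gfp_gain != 1.0:
            t_ms = cfg.t0_ms + 1000.0 * np.arange(cfg.n_samples) / cfg.fs
            win = (t_ms >= cfg.gfp_window_ms[0]) & (t_ms < cfg.gfp_window_ms[1])
            x[:, win] *= cfg.gfp_gain
        data[e] = x
        realized[e] = float(np.mean(gains_this)) if gains_this else 0.0
        base_gains = [cfg.common_gain] * len(planted_common) + [g_cond] * len(planted_diff)
        expected[e] = float(np.mean(base_gains)) if base_gains else 0.0

    epochs = EpochSet(data, labels, subjects, cfg.fs, cfg.t0_ms)
    return epochs, GroundTruth(planted_common, planted_diff, realized, expected,
                               labels.copy(), cfg)


def simulate_trials(
    ground_truth: GroundTruth, rng: np.random.Generator | None = None
) -> tuple[TrialTable, np.ndarray]:
    """Behavioral trials for every simulated cue epoch.

    The first post-cue target's RT follows the linear model
    intercept + slope * (realized planted gain - condition mean gain)
    + switch cost + Gaussian noise, so condition mean RTs are set by the
    switch cost while trial-level RT variability tracks the realized
    coupling strength; later targets relax toward the intercept minus the
    restart cost. Returns the trial table and the first-target RTs aligned
    to the epoch order.
    """
    import pandas as pd

    cfg = ground_truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = ground_truth.realized_gain.shape[0]
    labels = ground_truth.labels
    subjects = np.repeat([f"sub{c + 1:02d}" for c in range(cfg.n_subjects)], cfg.epochs_per_subject)

    rows = []
    rt1 = np.zeros(n)
    for e in range(n):
        cue = "switch" if labels[e] == 1 else "repeat"
        gain_fluct = ground_truth.realized_gain[e] - ground_truth.expected_gain[e]
        base = cfg.rt_intercept_ms + cfg.rt_slope_ms * gain_fluct
        if labels[e] == 1:
            base += cfg.switch_cost_ms
        rts = [
            base + rng.normal(0, cfg.rt_noise_sd_ms),
            base - 0.5 * cfg.restart_cost_ms + rng.normal(0, cfg.rt_noise_sd_ms),
            base - cfg.restart_cost_ms + rng.normal(0, cfg.rt_noise_sd_ms),
        ]
        rt1[e] = rts[0]
        for pos, rt in enumerate(rts, start=1):
            correct = int(rng.random() >= cfg.error_rate)
            rows.append((subjects[e], cue, pos, max(rt, 1.0), correct, e))
    df = pd.DataFrame(rows, columns=["subject", "cue", "target_position", "rt_ms", "correct", "epoch"])
    table = TrialTable(df, epoch_index=df["epoch"].to_numpy())
    return table, rt1


def default_study_config(seed: int = 0, n_planted: int = 8) -> SimulationConfig:
    """The canonical synthetic study: 68/248 small-world template, 20 subjects
    x 20 balanced epochs of 300 ms (T=30 at 100 Hz), with ``n_planted``
    structural edges carrying condition-dependent coupling (gain 2.0 in
    'switch', 0.0 in 'repeat')."""
    rng = np.random.default_rng(seed)
    planted = tuple(int(i) for i in rng.choice(248, size=n_planted, replace=False))
    return SimulationConfig(planted_diff_edges=planted, seed=seed)
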