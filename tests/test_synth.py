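"""Synthetic-study generator: connectome topology, signal couplings,
behavioral model, determinism."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from acgfc.synth import (
    SimulationConfig,
    default_study_config,
    make_connectome,
    simulate_epochs,
    simulate_trials,
)


class TestMakeConnectome:
    def test_ring_lattice_without_rewiring(self):
        conn = make_connectome(6, 6, rewire_prob=0.0, seed=0)
        assert conn.n_edges == 6
        assert np.all(conn.adjacency.sum(axis=1) == 2)

    def test_template_scale_density(self):
        conn = make_connectome(68, 248, 0.1, seed=0)
        assert conn.n_edges == 248
        assert round(conn.density, 2) == 0.11

    def test_exact_edge_count_and_connectivity(self):
        for n_edges in (70, 248, 400):
            conn = make_connectome(68, n_edges, 0.15, seed=3)
            assert conn.n_edges == n_edges
            assert nx.is_connected(nx.from_numpy_array(conn.adjacency))

    def test_deterministic_under_seed(self):
        a = make_connectome(30, 80, 0.1, seed=9)
        b = make_connectome(30, 80, 0.1, seed=9)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_small_world_sigma_exceeds_one(self):
        """sigma = (C / C_rand) / (L / L_rand) against degree-matched
        random graphs (edge-count-matched Erdos-Renyi oracle)."""
        conn = make_connectome(68, 248, 0.1, seed=1)
        G = nx.from_numpy_array(conn.adjacency)
        C, L = nx.average_clustering(G), nx.average_shortest_path_length(G)
        rng = np.random.default_rng(0)
        Cr, Lr = [], []
        draws = 0
        while len(Cr) < 50 and draws < 500:
            draws += 1
            R = nx.gnm_random_graph(68, 248, seed=int(rng.integers(2**31)))
            if not nx.is_connected(R):
                continue
            Cr.append(nx.average_clustering(R))
            Lr.append(nx.average_shortest_path_length(R))
        sigma = (C / np.mean(Cr)) / (L / np.mean(Lr))
        assert sigma > 1.0

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            make_connectome(10, 100, 0.1, seed=0)


class TestSimulateEpochs:
    def _tiny(self, **kw):
        base = dict(n_nodes=10, n_edges=20, n_subjects=4, epochs_per_subject=10,
                    n_samples=50, seed=5)
        base.update(kw)
        return SimulationConfig(**base)

    def test_seed_reproducibility_bit_identical(self):
        cfg = self._tiny()
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        a, _ = simulate_epochs(conn, cfg)
        b, _ = simulate_epochs(conn, cfg)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_coupling_zero_noise_deterministic_oscillation(self):
        cfg = self._tiny(noise_sd=0.0, n_samples=100)
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        eps, _ = simulate_epochs(conn, cfg)
        again, _ = simulate_epochs(conn, cfg)
        assert np.array_equal(eps.data, again.data)
        # each epoch is a pure sum of band sinusoids: spectrum confined to
        # the component frequencies
        spec = np.abs(np.fft.rfft(eps.data[0, 0]))
        freqs = np.fft.rfftfreq(cfg.n_samples, 1 / cfg.fs)
        power_in = spec[np.isin(freqs, (3.0, 6.0, 10.0))].sum()
        assert power_in / spec.sum() > 0.95

    def test_planted_edge_raises_lagged_crosscorrelation(self):
        cfg = self._tiny(planted_diff_edges=(3,), diff_gains=(2.0, 2.0),
                         gain_jitter_sd=0.0, coupling_lag=2, n_samples=100)
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        eps, gt = simulate_epochs(conn, cfg)
        (pi, pj) = gt.planted_diff[0]

        def lagcorr(a, b, lag):
            a, b = a[..., :-lag], b[..., lag:]
            a = a - a.mean(-1, keepdims=True)
            b = b - b.mean(-1, keepdims=True)
            return (a * b).sum(-1) / np.sqrt((a**2).sum(-1) * (b**2).sum(-1))

        scores = {}
        for (i, j) in conn.edges:
            scores[(i, j)] = np.abs(np.mean(lagcorr(eps.data[:, i], eps.data[:, j],
                                                    cfg.coupling_lag)))
        planted_score = scores.pop((pi, pj))
        assert planted_score > np.percentile(list(scores.values()), 95)

    def test_label_counts_within_binomial_interval(self):
        cfg = self._tiny(n_subjects=20, epochs_per_subject=20, class_ratio=0.5)
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        eps, _ = simulate_epochs(conn, cfg)
        n1 = int(eps.labels.sum())
        # binomial 99% interval around 200 of 400
        assert abs(n1 - 200) <= 2.58 * np.sqrt(400 * 0.25)

    def test_coupling_variance_share_matches_analytic_curve(self):
        """The injected component's variance share should track
        g^2 / (1 + g^2) and grow monotonically with the gain."""
        shares = []
        for g in (0.5, 1.0, 2.0):
            cfg = self._tiny(planted_diff_edges=(0,), diff_gains=(g, g),
                             gain_jitter_sd=0.0, noise_sd=0.0, phase_jitter_sd=0.0,
                             epochs_per_subject=4)
            conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
            eps, gt = simulate_epochs(conn, cfg)
            base_cfg = dataclasses.replace(cfg, planted_diff_edges=(), diff_gains=(0.0, 0.0))
            base, _ = simulate_epochs(conn, base_cfg)
            (i, j) = gt.planted_diff[0]
            injected = eps.data[:, j] - base.data[:, j] / np.sqrt(1 + g * g)
            share = injected.var() / eps.data[:, j].var()
            shares.append(share)
            assert share == pytest.approx(g * g / (1 + g * g), rel=0.35)
        assert shares[0] < shares[1] < shares[2]

    def test_planted_edge_outside_template_rejected(self):
        cfg = self._tiny(planted_diff_edges=(99,))
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        with pytest.raises(ValueError):
            simulate_epochs(conn, cfg)

    def test_no_planted_edges_conditions_exchangeable(self):
        cfg = self._tiny()
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        eps, _ = simulate_epochs(conn, cfg)
        v1 = eps.data[eps.labels == 1].var(axis=(0, 2)).mean()
        v0 = eps.data[eps.labels == 0].var(axis=(0, 2)).mean()
        assert v1 == pytest.approx(v0, rel=0.05)


class TestSimulateTrials:
    def _truth(self, **kw):
        cfg_kw = dict(n_nodes=10, n_edges=20, n_subjects=5, epochs_per_subject=12,
                      planted_diff_edges=(1,), seed=6)
        cfg_kw.update(kw)
        cfg = SimulationConfig(**cfg_kw)
        conn = make_connectome(cfg.n_nodes, cfg.n_edges, seed=cfg.seed)
        _, gt = simulate_epochs(conn, cfg)
        return gt

    def test_zero_slope_zero_noise_constant_rts(self):
        gt = self._truth(rt_slope_ms=0.0, rt_noise_sd_ms=0.0, switch_cost_ms=0.0,
                         restart_cost_ms=0.0)
        trials, rt1 = simulate_trials(gt)
        assert np.allclose(rt1, gt.config.rt_intercept_ms)
        assert np.allclose(trials.df["rt_ms"], gt.config.rt_intercept_ms)

    def test_exact_linearity_gives_perfect_correlation(self):
        gt = self._truth(rt_slope_ms=-50.0, rt_noise_sd_ms=0.0, switch_cost_ms=0.0,
                         gain_jitter_sd=0.3)
        _, rt1 = simulate_trials(gt)
        sel = gt.labels == 1  # constant condition: RT purely gain-driven
        r = np.corrcoef(gt.realized_gain[sel], rt1[sel])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_noisy_correlation_matches_analytic_value(self):
        gt = self._truth(n_subjects=20, epochs_per_subject=30, rt_slope_ms=-50.0,
                         rt_noise_sd_ms=30.0, switch_cost_ms=0.0, gain_jitter_sd=0.3)
        _, rt1 = simulate_trials(gt)
        sel = gt.labels == 1
        g = gt.realized_gain[sel]
        expected = -50.0 * g.std() / np.sqrt((50.0 * g.std()) ** 2 + 30.0**2)
        r = np.corrcoef(g, rt1[sel])[0, 1]
        assert r == pytest.approx(expected, abs=0.1)

    def test_switch_cost_visible_in_mean_rts(self):
        gt = self._truth(rt_noise_sd_ms=10.0, switch_cost_ms=80.0,
                         diff_gains=(0.0, 0.0))
        trials, _ = simulate_trials(gt)
        df = trials.df[trials.df["target_position"] == 1]
        sw = df[df["cue"] == "switch"]["rt_ms"].mean()
        rp = df[df["cue"] == "repeat"]["rt_ms"].mean()
        assert sw > rp


def test_default_study_config_is_template_scale():
    cfg = default_study_config(seed=0)
    assert (cfg.n_nodes, cfg.n_edges) == (68, 248)
    assert cfg.n_subjects * cfg.epochs_per_subject == 400
    assert len(cfg.planted_diff_edges) == 8
    assert cfg.n_samples == 30 and cfg.fs == 100.0
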