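"""Phase- and coherence-based FC metrics and their significance tests."""

import numpy as np
import pytest

from acgfc.data import EpochSet
from acgfc.fc import acm_mask, common_fc_test, differential_fc_test, fc_matrix, fc_metric
from acgfc.stats import EdgeTestResult

FS = 100.0
BAND = (2.0, 13.0)


def _tone(freq, T=500, phase=0.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(T) / fs + phase)


class TestFcMetric:
    def test_identical_signals_closed_forms(self):
        x = _tone(6.0)
        assert fc_metric(x, x, "plv", FS, BAND) == pytest.approx(1.0, abs=1e-6)
        assert fc_metric(x, x, "coh", FS, BAND) == pytest.approx(1.0, abs=1e-6)
        assert fc_metric(x, x, "imcoh", FS, BAND) == pytest.approx(0.0, abs=1e-6)

    def test_constant_phase_offset_gives_unit_plv(self):
        # exact on phase series; near-exact on raw tones (Hilbert edge effects)
        phi = np.linspace(0, 40 * np.pi, 400)
        assert fc_metric(phi, phi - np.pi / 3, "plv", is_phase=True) == pytest.approx(1.0)
        a, b = _tone(6.0), _tone(6.0, phase=np.pi / 3)
        assert fc_metric(a, b, "plv", FS, BAND) == pytest.approx(1.0, abs=5e-3)

    def test_ppc_matches_pairwise_cosine_oracle(self, rng):
        # O(n^2) oracle: mean cos(phi_a_j - phi_b_j - (phi_a_k - phi_b_k))
        for n in (10, 30, 50):
            dphi = rng.uniform(0, 2 * np.pi, size=n)
            acc = 0.0
            for j in range(n):
                for k in range(n):
                    if j != k:
                        acc += np.cos(dphi[j] - dphi[k])
            oracle = acc / (n * (n - 1))
            got = fc_metric(dphi, np.zeros(n), "ppc", is_phase=True)
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_independent_phases_give_small_plv(self, rng):
        n = 10000
        a = rng.uniform(0, 2 * np.pi, n)
        b = rng.uniform(0, 2 * np.pi, n)
        assert fc_metric(a, b, "plv", is_phase=True) < 0.05

    def test_plv_positive_bias_ppc_unbiased_under_independence(self):
        n, reps = 200, 300
        plvs, ppcs = [], []
        for rep in range(reps):
            r = np.random.default_rng(rep)
            dphi = r.uniform(0, 2 * np.pi, n)
            zeros = np.zeros(n)
            plvs.append(fc_metric(dphi, zeros, "plv", is_phase=True))
            ppcs.append(fc_metric(dphi, zeros, "ppc", is_phase=True))
        # PLV bias ~ sqrt(pi)/2/sqrt(n); PPC centred on zero
        assert np.mean(plvs) == pytest.approx(np.sqrt(np.pi) / 2 / np.sqrt(n), rel=0.15)
        assert abs(np.mean(ppcs)) < 3.0 / n

    def test_imcoh_zero_for_zero_lag_mixture(self, rng):
        # two zero-lag mixtures of one source: volume-conduction insensitivity
        s = rng.normal(size=600)
        a, b = 1.5 * s, 0.4 * s
        assert fc_metric(a, b, "imcoh", FS, BAND) == pytest.approx(0.0, abs=1e-8)

    def test_amplitude_rescaling_invariance(self, rng):
        a = rng.normal(size=400)
        b = np.roll(a, 3) + 0.2 * rng.normal(size=400)
        for metric in ("plv", "ppc", "coh", "imcoh"):
            v1 = fc_metric(a, b, metric, FS, BAND)
            v2 = fc_metric(5.0 * a, 0.1 * b, metric, FS, BAND)
            assert v1 == pytest.approx(v2, abs=1e-9)

    def test_matrix_agrees_with_pairwise_scalar(self, rng):
        data = rng.normal(size=(4, 256))
        for metric in ("plv", "coh", "imcoh"):
            M = fc_matrix(data, FS, BAND, metric).matrix
            assert np.allclose(M, M.T)
            v = fc_metric(data[0], data[2], metric, FS, BAND)
            assert M[0, 2] == pytest.approx(v, abs=1e-9)


def _coupled_epochs(rng, n_epochs=24, N=6, T=200, coupled=(0, 1), by_label=False):
    """Broadband-noise epochs; the `coupled` pair shares a strong common
    component (always, or only in label-1 epochs when by_label), so only that
    pair is phase-locked within the analysis band."""
    data = rng.normal(size=(n_epochs, N, T))
    labels = np.arange(n_epochs) % 2
    for e in range(n_epochs):
        if not by_label or labels[e] == 1:
            shared = rng.normal(size=T)
            for n in coupled:
                data[e, n] += 3.0 * shared
    subjects = np.array([f"s{e % 4}" for e in range(n_epochs)])
    return EpochSet(data, labels, subjects, FS, 0.0)


class TestCommonFcTest:
    def test_planted_coupling_detected(self, rng):
        # enough surrogates that the p floor survives the FDR correction
        eps = _coupled_epochs(rng, n_epochs=12)
        res = common_fc_test(eps, "plv", n_surrogate=400, seed=0)
        assert (0, 1) in res.significant_edges

    def test_type_one_error_on_independent_nodes(self):
        flagged = total = 0
        for rep in range(25):
            r = np.random.default_rng(300 + rep)
            eps = EpochSet(r.normal(size=(10, 5, 120)), np.arange(10) % 2,
                           np.array(["s"] * 10), FS, 0.0)
            res = common_fc_test(eps, "plv", n_surrogate=120, seed=rep)
            flagged += res.significant.sum()
            total += len(res.edge_index)
        assert flagged / total <= 0.05

    def test_surrogate_destroys_locking(self, rng):
        eps = _coupled_epochs(rng, n_epochs=8)
        res = common_fc_test(eps, "plv", n_surrogate=120, seed=1)
        i = res.edge_index.index((0, 1))
        assert res.p_raw[i] <= 2 / 121


class TestDifferentialFcTest:
    def test_label_swap_negates_signs(self, rng):
        eps = _coupled_epochs(rng, by_label=True)
        res = differential_fc_test(eps, "plv", n_perm=300, seed=0)
        swapped = EpochSet(eps.data, 1 - eps.labels, eps.subjects, eps.fs, eps.t0_ms)
        res2 = differential_fc_test(swapped, "plv", n_perm=300, seed=0)
        assert np.allclose(res.statistic, -res2.statistic)
        assert np.allclose(res.p_raw, res2.p_raw)

    def test_planted_condition_coupling_detected_with_sign(self, rng):
        eps = _coupled_epochs(rng, n_epochs=40, by_label=True)
        res = differential_fc_test(eps, "plv", n_perm=500, seed=0)
        i = res.edge_index.index((0, 1))
        assert res.significant[i]
        assert res.direction[i] == 1  # stronger in the switch condition

    def test_exchangeable_conditions_type_one(self):
        flagged = total = 0
        for rep in range(20):
            r = np.random.default_rng(400 + rep)
            eps = EpochSet(r.normal(size=(12, 5, 100)), np.arange(12) % 2,
                           np.array(["s"] * 12), FS, 0.0)
            res = differential_fc_test(eps, "plv", n_perm=200, seed=rep)
            flagged += res.significant.sum()
            total += len(res.edge_index)
        assert flagged / total <= 0.05


class TestAcmMask:
    def _result(self, pairs, sig):
        n = len(pairs)
        return EdgeTestResult(pairs, np.ones(n), np.full(n, 0.01), np.full(n, 0.02),
                              np.asarray(sig, bool), np.zeros(n, int), 0.05, 100)

    def test_intersection_counts(self, small_connectome):
        template = small_connectome.edges
        off = [(i, j) for i in range(10) for j in range(i + 1, 10) if (i, j) not in template]
        pairs = template[:3] + off[:2]
        res = acm_mask(self._result(pairs, [True] * 5), small_connectome)
        assert res.significant.sum() == 3

    def test_disjoint_fc_set_gives_empty_mask(self, small_connectome):
        off = [(i, j) for i in range(10) for j in range(i + 1, 10)
               if (i, j) not in small_connectome.edges]
        res = acm_mask(self._result(off[:4], [True] * 4), small_connectome)
        assert res.significant.sum() == 0

    def test_subset_fc_set_fully_retained(self, small_connectome):
        pairs = small_connectome.edges[:5]
        res = acm_mask(self._result(pairs, [True] * 5), small_connectome)
        assert res.significant.sum() == 5
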