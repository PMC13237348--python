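"""Graph Laplacian, Chebyshev filtering, the recurrent graph classifier, its
hand-written gradients, evaluation metrics, and the MAR(1) baseline."""

import numpy as np
import pytest

from acgfc.data import Connectome, EpochSet, ROIAtlas
from acgfc.models import (
    GRUBaseline,
    TGCN,
    TrainConfig,
    cheb_conv,
    classify_mar1,
    evaluate,
    fit_mar1,
    scaled_laplacian,
    subject_folds,
    tgcn_forward,
    train_model,
)
from acgfc.models.nn import cross_entropy, softmax
from acgfc.synth import make_connectome


class TestScaledLaplacian:
    def test_empty_graph_gives_minus_identity(self):
        conn = Connectome(np.zeros((4, 4), dtype=np.int8), ROIAtlas.generic(4))
        slap = scaled_laplacian(conn)
        # A-hat = I, D = I, L = 0, so L-tilde = -I
        assert np.allclose(slap.Lt, -np.eye(4))

    def test_spectrum_in_unit_interval(self, small_connectome):
        ev = np.linalg.eigvalsh(scaled_laplacian(small_connectome).Lt)
        assert ev.min() >= -1 - 1e-9 and ev.max() <= 1 + 1e-9

    def test_isomorphic_graphs_share_spectrum(self, small_connectome, rng):
        perm = rng.permutation(10)
        A = small_connectome.adjacency[np.ix_(perm, perm)]
        other = Connectome(A, ROIAtlas.generic(10))
        e1 = np.linalg.eigvalsh(scaled_laplacian(small_connectome).Lt)
        e2 = np.linalg.eigvalsh(scaled_laplacian(other).Lt)
        assert np.allclose(np.sort(e1), np.sort(e2))

    def test_edge_weight_parameterization_recovers_template(self, small_connectome):
        slap = scaled_laplacian(small_connectome)
        assert np.allclose(slap.with_edge_weights(np.ones(slap.n_edges)), slap.Lt)


class TestChebConv:
    def test_order_zero_identity_filter(self, rng):
        X = rng.normal(size=(5, 3))
        theta = np.eye(3)[None]  # K = 0, theta_0 = I
        out = cheb_conv(X, np.zeros((5, 5)), theta, activation=lambda z: z)
        assert np.allclose(out, X)

    def test_two_node_hand_unrolled_oracle(self):
        # path graph on 2 nodes: A-hat = [[1,1],[1,1]], D = 2I
        conn = Connectome(np.array([[0, 1], [1, 0]], dtype=np.int8), ROIAtlas.generic(2))
        slap = scaled_laplacian(conn)
        X = np.array([[1.0], [2.0]])
        th0, th1 = 0.5, -1.25
        theta = np.array([[[th0]], [[th1]]])
        expected = th0 * X + th1 * (slap.Lt @ X)
        out = cheb_conv(X, slap.Lt, theta, activation=lambda z: z)
        assert np.allclose(out, expected)

    def test_permutation_equivariance(self, small_connectome, rng):
        slap = scaled_laplacian(small_connectome)
        X = rng.normal(size=(10, 2))
        theta = rng.normal(size=(3, 2, 4))
        perm = rng.permutation(10)
        P = np.eye(10)[perm]
        conn_p = Connectome(small_connectome.adjacency[np.ix_(perm, perm)],
                            ROIAtlas.generic(10))
        out_p = cheb_conv(X[perm], scaled_laplacian(conn_p).Lt, theta)
        assert np.allclose(out_p, cheb_conv(X, slap.Lt, theta)[perm], atol=1e-10)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            cheb_conv(np.zeros((3, 1)), np.zeros((3, 3)), np.zeros((0, 1, 2)))


class TestTGCNForward:
    def test_single_step_single_node_matches_hand_unrolled_gru(self):
        conn = Connectome(np.zeros((1, 1), dtype=np.int8), ROIAtlas.generic(1))
        slap = scaled_laplacian(conn)
        model = TGCN(1, 1, cheb_order=0, cheb_channels=1, hidden=1, seed=0,
                     activation="relu", dtype=np.float64)
        p = model.params
        p["theta"][:] = 1.0
        for k in ("Wu", "bu", "Wr", "br", "Wh", "bh"):
            p[k][:] = 0.3
        p["Wo"][:] = np.array([[1.0], [-1.0]]).T
        p["bo"][:] = 0.0
        x = 0.7
        hc = max(x, 0.0)  # conv with theta=1 then ReLU
        sig = lambda v: 1 / (1 + np.exp(-v))
        u = sig(0.3 * hc + 0.3)          # h_prev = 0
        r = sig(0.3 * hc + 0.3)
        cand = np.tanh(0.3 * hc + 0.3)   # r * h_prev = 0
        h = u * 0 + (1 - u) * cand
        logits = tgcn_forward(model, np.array([[[x]]]), slap.Lt)
        assert logits[0] == pytest.approx(h, rel=1e-6)
        assert logits[1] == pytest.approx(-h, rel=1e-6)

    def test_duplicate_epoch_deterministic(self, small_connectome, rng):
        slap = scaled_laplacian(small_connectome)
        model = TGCN(10, 1, seed=1)
        X = np.repeat(rng.normal(size=(1, 6, 10, 1)), 2, axis=0)
        logits, _ = model.forward(X, slap.Lt)
        assert np.allclose(logits[0], logits[1])

    def test_nan_input_rejected(self, small_connectome):
        slap = scaled_laplacian(small_connectome)
        model = TGCN(10, 1, seed=1)
        X = np.full((1, 3, 10, 1), np.nan)
        with pytest.raises(ValueError):
            model.forward(X, slap.Lt)

    def test_relabeling_equivariance_with_matched_readout(self, small_connectome, rng):
        """Permuting nodes in (A, X) and permuting the readout blocks the same
        way leaves the logits unchanged."""
        slap = scaled_laplacian(small_connectome)
        model = TGCN(10, 1, hidden=4, seed=3, dtype=np.float64)
        X = rng.normal(size=(2, 5, 10, 1))
        logits, _ = model.forward(X, slap.Lt)
        perm = rng.permutation(10)
        conn_p = Connectome(small_connectome.adjacency[np.ix_(perm, perm)],
                            ROIAtlas.generic(10))
        slap_p = scaled_laplacian(conn_p)
        model_p = TGCN(10, 1, hidden=4, seed=3, dtype=np.float64)
        for k, v in model.params.items():
            model_p.params[k] = v.copy()
        Wo = model.params["Wo"].reshape(10, 4, 2)
        model_p.params["Wo"] = Wo[perm].reshape(40, 2)
        logits_p, _ = model_p.forward(X[:, :, perm], slap_p.Lt)
        assert np.allclose(logits_p, logits, atol=1e-9)


class TestGradients:
    """Finite-difference verification of the hand-written backprop."""

    def _loss(self, model, X, y, Lt=None):
        logits, _ = model.forward(X, Lt) if Lt is not None else model.forward(X)
        return cross_entropy(softmax(logits), y)

    @pytest.mark.parametrize("activation", ["square", "relu"])
    def test_tgcn_parameter_gradients(self, activation, rng):
        conn = make_connectome(6, 9, 0.2, seed=5)
        slap = scaled_laplacian(conn)
        model = TGCN(6, 2, cheb_order=2, cheb_channels=3, hidden=4, seed=7,
                     activation=activation, dtype=np.float64)
        X = rng.normal(size=(3, 4, 6, 2))
        y = np.array([0, 1, 1])
        logits, cache = model.forward(X, slap.Lt)
        probs = softmax(logits)
        dl = probs.copy()
        dl[np.arange(3), y] -= 1
        dl /= 3
        grads, _ = model.backward(cache, dl)
        eps = 1e-6
        for k, g in grads.items():
            P = model.params[k]
            idx = tuple(r % s for r, s in zip((1, 2, 3), P.shape))
            old = P[idx]
            P[idx] = old + eps
            lp = self._loss(model, X, y, slap.Lt)
            P[idx] = old - eps
            lm = self._loss(model, X, y, slap.Lt)
            P[idx] = old
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-10), k

    def test_laplacian_gradient_matches_finite_difference(self, rng):
        conn = make_connectome(6, 9, 0.2, seed=5)
        slap = scaled_laplacian(conn)
        model = TGCN(6, 1, cheb_order=2, cheb_channels=3, hidden=3, seed=2,
                     dtype=np.float64)
        X = rng.normal(size=(2, 4, 6, 1))
        y = np.array([1, 0])
        logits, cache = model.forward(X, slap.Lt)
        onehot = np.eye(2)[y]
        _, dLt = model.backward(cache, onehot, need_edge_grad=True)
        total = dLt.sum(axis=0)
        eps = 1e-6
        for (i, j) in [(0, 1), (3, 2), (5, 5)]:
            Lp, Lm = slap.Lt.copy(), slap.Lt.copy()
            Lp[i, j] += eps
            Lm[i, j] -= eps
            fp = model.forward(X, Lp)[0][np.arange(2), y].sum()
            fm = model.forward(X, Lm)[0][np.arange(2), y].sum()
            num = (fp - fm) / (2 * eps)
            assert total[i, j] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_gru_baseline_gradients(self, rng):
        model = GRUBaseline(5, 1, hidden=4, seed=3, dtype=np.float64)
        X = rng.normal(size=(3, 6, 5, 1))
        y = np.array([1, 0, 1])
        logits, cache = model.forward(X)
        probs = softmax(logits)
        dl = probs.copy()
        dl[np.arange(3), y] -= 1
        dl /= 3
        grads, _ = model.backward(cache, dl)
        eps = 1e-6
        for k, g in grads.items():
            P = model.params[k]
            idx = tuple(r % s for r, s in zip((0, 1), P.shape))
            old = P[idx]
            P[idx] = old + eps
            lp = self._loss(model, X, y)
            P[idx] = old - eps
            lm = self._loss(model, X, y)
            P[idx] = old
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-10), k


class TestEvaluate:
    def test_perfect_probabilities(self):
        m = evaluate(np.array([1, 0, 1, 0]), np.array([1.0, 0.0, 1.0, 0.0]))
        assert m["accuracy"] == m["f1"] == m["mcc"] == m["auroc"] == 1.0

    def test_auroc_rank_oracle(self):
        m = evaluate(np.array([1, 0, 1, 0]), np.array([0.9, 0.1, 0.8, 0.2]))
        assert m["auroc"] == 1.0  # all 4 positive-negative pairs ordered

    def test_constant_half_predictions_give_zero_mcc(self):
        m = evaluate(np.array([1, 0, 1]), np.array([0.5, 0.5, 0.5]))
        assert m["mcc"] == 0.0

    def test_single_class_auroc_missing(self):
        m = evaluate(np.array([1, 1]), np.array([0.9, 0.8]))
        assert m["auroc"] is None


class TestSubjectFolds:
    def test_folds_partition_subjects(self):
        subjects = np.repeat([f"s{i}" for i in range(20)], 5)
        folds = subject_folds(subjects, 10, seed=1)
        assert len(folds) == 10
        counts = np.zeros(len(subjects), dtype=int)
        for mask in folds:
            held = set(subjects[mask])
            assert len(held) == 2
            counts += mask
        assert np.all(counts == 1)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            subject_folds(np.array(["a", "b"]), 10, 0)


class TestMAR:
    def _masked_system(self, conn, rng, spectral_radius=0.6):
        N = conn.n_nodes
        mask = conn.adjacency.astype(bool) | np.eye(N, dtype=bool)
        A = rng.normal(0, 1.0, size=(N, N)) * mask
        A *= spectral_radius / np.max(np.abs(np.linalg.eigvals(A)))
        return A, mask

    def _simulate(self, A, n_epochs, T, noise, rng):
        N = A.shape[0]
        out = np.zeros((n_epochs, N, T))
        for e in range(n_epochs):
            x = rng.normal(size=N)
            for t in range(T):
                x = A @ x + rng.normal(0, noise, size=N)
                out[e, :, t] = x
        return out

    def test_parameter_recovery_small_noise(self, rng):
        conn = make_connectome(8, 14, 0.2, seed=3)
        A, mask = self._masked_system(conn, rng)
        data = self._simulate(A, 30, 80, 0.01, rng)
        eps = EpochSet(np.concatenate([data, data]), np.r_[np.zeros(30), np.ones(30)],
                       np.array(["s"] * 60), 100.0)
        model = fit_mar1(eps, conn)
        assert np.max(np.abs(model.transition[0] - A)) < 0.05
        assert np.all(model.transition[0][~mask] == 0)

    def test_two_distinct_systems_classified(self, rng):
        conn = make_connectome(8, 14, 0.2, seed=4)
        A0, _ = self._masked_system(conn, rng)
        A1, _ = self._masked_system(conn, rng)
        tr = np.concatenate([self._simulate(A0, 40, 60, 0.1, rng),
                             self._simulate(A1, 40, 60, 0.1, rng)])
        te = np.concatenate([self._simulate(A0, 20, 60, 0.1, rng),
                             self._simulate(A1, 20, 60, 0.1, rng)])
        y_tr = np.r_[np.zeros(40, int), np.ones(40, int)]
        y_te = np.r_[np.zeros(20, int), np.ones(20, int)]
        eps_tr = EpochSet(tr, y_tr, np.array(["s"] * 80), 100.0)
        eps_te = EpochSet(te, y_te, np.array(["s"] * 40), 100.0)
        model = fit_mar1(eps_tr, conn)
        labels, _ = classify_mar1(model, eps_te)
        assert (labels == y_te).mean() >= 0.90

    def test_identical_generators_classify_at_chance(self, rng):
        conn = make_connectome(8, 14, 0.2, seed=5)
        A, _ = self._masked_system(conn, rng)
        tr = self._simulate(A, 80, 60, 0.1, rng)
        y = np.arange(80) % 2
        model = fit_mar1(EpochSet(tr, y, np.array(["s"] * 80), 100.0), conn)
        te = self._simulate(A, 60, 60, 0.1, rng)
        labels, _ = classify_mar1(model, EpochSet(te, np.arange(60) % 2,
                                                  np.array(["s"] * 60), 100.0))
        # symmetric null: accuracy inside the binomial 99% interval around 0.5
        assert abs((labels == np.arange(60) % 2).mean() - 0.5) < 2.58 * 0.5 / np.sqrt(60)
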