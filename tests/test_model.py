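import numpy as np
import pytest

from csdgi import ExpressionMatrix, ModelConfig, assign_subtypes, compute_lambda, fit, total_loss
from csdgi.model import (
    CSDGIModel,
    DecoderSharedParams,
    EncoderParams,
    SubtypeBranchParams,
    _backward,
    decoder_forward,
    encoder_forward,
    gene_weights,
    init_model,
    lowrank_propagate,
    weighted_cell_loss,
)


def _branch(V, M=None, E=None):
    V = np.atleast_2d(np.asarray(V, float).ravel()).T
    n = V.shape[0]
    return SubtypeBranchParams(
        V=V,
        M=np.ones(n) if M is None else np.asarray(M, float),
        E=np.zeros(n) if E is None else np.asarray(E, float),
    )


class TestInit:
    def test_deterministic_given_seed(self):
        a = init_model(ModelConfig(seed=5), 10)
        b = init_model(ModelConfig(seed=5), 10)
        np.testing.assert_array_equal(a.branches[0].V, b.branches[0].V)
        np.testing.assert_array_equal(a.encoder.weights[0], b.encoder.weights[0])
        c = init_model(ModelConfig(seed=6), 10)
        assert not np.array_equal(a.branches[0].V, c.branches[0].V)

    def test_initial_loss_finite_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(2.0, 0.5, (50, 30))
        model = init_model(ModelConfig(n_subtypes=3, seed=0), 30)
        loss, _ = total_loss(X, model)
        assert np.isfinite(loss)


class TestEncoder:
    def test_zero_weights_identity(self):
        enc = EncoderParams([np.zeros((3, 3))] * 2, [np.zeros(3)] * 2)
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(encoder_forward(x, enc), x)

    def test_hand_computed_single_block(self):
        enc = EncoderParams([np.array([[1.0, 0.0], [0.0, -1.0]])], [np.zeros(2)])
        out = encoder_forward(np.array([1.0, 1.0]), enc)
        np.testing.assert_allclose(out, [2.0, 1.0])

    def test_blocks_telescope(self):
        """Sequential residual blocks equal the input plus the sum of the
        per-block nonlinear terms."""
        rng = np.random.default_rng(1)
        enc = EncoderParams(
            [rng.normal(0, 0.2, (4, 4)) for _ in range(3)],
            [rng.normal(0, 0.1, 4) for _ in range(3)],
        )
        x = rng.normal(0, 1, 4)
        out = x.copy()
        acc = x.copy()
        for W, b in zip(enc.weights, enc.biases):
            h = np.maximum(W @ out + b, 0.0)
            acc = acc + h
            out = out + h
        np.testing.assert_allclose(encoder_forward(x, enc), acc, atol=1e-12)


class TestLowRankPropagate:
    def test_one_hot_column_gives_zero(self):
        out = lowrank_propagate(np.array([1.0, 2.0, 3.0]), _branch([0, 1, 0]))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_zero_input_gives_zero(self):
        out = lowrank_propagate(np.zeros(3), _branch([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_hand_computed(self):
        out = lowrank_propagate(np.array([1.0, 2.0, 3.0]), _branch([1.0, 1.0, 0.0]))
        np.testing.assert_allclose(out, [np.tanh(2.0), np.tanh(1.0), 0.0])


class TestDecoder:
    def test_zero_gain_returns_bias(self):
        dec = DecoderSharedParams(np.zeros((2, 2)), np.zeros(2))
        br = _branch([1.0, 1.0], E=[3.0, 4.0])
        np.testing.assert_array_equal(decoder_forward(np.array([0.5, 0.5]), dec, br), [3.0, 4.0])

    def test_hand_computed(self):
        dec = DecoderSharedParams(np.eye(2), np.zeros(2))
        br = _branch([1.0, 1.0], M=[2.0, 2.0], E=[1.0, 1.0])
        out = decoder_forward(np.array([0.5, -0.5]), dec, br)
        np.testing.assert_allclose(out, [1 + 2 * np.tanh(0.5), 1 - 2 * np.tanh(0.5)])

    def test_reconstruction_bounded_by_scale_plus_bias(self):
        rng = np.random.default_rng(2)
        dec = DecoderSharedParams(rng.normal(0, 1, (5, 5)), rng.normal(0, 1, 5))
        br = _branch(rng.normal(0, 1, 5), M=rng.normal(0, 2, 5), E=rng.normal(0, 2, 5))
        for _ in range(20):
            out = decoder_forward(rng.normal(0, 3, 5), dec, br)
            assert np.all(np.abs(out) <= np.abs(br.M) + np.abs(br.E) + 1e-12)


def _lambda_oracle(V):
    """Dense eigendecomposition of (I - L)^T, smallest-magnitude eigenvalue."""
    S = V @ V.T
    deg = S.sum(axis=1)
    L = S / deg[:, None]
    M = np.eye(V.shape[0]) - L
    vals, vecs = np.linalg.eig(M.T)
    mu = np.real(vecs[:, np.argmin(np.abs(vals))])
    lam = np.abs(mu)
    return lam / np.linalg.norm(lam)


class TestComputeLambda:
    def test_rank1_hand_example(self):
        lam, _ = compute_lambda(_branch([1.0, 2.0, 2.0]))
        np.testing.assert_allclose(lam, np.array([1.0, 2.0, 2.0]) / 3.0)

    def test_constant_vector_uniform(self):
        lam, _ = compute_lambda(_branch([2.0] * 4))
        np.testing.assert_allclose(lam, np.full(4, 0.5))

    def test_sign_invariance(self):
        v = np.array([0.3, -1.2, 0.7])
        lam_pos, _ = compute_lambda(_branch(v))
        lam_neg, _ = compute_lambda(_branch(-v))
        np.testing.assert_allclose(lam_pos, lam_neg)

    @pytest.mark.parametrize("seed", range(10))
    def test_rank1_matches_dense_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 21)
        v = rng.normal(0, 1, n)
        while abs(v.sum()) < 0.3:  # keep degrees well-conditioned
            v = rng.normal(0, 1, n)
        lam, _ = compute_lambda(_branch(v))
        np.testing.assert_allclose(lam, _lambda_oracle(v[:, None]), atol=1e-8)
        np.testing.assert_allclose(lam, np.abs(v) / np.linalg.norm(v), atol=1e-10)

    def test_rank2_generic_path_unit_norm_nonnegative(self):
        rng = np.random.default_rng(3)
        br = SubtypeBranchParams(V=rng.normal(1.0, 0.5, (8, 2)), M=np.ones(8), E=np.zeros(8))
        lam, mu = compute_lambda(br)
        assert lam.shape == (8,)
        assert np.all(lam >= 0)
        assert np.linalg.norm(lam) == pytest.approx(1.0)
        np.testing.assert_allclose(lam, np.abs(mu))


class TestLosses:
    def test_weighted_loss_hand_examples(self):
        assert weighted_cell_loss([1.0, 0.0], [1.0, 0.0], [0.7, 0.7]) == 0.0
        assert weighted_cell_loss([1.0, 0.0], [0.0, 0.0], np.full(2, 1 / np.sqrt(2))) == pytest.approx(0.5)
        assert weighted_cell_loss([5.0, 5.0], [0.0, 1.0], [0.0, 0.0]) == 0.0

    def _toy_model(self, n=3, k=2, seed=0):
        rng = np.random.default_rng(seed)
        cfg = ModelConfig(n_subtypes=k, n_res_blocks=1, seed=seed)
        enc = EncoderParams([np.zeros((n, n))], [np.zeros(n)])
        dec = DecoderSharedParams(rng.normal(0, 0.3, (n, n)), np.zeros(n))
        branches = [
            SubtypeBranchParams(rng.normal(0.5, 0.3, (n, 1)), np.ones(n), rng.normal(0, 1, n))
            for _ in range(k)
        ]
        return CSDGIModel(cfg, enc, dec, branches)

    def test_min_over_branches_matches_enumeration(self):
        model = self._toy_model()
        rng = np.random.default_rng(1)
        X = rng.gamma(2, 0.5, (4, 3))
        weights = gene_weights(model)
        loss, assignment = total_loss(X, model, weights)
        # brute force: every cell against every branch independently
        expected = []
        for i in range(4):
            per_k = []
            for k, br in enumerate(model.branches):
                xp = encoder_forward(X[i], model.encoder)
                xhat = decoder_forward(lowrank_propagate(xp, br), model.decoder, br)
                per_k.append(weighted_cell_loss(X[i], xhat, weights.lam[k]))
            expected.append(min(per_k))
            assert assignment.labels[i] == int(np.argmin(per_k)) + 1
        assert loss == pytest.approx(np.mean(expected))
        assert np.all(assignment.losses.min(axis=1) <= assignment.losses.max(axis=1))

    def test_duplicated_branch_cannot_increase_loss(self):
        model = self._toy_model(k=2, seed=2)
        rng = np.random.default_rng(2)
        X = rng.gamma(2, 0.5, (6, 3))
        base, _ = total_loss(X, model)
        bigger = CSDGIModel(
            ModelConfig(n_subtypes=3), model.encoder, model.decoder,
            model.branches + [model.branches[0]],
        )
        dup, _ = total_loss(X, bigger)
        assert dup <= base + 1e-12

    def test_cell_permutation_invariance_and_branch_equivariance(self):
        model = self._toy_model(k=2, seed=4)
        rng = np.random.default_rng(4)
        X = rng.gamma(2, 0.5, (6, 3))
        loss, asg = total_loss(X, model)
        perm = rng.permutation(6)
        loss_p, asg_p = total_loss(X[perm], model)
        assert loss_p == pytest.approx(loss)
        np.testing.assert_array_equal(asg_p.labels, asg.labels[perm])
        swapped = CSDGIModel(model.config, model.encoder, model.decoder, model.branches[::-1])
        loss_s, asg_s = total_loss(X, swapped)
        assert loss_s == pytest.approx(loss)
        np.testing.assert_array_equal(asg_s.labels, 3 - asg.labels)

    def test_single_branch_all_labels_one(self):
        model = self._toy_model(k=1, seed=5)
        rng = np.random.default_rng(5)
        X = rng.gamma(2, 0.5, (5, 3))
        _, asg = total_loss(X, model)
        assert set(asg.labels) == {1}

    def test_tie_breaks_to_lowest_index(self):
        model = self._toy_model(k=2, seed=6)
        model.branches[1] = model.branches[0]  # identical branches -> exact ties
        rng = np.random.default_rng(6)
        X = rng.gamma(2, 0.5, (5, 3))
        asg = assign_subtypes(model, X)
        assert set(asg.labels) == {1}

    def test_branch_reconstructing_cell_exactly_wins_it(self):
        n = 3
        enc = EncoderParams([np.zeros((n, n))], [np.zeros(n)])
        dec = DecoderSharedParams(np.zeros((n, n)), np.zeros(n))
        x_target = np.array([1.0, 2.0, 3.0])
        far = SubtypeBranchParams(np.full((n, 1), 0.5), np.ones(n), np.full(n, 10.0))
        exact = SubtypeBranchParams(np.full((n, 1), 0.7), np.ones(n), x_target.copy())
        model = CSDGIModel(ModelConfig(n_subtypes=2), enc, dec, [far, exact])
        asg = assign_subtypes(model, x_target[None, :])
        assert asg.labels[0] == 2


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2.0, 0.5, (6, 5))
        model = init_model(ModelConfig(n_subtypes=2, n_res_blocks=2, seed=1, init_scale=0.1), 5)
        weights = gene_weights(model)
        loss, _, grads = _backward(model, X, weights)
        checks = [
            (model.encoder.weights[0], grads["W"][0]),
            (model.encoder.biases[1], grads["b"][1]),
            (model.decoder.G, grads["G"]),
            (model.decoder.e, grads["e"]),
            (model.branches[0].V, grads["V"][0]),
            (model.branches[1].M, grads["M"][1]),
            (model.branches[0].E, grads["E"][0]),
        ]
        eps = 1e-6
        rng_idx = np.random.default_rng(0)
        for param, grad in checks:
            flat = param.reshape(-1)
            for idx in rng_idx.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = _backward(model, X, weights)[0]
                flat[idx] = orig - eps
                lm = _backward(model, X, weights)[0]
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad.reshape(-1)[idx] == pytest.approx(numeric, abs=5e-7)

    def test_softmin_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2.0, 0.5, (5, 4))
        cfg = ModelConfig(n_subtypes=2, seed=2, init_scale=0.1, soft_min_temperature=0.7)
        model = init_model(cfg, 4)
        weights = gene_weights(model)
        _, _, grads = _backward(model, X, weights)
        eps = 1e-6
        param, grad = model.branches[0].V, grads["V"][0]
        flat = param.reshape(-1)
        for idx in [0, 2]:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = _backward(model, X, weights)[0]
            flat[idx] = orig - eps
            lm = _backward(model, X, weights)[0]
            flat[idx] = orig
            assert grad.reshape(-1)[idx] == pytest.approx((lp - lm) / (2 * eps), abs=5e-7)


class TestFit:
    def _data(self, seed=0, m=60, n=20):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 0.5, (m, n))
        values[: m // 2, :5] += 1.5
        return ExpressionMatrix(values.clip(0), [f"g{j}" for j in range(n)], [f"c{i}" for i in range(m)])

    def test_loss_descends_on_average(self):
        X = self._data()
        _, _, _, trace = fit(X, ModelConfig(n_subtypes=2, epochs=200, seed=0))
        assert np.mean(trace[-50:]) <= np.mean(trace[:50])

    def test_same_seed_reproduces_labels(self):
        X = self._data(seed=1)
        cfg = ModelConfig(n_subtypes=2, epochs=60, seed=3)
        _, _, asg_a, trace_a = fit(X, cfg)
        _, _, asg_b, trace_b = fit(X, cfg)
        np.testing.assert_array_equal(asg_a.labels, asg_b.labels)
        assert trace_a == trace_b

    def test_more_subtypes_than_cells_rejected(self):
        X = self._data(m=3, n=5)
        with pytest.raises(ValueError, match="subtypes"):
            fit(X, ModelConfig(n_subtypes=5, epochs=1))

    def test_lambda_unit_norm_nonnegative_after_training(self):
        X = self._data(seed=2)
        _, weights, _, _ = fit(X, ModelConfig(n_subtypes=2, epochs=40, seed=0))
        for lam in weights.lam:
            assert np.all(lam >= 0)
            assert np.linalg.norm(lam) == pytest.approx(1.0)
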