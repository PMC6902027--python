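"""Scoring-network mechanics: forward pass, gradients, training loop."""

import numpy as np
import pytest

from blockcnn.model import (
    ModelParams,
    TrainConfig,
    Velocity,
    backward,
    batch_forward,
    batch_nll,
    block_score,
    conv1_forward,
    conv2_forward,
    init_params,
    nll_loss,
    pretrain_autoencoder,
    sgd_momentum_step,
    snp_scores,
    split_dataset,
    train,
)
from blockcnn.simulate import PatternSpec, simulate_block_dataset
from conftest import make_matrix


def loop_forward(X, W, b, w2, b2):
    """Nested-loop reference implementation of both convolution layers."""
    K, M = W.shape
    N = X.shape[1]
    H = np.zeros((K, N))
    for k in range(K):
        for n in range(N):
            c = sum(W[k, m] * X[m, n] for m in range(M)) + b[k]
            H[k, n] = max(0.0, c)
    o = np.zeros(N)
    for n in range(N):
        c = sum(w2[k] * H[k, n] for k in range(K)) + b2
        o[n] = 1.0 / (1.0 + np.exp(-c))
    return H, o


def random_params(M, K, seed, variant="full"):
    rng = np.random.default_rng(seed)
    params = init_params(M, TrainConfig(K=K, seed=seed), variant, rng)
    # keep pre-activations away from the ReLU kink where the subgradient
    # convention legitimately differs from finite differences
    params.b = params.b + rng.uniform(0.01, 0.05, size=params.b.shape)
    return params


class TestForward:
    def test_zero_parameters_give_zero_feature_map(self):
        p = ModelParams(W=np.zeros((2, 3)), b=np.zeros(2), w2=np.zeros(2), b2=0.0)
        H = conv1_forward(np.ones((3, 4)), p)
        assert np.array_equal(H, np.zeros((2, 4)))

    def test_relu_clips_negative_preactivation(self):
        # one active feature with weight 2 and bias -3: 2 - 3 = -1 -> 0
        p = ModelParams(W=np.array([[2.0]]), b=np.array([-3.0]), w2=np.ones(1), b2=0.0)
        H = conv1_forward(np.array([[1]]), p)
        assert H[0, 0] == 0.0

    def test_sigmoid_of_zero_is_half(self):
        p = ModelParams(W=np.zeros((2, 3)), b=np.zeros(2), w2=np.zeros(2), b2=0.0)
        o = conv2_forward(np.random.default_rng(0).random((2, 5)), p)
        assert np.allclose(o, 0.5)

    def test_large_bias_saturates_toward_one(self):
        p = ModelParams(W=np.zeros((1, 1)), b=np.zeros(1), w2=np.zeros(1), b2=30.0)
        o = conv2_forward(np.zeros((1, 3)), p)
        assert np.all(o > 1 - 1e-12)

    def test_forward_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        X = (rng.random((6, 4)) < 0.5).astype(float)
        p = random_params(6, 3, seed=5)
        H_ref, o_ref = loop_forward(X, p.W, p.b, p.w2, p.b2)
        assert np.max(np.abs(conv1_forward(X, p) - H_ref)) < 1e-12
        assert np.max(np.abs(snp_scores(X, p) - o_ref)) < 1e-12

    def test_shape_mismatch_reports_dimensions(self):
        p = ModelParams(W=np.zeros((2, 3)), b=np.zeros(2), w2=np.zeros(2), b2=0.0)
        with pytest.raises(ValueError, match="feature rows"):
            conv1_forward(np.ones((4, 2)), p)

    def test_snp_order_equivariance(self):
        rng = np.random.default_rng(8)
        X = (rng.random((10, 6)) < 0.4).astype(float)
        p = random_params(10, 4, seed=8)
        perm = rng.permutation(6)
        assert np.allclose(snp_scores(X, p)[perm], snp_scores(X[:, perm], p))
        assert block_score(snp_scores(X, p)) == block_score(snp_scores(X[:, perm], p))


class TestPoolingAndLoss:
    def test_max_pooling(self):
        assert block_score(np.array([0.2, 0.9, 0.4])) == 0.9
        assert block_score(np.array([0.7])) == 0.7
        with pytest.raises(ValueError, match="empty"):
            block_score(np.array([]))

    def test_adding_a_column_never_decreases_block_score(self):
        rng = np.random.default_rng(3)
        X = (rng.random((8, 4)) < 0.4).astype(float)
        extra = (rng.random((8, 1)) < 0.4).astype(float)
        p = random_params(8, 3, seed=3)
        assert block_score(snp_scores(np.hstack([X, extra]), p)) >= block_score(
            snp_scores(X, p)
        )

    def test_nll_closed_forms(self):
        assert nll_loss([0.5], [1]) == pytest.approx(np.log(2), abs=1e-12)
        assert nll_loss([1 - 1e-13], [1]) < 1e-10
        scores = np.array([0.9, 0.2, 0.6])
        labels = np.array([1, 0, 0])
        by_hand = -(np.log(0.9) + np.log(0.8) + np.log(0.4)) / 3
        assert nll_loss(scores, labels) == pytest.approx(by_hand, rel=1e-12)


class TestBackward:
    def blocks(self, seed=5, m=6, n=4, count=6):
        rng = np.random.default_rng(seed)
        return [
            make_matrix(f"b{i}", (rng.random((m, n)) < 0.4), label=i % 2)
            for i in range(count)
        ]

    @pytest.mark.parametrize("variant", ["full", "linear", "lead_only"])
    def test_gradients_match_central_finite_differences(self, variant):
        blocks = self.blocks()
        p = random_params(6, 3, seed=7, variant=variant)
        grads = backward(blocks, p)
        h = 1e-5
        for name, grad in grads.items():
            arr = getattr(p, name)
            if np.ndim(arr) == 0:  # scalar b2
                p.b2 = arr + h
                fp = batch_nll(blocks, p)
                p.b2 = arr - h
                fm = batch_nll(blocks, p)
                p.b2 = arr
                fd = (fp - fm) / (2 * h)
                assert abs(fd - grad) / max(abs(fd), abs(grad), 1e-8) < 1e-6
                continue
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                fp = batch_nll(blocks, p)
                arr[idx] = orig - h
                fm = batch_nll(blocks, p)
                arr[idx] = orig
                fd = (fp - fm) / (2 * h)
                assert abs(fd - grad[idx]) / max(abs(fd), abs(grad[idx]), 1e-8) < 1e-6

    def test_gradient_sign_at_zero_parameters_with_positive_label(self):
        # score is 0.5 everywhere; the output bias must rise, so dNLL/db2 < 0
        blocks = [make_matrix("b", np.ones((3, 2)), label=1)]
        p = ModelParams(W=np.zeros((2, 3)), b=np.zeros(2), w2=np.zeros(2), b2=0.0)
        grads = backward(blocks, p)
        assert grads["b2"] < 0

    def test_non_argmax_columns_receive_no_gradient(self):
        # column 1 dominates the pool; editing column 0 leaves grads unchanged
        X = np.zeros((3, 2), dtype=np.int8)
        X[:, 1] = 1
        p = ModelParams(
            W=np.full((2, 3), 0.5), b=np.zeros(2), w2=np.ones(2), b2=0.0
        )
        g1 = backward([make_matrix("b", X, label=1)], p)
        X2 = X.copy()
        X2[0, 0] = 1  # only the non-argmax column differs
        g2 = backward([make_matrix("b", X2, label=1)], p)
        assert np.array_equal(g1["W"], g2["W"]) and np.array_equal(g1["b"], g2["b"])


class TestMomentumStep:
    def params(self):
        return ModelParams(
            W=np.ones((2, 3)), b=np.zeros(2), w2=np.ones(2), b2=0.0
        )

    def grads(self):
        return {
            "W": np.full((2, 3), 0.5),
            "b": np.array([1.0, -1.0]),
            "w2": np.array([0.2, 0.4]),
            "b2": 0.3,
        }

    def test_zero_momentum_is_plain_gradient_descent(self):
        p = self.params()
        sgd_momentum_step(p, self.grads(), Velocity.zeros_like(p), 0.1, 0.0)
        assert np.allclose(p.W, 1 - 0.05)
        assert np.allclose(p.b, [-0.1, 0.1])

    def test_zero_gradient_moves_by_momentum_only(self):
        p = self.params()
        v = Velocity.zeros_like(p)
        v.W += 0.2
        zero = {"W": np.zeros((2, 3)), "b": np.zeros(2), "w2": np.zeros(2), "b2": 0.0}
        sgd_momentum_step(p, zero, v, 0.1, 0.9)
        assert np.allclose(p.W, 1 + 0.18)

    def test_two_steps_match_hand_unrolled_recursion(self):
        p = self.params()
        v = Velocity.zeros_like(p)
        lr, mu = 0.1, 0.9
        g = self.grads()
        sgd_momentum_step(p, g, v, lr, mu)
        sgd_momentum_step(p, g, v, lr, mu)
        # v1 = -lr g; v2 = mu v1 - lr g; theta = theta0 + v1 + v2
        expected_w = 1.0 + (-lr * 0.5) + (mu * (-lr * 0.5) - lr * 0.5)
        assert np.allclose(p.W, expected_w)


class TestAutoencoder:
    def test_loss_declines_on_all_zero_columns(self):
        cols = np.zeros((20, 10))
        _, _, losses = pretrain_autoencoder(cols, K=4, epochs=30, seed=0)
        assert losses[-1] < losses[0]

    def test_reconstruction_loss_non_increasing_on_average(self):
        rng = np.random.default_rng(1)
        cols = (rng.random((100, 30)) < 0.2).astype(float)
        _, _, losses = pretrain_autoencoder(cols, K=6, epochs=40, seed=1)
        diffs = np.diff(losses)
        assert np.mean(diffs) < 0

    def test_identical_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        cols = (rng.random((50, 20)) < 0.3).astype(float)
        W1, b1, _ = pretrain_autoencoder(cols, K=5, epochs=10, seed=9)
        W2, b2, _ = pretrain_autoencoder(cols, K=5, epochs=10, seed=9)
        assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_pretraining_beats_random_init_within_short_budget(self):
        """Mean best validation NLL over 10 seeds, 10-epoch budget."""
        spec = PatternSpec(
            pattern_features=tuple(range(4)), logic="AND", background_rate=0.05
        )
        nll = {True: [], False: []}
        for seed in range(1, 11):
            ds = simulate_block_dataset(40, 80, 10, spec, neg_ratio=10, seed=seed)
            for pre in (True, False):
                cfg = TrainConfig(
                    K=8, seed=seed, max_epochs=10, patience=10, pretrain_epochs=30
                )
                res = train(ds.blocks, cfg, variant="full", pretrain=pre)
                nll[pre].append(min(row["val_nll"] for row in res.log))
        assert np.mean(nll[True]) < np.mean(nll[False])


class TestSplit:
    def test_groups_stay_together_and_counts_match(self):
        rng = np.random.default_rng(4)
        blocks = []
        for i in range(10):
            t = make_matrix(f"b{i}", (rng.random((4, 3)) < 0.5), label=1)
            blocks.append(t)
            for j in range(10):
                n = make_matrix(f"b{i}", (rng.random((4, 3)) < 0.5), label=0)
                n.block_id = f"b{i}::neg{j}"
                n.source_id = f"b{i}"
                blocks.append(n)
        train_b, val_b, test_b = split_dataset(blocks, (0.6, 0.2, 0.2), seed=0)
        assert (len(train_b), len(val_b), len(test_b)) == (66, 22, 22)
        for part in (train_b, val_b, test_b):
            sources = {b.source_id for b in part}
            assert sum(b.label for b in part) == len(sources)
        all_ids = sorted(b.block_id for b in train_b + val_b + test_b)
        assert all_ids == sorted(b.block_id for b in blocks)

    def test_split_deterministic_under_seed(self):
        blocks = [make_matrix(f"b{i}", np.ones((2, 2)), label=1) for i in range(9)]
        a = split_dataset(blocks, seed=3)
        b = split_dataset(blocks, seed=3)
        assert [[x.block_id for x in part] for part in a] == [
            [x.block_id for x in part] for part in b
        ]


class TestTraining:
    def test_separable_toy_reaches_near_zero_nll(self):
        """Pattern blocks vs all-zero blocks, no noise: NLL -> ~0."""
        pattern = np.zeros((10, 3), dtype=np.int8)
        pattern[:4, 1] = 1
        blocks = [make_matrix(f"t{i}", pattern, label=1) for i in range(20)]
        zero = np.zeros((10, 3), dtype=np.int8)
        for i in range(20):
            b = make_matrix(f"t{i}", zero, label=0)
            b.block_id = f"t{i}::neg0"
            b.source_id = f"t{i}"
            blocks.append(b)
        cfg = TrainConfig(K=4, seed=0, max_epochs=150, patience=150, batch_size=10)
        res = train(blocks, cfg, variant="full")
        assert res.log[-1]["train_nll"] < 0.01

    def test_training_is_deterministic(self):
        spec = PatternSpec(
            pattern_features=tuple(range(3)), logic="AND", background_rate=0.05
        )
        ds = simulate_block_dataset(15, 30, 6, spec, neg_ratio=5, seed=2)
        cfg = TrainConfig(K=4, seed=5, max_epochs=10, patience=10)
        a = train(ds.blocks, cfg, variant="full")
        b = train(ds.blocks, cfg, variant="full")
        assert np.array_equal(a.params.W, b.params.W)
        assert np.array_equal(a.params.w2, b.params.w2)

    def test_lead_only_variant_sees_single_column(self):
        X = np.zeros((4, 3), dtype=np.int8)
        X[:, 2] = 1  # pattern in a non-lead column
        blk = make_matrix("b", X, lead_index=0)
        p = ModelParams(
            W=np.ones((2, 4)), b=np.zeros(2), w2=np.ones(2), b2=-3.0,
            variant="lead_only",
        )
        scores, _ = batch_forward([blk], p)
        assert scores[0] == pytest.approx(1 / (1 + np.exp(3.0)))

    def test_single_class_data_rejected(self):
        blocks = [make_matrix("b", np.ones((2, 2)), label=1)]
        with pytest.raises(ValueError, match="both labels"):
            train(blocks, TrainConfig(K=2, seed=0), variant="full")

    def test_default_model_has_fifty_kernels(self):
        assert TrainConfig().K == 50
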