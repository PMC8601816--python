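"""Forward/backward passes, the Nadam update, and training behaviour."""

import numpy as np
import pytest

from rsdnet.network import (RSDNetClassifier, TrainConfig, backward,
                            cross_entropy, forward, init_network,
                            init_opt_state, nadam_step, penalized_loss, train)
from rsdnet.preprocess import FeatureTable
from rsdnet.regularizers import Regularizer
from rsdnet.synthetic_data import generate_separable


class TestInit:
    def test_identical_seed_gives_bitwise_identical_params(self):
        a = init_network([4, 5, 3, 2], 0.05, seed=42)
        b = init_network([4, 5, 3, 2], 0.05, seed=42)
        for (wa, ba), (wb, bb) in zip(a, b):
            assert np.array_equal(wa, wb) and np.array_equal(ba, bb)

    def test_zero_std_gives_zero_kernels_and_biases_start_zero(self):
        params = init_network([3, 5, 2], 0.0, seed=0)
        assert all((w == 0).all() and (b == 0).all() for w, b in params)

    def test_sample_std_near_requested(self):
        params = init_network([100, 100, 2], 0.05, seed=3)
        draws = params[0][0].ravel()  # 10^4 draws
        assert draws.std() == pytest.approx(0.05, rel=0.05)

    def test_too_few_layer_sizes_errors(self):
        with pytest.raises(ValueError):
            init_network([4], 0.05, seed=0)


class TestForward:
    def test_zero_params_give_uniform_softmax(self):
        params = init_network([3, 5, 2], 0.0, seed=0)
        probs = forward(params, np.ones((4, 3)))[-1]
        assert np.allclose(probs, 0.5)

    def test_rows_sum_to_one(self, rng):
        params = init_network([6, 5, 3, 2], 0.5, seed=1)
        probs = forward(params, rng.normal(size=(10, 6)))[-1]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert ((probs > 0) & (probs < 1)).all()

    def test_hand_computed_single_unit_chain(self):
        # 1 input -> 1 tanh unit -> 2-way softmax, all weights set by hand
        params = [
            (np.array([[2.0]]), np.array([0.5])),
            (np.array([[1.0, -1.0]]), np.array([0.0, 0.3])),
        ]
        x = np.array([[0.7]])
        h = np.tanh(0.7 * 2.0 + 0.5)
        z = np.array([h * 1.0, h * -1.0 + 0.3])
        expected = np.exp(z) / np.exp(z).sum()
        acts = forward(params, x)
        assert np.allclose(acts[0], h)
        assert np.allclose(acts[-1], expected, atol=1e-12)

    def test_dimension_mismatch_errors(self):
        params = init_network([3, 2], 0.1, seed=0)
        with pytest.raises(ValueError):
            forward(params, np.ones((2, 4)))


class TestCrossEntropy:
    def test_closed_forms(self):
        assert cross_entropy([[1.0, 0.0]], [[1, 0]]) <= 1e-11
        assert cross_entropy([[0.5, 0.5]], [[0, 1]]) == pytest.approx(np.log(2))
        assert cross_entropy([[0.8, 0.2]], [[1, 0]]) == pytest.approx(-np.log(0.8))

    def test_mean_over_rows_and_shape_check(self):
        two = cross_entropy([[0.8, 0.2], [0.8, 0.2]], [[1, 0], [1, 0]])
        assert two == pytest.approx(-np.log(0.8))
        with pytest.raises(ValueError):
            cross_entropy([[0.5, 0.5]], [[1, 0], [0, 1]])


def _random_net_and_batch(rng, n_in=3, n_batch=5):
    params = init_network([n_in, 4, 3, 2], 0.4, seed=int(rng.integers(2**31)))
    # keep weights clear of the |w|=0 kink for l1/elastic finite differences
    params = [(np.where(np.abs(w) < 1e-2, 0.1, w), b) for w, b in params]
    X = rng.normal(size=(n_batch, n_in))
    y = rng.integers(0, 2, size=n_batch)
    one_hot = np.zeros((n_batch, 2))
    one_hot[np.arange(n_batch), y] = 1.0
    return params, X, one_hot


def _fd_param_grads(params, X, one_hot, reg, h=1e-6):
    fd = []
    for i, (w, b) in enumerate(params):
        gw, gb = np.zeros_like(w), np.zeros_like(b)
        for arr, g in ((w, gw), (b, gb)):
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + h
                lp = penalized_loss(params, X, one_hot, reg)
                arr[idx] = orig - h
                lm = penalized_loss(params, X, one_hot, reg)
                arr[idx] = orig
                g[idx] = (lp - lm) / (2 * h)
        fd.append((gw, gb))
    return fd


@pytest.mark.parametrize(
    "reg",
    [
        Regularizer("none"),
        Regularizer("l1", 0.05),
        Regularizer("l2", 0.05),
        Regularizer("elastic", 0.05, alpha=0.4),
        Regularizer("rsd", 0.05),
        Regularizer("rsd", 0.05, rsd_mode="rowwise"),
    ],
    ids=lambda r: f"{r.family}-{r.rsd_mode}" if r.family == "rsd" else r.family,
)
def test_backward_matches_finite_differences(reg, rng):
    params, X, one_hot = _random_net_and_batch(rng)
    grads = backward(params, X, one_hot, reg)
    fd = _fd_param_grads(params, X, one_hot, reg)
    for (gw, gb), (fw, fb) in zip(grads, fd):
        assert np.allclose(gw, fw, rtol=1e-4, atol=1e-6)
        assert np.allclose(gb, fb, rtol=1e-4, atol=1e-6)


def test_backward_mean_reduction_invariant_to_duplicated_rows(rng):
    params, X, one_hot = _random_net_and_batch(rng)
    g1 = backward(params, X, one_hot, Regularizer("rsd", 0.1))
    g2 = backward(params, np.vstack([X, X]), np.vstack([one_hot, one_hot]),
                  Regularizer("rsd", 0.1))
    for (gw1, gb1), (gw2, gb2) in zip(g1, g2):
        assert np.allclose(gw1, gw2, atol=1e-12)
        assert np.allclose(gb1, gb2, atol=1e-12)

    with pytest.raises(ValueError):
        backward(params, X[:0], one_hot[:0], Regularizer("none"))


class TestNadam:
    def test_zero_gradient_is_a_noop(self):
        params = init_network([2, 3, 2], 0.1, seed=0)
        zero = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        out, _ = nadam_step(params, zero, init_opt_state(params), TrainConfig(), 1)
        for (w0, b0), (w1, b1) in zip(params, out):
            assert np.array_equal(w0, w1) and np.array_equal(b0, b1)

    def test_beta_zero_limit_is_sign_scaled_step(self):
        cfg = TrainConfig(beta1=0.0, beta2=0.0, learning_rate=0.1)
        params = [(np.array([[2.0]]), np.zeros(1))]
        grads = [(np.array([[0.5]]), np.zeros(1))]
        out, _ = nadam_step(params, grads, init_opt_state(params), cfg, 1)
        expected = 2.0 - 0.1 * 0.5 / (0.5 + cfg.eps_opt)
        assert out[0][0].item() == pytest.approx(expected, rel=1e-9)

    def test_converges_on_quadratic_toy(self):
        cfg = TrainConfig(learning_rate=0.05)
        params = [(np.array([[0.0]]), np.zeros(1))]
        state = init_opt_state(params)
        for t in range(1, 201):
            g = params[0][0] - 3.0
            params, state = nadam_step(params, [(g, np.zeros(1))], state, cfg, t)
        assert abs(params[0][0].item() - 3.0) < 1e-2

    def test_step_index_must_be_positive(self):
        params = [(np.zeros((1, 1)), np.zeros(1))]
        with pytest.raises(ValueError):
            nadam_step(params, params, init_opt_state(params), TrainConfig(), 0)


class TestTraining:
    def test_same_seed_reproduces_history_and_weights(self, separable_table):
        X, y = separable_table.values, separable_table.labels
        runs = []
        for _ in range(2):
            clf = RSDNetClassifier(family="rsd", lam=1e-6, epochs=5,
                                   random_state=11)
            clf.fit(X, y, validation_data=(X, y))
            runs.append(clf)
        assert runs[0].history_.equals(runs[1].history_)
        for wa, wb in zip(runs[0].coefs_, runs[1].coefs_):
            assert np.array_equal(wa, wb)

    def test_history_length_equals_epochs(self, separable_table):
        clf = RSDNetClassifier(epochs=7, random_state=0)
        clf.fit(separable_table.values, separable_table.labels)
        assert len(clf.history_) == 7

    def test_large_l2_lambda_shrinks_kernels(self, separable_table):
        X, y = separable_table.values, separable_table.labels
        free = RSDNetClassifier(family="none", epochs=30, random_state=2).fit(X, y)
        tight = RSDNetClassifier(family="l2", lam=10.0, epochs=30,
                                 random_state=2).fit(X, y)
        norm = lambda coefs: sum(np.linalg.norm(w) for w in coefs)
        assert norm(tight.coefs_) < norm(free.coefs_)

    def test_tight_blobs_learned_at_full_protocol(self):
        # margin-1 blobs with sd 0.25 are separable; the 100-epoch batch-4
        # protocol should fit them nearly perfectly at negligible lambda
        t = generate_separable(200, 2, margin=1.0, seed=3, scale=0.25)
        clf = RSDNetClassifier(family="rsd", lam=1e-6, epochs=100,
                               batch_size=4, random_state=1)
        clf.fit(t.values, t.labels)
        assert (clf.predict(t.values) == t.labels).mean() >= 0.98

    def test_empty_training_set_errors(self):
        clf = RSDNetClassifier()
        with pytest.raises(ValueError):
            clf.fit(np.empty((0, 2)), np.empty(0, dtype=int))

    def test_train_wrapper_returns_params_and_history(self, separable_table):
        cfg = TrainConfig(epochs=3, seed=5, regularizer=Regularizer("l1", 1e-8))
        tr = FeatureTable(separable_table.values[:150],
                          separable_table.column_names,
                          separable_table.labels[:150])
        va = FeatureTable(separable_table.values[150:],
                          separable_table.column_names,
                          separable_table.labels[150:])
        params, hist = train(tr, va, cfg)
        assert [w.shape for w, _ in params] == [(2, 5), (5, 3), (3, 2)]
        assert len(hist) == 3
        assert hist["val_accuracy"].notna().all()

    def test_sklearn_get_set_params_round_trip(self):
        clf = RSDNetClassifier(family="rsd", lam=1e-6)
        p = clf.get_params()
        assert p["family"] == "rsd"
        clf.set_params(lam=0.5)
        assert clf.lam == 0.5
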