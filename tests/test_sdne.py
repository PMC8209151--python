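"""Network-embedding losses, gradients and training behaviour."""

import numpy as np
import pytest

from mdlink import (
    SdneConfig,
    first_order_loss,
    fit_sdne,
    reg_loss,
    second_order_loss,
    total_loss,
)
from mdlink import _autoencoder as ae
from mdlink.sdne import encode


def _tiny_state(rng, dims=(4, 3, 2)):
    return ae.init_state(list(dims), rng)


class TestEncode:
    def test_sigmoid_of_zero_weights(self, rng):
        state = _tiny_state(rng)
        for W in state.W:
            W[:] = 0.0
        y = encode(np.ones(4), state)
        assert np.allclose(y, 0.5)

    def test_identity_network(self, rng):
        state = ae.init_state([3, 3], rng, activation="identity",
                              output_activation="identity")
        state.W[0][:] = np.eye(3)
        state.b[0][:] = 0.0
        x = np.array([0.3, -1.2, 4.0])
        assert np.allclose(encode(x, state), x)

    def test_matches_hand_matrix_product(self, rng):
        state = _tiny_state(rng)
        x = rng.random(4)
        # independent recomputation with explicit loops
        h = x
        for W, b in zip(state.W, state.b):
            z = W @ h + b
            h = 1.0 / (1.0 + np.exp(-z))
        assert np.allclose(encode(x, state), h, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        state = _tiny_state(rng)
        with pytest.raises(ValueError):
            encode(np.ones(5), state)


class TestLossTerms:
    def test_first_order_identical_rows_zero(self):
        Y = np.ones((3, 2))
        s = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        assert first_order_loss(Y, s) == 0.0

    def test_first_order_two_nodes_hand_value(self):
        Y = np.array([[0.0, 0.0], [1.0, 0.0]])
        s = np.array([[0, 1], [1, 0]], dtype=float)
        # two ordered pairs each contributing ||y1-y2||^2 = 1
        assert first_order_loss(Y, s) == pytest.approx(2.0)

    def test_first_order_zero_adjacency(self, rng):
        Y = rng.random((5, 3))
        assert first_order_loss(Y, np.zeros((5, 5))) == 0.0

    def test_first_order_matches_double_loop(self, rng):
        Y = rng.random((6, 4))
        s = (rng.random((6, 6)) < 0.4).astype(float)
        s = np.triu(s, 1)
        s = s + s.T
        brute = sum(
            s[i, j] * np.sum((Y[i] - Y[j]) ** 2)
            for i in range(6)
            for j in range(6)
        )
        assert first_order_loss(Y, s) == pytest.approx(brute, rel=1e-12)

    def test_second_order_exact_reconstruction(self, rng):
        X = rng.random((3, 4))
        assert second_order_loss(X, X.copy(), beta=5.0) == 0.0

    def test_second_order_hand_value(self):
        X = np.array([[1.0, 0.0]])
        X_hat = np.array([[0.0, 0.0]])
        assert second_order_loss(X, X_hat, beta=5.0) == pytest.approx(25.0)

    def test_second_order_beta_one_is_frobenius(self, rng):
        X = (rng.random((4, 5)) < 0.5).astype(float)
        X_hat = rng.random((4, 5))
        assert second_order_loss(X, X_hat, 1.0) == pytest.approx(
            np.sum((X_hat - X) ** 2)
        )

    def test_reg_loss_hand_value(self, rng):
        state = _tiny_state(rng, dims=(1, 1))
        state.W[0][:] = 2.0
        state.W_hat[0][:] = 2.0
        assert reg_loss(state) == pytest.approx(4.0)

    def test_reg_loss_quadratic_scaling(self, rng):
        state = _tiny_state(rng)
        base = reg_loss(state)
        for W in state.W + state.W_hat:
            W *= 3.0
        assert reg_loss(state) == pytest.approx(9.0 * base)

    def test_total_loss_componentwise(self, rng):
        X = (rng.random((3, 3)) < 0.5).astype(float)
        np.fill_diagonal(X, 0)
        X = np.triu(X) + np.triu(X).T
        X_hat = rng.random((3, 3))
        Y = rng.random((3, 2))
        cfg = SdneConfig(alpha=0.7, nu=0.0, beta=3.0)
        expect = second_order_loss(X, X_hat, 3.0) + 0.7 * first_order_loss(Y, X)
        assert total_loss(X, X_hat, Y, X, cfg) == pytest.approx(expect)

    def test_total_loss_alpha_zero(self, rng):
        X = np.eye(3)[::-1] * 1.0
        np.fill_diagonal(X, 0)
        X_hat = rng.random((3, 3))
        cfg = SdneConfig(alpha=0.0, nu=0.0, beta=2.0)
        assert total_loss(X, X_hat, rng.random((3, 2)), X, cfg) == pytest.approx(
            second_order_loss(X, X_hat, 2.0)
        )


class TestGradients:
    def test_finite_difference_check(self, rng):
        """Analytic gradients of the combined objective agree with central
        finite differences on a 4-node network."""
        X = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]],
            dtype=float,
        )
        state = _tiny_state(rng)
        alpha, beta, nu = 0.05, 5.0, 1e-4
        _, grads = ae.loss_and_grads(X, X, state, alpha, beta, nu)
        eps = 1e-6
        for p, g in zip(state.params(), grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + eps
                up = ae.total_loss(X, X, state, alpha, beta, nu)
                p[ix] = orig - eps
                dn = ae.total_loss(X, X, state, alpha, beta, nu)
                p[ix] = orig
                num = (up - dn) / (2 * eps)
                assert abs(num - g[ix]) <= 1e-4 * max(1.0, abs(num))


class TestFitSdne:
    def test_shapes_and_loss_decrease(self, small_fixture):
        cfg = SdneConfig(seed=0, epochs=12, layer_dims=(64, 128))
        res = fit_sdne(small_fixture.network, cfg)
        assert len(res.embeddings) == len(small_fixture.network.nodes)
        assert all(v.shape == (128,) for v in res.embeddings.values())
        assert len(res.loss_history) == 12
        assert res.loss_history[-1] < res.loss_history[0]

    def test_zero_epochs_untrained_forward_pass(self, small_fixture):
        cfg = SdneConfig(seed=3, epochs=0, layer_dims=(32, 128))
        res = fit_sdne(small_fixture.network, cfg)
        X = small_fixture.network.adjacency.astype(float)
        assert np.allclose(res.matrix(), encode(X, res.state))
        assert res.loss_history == []

    def test_seed_determinism(self, small_fixture):
        cfg = SdneConfig(seed=5, epochs=5, layer_dims=(32, 128))
        a = fit_sdne(small_fixture.network, cfg).matrix()
        b = fit_sdne(small_fixture.network, cfg).matrix()
        assert np.allclose(a, b, atol=1e-6)

    def test_final_loss_matches_recomputation(self, small_fixture):
        cfg = SdneConfig(seed=1, epochs=6, layer_dims=(32, 128))
        res = fit_sdne(small_fixture.network, cfg)
        X = small_fixture.network.adjacency.astype(float)
        recomputed = ae.total_loss(X, X, res.state, cfg.alpha, cfg.beta, cfg.nu)
        assert res.loss_history[-1] == pytest.approx(recomputed, rel=1e-12)

    def test_planted_blocks_separate(self, small_fixture):
        """Within-block embedding distances shrink below between-block ones."""
        from mdlink.simulate import block_assignment

        cfg = SdneConfig(seed=2, epochs=60, layer_dims=(64, 128))
        res = fit_sdne(small_fixture.network, cfg)
        blocks = block_assignment(small_fixture.spec)
        keys = [k for k in res.embeddings if k[0] in ("miRNA", "disease")]
        E = np.array([res.embeddings[k] for k in keys])
        lab = np.array([blocks[k] for k in keys])
        d = ((E[:, None, :] - E[None, :, :]) ** 2).sum(-1)
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(keys), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()

    def test_linear_separation_of_blocks(self, small_fixture):
        from sklearn.linear_model import LogisticRegression

        from mdlink.simulate import block_assignment

        cfg = SdneConfig(seed=2, epochs=60, layer_dims=(64, 128))
        res = fit_sdne(small_fixture.network, cfg)
        blocks = block_assignment(small_fixture.spec)
        keys = [k for k in res.embeddings if k[0] in ("miRNA", "disease")]
        E = np.array([res.embeddings[k] for k in keys])
        lab = np.array([blocks[k] for k in keys])
        acc = LogisticRegression(max_iter=2000).fit(E, lab).score(E, lab)
        assert acc > 0.9

    def test_losses_pure(self, rng):
        Y = rng.random((4, 2))
        s = (rng.random((4, 4)) < 0.5).astype(float)
        s = np.triu(s, 1)
        s = s + s.T
        assert first_order_loss(Y, s) == first_order_loss(Y, s)
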