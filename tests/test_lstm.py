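"""LSTM cell/network: forward oracles, gradients, training, memristive mode."""

import numpy as np
import pytest

from memlstm.errors import InvalidInputError, ShapeError
from memlstm.evalmetrics import rmse
from memlstm.lstm import (
    CellState,
    LSTMCellParams,
    LSTMNetwork,
    LSTMNetworkParams,
    TrainConfig,
    XbarConfig,
    cell_forward,
    init_params,
    mse_loss_and_grads,
    network_forward,
    to_memristive,
    train,
)


def _sig(z):
    return 1.0 / (1.0 + np.exp(-z))


def _zero_cell(hidden, input_dim, **overrides):
    kw = {}
    for g in "figo":
        kw[f"W_x{g}"] = np.zeros((hidden, input_dim))
        kw[f"W_h{g}"] = np.zeros((hidden, hidden))
        kw[f"b_{g}"] = np.zeros(hidden)
    kw.update(overrides)
    return LSTMCellParams(**kw)


def _reference_cell_step(x, h_prev, c_prev, p):
    """Straight-line recoding of the gate equations, loops only."""
    H, D = p.W_xf.shape
    f = np.empty(H); i = np.empty(H); g = np.empty(H); o = np.empty(H)
    for k in range(H):
        zf = zi = zg = zo = 0.0
        for d in range(D):
            zf += p.W_xf[k, d] * x[d]
            zi += p.W_xi[k, d] * x[d]
            zg += p.W_xg[k, d] * x[d]
            zo += p.W_xo[k, d] * x[d]
        for d in range(H):
            zf += p.W_hf[k, d] * h_prev[d]
            zi += p.W_hi[k, d] * h_prev[d]
            zg += p.W_hg[k, d] * h_prev[d]
            zo += p.W_ho[k, d] * h_prev[d]
        f[k] = _sig(zf + p.b_f[k])
        i[k] = _sig(zi + p.b_i[k])
        g[k] = np.tanh(zg + p.b_g[k])
        o[k] = _sig(zo + p.b_o[k])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


class TestCellForward:
    def test_all_zero_parameters_give_half_open_gates(self):
        p = _zero_cell(3, 2)
        state, gates = cell_forward(np.zeros(2), CellState.zeros(3), p)
        np.testing.assert_allclose(gates["f"], 0.5)
        np.testing.assert_allclose(gates["i"], 0.5)
        np.testing.assert_allclose(gates["o"], 0.5)
        np.testing.assert_allclose(gates["g"], 0.0)
        np.testing.assert_allclose(state.c, 0.0)
        np.testing.assert_allclose(state.h, 0.0)

    def test_saturated_gates_retain_cell_state(self):
        # forget gate saturated open, input gate saturated shut
        p = _zero_cell(4, 2, b_f=np.full(4, 20.0), b_i=np.full(4, -20.0))
        c0 = np.array([0.5, -1.0, 2.0, 0.1])
        state = CellState(h=np.zeros(4), c=c0.copy())
        rng = np.random.default_rng(0)
        for _ in range(50):
            state, _ = cell_forward(rng.normal(size=2), state, p)
        np.testing.assert_allclose(state.c, c0, atol=1e-5)

    def test_matches_straight_line_reference_implementation(self):
        rng = np.random.default_rng(4)
        p = init_params(feature_dim=3, hidden=5, seed=9).cell1
        x = rng.normal(size=3)
        h0, c0 = rng.normal(size=5) * 0.1, rng.normal(size=5) * 0.1
        state, _ = cell_forward(x, CellState(h=h0.copy(), c=c0.copy()), p)
        h_ref, c_ref = _reference_cell_step(x, h0, c0, p)
        np.testing.assert_allclose(state.h, h_ref, atol=1e-12)
        np.testing.assert_allclose(state.c, c_ref, atol=1e-12)

    def test_gate_ranges_on_random_inputs(self):
        rng = np.random.default_rng(1)
        p = init_params(feature_dim=4, hidden=6, seed=2).cell1
        state = CellState.zeros(6)
        for _ in range(30):
            state, gates = cell_forward(rng.normal(size=4) * 3, state, p)
            for name in ("f", "i", "o"):
                assert np.all(gates[name] > 0) and np.all(gates[name] < 1)
            assert np.all(np.abs(gates["g"]) < 1)
            assert np.all(np.abs(state.h) < 1)  # sigmoid x tanh product

    def test_shape_mismatch_raises(self):
        p = _zero_cell(3, 2)
        with pytest.raises(ShapeError):
            cell_forward(np.zeros(5), CellState.zeros(3), p)


class TestNetworkForward:
    def _tiny(self, seed=0):
        return init_params(feature_dim=2, hidden=2, seed=seed)

    def test_all_zero_parameters_predict_output_bias(self):
        p = self._tiny()
        zero = {k: np.zeros_like(v) for k, v in p.as_dict().items()}
        p0 = LSTMNetworkParams.from_dict(zero)
        assert network_forward(np.ones(5), p0) == 0.0

    def test_forward_is_deterministic(self):
        p = self._tiny(3)
        w = np.random.default_rng(0).normal(size=7)
        assert network_forward(w, p) == network_forward(w, p)

    def test_matches_manual_unrolling_oracle(self):
        p = self._tiny(5)
        window = np.array([0.3, -0.7, 1.1])
        s1, s2 = CellState.zeros(2), CellState.zeros(2)
        for x in window:
            u = p.W_in[:, 0] * x + p.b_in
            h1, c1 = _reference_cell_step(u, s1.h, s1.c, p.cell1)
            s1 = CellState(h=h1, c=c1)
            h2, c2 = _reference_cell_step(s1.h, s2.h, s2.c, p.cell2)
            s2 = CellState(h=h2, c=c2)
        expected = float(s2.h @ p.W_out[0] + p.b_out[0])
        assert network_forward(window, p) == pytest.approx(expected, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidInputError):
            network_forward(np.array([]), self._tiny())


class TestGradients:
    def test_analytic_gradients_match_central_differences(self):
        params = init_params(feature_dim=3, hidden=4, seed=0)
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(5, 6)), rng.normal(size=5)
        _, grads = mse_loss_and_grads(params, X, y)
        flat = params.as_dict()
        eps = 1e-5
        for k, W in flat.items():
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = W[ix]
                W[ix] = orig + eps
                lp, _ = mse_loss_and_grads(params, X, y)
                W[ix] = orig - eps
                lm, _ = mse_loss_and_grads(params, X, y)
                W[ix] = orig
                num = (lp - lm) / (2 * eps)
                a = grads[k][ix]
                assert abs(num - a) <= 1e-4 * max(abs(num), abs(a), 1e-3), (
                    f"gradient mismatch at {k}{ix}: analytic {a}, numeric {num}"
                )


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, sine_dataset):
        train_ds, _ = sine_dataset
        hyper = TrainConfig(hidden=8, feature_dim=8, max_epochs=5, patience=5)
        _, history = train(train_ds, hyper, seed=1)
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_training_is_seed_reproducible(self, sine_dataset):
        train_ds, _ = sine_dataset
        hyper = TrainConfig(hidden=4, feature_dim=4, max_epochs=2)
        a, _ = train(train_ds, hyper, seed=7)
        b, _ = train(train_ds, hyper, seed=7)
        for k, v in a.params.as_dict().items():
            np.testing.assert_array_equal(v, b.params.as_dict()[k])

    def test_sine_forecasting_converges(self, sine_net, sine_dataset):
        network, history = sine_net
        _, test_ds = sine_dataset
        assert len(history["train_loss"]) <= 200
        err = rmse(test_ds.targets, network.predict_batch(test_ds.inputs))
        assert err < 0.05


class TestMemristiveMode:
    def test_ideal_crossbars_reproduce_digital_forward(self, sine_net):
        network, _ = sine_net
        mem = to_memristive(network, XbarConfig(levels=None))
        rng = np.random.default_rng(0)
        W = rng.uniform(-1, 1, size=(20, 20))
        np.testing.assert_allclose(
            mem.predict_batch(W), network.predict_batch(W), atol=1e-10
        )

    def test_quantized_inference_still_solves_the_task(self, sine_net, sine_dataset):
        # 256-level quantization perturbs each weight by at most one grid
        # step; the forecast must stay accurate in absolute terms (the
        # relative-degradation bound is checked on the LFP benchmark,
        # whose targets are order-1 in normalized units)
        network, _ = sine_net
        _, test_ds = sine_dataset
        mem = to_memristive(network, XbarConfig(levels=256))
        quantized = rmse(test_ds.targets, mem.predict_batch(test_ds.inputs))
        assert quantized < 0.05

    def test_degradation_monotone_in_programming_noise(self, sine_net, sine_dataset):
        network, _ = sine_net
        _, test_ds = sine_dataset
        means = []
        for sigma in (0.0, 0.3):
            vals = []
            for seed in range(10):
                cfg = XbarConfig(levels=256, noise_sigma=sigma,
                                 seed=seed + 1 if sigma else None)
                mem = to_memristive(network, cfg)
                vals.append(rmse(test_ds.targets, mem.predict_batch(test_ds.inputs)))
            means.append(np.mean(vals))
        assert means[1] > means[0]


def test_checkpoint_round_trip(tmp_path, sine_net):
    network, _ = sine_net
    path = tmp_path / "model.h5"
    network.save(path, seed=0)
    loaded = LSTMNetwork.load(path)
    w = np.random.default_rng(3).normal(size=20)
    assert loaded.predict(w) == network.predict(w)
    assert (tmp_path / "model.h5.json").exists()
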