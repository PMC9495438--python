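"""LSTM cell/stack contracts, training mechanics, and CMC/RMSE metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutcoord._rng import substream
from cutcoord.lstm import (
    EvalMetrics,
    LSTMCellParams,
    LSTMCellState,
    LSTMRegressor,
    LSTMRunConfig,
    cmc,
    cmc_detailed,
    default_run_config,
    lstm_cell_step,
    rmse,
    split_by_trial,
    train,
)


class TestCellStep:
    def test_zero_params_zero_state(self):
        p = LSTMCellParams.zeros(3, 2)
        st0 = LSTMCellState(h=np.zeros(3), C=np.zeros(3))
        out = lstm_cell_step(p, st0, np.array([0.4, -1.0]))
        np.testing.assert_allclose(out.C, 0.0, atol=1e-15)
        np.testing.assert_allclose(out.h, 0.0, atol=1e-15)

    def test_zero_params_carried_cell_state(self):
        # f = i = o = 1/2, candidate 0: C_t = C_{t-1}/2, h_t = tanh(C_t)/2
        p = LSTMCellParams.zeros(1, 1)
        out = lstm_cell_step(p, LSTMCellState(h=np.zeros(1),
                                              C=np.array([2.0])),
                             np.array([0.3]))
        assert out.C[0] == pytest.approx(1.0, abs=1e-12)
        assert out.h[0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-12)

    def test_saturated_forget_gate_carries_cell_state(self):
        p = LSTMCellParams.zeros(1, 1)
        p.b_f[:] = 20.0
        c_prev = 3.14
        out = lstm_cell_step(p, LSTMCellState(h=np.zeros(1),
                                              C=np.array([c_prev])),
                             np.array([0.0]))
        assert out.C[0] == pytest.approx(c_prev, abs=1e-7)

    def test_dimension_mismatch_rejected(self):
        p = LSTMCellParams.zeros(3, 2)
        st0 = LSTMCellState(h=np.zeros(3), C=np.zeros(3))
        with pytest.raises(ValueError, match="weights expect"):
            lstm_cell_step(p, st0, np.zeros(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_gate_ranges_for_arbitrary_inputs(self, seed):
        """h stays in (-1, 1) elementwise for any finite parameters."""
        rng = np.random.default_rng(seed)
        H, D = 4, 3
        p = LSTMCellParams(
            *(rng.normal(scale=1, size=(H + D, H)) for _ in range(4)),
            *(rng.normal(scale=1, size=H) for _ in range(4)),
        )
        state = LSTMCellState(h=rng.uniform(-1, 1, H),
                              C=rng.normal(scale=5, size=H))
        x = rng.normal(scale=2, size=D)
        out = lstm_cell_step(p, state, x)
        assert np.all(np.abs(out.h) < 1.0)
        # gates themselves are sigmoid/tanh outputs -> open unit intervals
        xcat = np.concatenate([state.h, x])
        for W, b in ((p.W_f, p.b_f), (p.W_i, p.b_i), (p.W_o, p.b_o)):
            gate = 1 / (1 + np.exp(-(xcat @ W + b)))
            assert np.all((gate > 0) & (gate < 1))


class TestForward:
    def test_zero_parameters_give_zero_readout(self):
        m = LSTMRegressor(n_channels=2, units=3, n_layers=3, seed=0,
                          dtype=np.float64)
        for layer in m.layers:
            layer["W"][:] = 0.0
            layer["b"][:] = 0.0
        m.head_w[:] = 1.0  # nonzero head exposes any hidden activity
        m.head_b[:] = 0.0
        out = m.forward(np.random.default_rng(0).normal(size=(2, 6, 2)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(5).normal(size=(3, 8, 18))
        a = LSTMRegressor(seed=11, units=8).forward(X)
        b = LSTMRegressor(seed=11, units=8).forward(X)
        np.testing.assert_array_equal(a, b)

    def test_wrong_channel_count_rejected(self):
        m = LSTMRegressor(units=4)
        with pytest.raises(ValueError, match="18"):
            m.forward(np.zeros((1, 5, 3)))

    def test_matches_reference_cell_unroll(self):
        """The batched stack reproduces a manual unroll of the reference
        cell equations over 3 time steps and 3 layers."""
        m = LSTMRegressor(n_channels=1, units=1, n_layers=3, seed=3,
                          dtype=np.float64)
        X = np.array([[[0.5], [-1.0], [2.0]]])
        out = m.forward(X)
        inp = X[0]
        for li in range(3):
            p = m.cell_params(li)
            state = LSTMCellState(h=np.zeros(1), C=np.zeros(1))
            hs = []
            for t in range(3):
                state = lstm_cell_step(p, state, inp[t])
                hs.append(state.h)
            inp = np.array(hs)
        expected = inp[:, 0] * float(m.head_w[0]) + float(m.head_b[0])
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_time_order_sensitivity(self):
        m = LSTMRegressor(n_channels=18, units=6, seed=2)
        X = np.random.default_rng(3).normal(size=(1, 10, 18))
        fwd = m.predict_curve(X)
        rev = m.predict_curve(X[:, ::-1, :])
        assert not np.allclose(fwd, rev)

    def test_gradients_match_numerical_differentiation(self):
        m = LSTMRegressor(n_channels=2, units=3, n_layers=2, seed=7,
                          dtype=np.float64)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 4, 2))
        Y = rng.normal(size=(2, 3))
        _, grads = m.loss_and_grads(X, Y)
        eps = 1e-6
        for pi, param in enumerate(m.parameters()):
            flat = param.reshape(-1)
            for ix in rng.choice(flat.size, size=min(4, flat.size),
                                 replace=False):
                orig = flat[ix]
                flat[ix] = orig + eps
                l1, _ = m.loss_and_grads(X, Y)
                flat[ix] = orig - eps
                l2, _ = m.loss_and_grads(X, Y)
                flat[ix] = orig
                num = (l1 - l2) / (2 * eps)
                ana = grads[pi].reshape(-1)[ix]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-9)


class TestTraining:
    def _toy_dataset(self, n=24, T=12):
        rng = substream(0, "toy")
        X = rng.normal(size=(n, T, 18))
        w = rng.normal(size=18) / np.sqrt(18)
        Y = 0.5 + 0.3 * np.tanh(X[:, 1:, :] @ w)
        return X, Y

    def test_split_allocation_rule(self):
        tr, va, te = split_by_trial(225, (0.7, 0.2, 0.1),
                                    np.random.default_rng(0))
        assert (len(tr), len(va), len(te)) == (157, 45, 23)
        assert sorted(np.concatenate([tr, va, te])) == list(range(225))

    def test_split_rejects_empty_partition(self):
        with pytest.raises(ValueError, match="empty"):
            split_by_trial(4, (0.7, 0.2, 0.1), np.random.default_rng(0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LSTMRunConfig(direction=90, split=(0.5, 0.2, 0.2))

    def test_per_direction_defaults(self):
        assert (default_run_config(90).units,
                default_run_config(90).epochs) == (100, 600)
        assert (default_run_config(135).units,
                default_run_config(135).epochs) == (120, 700)
        assert (default_run_config(180).units,
                default_run_config(180).epochs) == (120, 750)

    def test_smoke_training_reduces_loss(self):
        X, Y = self._toy_dataset()
        cfg = LSTMRunConfig(direction=90, units=8, epochs=5, batch_size=8,
                            seed=1)
        trained = train(cfg, X, Y)
        h = trained.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]
        assert len(h) == 5

    def test_training_is_deterministic(self):
        X, Y = self._toy_dataset()
        cfg = LSTMRunConfig(direction=90, units=6, epochs=3, batch_size=8,
                            seed=5)
        h1 = train(cfg, X, Y).history
        h2 = train(cfg, X, Y).history
        assert h1.equals(h2)

    def test_feature_scaling_uses_train_statistics_only(self):
        X, Y = self._toy_dataset()
        cfg = LSTMRunConfig(direction=90, units=4, epochs=2, batch_size=8,
                            seed=2)
        trained = train(cfg, X, Y)
        tr = trained.splits["train"]
        np.testing.assert_allclose(trained.x_stats.minimum,
                                   X[tr].min(axis=(0, 1)))
        np.testing.assert_allclose(trained.x_stats.maximum,
                                   X[tr].max(axis=(0, 1)))


class TestMetrics:
    def test_identical_curves(self, rng):
        y = rng.normal(size=(3, 101))
        assert cmc(y, y) == pytest.approx(1.0, abs=1e-12)
        assert rmse(y, y) == 0.0

    def test_constant_offset_rmse(self, rng):
        y = rng.normal(size=101)
        assert rmse(y + 0.1, y) == pytest.approx(0.1, abs=1e-12)

    def test_two_point_rmse(self):
        assert rmse([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_anticorrelated_curves_clip_to_zero(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 101))
        value, flag = cmc_detailed(-y, y)
        assert value == 0.0
        assert "clipped" in flag

    def test_identical_constant_curves_flagged_degenerate(self):
        value, flag = cmc_detailed(np.full(101, 0.3), np.full(101, 0.3))
        assert value == 1.0
        assert "degenerate" in flag

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(5), np.zeros(6))

    def test_matches_brute_force_formula(self, rng):
        """Vectorized CMC/RMSE equal a literal double-loop evaluation of
        their defining formulas on 50 random curve pairs."""
        for _ in range(50):
            pred = rng.normal(size=101)
            meas = rng.normal(size=101)
            Y = [pred, meas]
            F, P = 101, 2
            ybar_f = [(pred[f] + meas[f]) / 2 for f in range(F)]
            num = sum((Y[p][f] - ybar_f[f]) ** 2
                      for p in range(P) for f in range(F)) / (F * (P - 1))
            ybar = sum(Y[p][f] for p in range(P) for f in range(F)) / (P * F)
            den = sum((Y[p][f] - ybar) ** 2
                      for p in range(P) for f in range(F)) / (P * F - 1)
            expected = np.sqrt(max(1 - num / den, 0.0))
            assert cmc(pred, meas) == pytest.approx(expected, abs=1e-12)
            brute_rmse = np.sqrt(
                sum((pred[f] - meas[f]) ** 2 for f in range(F)) / F
            )
            assert rmse(pred, meas) == pytest.approx(brute_rmse, abs=1e-12)

    def test_offset_curve_cmc_matches_oracle(self):
        meas = np.sin(np.linspace(0, 2 * np.pi, 101))
        pred = meas + 0.5
        Y = np.stack([pred, meas])
        within = ((Y - Y.mean(0)) ** 2).sum() / (101 * 1)
        total = ((Y - Y.mean()) ** 2).sum() / (2 * 101 - 1)
        expected = np.sqrt(1 - within / total)
        assert cmc(pred, meas) == pytest.approx(expected, abs=1e-12)

    def test_eval_metrics_container(self):
        m = EvalMetrics(cmc=0.99, rmse=0.01)
        assert m.flags == []
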