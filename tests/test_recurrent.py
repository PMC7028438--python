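"""Grouped Bi-LSTM: gate equations, global access wiring, gradients.

The manual oracles re-evaluate the gate equations in plain numpy with an
independent implementation, including a reference peephole-forget LSTM for
the zeroed-global-access reduction.
"""

import numpy as np
import pytest

from groupecg.autodiff import Tensor
from groupecg.recurrent import GroupBiLSTM, LSTMCell, RecurrentConfig


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def manual_global_step(cell, x, c_prev, h_prev):
    """Independent evaluation of the global-cell gate equations."""
    base = np.concatenate([h_prev, x])
    with_c = np.concatenate([c_prev, h_prev, x])
    f = sigmoid(with_c @ cell.W_f.data + cell.b_f.data)
    i = sigmoid(base @ cell.W_i.data + cell.b_i.data)
    cand = np.tanh(base @ cell.W_c.data + cell.b_c.data)
    c = f * c_prev + i * cand
    o = sigmoid(base @ cell.W_o.data + cell.b_o.data)
    return c, o * np.tanh(c)


def manual_intra_step(cell, x, h_g, c_prev, h_prev):
    """Independent evaluation of the intra-cell gate equations."""
    base = np.concatenate([h_prev, h_g, x])
    with_c = np.concatenate([c_prev, h_prev, h_g, x])
    f = sigmoid(with_c @ cell.W_f.data + cell.b_f.data)
    i = sigmoid(base @ cell.W_i.data + cell.b_i.data)
    cand = np.tanh(base @ cell.W_c.data + cell.b_c.data)
    c = f * c_prev + i * cand
    o = sigmoid(base @ cell.W_o.data + cell.b_o.data)
    return c, o * np.tanh(c)


def plain_lstm_sequence(weights, xs):
    """Reference peephole-forget LSTM (forget gate reads C_{t-1})."""
    W_f, W_i, W_c, W_o, b_f, b_i, b_c, b_o, dh = weights
    c = np.zeros(dh)
    h = np.zeros(dh)
    out = []
    for x in xs:
        base = np.concatenate([h, x])
        f = sigmoid(np.concatenate([c, base]) @ W_f + b_f)
        i = sigmoid(base @ W_i + b_i)
        cand = np.tanh(base @ W_c + b_c)
        c = f * c + i * cand
        o = sigmoid(base @ W_o + b_o)
        h = o * np.tanh(c)
        out.append(h)
    return np.array(out)


def small_integer_cell(context_size=0):
    """2-unit cell with hand-chosen small integer weights."""
    cell = LSTMCell(2, 2, np.random.default_rng(0), context_size=context_size)
    for k, p in enumerate([cell.W_f, cell.W_i, cell.W_c, cell.W_o]):
        rows = p.shape[0]
        p.data[:] = (np.arange(rows * 2).reshape(rows, 2) % 3 - 1) * 0.5
    cell.b_f.data[:] = (0.5, -0.5)
    cell.b_i.data[:] = (0.25, 0.0)
    cell.b_c.data[:] = (0.0, -0.25)
    cell.b_o.data[:] = (-0.5, 0.5)
    return cell


class TestGlobalCellStep:
    def test_zero_weights_zero_state(self):
        cell = LSTMCell(3, 4, np.random.default_rng(0))
        for p in cell.parameters():
            p.data[:] = 0.0
        c, h = cell.step(Tensor(np.ones((1, 3))),
                         Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))))
        np.testing.assert_array_equal(c.data, 0.0)  # i=0.5, cand=tanh(0)=0
        np.testing.assert_array_equal(h.data, 0.0)

    def test_zero_weights_halve_previous_cell_state(self):
        cell = LSTMCell(3, 4, np.random.default_rng(0))
        for p in cell.parameters():
            p.data[:] = 0.0
        c_prev = np.array([[1.0, -2.0, 0.5, 4.0]])
        c, h = cell.step(Tensor(np.zeros((1, 3))), Tensor(c_prev),
                         Tensor(np.zeros((1, 4))))
        np.testing.assert_allclose(c.data, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h.data, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_matches_manual_two_unit_evaluation(self):
        cell = small_integer_cell()
        x = np.array([0.3, -0.7])
        c_prev = np.array([0.2, -0.1])
        h_prev = np.array([-0.4, 0.6])
        c, h = cell.step(Tensor(x[None]), Tensor(c_prev[None]), Tensor(h_prev[None]))
        c_ref, h_ref = manual_global_step(cell, x, c_prev, h_prev)
        np.testing.assert_allclose(c.data[0], c_ref, atol=1e-10)
        np.testing.assert_allclose(h.data[0], h_ref, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        cell = LSTMCell(3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cell.step(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 4))),
                      Tensor(np.zeros((1, 4))), h_global=Tensor(np.zeros((1, 4))))


class TestIntraCellStep:
    def test_zero_weights_degenerate_values(self):
        cell = LSTMCell(3, 4, np.random.default_rng(0), context_size=4)
        for p in cell.parameters():
            p.data[:] = 0.0
        c, h = cell.step(Tensor(np.ones((1, 3))), Tensor(np.zeros((1, 4))),
                         Tensor(np.zeros((1, 4))), h_global=Tensor(np.ones((1, 4))))
        np.testing.assert_array_equal(c.data, 0.0)
        np.testing.assert_array_equal(h.data, 0.0)

    def test_matches_manual_two_unit_evaluation_with_context(self):
        cell = small_integer_cell(context_size=2)
        x = np.array([0.3, -0.7])
        h_g = np.array([0.5, 0.2])
        c_prev = np.array([0.2, -0.1])
        h_prev = np.array([-0.4, 0.6])
        c, h = cell.step(Tensor(x[None]), Tensor(c_prev[None]), Tensor(h_prev[None]),
                         h_global=Tensor(h_g[None]))
        c_ref, h_ref = manual_intra_step(cell, x, h_g, c_prev, h_prev)
        np.testing.assert_allclose(c.data[0], c_ref, atol=1e-10)
        np.testing.assert_allclose(h.data[0], h_ref, atol=1e-10)

    def test_zeroed_context_weights_reduce_to_plain_lstm(self):
        """With the global-access rows zeroed, the intra step is a standard
        peephole-forget LSTM step."""
        dh, d = 3, 2
        rng = np.random.default_rng(5)
        cell = LSTMCell(d, dh, rng, context_size=dh)
        # rows receiving h_g: after c_prev+h_prev in W_f, after h_prev otherwise
        cell.W_f.data[2 * dh:3 * dh] = 0.0
        for W in (cell.W_i, cell.W_c, cell.W_o):
            W.data[dh:2 * dh] = 0.0
        plain = (
            np.delete(cell.W_f.data, slice(2 * dh, 3 * dh), axis=0),
            np.delete(cell.W_i.data, slice(dh, 2 * dh), axis=0),
            np.delete(cell.W_c.data, slice(dh, 2 * dh), axis=0),
            np.delete(cell.W_o.data, slice(dh, 2 * dh), axis=0),
            cell.b_f.data, cell.b_i.data, cell.b_c.data, cell.b_o.data, dh)
        xs = rng.normal(size=(6, d))
        ref = plain_lstm_sequence(plain, xs)
        c = Tensor(np.zeros((1, dh)))
        h = Tensor(np.zeros((1, dh)))
        for t, x in enumerate(xs):
            c, h = cell.step(Tensor(x[None]), c, h,
                             h_global=Tensor(rng.normal(size=(1, dh))))
            np.testing.assert_allclose(h.data[0], ref[t], atol=1e-8)


class TestRunGroup:
    @pytest.fixture
    def features(self, rng):
        return rng.normal(size=(2, 3, 4, 5))     # [M, n, T', D]

    def test_output_structure(self, features):
        net = GroupBiLSTM(5, 3, RecurrentConfig(hidden_size=6),
                          np.random.default_rng(0))
        out = net(Tensor(features))
        assert net.n_global == 1
        assert out.global_forward.shape == (2, 4, 6)
        assert out.global_backward.shape == (2, 4, 6)
        assert out.intra_forward.shape == (2, 3, 4, 6)
        assert out.intra_backward.shape == (2, 3, 4, 6)

    def test_twelve_leads_give_twelve_intra_sequences(self, rng):
        net = GroupBiLSTM(2, 12, RecurrentConfig(hidden_size=3),
                          np.random.default_rng(0))
        out = net(Tensor(rng.normal(size=(1, 12, 3, 2))))
        assert out.intra_forward.shape[1] == 12

    def test_lead_permutation_leaves_global_invariant(self, features):
        net = GroupBiLSTM(5, 3, RecurrentConfig(hidden_size=4),
                          np.random.default_rng(1))
        perm = [2, 0, 1]
        out = net(Tensor(features))
        out_p = net(Tensor(features[:, perm]))
        np.testing.assert_allclose(out_p.global_forward.data,
                                   out.global_forward.data, atol=1e-12)
        np.testing.assert_allclose(out_p.intra_forward.data,
                                   out.intra_forward.data[:, perm], atol=1e-12)
        np.testing.assert_allclose(out_p.intra_backward.data,
                                   out.intra_backward.data[:, perm], atol=1e-12)

    def test_single_step_reduces_to_cell_step(self, rng):
        net = GroupBiLSTM(3, 2, RecurrentConfig(hidden_size=4),
                          np.random.default_rng(2))
        x = rng.normal(size=(1, 2, 1, 3))
        out = net(Tensor(x))
        zeros = Tensor(np.zeros((1, 4)))
        x_sum = Tensor(x[:, :, 0, :].sum(axis=1))
        _, h_ref = net.global_fw.step(x_sum, zeros, zeros)
        np.testing.assert_allclose(out.global_forward.data[:, 0], h_ref.data,
                                   atol=1e-12)

    def test_hidden_activations_strictly_bounded(self, rng):
        net = GroupBiLSTM(4, 2, RecurrentConfig(hidden_size=5),
                          np.random.default_rng(3))
        out = net(Tensor(5.0 * rng.normal(size=(2, 2, 10, 4))))
        for seq in (out.global_forward, out.global_backward,
                    out.intra_forward, out.intra_backward):
            assert np.all(np.abs(seq.data) < 1.0)

    def test_mismatched_feature_shapes_rejected(self, rng):
        net = GroupBiLSTM(4, 3, RecurrentConfig(hidden_size=2),
                          np.random.default_rng(0))
        with pytest.raises(ValueError):
            net(Tensor(rng.normal(size=(1, 2, 5, 4))))   # wrong lead count

    def test_unshared_intra_cells_per_lead(self):
        cfg = RecurrentConfig(hidden_size=3, share_intra=False)
        net = GroupBiLSTM(2, 4, cfg, np.random.default_rng(0))
        assert len(net.intra_fw) == 4 and len(net.intra_bw) == 4
        out = net(Tensor(np.random.default_rng(1).normal(size=(2, 4, 3, 2))))
        assert out.intra_forward.shape == (2, 4, 3, 3)


class TestGradients:
    def test_finite_difference_through_group_step(self, rng):
        """Relative FD error < 1e-4 through one global+intra bidirectional pass."""
        net = GroupBiLSTM(2, 2, RecurrentConfig(hidden_size=2),
                          np.random.default_rng(4))
        feats = rng.normal(size=(1, 2, 2, 2))

        def run():
            out = net(Tensor(feats))
            return (out.global_forward.sum() + out.global_backward.sum()
                    + out.intra_forward.sum() + out.intra_backward.sum())

        for p in net.parameters():
            p.grad = None
        run().backward()
        eps = 1e-6
        for p in net.parameters():
            assert p.grad is not None
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = run().item()
                flat[idx] = orig - eps
                down = run().item()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                # absolute floor absorbs central-difference roundoff on
                # near-zero derivatives
                denom = max(abs(num), abs(gflat[idx]), 1e-6)
                assert abs(num - gflat[idx]) / denom < 1e-4
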