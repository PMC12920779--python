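"""RANGE block: positional encoding, attention oracle equivalence, gates."""

import numpy as np
import pytest

import rangeff.autodiff as ad
from rangeff import AtomicConfiguration, EnergyModel
from rangeff.autodiff import Tensor
from rangeff.range_layer import (
    MasterGates,
    MasterState,
    RangeBlock,
    RangeHyperparams,
    gate_penalty,
    positional_encode,
)
from conftest import random_rotation, tiny_model_config


def _lrelu(x, slope=0.2):
    return np.where(x >= 0, x, slope * x)


def _split_heads(x, H, Dh):
    return x.reshape(len(x), H, Dh)


def _linear(lin, x):
    out = x @ lin.W.data
    return out + lin.b.data if lin.b is not None else out


def dense_range_oracle(block, h, p, M0, gates):
    """Triple-loop reference for one aggregation–broadcast cycle.

    Written directly from the additive-attention definition, independent of
    the vectorized scatter/softmax implementation it checks.
    """
    hp = block.hp
    N, K, H, Dh = len(h), M0.shape[0], hp.n_heads, hp.head_dim
    kh = _split_heads(_linear(block.A_K, h), H, Dh)
    eh = _split_heads(_linear(block.A_E, p), H, Dh)
    vh = _split_heads(_linear(block.A_V, h), H, Dh)

    alpha = np.zeros((H, K, N))
    M1 = np.zeros_like(M0)
    for hd in range(H):
        for k in range(K):
            q = M0[k, hd] @ block.A_Q.data[hd]
            scores = np.array([
                _lrelu(q + kh[i, hd] + eh[i, hd]) @ block.a_vec.data[hd]
                for i in range(N)
            ])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            alpha[hd, k] = w
            M1[k, hd] = np.tanh(sum(w[i] * vh[i, hd] for i in range(N)))

    qn = _split_heads(_linear(block.B_Q, h), H, Dh)
    eB = _split_heads(_linear(block.B_E, p), H, Dh)
    ks = _split_heads(_linear(block.B_K_self, h), H, Dh)
    vs = _split_heads(_linear(block.B_V_self, h), H, Dh)
    g = 1.0 / (1.0 + np.exp(-gates.logits.data))

    beta = np.zeros((H, N, K + 1))
    o = np.zeros((N, H, Dh))
    for hd in range(H):
        for i in range(N):
            t = [
                _lrelu(qn[i, hd] + eB[i, hd] + M1[k, hd] @ block.B_K.data[hd])
                @ block.b_vec.data[hd]
                for k in range(K)
            ]
            t.append(_lrelu(qn[i, hd] + ks[i, hd]) @ block.b_vec.data[hd])
            t = np.array(t)
            w = np.exp(t - t.max())
            w /= w.sum()
            beta[hd, i] = w
            o[i, hd] = w[K] * vs[i, hd] + sum(
                g[k] * w[k] * (M1[k, hd] @ block.B_V.data[hd]) for k in range(K)
            )

    flat = o.reshape(N, H * Dh)
    mixed = flat
    for li, lin in enumerate(block.mix.layers):
        mixed = _linear(lin, mixed)
        if li < len(block.mix.layers) - 1:
            mixed = np.logaddexp(0, mixed) - np.log(2)
    return h + mixed, M1, alpha, beta


def _run_block(block, h, p, M0, gates):
    """Drive the vectorized implementation on a single graph."""
    from rangeff.range_layer import range_cycle, AttentionRecord, PositionalEncoding

    N, K = len(h), M0.shape[0]
    pm = np.repeat(np.arange(K), N)
    pa = np.tile(np.arange(N), K)
    masters = MasterState(
        M=Tensor(M0), position=np.zeros((1, 3)),
        k_of_master=np.arange(K), graph_of_master=np.zeros(K, dtype=int),
    )
    pe = PositionalEncoding(u=Tensor(np.zeros(N)), p=Tensor(p), lambda_scale=10.0)
    rec = AttentionRecord()
    h_new, m_new = range_cycle(block, Tensor(h), masters, pe, gates, pm, pa, rec)
    return h_new.data, m_new.M.data, rec


@pytest.mark.parametrize("seed", range(25))
def test_vectorized_cycle_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(1, 11))
    K = int(rng.integers(1, 4))
    H = int(rng.integers(1, 3))
    Dh, F, n_pe = 4, 8, 5
    hp = RangeHyperparams(n_masters=K, n_heads=H, head_dim=Dh, n_pe=n_pe)
    block = RangeBlock(F, hp, rng)
    for lin in block.mix.layers:  # exercise a non-trivial mixing MLP
        lin.W.data[:] = rng.normal(size=lin.W.shape) * 0.3
    h = rng.normal(size=(N, F))
    p = rng.uniform(0, 1, (N, n_pe))
    M0 = rng.normal(size=(K, H, Dh))
    gates = MasterGates(K, penalty_weight=0.0)
    gates.logits.data[:] = rng.normal(size=K)

    h_vec, M_vec, rec = _run_block(block, h, p, M0, gates)
    h_ref, M_ref, alpha_ref, beta_ref = dense_range_oracle(block, h, p, M0, gates)
    assert np.allclose(h_vec, h_ref, atol=1e-12)
    assert np.allclose(M_vec, M_ref, atol=1e-12)
    assert np.allclose(rec.agg[0], alpha_ref, atol=1e-12)
    assert np.allclose(rec.bro[0], beta_ref, atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_attention_rows_are_probability_distributions(seed):
    rng = np.random.default_rng(500 + seed)
    hp = RangeHyperparams(n_masters=3, n_heads=2, head_dim=4, n_pe=5)
    block = RangeBlock(8, hp, rng)
    N = int(rng.integers(2, 9))
    h = rng.normal(size=(N, 8)) * 2
    p = rng.uniform(0, 1, (N, 5))
    M0 = rng.normal(size=(3, 2, 4))
    _, _, rec = _run_block(block, h, p, M0, MasterGates(3, 0.0))
    agg, bro = rec.agg[0], rec.bro[0]
    assert np.all(agg >= 0) and np.all(agg <= 1)
    assert np.all(bro >= 0) and np.all(bro <= 1)
    assert np.allclose(agg.sum(axis=2), 1.0, atol=1e-6)
    assert np.allclose(bro.sum(axis=2), 1.0, atol=1e-6)


def test_single_atom_attention_is_one():
    rng = np.random.default_rng(0)
    hp = RangeHyperparams(n_masters=2, n_heads=2, head_dim=3, n_pe=4)
    block = RangeBlock(6, hp, rng)
    _, _, rec = _run_block(
        block, rng.normal(size=(1, 6)), rng.uniform(0, 1, (1, 4)),
        rng.normal(size=(2, 2, 3)), MasterGates(2, 0.0),
    )
    assert np.allclose(rec.agg[0], 1.0, atol=1e-12)


def test_identical_atoms_get_uniform_aggregation():
    rng = np.random.default_rng(1)
    hp = RangeHyperparams(n_masters=1, n_heads=1, head_dim=3, n_pe=4)
    block = RangeBlock(6, hp, rng)
    h = np.tile(rng.normal(size=6), (5, 1))
    p = np.tile(rng.uniform(0, 1, 4), (5, 1))
    _, _, rec = _run_block(block, h, p, rng.normal(size=(1, 1, 3)), MasterGates(1, 0.0))
    assert np.allclose(rec.agg[0], 0.2, atol=1e-12)


def test_closed_gates_silence_masters():
    rng = np.random.default_rng(2)
    hp = RangeHyperparams(n_masters=2, n_heads=2, head_dim=3, n_pe=4)
    block = RangeBlock(6, hp, rng)
    h = rng.normal(size=(4, 6))
    p = rng.uniform(0, 1, (4, 4))
    M0 = rng.normal(size=(2, 2, 3))
    gates = MasterGates(2, 0.0)
    gates.logits.data[:] = -60.0  # g → 0
    h_out, _, rec = _run_block(block, h, p, M0, gates)
    # only the self-loop value survives in the broadcast output
    _, _, _, beta = dense_range_oracle(block, h, p, M0, gates)
    vs = _split_heads(_linear(block.B_V_self, h), 2, 3)
    o_expect = vs * beta[:, :, 2].T[:, :, None]
    flat = o_expect.reshape(4, 6)
    mixed = flat
    for li, lin in enumerate(block.mix.layers):
        mixed = _linear(lin, mixed)
        if li < len(block.mix.layers) - 1:
            mixed = np.logaddexp(0, mixed) - np.log(2)
    assert np.allclose(h_out, h + mixed, atol=1e-10)


def test_equal_pair_softmax_is_half():
    # K = 1 with equal self and master scores → β = (0.5, 0.5)
    t = Tensor(np.zeros((2, 1)))
    sm = ad.segment_softmax(t, np.array([0, 0]), 1)
    assert np.allclose(sm.data, 0.5)


class TestPositionalEncoding:
    def test_atom_at_center_maps_to_zero(self):
        cfg = AtomicConfiguration([[1.0, 2.0, 3.0]], [1])
        pe = positional_encode(cfg, np.array([1.0, 2.0, 3.0]), 10.0, 8)
        assert pe.u.data[0] == pytest.approx(0.0, abs=1e-6)

    def test_value_at_lambda_is_one_minus_inv_e(self):
        cfg = AtomicConfiguration([[10.0, 0.0, 0.0]], [1])
        pe = positional_encode(cfg, np.zeros(3), 10.0, 8)
        assert pe.u.data[0] == pytest.approx(1 - np.exp(-1), abs=1e-7)

    @pytest.mark.parametrize("lam", [0.5, 3.0, 10.0, 40.0])
    def test_monotone_in_distance(self, lam):
        cfg = AtomicConfiguration([[5.0, 0, 0], [10.0, 0, 0]], [1, 1])
        pe = positional_encode(cfg, np.zeros(3), lam, 8)
        assert pe.u.data[0] < pe.u.data[1]

    def test_u_bounded_and_p_in_unit_interval_even_at_huge_distance(self):
        cfg = AtomicConfiguration([[200.0, 0, 0], [4000.0, 0, 0]], [1, 1])
        pe = positional_encode(cfg, np.zeros(3), 10.0, 8)
        assert 0 <= pe.u.data[0] < 1
        assert np.all(np.isfinite(pe.u.data)) and np.all(pe.u.data <= 1.0)
        assert np.all(pe.p.data > 0) and np.all(pe.p.data <= 1)

    def test_invalid_arguments_rejected(self):
        cfg = AtomicConfiguration([[0, 0, 0]], [1])
        with pytest.raises(ValueError):
            positional_encode(cfg, np.zeros(3), -1.0, 8)
        with pytest.raises(ValueError):
            positional_encode(cfg, np.zeros(3), 10.0, 1)


class TestGates:
    def test_penalty_worked_example(self):
        gates = MasterGates(2, penalty_weight=0.1)
        gates.logits.data[:] = [0.0, np.log(1.0 / 3.0)]  # g = 0.5, 0.25
        assert gate_penalty(gates).item() == pytest.approx(0.075, rel=1e-12)

    def test_zero_weight_switches_penalty_off(self):
        gates = MasterGates(4, penalty_weight=0.0)
        assert gate_penalty(gates).item() == 0.0

    def test_all_closed_gates_give_zero_penalty(self):
        gates = MasterGates(3, penalty_weight=0.5)
        gates.logits.data[:] = -1e3
        assert gate_penalty(gates).item() == pytest.approx(0.0, abs=1e-12)

    def test_penalty_is_differentiable_in_logits(self):
        gates = MasterGates(3, penalty_weight=0.5)
        gate_penalty(gates).backward()
        assert gates.logits.grad is not None
        assert np.all(gates.logits.grad.data > 0)


class TestModelLevelProperties:
    def test_zero_mixing_reduces_to_baseline_energy(self, tiny_model, random_config):
        from rangeff import predict_energy

        tiny_model.zero_range_mixing()
        twin = EnergyModel(tiny_model_config(range_enabled=False), seed=0)
        assert predict_energy(tiny_model, random_config) == pytest.approx(
            predict_energy(twin, random_config), abs=1e-12
        )

    def test_attention_op_count_is_exactly_linear(self):
        from rangeff.model_training import prepare_batch

        model = EnergyModel(tiny_model_config(), seed=0)
        rng = np.random.default_rng(0)
        counts = {}
        for n in (5, 10, 20):
            cfg = AtomicConfiguration(rng.uniform(0, 20, (n, 3)), np.ones(n, dtype=int))
            batch = prepare_batch([cfg], 5.0, model.config.range_hp.n_masters)
            model.attention_ops = 0
            with ad.no_grad():
                model.forward(batch)
            counts[n] = model.attention_ops
        hp, bhp = model.config.range_hp, model.config.baseline
        per_atom = 2 * hp.n_masters * hp.n_heads * bhp.T
        assert counts == {n: n * per_atom for n in (5, 10, 20)}

    def test_attention_weights_invariant_under_rigid_motion(self):
        from rangeff.interpretability import collect_attention

        model = EnergyModel(tiny_model_config(), seed=3)
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 6, (8, 3))
        species = rng.integers(1, 8, 8)
        base = collect_attention(model, [AtomicConfiguration(pos, species)])
        for trial in range(20):
            R, t = random_rotation(rng), rng.normal(size=3) * 10
            moved = collect_attention(
                model, [AtomicConfiguration(pos @ R.T + t, species)]
            )
            assert np.allclose(moved.agg, base.agg, atol=1e-6)
            assert np.allclose(moved.bro, base.bro, atol=1e-6)

    def test_masters_persist_across_layers_by_default(self, random_config):
        """With persistence off, layer-2 aggregation sees fresh masters."""
        from rangeff.interpretability import collect_attention

        m_persist = EnergyModel(tiny_model_config(), seed=5)
        m_fresh = EnergyModel(tiny_model_config(), seed=5)
        m_fresh.config.range_hp.masters_persist = False
        a = collect_attention(m_persist, [random_config]).agg
        b = collect_attention(m_fresh, [random_config]).agg
        assert np.allclose(a[:, 0], b[:, 0], atol=1e-12)  # first layer identical
        assert not np.allclose(a[:, 1], b[:, 1])          # second differs
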