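"""RANGE: virtual master nodes with attention aggregation and broadcast.

K virtual "master" nodes sit at the geometric center of each graph and are
connected to every atom. After each local interaction layer, a cycle runs:

  aggregation  — GATv2-style additive multi-head attention pools all node
                 embeddings into each master:
                 s_{k,i} = aᵀ LeakyReLU(A_Q M_k + A_K h_i + A_E p_i),
                 α = softmax over atoms, M'_k = σ(Σ_i α_{k,i} A_V h_i)
  broadcast    — each atom attends over the K masters plus itself (a
                 self-loop that preserves local information):
                 t_{i,k} = bᵀ LeakyReLU(B_Q h_i + B_K M'_k + B_E p_i),
                 t_{i,self} = bᵀ LeakyReLU(B_Q h_i + B_K^self h_i),
                 β = softmax over K+1 candidates,
                 o_i = β_self B_V^self h_i + Σ_k g_k β_{i,k} B_V M'_k
  head mixing  — heads stay independent until a final MLP folds the
                 concatenated per-head outputs back into the embedding:
                 h_i ← h_i + MLP(concat_heads o_i)

p_i is an SE(3)-invariant positional encoding of the atom-to-center
distance: u = 1 − exp(−d/λ) maps any distance smoothly into [0, 1), then u
is expanded in Gaussian radial basis functions. No cutoff appears anywhere
in the cycle, so the block never introduces discontinuities.

The sigmoid gates g_k multiply master value contributions; an L1 penalty on
the gates lets training switch off masters a task does not need, dynamically
sizing the global representation.

Cost: exactly N·K·H attention-score evaluations per phase per layer —
linear in the number of atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .baseline_mpnn import MLP, Linear
from .graph_core import AtomicConfiguration, geometric_center


@dataclass
class RangeHyperparams:
    n_masters: int = 4       # K
    n_heads: int = 8         # H
    head_dim: int = 8        # D_h (defaults to F // H)
    n_pe: int = 16           # positional-encoding RBF count
    lambda_scale: float = 10.0   # Å, distance→[0,1) map length scale
    penalty_weight: float = 1e-3  # L1 gate regularization strength
    masters_persist: bool = True  # carry master state across layers
    center_epsilon: float = 1e-6  # Å, regularizes d=0 kink at the center


@dataclass
class PositionalEncoding:
    """u in [0,1) per atom and its RBF expansion p (length n_pe)."""

    u: Tensor
    p: Tensor
    lambda_scale: float


@dataclass
class AttentionRecord:
    """Per-layer, per-head attention weights kept for interpretability.

    agg[layer] has shape (H, K, N); bro[layer] has shape (H, N, K+1) with
    the last column the self-loop weight.
    """

    agg: list = field(default_factory=list)
    bro: list = field(default_factory=list)


class MasterGates:
    """Sigmoid gates on the K masters' broadcast value contributions.

    Logits start near 2 (g ≈ 0.88, masters active) with a small random
    spread: under an L1 penalty, degenerate masters have identical utility
    gradients, and without the spread nothing breaks the tie between them.
    """

    def __init__(self, n_masters: int, penalty_weight: float,
                 init_logit: float = 2.0, rng: np.random.Generator | None = None,
                 spread: float = 0.5):
        logits = np.full(n_masters, init_logit)
        if rng is not None and spread > 0:
            logits = logits + rng.normal(0.0, spread, n_masters)
        self.logits = Tensor(logits, requires_grad=True)
        self.penalty_weight = float(penalty_weight)

    def values(self) -> Tensor:
        return ad.sigmoid(self.logits)

    def parameters(self):
        return [self.logits]


def gate_penalty(gates: MasterGates) -> Tensor:
    """penalty_weight · Σ_k g_k, added to the training loss."""
    return gates.values().sum() * gates.penalty_weight


def _pe_from_distance(d: Tensor, lambda_scale: float, n_pe: int) -> PositionalEncoding:
    u = 1.0 - ad.exp(d * (-1.0 / lambda_scale))
    centers = np.linspace(0.0, 1.0, n_pe)
    gamma = 1.0 / (2.0 * (centers[1] - centers[0]) ** 2)
    p = ad.gauss_rbf(u, centers, gamma)
    return PositionalEncoding(u=u, p=p, lambda_scale=lambda_scale)


def positional_encode(
    config: AtomicConfiguration,
    center: np.ndarray,
    lambda_scale: float,
    n_pe: int,
    epsilon: float = 1e-6,
) -> PositionalEncoding:
    """Encode each atom's distance to the master position.

    u = 1 − exp(−d/λ) maps [0, ∞) onto [0, 1) monotonically; p is a Gaussian
    RBF expansion of u with centers on [0, 1]. d is regularized as
    sqrt(d² + ε²) so the encoding stays differentiable for an atom exactly
    at the center.
    """
    if lambda_scale <= 0:
        raise ValueError("lambda_scale must be positive")
    if n_pe < 2:
        raise ValueError("need at least 2 positional RBFs")
    delta = Tensor(config.positions) - Tensor(np.asarray(center, dtype=np.float64))
    d = ad.sqrt((delta * delta).sum(axis=1) + epsilon**2)
    return _pe_from_distance(d, lambda_scale, n_pe)


@dataclass
class MasterState:
    """K×H×D_h virtual-node embeddings, all located at the geometric center."""

    M: Tensor                       # (G·K, H, D_h) in batched form
    position: np.ndarray            # (G, 3) geometric centers
    k_of_master: np.ndarray         # (G·K,) master index within its graph
    graph_of_master: np.ndarray     # (G·K,) owning graph


class RangeBlock:
    """One aggregation–broadcast–mix cycle (per interaction layer)."""

    def __init__(self, F: int, hp: RangeHyperparams, rng: np.random.Generator):
        H, Dh = hp.n_heads, hp.head_dim
        self.hp = hp
        self.F = F

        def headmat(n_in, n_out):
            scale = 1.0 / np.sqrt(n_in)
            return Tensor(rng.uniform(-scale, scale, (H, n_in, n_out)), requires_grad=True)

        # aggregation: atoms (senders) -> masters
        self.A_Q = headmat(Dh, Dh)                 # master side, per head
        self.A_K = Linear(F, H * Dh, rng)          # atom side
        self.A_E = Linear(hp.n_pe, H * Dh, rng)    # positional encoding
        self.A_V = Linear(F, H * Dh, rng)
        self.a_vec = Tensor(rng.uniform(-1, 1, (H, Dh)) / np.sqrt(Dh), requires_grad=True)
        # broadcast: masters (senders) + self-loop -> atoms
        self.B_Q = Linear(F, H * Dh, rng)
        self.B_K = headmat(Dh, Dh)
        self.B_E = Linear(hp.n_pe, H * Dh, rng)
        self.B_V = headmat(Dh, Dh)
        self.B_K_self = Linear(F, H * Dh, rng)
        self.B_V_self = Linear(F, H * Dh, rng)
        self.b_vec = Tensor(rng.uniform(-1, 1, (H, Dh)) / np.sqrt(Dh), requires_grad=True)
        # head mixing; zero-initialized last layer => the whole model starts
        # as (and can exactly reduce to) the pure baseline
        self.mix = MLP([H * Dh, F, F], rng, zero_last=True)

    # -- helpers ----------------------------------------------------------
    def _heads(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        return ad.reshape(x, (n, self.hp.n_heads, self.hp.head_dim))

    # -- phases -----------------------------------------------------------
    def aggregate(self, h: Tensor, masters: MasterState, pe: PositionalEncoding,
                  pair_master: np.ndarray, pair_atom: np.ndarray):
        """Pool all node embeddings into each master via additive attention.

        pair_master/pair_atom enumerate every (master, atom) pair within the
        same graph; attention never crosses graph boundaries.
        """
        if h.shape[0] == 0:
            raise ValueError("aggregate on an empty graph")
        n_masters = masters.M.shape[0]
        q = ad.einsum2("nhd,hde->nhe", masters.M, self.A_Q)
        k = self._heads(self.A_K(h))
        e = self._heads(self.A_E(pe.p))
        z = ad.gather(q, pair_master) + ad.gather(k + e, pair_atom)
        scores = (ad.leaky_relu(z, 0.2) * self.a_vec).sum(axis=2)  # (P, H)
        if not np.all(np.isfinite(scores.data)):
            raise FloatingPointError("non-finite aggregation attention score")
        alpha = ad.segment_softmax(scores, pair_master, n_masters)
        v = ad.gather(self._heads(self.A_V(h)), pair_atom)
        pooled = ad.scatter_rows(v * ad.reshape(alpha, alpha.shape + (1,)), pair_master, n_masters)
        m_new = ad.tanh(pooled)  # elementwise nonlinearity after the weighted sum
        updated = MasterState(
            M=m_new,
            position=masters.position,
            k_of_master=masters.k_of_master,
            graph_of_master=masters.graph_of_master,
        )
        return updated, alpha

    def broadcast(self, h: Tensor, masters: MasterState, pe: PositionalEncoding,
                  gates: MasterGates, pair_master: np.ndarray, pair_atom: np.ndarray):
        """Redistribute master information to atoms, with a self-loop."""
        n_atoms = h.shape[0]
        qn = self._heads(self.B_Q(h))
        kM = ad.einsum2("nhd,hde->nhe", masters.M, self.B_K)
        eB = self._heads(self.B_E(pe.p))
        z_pair = ad.gather(qn + eB, pair_atom) + ad.gather(kM, pair_master)
        t_pair = (ad.leaky_relu(z_pair, 0.2) * self.b_vec).sum(axis=2)  # (P, H)
        z_self = qn + self._heads(self.B_K_self(h))
        t_self = (ad.leaky_relu(z_self, 0.2) * self.b_vec).sum(axis=2)  # (N, H)

        # joint softmax over {K masters} ∪ {self}, max-subtracted
        shift = t_self.data.copy()
        np.maximum.at(shift, pair_atom, t_pair.data)
        e_pair = ad.exp(t_pair - Tensor(shift[pair_atom]))
        e_self = ad.exp(t_self - Tensor(shift))
        denom = ad.scatter_rows(e_pair, pair_atom, n_atoms) + e_self
        beta_pair = e_pair / ad.gather(denom, pair_atom)
        beta_self = e_self / denom

        vM = ad.einsum2("nhd,hde->nhe", masters.M, self.B_V)
        v_self = self._heads(self.B_V_self(h))
        g_pair = ad.gather(gates.values(), masters.k_of_master[pair_master])
        w = beta_pair * ad.reshape(g_pair, (len(pair_master), 1))
        contrib = ad.gather(vM, pair_master) * ad.reshape(w, w.shape + (1,))
        o = ad.scatter_rows(contrib, pair_atom, n_atoms)
        o = o + v_self * ad.reshape(beta_self, beta_self.shape + (1,))
        return o, beta_pair, beta_self

    def mix_heads(self, o: Tensor, h: Tensor) -> Tensor:
        """Residual head-mixing MLP over the concatenated per-head outputs."""
        n = o.shape[0]
        flat = ad.reshape(o, (n, self.hp.n_heads * self.hp.head_dim))
        out = self.mix(flat)
        if out.shape[1] != h.shape[1]:
            raise ValueError("head mixing output width does not match embeddings")
        return h + out

    def parameters(self):
        ps = [self.A_Q, self.a_vec, self.B_K, self.B_V, self.b_vec]
        for lin in (self.A_K, self.A_E, self.A_V, self.B_Q, self.B_E,
                    self.B_K_self, self.B_V_self):
            ps += lin.parameters()
        return ps + self.mix.parameters()


def range_cycle(block: RangeBlock, h: Tensor, masters: MasterState,
                pe: PositionalEncoding, gates: MasterGates,
                pair_master: np.ndarray, pair_atom: np.ndarray,
                record: Optional[AttentionRecord] = None):
    """aggregate → broadcast → mix; returns (h', masters', α, β)."""
    updated, alpha = block.aggregate(h, masters, pe, pair_master, pair_atom)
    o, beta_pair, beta_self = block.broadcast(
        h, updated, pe, gates, pair_master, pair_atom
    )
    h_new = block.mix_heads(o, h)
    if record is not None:
        K, H = block.hp.n_masters, block.hp.n_heads
        n = h.shape[0]
        # pairs are built master-major within each graph, so for a single
        # graph alpha is (K·N, H) in (k, i) order
        agg = alpha.data.reshape(K, n, H).transpose(2, 0, 1)          # (H, K, N)
        bro_m = beta_pair.data.reshape(K, n, H).transpose(2, 1, 0)    # (H, N, K)
        bro_s = beta_self.data.T[:, :, None]                          # (H, N, 1)
        record.agg.append(agg.copy())
        record.bro.append(np.concatenate([bro_m, bro_s], axis=2))
    return h_new, updated
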