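"""Invariant continuous-filter-convolution message-passing baseline.

A SchNet-style network: per-species learnable embeddings h_i^(0), then T
interaction layers, each computing messages

    m_i = sum_{j in N(i)}  W_filter(rbf(d_ij)) ⊙ (W1 h_j) · f_cut(d_ij)

followed by a residual update h_i ← h_i + MLP(m_i). Distances are the only
geometric input, so the energy is exactly invariant under rigid motions and
atom permutations. Smooth (shifted-softplus) activations and the cosine
cutoff keep energies and forces continuous in the positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class BaselineHyperparams:
    F: int = 64          # embedding width
    T: int = 2           # interaction layers
    cutoff: float = 5.0  # Å
    n_rbf: int = 20
    species_vocab: int = 86  # largest atomic number accepted


def rbf_expand(d, cutoff: float, n: int):
    """Gaussian radial basis expansion of a distance.

    Centers are equally spaced on [0, cutoff]; gamma = 1/(2 Δc²) with Δc the
    center spacing. Accepts scalars, arrays, or Tensors; d beyond the cutoff
    is allowed (the features simply decay).
    """
    if n < 2:
        raise ValueError("need at least 2 radial basis functions")
    centers = np.linspace(0.0, cutoff, n)
    gamma = 1.0 / (2.0 * (centers[1] - centers[0]) ** 2)
    if isinstance(d, Tensor):
        dd = d if d.ndim == 1 else ad.reshape(d, (-1,))
        return ad.gauss_rbf(dd, centers, gamma)
    d = np.asarray(d, dtype=np.float64)
    return np.exp(-gamma * (d[..., None] - centers) ** 2)


def cosine_cutoff(d, cutoff: float):
    """0.5 (cos(π d / r_c) + 1) for d < r_c, exactly 0 beyond; C¹ at r_c."""
    if isinstance(d, Tensor):
        mask = (d.data < cutoff).astype(np.float64)
        return (ad.cos(d * (np.pi / cutoff)) + 1.0) * 0.5 * Tensor(mask)
    d = np.asarray(d, dtype=np.float64)
    return np.where(d < cutoff, 0.5 * (np.cos(np.pi * d / cutoff) + 1.0), 0.0)


def shifted_softplus(x: Tensor) -> Tensor:
    """ln(1 + e^x) − ln 2; smooth, zero at zero."""
    return ad.softplus(x) - np.log(2.0)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.affine(x, self.W, self.b)

    def zero_(self):
        self.W.data[:] = 0.0
        if self.b is not None:
            self.b.data[:] = 0.0

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Dense layers with shifted-softplus between (not after) them."""

    def __init__(self, widths, rng, zero_last: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        if zero_last:
            self.layers[-1].zero_()

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = shifted_softplus(x)
        return x

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]


class SpeciesEmbedding:
    def __init__(self, vocab: int, width: int, rng):
        self.table = Tensor(rng.normal(0.0, 1.0, size=(vocab + 1, width)), requires_grad=True)
        self.vocab = vocab

    def __call__(self, species: np.ndarray) -> Tensor:
        species = np.asarray(species)
        bad = species[(species < 1) | (species > self.vocab)]
        if len(bad):
            raise ValueError(f"species outside vocabulary: {sorted(set(bad.tolist()))}")
        return ad.gather(self.table, species)

    def parameters(self):
        return [self.table]


def embed_species(embedding: SpeciesEmbedding, species) -> Tensor:
    """Look up the learnable per-species initial embedding h^(0)."""
    return embedding(species)


class InteractionLayer:
    """One continuous-filter convolution block with residual update."""

    def __init__(self, hp: BaselineHyperparams, rng):
        F = hp.F
        self.hp = hp
        self.w1 = Linear(F, F, rng, bias=False)
        self.filter_net = MLP([hp.n_rbf, F, F], rng)
        self.update_mlp = MLP([F, F, F], rng)

    def message(self, h: Tensor, senders, receivers, dist: Tensor, n_atoms: int) -> Tensor:
        if len(senders) == 0:
            return Tensor(np.zeros((n_atoms, self.hp.F)))
        if float(np.max(dist.data)) > self.hp.cutoff + 1e-9:
            raise ValueError(
                "stale neighbor list: edge distance exceeds the model cutoff "
                f"({float(np.max(dist.data)):.6g} > {self.hp.cutoff} Å)"
            )
        filt = self.filter_net(rbf_expand(dist, self.hp.cutoff, self.hp.n_rbf))
        hj = ad.gather(self.w1(h), senders)
        fc = ad.reshape(cosine_cutoff(dist, self.hp.cutoff), (len(senders), 1))
        return ad.scatter_rows(filt * hj * fc, receivers, n_atoms)

    def update(self, h: Tensor, m: Tensor) -> Tensor:
        return h + self.update_mlp(m)

    def parameters(self):
        return self.w1.parameters() + self.filter_net.parameters() + self.update_mlp.parameters()


def message_step(layer: InteractionLayer, h: Tensor, graph) -> Tensor:
    """Aggregate messages for every atom given a NeighborGraph."""
    n = h.shape[0]
    return layer.message(h, graph.senders, graph.receivers, Tensor(graph.distances), n)


def update_step(layer: InteractionLayer, h: Tensor, m: Tensor) -> Tensor:
    if h.shape[1] != m.shape[1]:
        raise ValueError("embedding / message width mismatch")
    return layer.update(h, m)
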