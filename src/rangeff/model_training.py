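"""Energy/force model assembly, training, and evaluation.

An :class:`EnergyModel` stacks the invariant message-passing baseline with
one RANGE cycle after every interaction layer (when enabled), followed by an
atom-wise readout summed into the total energy. Forces are exact gradients
−∂E/∂x obtained by reverse-mode differentiation of the same computation.

Training minimizes

    energy_weight · MSE(ΔE / N_atoms) + force_weight · MSE(F) + gate penalty

with decoupled-weight-decay Adam (AdamW) and a cosine learning-rate decay.
Runs are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .baseline_mpnn import (
    MLP,
    BaselineHyperparams,
    InteractionLayer,
    SpeciesEmbedding,
)
from .graph_core import AtomicConfiguration, build_neighbor_list
from .range_layer import (
    AttentionRecord,
    MasterGates,
    MasterState,
    RangeBlock,
    RangeHyperparams,
    _pe_from_distance,
    gate_penalty,
)


@dataclass
class TrainingConfig:
    energy_weight: float = 0.05
    force_weight: float = 0.95
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 5e-4
    weight_decay: float = 1e-6
    seed: int = 0
    penalty_weight: float = 1e-3
    val_fraction: float = 0.1
    val_every: int = 1           # validation cadence, epochs
    init_species_ref: bool = False

    def __post_init__(self):
        if self.energy_weight < 0 or self.force_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.energy_weight + self.force_weight <= 0 and self.penalty_weight <= 0:
            pass  # a null objective is allowed (weights then stay untouched)


@dataclass
class BatchData:
    """Precomputed arrays for one forward pass over a set of frames."""

    positions: np.ndarray
    species: np.ndarray
    graph_index: np.ndarray
    n_per_graph: np.ndarray
    senders: np.ndarray
    receivers: np.ndarray
    offsets: np.ndarray
    pair_master: np.ndarray
    pair_atom: np.ndarray
    k_of_master: np.ndarray
    graph_of_master: np.ndarray
    energies: np.ndarray | None = None
    forces: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_graphs(self) -> int:
        return len(self.n_per_graph)


def prepare_batch(configs, cutoff: float, n_masters: int) -> BatchData:
    """Concatenate frames, build neighbor lists and master-atom pair lists."""
    if isinstance(configs, AtomicConfiguration):
        configs = [configs]
    if not configs:
        raise ValueError("empty batch")
    pos, spec, senders, receivers, offsets = [], [], [], [], []
    pm, pa, k_of, g_of = [], [], [], []
    n_per = []
    atom_offset = 0
    for g, c in enumerate(configs):
        graph = build_neighbor_list(c, cutoff)
        pos.append(c.positions)
        spec.append(c.species)
        senders.append(graph.senders + atom_offset)
        receivers.append(graph.receivers + atom_offset)
        offsets.append(graph.offsets)
        n = c.n_atoms
        # master-atom pairs, master-major within the graph
        m_base = g * n_masters
        pm.append(np.repeat(np.arange(m_base, m_base + n_masters), n))
        pa.append(np.tile(np.arange(atom_offset, atom_offset + n), n_masters))
        k_of.append(np.arange(n_masters))
        g_of.append(np.full(n_masters, g))
        n_per.append(n)
        atom_offset += n
    energies = forces = None
    if all(c.energy is not None for c in configs):
        energies = np.array([c.energy for c in configs])
    if all(c.forces is not None for c in configs):
        forces = np.concatenate([c.forces for c in configs])
    return BatchData(
        positions=np.concatenate(pos),
        species=np.concatenate(spec),
        graph_index=np.repeat(np.arange(len(configs)), n_per),
        n_per_graph=np.array(n_per, dtype=np.int64),
        senders=np.concatenate(senders),
        receivers=np.concatenate(receivers),
        offsets=np.concatenate(offsets),
        pair_master=np.concatenate(pm),
        pair_atom=np.concatenate(pa),
        k_of_master=np.concatenate(k_of),
        graph_of_master=np.concatenate(g_of),
        energies=energies,
        forces=forces,
    )


@dataclass
class ModelConfig:
    baseline: BaselineHyperparams = field(default_factory=BaselineHyperparams)
    range_hp: RangeHyperparams = field(default_factory=RangeHyperparams)
    range_enabled: bool = True
    seed: int = 0
    # fixed short-range repulsive prior k·(r0/r)¹²·f_cut(r): guarantees a
    # physical wall below the distances the training data samples; the
    # network learns the residual (standard delta-learning baseline)
    repulsive_prior: bool = True
    prior_strength: float = 0.05   # kcal/mol at r = prior_radius
    prior_radius: float = 2.0      # Å

    def __post_init__(self):
        if isinstance(self.baseline, dict):
            self.baseline = BaselineHyperparams(**self.baseline)
        if isinstance(self.range_hp, dict):
            self.range_hp = RangeHyperparams(**self.range_hp)


class EnergyModel:
    """Baseline MPNN, optional RANGE cycles, and an atom-wise energy readout."""

    def __init__(self, config: ModelConfig | None = None, seed: int | None = None):
        config = config or ModelConfig()
        if seed is not None:
            config.seed = seed
        self.config = config
        hp = config.baseline
        rng = np.random.default_rng(config.seed)
        self.embedding = SpeciesEmbedding(hp.species_vocab, hp.F, rng)
        self.layers = [InteractionLayer(hp, rng) for _ in range(hp.T)]
        rhp = config.range_hp
        self.range_blocks = [RangeBlock(hp.F, rhp, rng) for _ in range(hp.T)]
        self.gates = MasterGates(rhp.n_masters, rhp.penalty_weight, rng=rng)
        self.master_init = Tensor(
            rng.normal(0.0, 1.0, (rhp.n_masters, rhp.n_heads, rhp.head_dim)),
            requires_grad=True,
        )
        self.readout = MLP([hp.F, hp.F // 2, 1], rng)
        self.species_ref = Tensor(np.zeros(hp.species_vocab + 1), requires_grad=True)
        self.attention_ops = 0  # exact score-evaluation counter

    # -- parameters -------------------------------------------------------
    def parameters(self) -> dict:
        ps: dict[str, Tensor] = {"embedding.table": self.embedding.table}
        for t, layer in enumerate(self.layers):
            for i, p in enumerate(layer.parameters()):
                ps[f"layer{t}.p{i}"] = p
        if self.config.range_enabled:
            for t, blk in enumerate(self.range_blocks):
                for i, p in enumerate(blk.parameters()):
                    ps[f"range{t}.p{i}"] = p
            ps["gates.logits"] = self.gates.logits
            ps["master_init"] = self.master_init
        for i, p in enumerate(self.readout.parameters()):
            ps[f"readout.p{i}"] = p
        ps["species_ref"] = self.species_ref
        return ps

    def zero_range_mixing(self):
        """Zero the head-mixing MLPs: the model then equals the pure baseline."""
        for blk in self.range_blocks:
            for lin in blk.mix.layers:
                lin.zero_()

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        batch: BatchData,
        positions: Tensor | None = None,
        record: AttentionRecord | None = None,
    ) -> Tensor:
        """Per-graph total energies (kcal/mol) as a length-G Tensor."""
        if record is not None and not self.config.range_enabled:
            raise ValueError("attention recording requires range_enabled=True")
        if record is not None and batch.n_graphs != 1:
            raise ValueError("attention recording works on single-frame batches")
        hp = self.config.baseline
        rhp = self.config.range_hp
        pos = positions if positions is not None else Tensor(batch.positions)
        G = batch.n_graphs

        # differentiable edge distances (offsets are constant image shifts)
        if len(batch.senders):
            dist = ad.pair_distances(pos, batch.senders, batch.receivers, batch.offsets)
        else:
            dist = Tensor(np.zeros(0))

        h = self.embedding(batch.species)

        if self.config.range_enabled:
            counts = Tensor(batch.n_per_graph[:, None].astype(np.float64))
            centers = ad.scatter_rows(pos, batch.graph_index, G) / counts
            delta = pos - ad.gather(centers, batch.graph_index)
            d_c = ad.sqrt((delta * delta).sum(axis=1) + rhp.center_epsilon**2)
            pe = _pe_from_distance(d_c, rhp.lambda_scale, rhp.n_pe)
            masters = MasterState(
                M=ad.gather(
                    ad.reshape(self.master_init, (rhp.n_masters, rhp.n_heads * rhp.head_dim)),
                    batch.k_of_master,
                ).reshape(len(batch.k_of_master), rhp.n_heads, rhp.head_dim),
                position=centers.data,
                k_of_master=batch.k_of_master,
                graph_of_master=batch.graph_of_master,
            )

        from .range_layer import range_cycle

        for t, layer in enumerate(self.layers):
            m = layer.message(h, batch.senders, batch.receivers, dist, batch.n_atoms)
            h = layer.update(h, m)
            if self.config.range_enabled:
                h, new_masters = range_cycle(
                    self.range_blocks[t], h, masters, pe, self.gates,
                    batch.pair_master, batch.pair_atom, record,
                )
                if rhp.masters_persist:
                    masters = new_masters
                self.attention_ops += 2 * batch.n_atoms * rhp.n_masters * rhp.n_heads

        e_atom = self.readout(h) + ad.reshape(
            ad.gather(self.species_ref, batch.species), (batch.n_atoms, 1)
        )
        energies = ad.reshape(
            ad.scatter_rows(e_atom, batch.graph_index, G), (G,)
        )
        if self.config.repulsive_prior and len(batch.senders):
            from .baseline_mpnn import cosine_cutoff

            inv = Tensor(self.config.prior_radius) / dist
            # each pair appears as two directed edges → half per edge
            e_edge = (inv ** 12) * cosine_cutoff(dist, hp.cutoff) * (
                0.5 * self.config.prior_strength
            )
            e_rep = ad.scatter_rows(
                ad.reshape(e_edge, (len(batch.senders), 1)),
                batch.graph_index[batch.receivers], G,
            )
            energies = energies + ad.reshape(e_rep, (G,))
        if not np.all(np.isfinite(energies.data)):
            bad = np.where(~np.isfinite(energies.data))[0]
            raise FloatingPointError(f"non-finite energy for graphs {bad.tolist()}")
        return energies


def predict_energy(model: EnergyModel, config: AtomicConfiguration) -> float:
    """Total potential energy of one configuration, kcal/mol."""
    batch = prepare_batch([config], model.config.baseline.cutoff,
                          model.config.range_hp.n_masters)
    with ad.no_grad():
        return float(model.forward(batch).data[0])


def predict_forces(model: EnergyModel, config: AtomicConfiguration):
    """(energy, forces): forces are the exact gradient −∂E/∂x_i."""
    batch = prepare_batch([config], model.config.baseline.cutoff,
                          model.config.range_hp.n_masters)
    pos = Tensor(batch.positions, requires_grad=True)
    e = model.forward(batch, positions=pos)
    (g,) = ad.grad(e.sum(), [pos])
    forces = -g.data
    if not np.all(np.isfinite(forces)):
        bad = np.where(~np.isfinite(forces).all(axis=1))[0]
        raise FloatingPointError(f"non-finite forces on atoms {bad.tolist()}")
    return float(e.data[0]), forces


def predict_batch(model: EnergyModel, configs, with_forces: bool = False):
    """Energies (and optionally forces) for many frames in one pass."""
    batch = prepare_batch(configs, model.config.baseline.cutoff,
                          model.config.range_hp.n_masters)
    if not with_forces:
        with ad.no_grad():
            return model.forward(batch).data.copy(), None
    pos = Tensor(batch.positions, requires_grad=True)
    e = model.forward(batch, positions=pos)
    (g,) = ad.grad(e.sum(), [pos])
    return e.data.copy(), -g.data


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimizer.

    ``param_lr`` holds per-parameter learning-rate multipliers: the gate
    logits use a large multiplier because they are O(1) allocation scalars
    whose Adam-normalized steps would otherwise be far too small to open or
    close a gate within a typical run.
    """

    GATE_LR_MULTIPLIER = 100.0

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.param_lr = {
            k: (self.GATE_LR_MULTIPLIER if k == "gates.logits" else 1.0)
            for k in params
        }

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            lr = self.lr * lr_scale * self.param_lr[k]
            g = p.grad.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _loss_on_batch(model: EnergyModel, batch: BatchData, cfg: TrainingConfig):
    need_forces = cfg.force_weight > 0
    pos = Tensor(batch.positions, requires_grad=True) if need_forces else Tensor(batch.positions)
    energies = model.forward(batch, positions=pos)
    terms = []
    if cfg.energy_weight > 0:
        de = (energies - Tensor(batch.energies)) / Tensor(batch.n_per_graph.astype(np.float64))
        terms.append((de * de).mean() * cfg.energy_weight)
    if need_forces:
        (g,) = ad.grad(energies.sum(), [pos], create_graph=True)
        df = (-g) - Tensor(batch.forces)
        terms.append((df * df).mean() * cfg.force_weight)
    if model.config.range_enabled and cfg.penalty_weight > 0:
        model.gates.penalty_weight = cfg.penalty_weight
        terms.append(gate_penalty(model.gates))
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def train(model: EnergyModel, dataset, cfg: TrainingConfig):
    """Train in place; returns a history list of per-epoch records.

    The best-validation-loss parameters are restored at the end (and stored
    in each history record as ``best`` flags). Deterministic under cfg.seed.
    """
    frames = list(dataset)
    if not frames:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(frames)))
    perm = rng.permutation(len(frames))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training frames after validation split")

    cutoff = model.config.baseline.cutoff
    K = model.config.range_hp.n_masters
    cache = [prepare_batch([f], cutoff, K) for f in frames]

    # optional: seed per-species reference energies by least squares on the
    # composition (off by default — offsets are learned jointly otherwise)
    if (cfg.init_species_ref and cfg.energy_weight > 0
            and np.all(model.species_ref.data == 0.0)
            and all(f.energy is not None for f in frames)):
        vocab = model.config.baseline.species_vocab + 1
        comp = np.zeros((len(frames), vocab))
        for r, f in enumerate(frames):
            np.add.at(comp[r], f.species, 1.0)
        e_ref = np.array([f.energy for f in frames])
        ridge = comp.T @ comp + 1e-6 * np.eye(vocab)
        model.species_ref.data[:] = np.linalg.solve(ridge, comp.T @ e_ref)
    val_batch = _merge_batches([cache[i] for i in val_idx], K) if n_val else None

    params = model.parameters()
    opt = AdamW(params, cfg.learning_rate, cfg.weight_decay)
    null_objective = (
        cfg.energy_weight == 0 and cfg.force_weight == 0 and cfg.penalty_weight == 0
    )

    n_batches = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    total_steps = max(1, cfg.epochs * n_batches)
    history, best = [], None
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            batch = _merge_batches([cache[i] for i in idx], K)
            loss = _loss_on_batch(model, batch, cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN loss at epoch {epoch}, batch {b}")
            if not null_objective:
                opt.zero_grad()
                loss.backward()
                lr_scale = 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
                opt.step(lr_scale=max(lr_scale, 0.01))
            epoch_loss += float(loss.data) * len(idx)
            step += 1
        epoch_loss /= len(train_idx)

        val_loss = epoch_loss
        if val_batch is not None and (
            epoch % cfg.val_every == 0 or epoch == cfg.epochs - 1
        ):
            val_loss = float(_loss_on_batch(model, val_batch, cfg).data)
        rec = {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
        history.append(rec)
        if best is None or val_loss < best[0]:
            best = (val_loss, {k: p.data.copy() for k, p in params.items()}, epoch)

    if best is not None and not null_objective:
        for k, p in params.items():
            p.data[:] = best[1][k]
        history[-1]["best_epoch"] = best[2]
    return history


def _merge_batches(batches, n_masters: int) -> BatchData:
    """Concatenate per-frame BatchData with index offsetting."""
    if len(batches) == 1:
        return batches[0]
    pos, spec, snd, rcv, off, pm, pa, kof, gof, npg = [], [], [], [], [], [], [], [], [], []
    energies, forces = [], []
    a_off = m_off = 0
    for g, b in enumerate(batches):
        pos.append(b.positions)
        spec.append(b.species)
        snd.append(b.senders + a_off)
        rcv.append(b.receivers + a_off)
        off.append(b.offsets)
        pm.append(b.pair_master + m_off)
        pa.append(b.pair_atom + a_off)
        kof.append(b.k_of_master)
        gof.append(np.full(n_masters, g))
        npg.append(b.n_per_graph[0])
        if b.energies is not None:
            energies.append(b.energies[0])
        if b.forces is not None:
            forces.append(b.forces)
        a_off += b.n_atoms
        m_off += n_masters
    n_per = np.array(npg, dtype=np.int64)
    return BatchData(
        positions=np.concatenate(pos),
        species=np.concatenate(spec),
        graph_index=np.repeat(np.arange(len(batches)), n_per),
        n_per_graph=n_per,
        senders=np.concatenate(snd),
        receivers=np.concatenate(rcv),
        offsets=np.concatenate(off),
        pair_master=np.concatenate(pm),
        pair_atom=np.concatenate(pa),
        k_of_master=np.concatenate(kof),
        graph_of_master=np.concatenate(gof),
        energies=np.array(energies) if len(energies) == len(batches) else None,
        forces=np.concatenate(forces) if len(forces) == len(batches) else None,
    )


def evaluate(model: EnergyModel, dataset, batch_size: int = 50):
    """(MAE_energy kcal/mol per frame, MAE_forces kcal/mol/Å per component)."""
    frames = list(dataset)
    if not frames:
        raise ValueError("cannot evaluate on an empty dataset")
    e_err, f_err = [], []
    for i in range(0, len(frames), batch_size):
        chunk = frames[i : i + batch_size]
        e_pred, f_pred = predict_batch(model, chunk, with_forces=True)
        e_ref = np.array([c.energy for c in chunk])
        f_ref = np.concatenate([c.forces for c in chunk])
        e_err.append(np.abs(e_pred - e_ref))
        f_err.append(np.abs(f_pred - f_ref).ravel())
    return float(np.concatenate(e_err).mean()), float(np.concatenate(f_err).mean())


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: EnergyModel, path, extra: dict | None = None):
    params = model.parameters()
    cfg = {
        "baseline": asdict(model.config.baseline),
        "range_hp": asdict(model.config.range_hp),
        "range_enabled": model.config.range_enabled,
        "seed": model.config.seed,
        "repulsive_prior": model.config.repulsive_prior,
        "prior_strength": model.config.prior_strength,
        "prior_radius": model.config.prior_radius,
        "extra": extra or {},
    }
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **{k: p.data for k, p in params.items()})


def load_checkpoint(path) -> EnergyModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        model = EnergyModel(
            ModelConfig(
                baseline=BaselineHyperparams(**cfg["baseline"]),
                range_hp=RangeHyperparams(**cfg["range_hp"]),
                range_enabled=cfg["range_enabled"],
                seed=cfg["seed"],
                repulsive_prior=cfg.get("repulsive_prior", True),
                prior_strength=cfg.get("prior_strength", 0.05),
                prior_radius=cfg.get("prior_radius", 2.0),
            )
        )
        params = model.parameters()
        for k, p in params.items():
            if k in data:
                p.data[:] = data[k]
    return model
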