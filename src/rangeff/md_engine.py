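"""Langevin molecular dynamics and structural observables.

Integration uses the BAOAB splitting of the Langevin equation: two velocity
half-kicks (B) and two half drifts (A) around an exact Ornstein–Uhlenbeck
update (O) whose noise obeys fluctuation–dissipation. With zero friction the
scheme reduces exactly to velocity Verlet.

Units: positions Å, time fs, masses amu, energies kcal/mol. The conversion
1 (kcal/mol/Å)/amu = 4.184e-4 Å/fs² fixes the acceleration scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .elements import mass_of
from .graph_core import AtomicConfiguration

KB = 0.0019872041          # kcal/mol/K
ACC = 4.184e-4             # (kcal/mol/Å)/amu → Å/fs²


@dataclass
class MDState:
    positions: np.ndarray   # Å
    velocities: np.ndarray  # Å/fs
    masses: np.ndarray      # amu
    species: np.ndarray
    time: float = 0.0       # fs
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self):
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")


@dataclass
class Trajectory:
    frames: list            # list of dicts: positions, energy, temperature, time
    stride: int
    stable: bool = True

    def __len__(self):
        return len(self.frames)

    def to_configurations(self, species) -> list:
        out = []
        for fr in self.frames:
            out.append(
                AtomicConfiguration(
                    positions=fr["positions"],
                    species=species,
                    energy=fr["energy"],
                    tags={"time": f"{fr['time']:.3f}",
                          "temperature": f"{fr['temperature']:.3f}"},
                )
            )
        return out


class ModelForceField:
    """Adapts a trained EnergyModel to the (energy, forces) callable MD needs."""

    def __init__(self, model, species):
        self.model = model
        self.species = np.asarray(species, dtype=np.int64)

    def energy_forces(self, positions: np.ndarray):
        from .model_training import predict_forces

        cfg = AtomicConfiguration(positions=positions, species=self.species)
        return predict_forces(self.model, cfg)

    def energy_forces_batch(self, positions_list):
        """One batched forward/backward over independent replicas.

        Graphs in a batch never exchange information, so the result is
        identical to per-replica calls — at a fraction of the overhead.
        """
        from .model_training import predict_batch

        configs = [AtomicConfiguration(positions=p, species=self.species)
                   for p in positions_list]
        energies, forces = predict_batch(self.model, configs, with_forces=True)
        out, start = [], 0
        for p in positions_list:
            out.append(forces[start : start + len(p)])
            start += len(p)
        return energies, out


def kinetic_temperature(state: MDState) -> float:
    ke = 0.5 * np.sum(state.masses[:, None] * state.velocities**2) / ACC
    dof = 3 * len(state.masses)
    return 2.0 * ke / (dof * KB)


def maxwell_boltzmann_velocities(masses, temperature, rng) -> np.ndarray:
    std = np.sqrt(KB * temperature * ACC / np.asarray(masses))[:, None]
    return rng.normal(size=(len(masses), 3)) * std


def init_state(config: AtomicConfiguration, temperature: float,
               seed: int = 0) -> MDState:
    masses = np.array([mass_of(int(z)) for z in config.species])
    rng = np.random.default_rng(seed)
    v = maxwell_boltzmann_velocities(masses, temperature, rng) if temperature > 0 \
        else np.zeros_like(config.positions)
    return MDState(positions=config.positions.copy(), velocities=v,
                   masses=masses, species=config.species.copy(), rng=rng)


def langevin_step(state: MDState, forces: np.ndarray, force_fn: Callable,
                  dt: float, temperature: float, friction: float):
    """One BAOAB step; returns (new forces, new energy).

    ``forces`` are the forces at the current positions (reused from the
    previous step). friction is in 1/fs; friction = 0 and temperature
    irrelevant gives velocity Verlet exactly.
    """
    if dt <= 0:
        raise ValueError("timestep must be positive")
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite forces entering MD step")
    m = state.masses[:, None]
    a = ACC * forces / m
    state.velocities = state.velocities + 0.5 * dt * a          # B
    state.positions = state.positions + 0.5 * dt * state.velocities  # A
    if friction > 0:                                            # O
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(KB * temperature * ACC / m) * np.sqrt(1.0 - c1 * c1)
        state.velocities = c1 * state.velocities + c2 * state.rng.normal(
            size=state.velocities.shape
        )
    state.positions = state.positions + 0.5 * dt * state.velocities  # A
    energy, forces_new = force_fn(state.positions)              # B
    a_new = ACC * forces_new / m
    state.velocities = state.velocities + 0.5 * dt * a_new
    state.time += dt
    return forces_new, energy


def _min_pair_distance(pos: np.ndarray) -> float:
    if len(pos) < 2:
        return np.inf
    from scipy.spatial.distance import pdist

    return float(pdist(pos).min())


def run_md(force_field, config: AtomicConfiguration, n_steps: int,
           dt: float = 1.0, temperature: float = 300.0,
           friction: float = 0.001, stride: int = 10,
           seed: int = 0, min_distance: float = 0.5) -> Trajectory:
    """Langevin dynamics from ``config``; frames are kept every ``stride`` steps.

    The run is declared stable if every coordinate stays finite and no pair
    distance drops below ``min_distance`` Å; on instability the trajectory is
    truncated, flagged, and returned.
    """
    state = init_state(config, temperature, seed=seed)
    fn = force_field.energy_forces
    energy, forces = fn(state.positions)
    frames = [_frame(state, energy)]
    for step in range(1, n_steps + 1):
        try:
            forces, energy = langevin_step(state, forces, fn, dt, temperature, friction)
        except FloatingPointError:
            return Trajectory(frames=frames, stride=stride, stable=False)
        bad = (not np.all(np.isfinite(state.positions))
               or _min_pair_distance(state.positions) < min_distance)
        if bad:
            frames.append(_frame(state, energy))
            return Trajectory(frames=frames, stride=stride, stable=False)
        if step % stride == 0:
            frames.append(_frame(state, energy))
    return Trajectory(frames=frames, stride=stride, stable=True)


def run_md_ensemble(force_field, config: AtomicConfiguration, n_steps: int,
                    seeds, dt: float = 1.0, temperature: float = 300.0,
                    friction: float = 0.001, stride: int = 10,
                    min_distance: float = 0.5) -> list:
    """Independent Langevin replicas advanced with shared batched force calls.

    Each seed gets its own initial velocities and noise stream; the dynamics
    of every replica is identical to a standalone :func:`run_md` with that
    seed, but the model evaluates all replicas in one batch per step.
    Returns one :class:`Trajectory` per seed (truncated individually on
    instability).
    """
    states = [init_state(config, temperature, seed=s) for s in seeds]
    alive = [True] * len(states)
    energies, forces = force_field.energy_forces_batch(
        [s.positions for s in states]
    )
    forces = list(forces)
    trajs = [[_frame(s, e)] for s, e in zip(states, energies)]
    stable = [True] * len(states)
    m = [s.masses[:, None] for s in states]

    for step in range(1, n_steps + 1):
        # B-A-O-A half of the step for every live replica
        for r, s in enumerate(states):
            if not alive[r]:
                continue
            s.velocities = s.velocities + 0.5 * dt * ACC * forces[r] / m[r]
            s.positions = s.positions + 0.5 * dt * s.velocities
            if friction > 0:
                c1 = np.exp(-friction * dt)
                c2 = np.sqrt(KB * temperature * ACC / m[r]) * np.sqrt(1 - c1 * c1)
                s.velocities = c1 * s.velocities + c2 * s.rng.normal(
                    size=s.velocities.shape
                )
            s.positions = s.positions + 0.5 * dt * s.velocities
        live = [r for r in range(len(states)) if alive[r]]
        if not live:
            break
        new_e, new_f = force_field.energy_forces_batch(
            [states[r].positions for r in live]
        )
        for e_val, f_val, r in zip(new_e, new_f, live):
            s = states[r]
            forces[r] = f_val
            s.velocities = s.velocities + 0.5 * dt * ACC * f_val / m[r]
            s.time += dt
            bad = (not np.all(np.isfinite(s.positions))
                   or not np.all(np.isfinite(f_val))
                   or _min_pair_distance(s.positions) < min_distance)
            if bad:
                trajs[r].append(_frame(s, e_val))
                stable[r] = False
                alive[r] = False
            elif step % stride == 0:
                trajs[r].append(_frame(s, e_val))
    return [
        Trajectory(frames=t, stride=stride, stable=st)
        for t, st in zip(trajs, stable)
    ]


def _frame(state: MDState, energy: float) -> dict:
    return {
        "positions": state.positions.copy(),
        "energy": float(energy),
        "temperature": kinetic_temperature(state),
        "time": state.time,
    }


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance from the (mass-unweighted) centroid, Å."""
    pos = np.asarray(positions).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("empty frame")
    c = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - c) ** 2, axis=1))))


def group_com_distance(positions: np.ndarray, masses: np.ndarray,
                       group_a, group_b) -> float:
    """Distance between mass-weighted centroids of two disjoint atom groups."""
    ga, gb = np.asarray(group_a, dtype=int), np.asarray(group_b, dtype=int)
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("groups must be non-empty")
    if set(ga.tolist()) & set(gb.tolist()):
        raise ValueError("groups overlap")
    pos = np.asarray(positions).reshape(-1, 3)
    m = np.asarray(masses, dtype=np.float64)
    ca = (m[ga, None] * pos[ga]).sum(axis=0) / m[ga].sum()
    cb = (m[gb, None] * pos[gb]).sum(axis=0) / m[gb].sum()
    return float(np.linalg.norm(ca - cb))
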