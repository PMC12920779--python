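"""Atomic configurations, neighbor lists, and batching.

The neighbor list is the local message-passing topology: a directed edge list
of all atom pairs within a cutoff radius. Non-periodic systems use cell-list
binning (O(N) construction); periodic systems use the minimum-image
convention, valid only while the cutoff does not exceed half the smallest
perpendicular cell width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class AtomicConfiguration:
    """One physical frame: positions (Å), species, and optional labels.

    Energies are total potential energies in kcal/mol; forces in kcal/mol/Å.
    """

    positions: np.ndarray
    species: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: Optional[np.ndarray] = None
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype=np.int64).reshape(-1)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atomic positions")
        if len(self.species) != len(self.positions):
            raise ValueError("species and positions length mismatch")
        if np.any(self.species < 1):
            raise ValueError("atomic numbers must be >= 1")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=np.float64).reshape(-1, 3)
            if len(self.forces) != len(self.positions):
                raise ValueError("forces and positions length mismatch")
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64).reshape(3, 3)
        if self.pbc is not None:
            self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
            if self.pbc.any():
                if self.cell is None:
                    raise ValueError("periodic axes require a cell")
                if abs(np.linalg.det(self.cell)) < 1e-12:
                    raise ValueError("periodic cell is singular")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            positions=self.positions.copy(),
            species=self.species.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=None if self.pbc is None else self.pbc.copy(),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            tags=dict(self.tags),
        )


@dataclass
class NeighborGraph:
    """Directed cutoff-limited edge list.

    ``displacements[e] = positions[senders[e]] + offsets[e] - positions[receivers[e]]``
    where ``offsets`` are the (constant) periodic image shifts in Å — zero for
    non-periodic systems. ``|displacements[e]| == distances[e]``.
    """

    senders: np.ndarray
    receivers: np.ndarray
    distances: np.ndarray
    displacements: np.ndarray
    cutoff: float
    offsets: np.ndarray = None

    def __post_init__(self):
        if self.offsets is None:
            self.offsets = np.zeros_like(self.displacements)

    @property
    def n_edges(self) -> int:
        return len(self.senders)


@dataclass
class ConfigurationBatch:
    """Several configurations concatenated; graph_index maps atom → frame."""

    positions: np.ndarray
    species: np.ndarray
    graph_index: np.ndarray
    n_per_graph: np.ndarray
    energies: Optional[np.ndarray] = None
    forces: Optional[np.ndarray] = None
    configs: Optional[list] = None

    @property
    def n_graphs(self) -> int:
        return len(self.n_per_graph)

    def unbatch(self) -> list:
        out = []
        start = 0
        for g, n in enumerate(self.n_per_graph):
            src = self.configs[g] if self.configs is not None else None
            out.append(
                AtomicConfiguration(
                    positions=self.positions[start : start + n].copy(),
                    species=self.species[start : start + n].copy(),
                    cell=None if src is None else (None if src.cell is None else src.cell.copy()),
                    pbc=None if src is None else (None if src.pbc is None else src.pbc.copy()),
                    energy=None if self.energies is None else float(self.energies[g]),
                    forces=None if self.forces is None else self.forces[start : start + n].copy(),
                    tags={} if src is None else dict(src.tags),
                )
            )
            start += n
        return out


def geometric_center(config: AtomicConfiguration) -> np.ndarray:
    """Unweighted centroid of the atomic positions (Å)."""
    if config.n_atoms == 0:
        raise ValueError("geometric center of an empty configuration")
    return config.positions.mean(axis=0)


def batch_configurations(configs: list) -> ConfigurationBatch:
    if not configs:
        raise ValueError("cannot batch an empty list of configurations")
    n_per = np.array([c.n_atoms for c in configs], dtype=np.int64)
    graph_index = np.repeat(np.arange(len(configs)), n_per)
    energies = None
    if all(c.energy is not None for c in configs):
        energies = np.array([c.energy for c in configs])
    forces = None
    if all(c.forces is not None for c in configs):
        forces = np.concatenate([c.forces for c in configs])
    return ConfigurationBatch(
        positions=np.concatenate([c.positions for c in configs]),
        species=np.concatenate([c.species for c in configs]),
        graph_index=graph_index,
        n_per_graph=n_per,
        energies=energies,
        forces=forces,
        configs=list(configs),
    )


def _perpendicular_widths(cell: np.ndarray) -> np.ndarray:
    """Distance between opposite cell faces along each lattice direction."""
    volume = abs(np.linalg.det(cell))
    widths = np.empty(3)
    for ax in range(3):
        b, c = cell[(ax + 1) % 3], cell[(ax + 2) % 3]
        widths[ax] = volume / np.linalg.norm(np.cross(b, c))
    return widths


def _neighbor_pairs_celllist(pos: np.ndarray, cutoff: float):
    """All (i, j), i != j, with |r_ij| <= cutoff, via spatial binning."""
    n = len(pos)
    lo = pos.min(axis=0)
    bins = np.maximum(1, np.floor((pos.max(axis=0) - lo) / cutoff).astype(int) + 1)
    cell_of = np.minimum((pos - lo) // cutoff, bins - 1).astype(int)
    key = (cell_of[:, 0] * bins[1] + cell_of[:, 1]) * bins[2] + cell_of[:, 2]
    buckets: dict[int, list] = {}
    for i, k in enumerate(key):
        buckets.setdefault(int(k), []).append(i)
    senders, receivers = [], []
    shifts = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    cutoff2 = cutoff * cutoff
    for i in range(n):
        cx, cy, cz = cell_of[i]
        for dx, dy, dz in shifts:
            nx, ny, nz = cx + dx, cy + dy, cz + dz
            if not (0 <= nx < bins[0] and 0 <= ny < bins[1] and 0 <= nz < bins[2]):
                continue
            for j in buckets.get(int((nx * bins[1] + ny) * bins[2] + nz), ()):
                if j == i:
                    continue
                d = pos[i] - pos[j]
                if d @ d <= cutoff2:
                    senders.append(j)
                    receivers.append(i)
    return np.asarray(senders, dtype=np.int64), np.asarray(receivers, dtype=np.int64)


def build_neighbor_list(config: AtomicConfiguration, cutoff: float) -> NeighborGraph:
    """Directed edges for all atom pairs within ``cutoff`` Å.

    Periodic axes use the minimum-image convention; the cutoff must not
    exceed half the smallest perpendicular cell width on any periodic axis.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if not np.all(np.isfinite(config.positions)):
        raise ValueError("non-finite atomic positions")
    pos = config.positions.astype(np.float64)
    n = len(pos)
    periodic = config.pbc is not None and config.pbc.any()

    if periodic:
        widths = _perpendicular_widths(config.cell)
        for ax in range(3):
            if config.pbc[ax] and cutoff > 0.5 * widths[ax] + 1e-12:
                raise ValueError(
                    f"cutoff {cutoff} Å exceeds half the perpendicular cell width "
                    f"({widths[ax]:.6g} Å) along periodic axis {ax}"
                )
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = ii != jj
        ii, jj = ii[mask], jj[mask]
        delta = pos[ii] - pos[jj]  # sender - receiver
        frac = np.linalg.solve(config.cell.T, delta.T).T
        wrap = np.where(config.pbc, np.round(frac), 0.0)
        frac_mic = frac - wrap
        disp = frac_mic @ config.cell
        dist = np.linalg.norm(disp, axis=1)
        keep = dist <= cutoff
        senders, receivers = ii[keep], jj[keep]
        disp, dist = disp[keep], dist[keep]
        offsets = disp - (pos[senders] - pos[receivers])
    else:
        senders, receivers = _neighbor_pairs_celllist(pos, cutoff)
        disp = pos[senders] - pos[receivers]
        dist = np.linalg.norm(disp, axis=1)
        offsets = np.zeros_like(disp)

    if len(dist) and dist.min() < 1e-12:
        raise ValueError("coincident atoms within cutoff (zero pair distance)")
    return NeighborGraph(
        senders=senders,
        receivers=receivers,
        distances=dist,
        displacements=disp,
        cutoff=float(cutoff),
        offsets=offsets,
    )
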