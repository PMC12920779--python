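"""Synthetic systems with closed-form energies and forces.

Three generators emulate the canonical long-range benchmark settings at desk
scale, so that training and extrapolation experiments need no external data:

* rigid fragment dimers (apolar / polar / charged) at 4–15 Å separation,
  with a train/extrapolation split by distance — the charged pair carries a
  ±1 e Coulomb tail (−k_e/r) that no 5 Å-cutoff message-passing model can
  see at test separations;
* a rock-salt-like ionic cluster with one corner ion displaced outward,
  whose energy profile has a 1/d Coulomb tail;
* a random Lennard-Jones gas at fixed density, used for scaling studies.

All energies are kcal/mol, positions Å, forces kcal/mol/Å. The Coulomb
constant is k_e = 332.0637 kcal·Å/(mol·e²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import AtomicConfiguration

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)


@dataclass
class FragmentSpec:
    """A rigid fragment: fixed internal geometry, charges, and LJ parameters."""

    local_positions: np.ndarray   # (n, 3) Å, arbitrary internal frame
    species: np.ndarray
    charges: np.ndarray           # per-atom partial charges, e
    lj_epsilon: float = 0.05      # kcal/mol
    lj_sigma: float = 2.0         # Å
    label: str = ""

    def __post_init__(self):
        self.local_positions = np.asarray(self.local_positions, dtype=np.float64)
        self.species = np.asarray(self.species, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.local_positions = self.local_positions - self.local_positions.mean(axis=0)
        if abs(self.net_charge) > 2 + 1e-9:
            raise ValueError("fragment net charge must be within ±2 e")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def n_atoms(self) -> int:
        return len(self.species)


def _pyramid(edge: float = 2.0, height: float = 1.5) -> np.ndarray:
    """5-atom square pyramid: 4 base corners + apex."""
    a = edge / 2.0
    return np.array(
        [[a, a, 0.0], [-a, a, 0.0], [-a, -a, 0.0], [a, -a, 0.0], [0.0, 0.0, height]]
    )


def default_fragments() -> dict:
    """The three fragment classes: (A)polar, (P)olar, (C)harged ±1 e."""
    geom = _pyramid()
    return {
        "A": FragmentSpec(geom, [6, 6, 6, 6, 6], np.zeros(5), label="apolar"),
        "P": FragmentSpec(geom, [6, 6, 6, 6, 7],
                          np.array([-0.075, -0.075, -0.075, -0.075, 0.3]),
                          label="polar"),
        "C+": FragmentSpec(geom, [6, 6, 6, 6, 11], np.full(5, 0.2), label="cation"),
        "C-": FragmentSpec(geom, [6, 6, 6, 6, 17], np.full(5, -0.2), label="anion"),
    }


@dataclass
class DimerFrame:
    """One placed dimer: configuration plus its nominal separation and class."""

    config: AtomicConfiguration
    separation: float
    class_label: str


def analytic_energy_forces(positions: np.ndarray, charges: np.ndarray,
                           lj_epsilon: np.ndarray, lj_sigma: np.ndarray,
                           exclude_pairs=None):
    """Pairwise LJ + Coulomb energy and its exact analytic gradient.

    E = Σ_{i<j} 4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶] + Σ_{i<j} k_e q_i q_j / r_ij

    with Lorentz–Berthelot combination (arithmetic σ, geometric ε) from the
    per-atom parameters. The force sum is exactly zero (Newton's third law).
    """
    pos = np.asarray(positions, dtype=np.float64)
    n = len(pos)
    q = np.asarray(charges, dtype=np.float64)
    eps = np.asarray(lj_epsilon, dtype=np.float64) * np.ones(n)
    sig = np.asarray(lj_sigma, dtype=np.float64) * np.ones(n)

    ii, jj = np.triu_indices(n, k=1)
    if exclude_pairs:
        excl = set(map(tuple, exclude_pairs))
        keep = np.array([(int(a), int(b)) not in excl and (int(b), int(a)) not in excl
                         for a, b in zip(ii, jj)])
        ii, jj = ii[keep], jj[keep]
    d = pos[ii] - pos[jj]
    r = np.linalg.norm(d, axis=1)
    if len(r) and r.min() < 0.1:
        raise ValueError(f"unphysical overlap: pair distance {r.min():.4f} Å < 0.1 Å")

    sij = 0.5 * (sig[ii] + sig[jj])
    eij = np.sqrt(eps[ii] * eps[jj])
    sr6 = (sij / r) ** 6
    e_lj = 4.0 * eij * (sr6 * sr6 - sr6)
    e_coul = COULOMB_CONSTANT * q[ii] * q[jj] / r
    energy = float(e_lj.sum() + e_coul.sum())

    # dE/dr per pair; force on i is -(dE/dr) * (r_i - r_j)/r
    dEdr = 4.0 * eij * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r - e_coul / r
    fpair = -(dEdr / r)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, fpair)
    np.add.at(forces, jj, -fpair)
    return energy, forces


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    u = rng.normal(size=4)
    w, x, y, z = u / np.linalg.norm(u)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_dimer_frame(spec_a: FragmentSpec, spec_b: FragmentSpec, separation: float,
                     rng: np.random.Generator, jitter: float = 0.05,
                     class_label: str = "") -> DimerFrame:
    """Place two rigidly rotated fragments at a center–center separation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    pa = spec_a.local_positions @ _random_rotation(rng).T - 0.5 * separation * axis
    pb = spec_b.local_positions @ _random_rotation(rng).T + 0.5 * separation * axis
    pos = np.concatenate([pa, pb])
    if jitter > 0:
        pos = pos + rng.normal(0.0, jitter, pos.shape)
    charges = np.concatenate([spec_a.charges, spec_b.charges])
    eps = np.concatenate([np.full(spec_a.n_atoms, spec_a.lj_epsilon),
                          np.full(spec_b.n_atoms, spec_b.lj_epsilon)])
    sig = np.concatenate([np.full(spec_a.n_atoms, spec_a.lj_sigma),
                          np.full(spec_b.n_atoms, spec_b.lj_sigma)])
    energy, forces = analytic_energy_forces(pos, charges, eps, sig)
    cfg = AtomicConfiguration(
        positions=pos,
        species=np.concatenate([spec_a.species, spec_b.species]),
        energy=energy,
        forces=forces,
        tags={"separation": f"{separation:.6f}", "class": class_label},
    )
    return DimerFrame(config=cfg, separation=float(separation), class_label=class_label)


def gen_dimer_dataset(n_frames: int, seed: int, specs=None,
                      r_min: float = 4.0, r_max: float = 15.0,
                      r_split: float = 9.0, jitter: float = 0.05,
                      class_label: str = "CC"):
    """Random-orientation dimers with a train/extrapolation split by distance.

    Frames with separation ≤ r_split form the training set; the remainder —
    separations the local message passing cannot bridge — form the test set.
    Returns (frames, train_indices, test_indices), deterministic under seed.
    """
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    if not (r_min < r_split < r_max):
        raise ValueError("require r_min < r_split < r_max")
    if specs is None:
        lib = default_fragments()
        pairs = {"CC": (lib["C+"], lib["C-"]), "AA": (lib["A"], lib["A"]),
                 "PP": (lib["P"], lib["P"])}
        specs = pairs[class_label]
    spec_a, spec_b = specs
    rng = np.random.default_rng(seed)
    seps = rng.uniform(r_min, r_max, n_frames)
    frames = [
        make_dimer_frame(spec_a, spec_b, s, rng, jitter=jitter, class_label=class_label)
        for s in seps
    ]
    train_idx = np.where(seps <= r_split)[0]
    test_idx = np.where(seps > r_split)[0]
    return frames, train_idx, test_idx


def interaction_energy(frame: DimerFrame, spec_a: FragmentSpec, spec_b: FragmentSpec) -> float:
    """E(dimer) − E(fragment A alone) − E(fragment B alone) for this geometry."""
    pos = frame.config.positions
    na = spec_a.n_atoms
    ea, _ = analytic_energy_forces(pos[:na], spec_a.charges,
                                   spec_a.lj_epsilon, spec_a.lj_sigma)
    eb, _ = analytic_energy_forces(pos[na:], spec_b.charges,
                                   spec_b.lj_epsilon, spec_b.lj_sigma)
    return frame.config.energy - ea - eb


# -- displaced-ion lattice ---------------------------------------------------


@dataclass
class LatticeScan:
    frames: list
    displacements: np.ndarray
    energies: np.ndarray


def _lattice_energy_forces(pos, charges, born_a, born_rho):
    """Coulomb + Born–Mayer repulsion A·exp(−r/ρ) over all pairs."""
    n = len(pos)
    ii, jj = np.triu_indices(n, k=1)
    d = pos[ii] - pos[jj]
    r = np.linalg.norm(d, axis=1)
    if r.min() < 0.1:
        raise ValueError("overlapping ions")
    e_rep = born_a * np.exp(-r / born_rho)
    e_coul = COULOMB_CONSTANT * charges[ii] * charges[jj] / r
    energy = float(e_rep.sum() + e_coul.sum())
    dEdr = -e_rep / born_rho - e_coul / r
    fpair = -(dEdr / r)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, fpair)
    np.add.at(forces, jj, -fpair)
    return energy, forces


def gen_displaced_ion_lattice(n_cells: int = 4, displacement_range=(0.0, 10.0),
                              n_frames: int = 40, seed: int = 0,
                              spacing: float = 2.82,
                              born_a: float = 30000.0, born_rho: float = 0.317):
    """Rock-salt-like cubic cluster of alternating ±1 e ions; one corner ion
    is displaced outward along the body diagonal by d.

    Returns a :class:`LatticeScan` over an even grid of displacements with
    analytic references. For an even cluster (net neutral), the remainder
    left behind carries the opposite charge of the displaced ion, so
    E(d) − E(∞) has a 1/d Coulomb tail.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells per axis")
    grid = np.arange(n_cells)
    sites = np.array([[i, j, k] for i in grid for j in grid for k in grid], dtype=float)
    charges = np.array([(-1.0) ** (i + j + k) for i in grid for j in grid for k in grid])
    base = sites * spacing
    corner = 0  # ion at the origin corner, charge +1
    diag = np.array([-1.0, -1.0, -1.0]) / np.sqrt(3.0)  # outward

    ds = np.linspace(displacement_range[0], displacement_range[1], n_frames)
    frames, energies = [], []
    species = np.where(charges > 0, 11, 17)  # Na/Cl for presentation
    for d in ds:
        pos = base.copy()
        pos[corner] = pos[corner] + d * diag
        e, f = _lattice_energy_forces(pos, charges, born_a, born_rho)
        frames.append(
            AtomicConfiguration(positions=pos, species=species, energy=e, forces=f,
                                tags={"displacement": f"{d:.6f}"})
        )
        energies.append(e)
    return LatticeScan(frames=frames, displacements=ds, energies=np.array(energies))


# -- scaling gas -------------------------------------------------------------


def gen_scaling_gas(n_atoms: int, density: float = 0.008, seed: int = 0,
                    sigma: float = 2.5, species: int = 18,
                    periodic: bool = True) -> AtomicConfiguration:
    """Random LJ gas in a cube at the given number density (atoms/Å³).

    Points are drawn by rejection sampling with minimum inter-atom distance
    0.8σ; used for timing and operation-count scaling only. The box is
    periodic by default so that edge counts reflect bulk density rather
    than an N-dependent surface deficit.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    box = (n_atoms / density) ** (1.0 / 3.0)
    dmin = 0.8 * sigma
    cell = max(dmin, 1e-6)
    accepted = np.empty((0, 3))
    grid: dict[tuple, list] = {}
    rejections = 0
    while len(accepted) < n_atoms:
        p = rng.uniform(0.0, box, 3)
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.linalg.norm(p - q) < dmin:
                            ok = False
        if ok:
            grid.setdefault(key, []).append(p)
            accepted = np.vstack([accepted, p])
        else:
            rejections += 1
            if rejections > 10_000 * n_atoms:
                raise RuntimeError(
                    f"density {density} infeasible: rejection sampling stalled"
                )
    return AtomicConfiguration(
        positions=accepted,
        species=np.full(n_atoms, species),
        cell=np.eye(3) * box if periodic else None,
        pbc=np.array([True] * 3) if periodic else None,
        tags={"density": f"{density}", "box": f"{box:.6f}"},
    )


def write_split_files(prefix, train_idx, test_idx):
    """Frame-index split files, one index per line."""
    for name, idx in (("train", train_idx), ("test", test_idx)):
        with open(f"{prefix}.{name}.idx", "w") as fh:
            fh.write("\n".join(str(int(i)) for i in idx) + "\n")
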