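"""System setup for the coarse-grained simulator.

One bead per residue; consecutive beads of a chain are bonded at r0.
Single-chain systems are placed as self-avoiding random walks in a cubic
box; slab systems pack many chains into the central third of an elongated
(z-long) box so that a condensed layer can equilibrate against vapor-like
dilute regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..sequence import ProteinSequence
from ..trajectory import Topology
from . import params as P


class PackingError(RuntimeError):
    """Raised when an initial configuration cannot be packed."""


@dataclass
class SimulationConfig:
    """Run protocol: thermostat, timestep, box, steps, seed.

    Defaults follow the reference slab protocol for this model family: 10 fs
    timestep and a Langevin damping time of 1000 ps (per-bead friction
    gamma_i = m_i / t_damp), at an ionic strength of 100 mM.
    """

    temperature_K: float = 300.0
    timestep_fs: float = 10.0
    t_damp_ps: float = 1000.0
    box_nm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    n_chains: int = 1
    n_steps: int = 100_000
    save_interval: int = 1000
    seed: int = 0
    ionic_strength_mM: float = 100.0

    def __post_init__(self) -> None:
        if min(self.temperature_K, self.timestep_fs, self.t_damp_ps) <= 0:
            raise ValueError("temperature, timestep and t_damp must be positive")
        if min(self.box_nm) <= 0:
            raise ValueError("box lengths must be positive")
        if self.n_steps <= 0 or self.save_interval <= 0:
            raise ValueError("n_steps and save_interval must be positive")

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * 1e-3


@dataclass
class CGTopology:
    """Bead-per-residue topology with per-bead force-field parameters."""

    residues: str                 # concatenated residue codes, all chains
    chain_id: np.ndarray          # (n_beads,)
    mass: np.ndarray              # amu
    charge: np.ndarray            # e
    lam: np.ndarray               # hydropathy, dimensionless
    sigma: np.ndarray             # nm
    bonds: np.ndarray             # (n_bonds, 2) bead indices
    bond_r0: float = P.BOND_R0_NM
    bond_k: float = P.BOND_K

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if np.any(self.mass <= 0) or np.any(self.sigma <= 0):
            raise ValueError("masses and diameters must be positive")
        for i, j in self.bonds:
            if self.chain_id[i] != self.chain_id[j] or abs(i - j) != 1:
                raise ValueError("bonds must connect consecutive beads of one chain")

    @property
    def n_beads(self) -> int:
        return len(self.residues)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1

    @property
    def chain_length(self) -> int:
        return int(np.sum(self.chain_id == 0))

    def net_charge(self) -> float:
        return float(self.charge.sum())

    def to_topology(self) -> Topology:
        """Analysis-side Topology: one CA-style heavy atom per residue."""
        n = self.n_beads
        return Topology(
            atom_names=["CA"] * n,
            residue_index=np.arange(n),
            residue_codes=list(self.residues),
            chain_of_residue=self.chain_id.copy(),
            masses=self.mass.copy(),
            heavy=np.ones(n, dtype=bool),
            bonds=self.bonds.copy(),
        )


def _chain_topology(seq: ProteinSequence, n_chains: int) -> CGTopology:
    mass, charge, sigma, lam = P.bead_parameters(seq.residues)
    n = len(seq.residues)
    bonds = []
    for c in range(n_chains):
        off = c * n
        bonds.extend((off + i, off + i + 1) for i in range(n - 1))
    return CGTopology(
        residues=seq.residues * n_chains,
        chain_id=np.repeat(np.arange(n_chains), n),
        mass=np.tile(mass, n_chains),
        charge=np.tile(charge, n_chains),
        lam=np.tile(lam, n_chains),
        sigma=np.tile(sigma, n_chains),
        bonds=np.array(bonds),
    )


def _random_walk_chain(rng: np.random.Generator, n: int, r0: float,
                       start: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                       existing: np.ndarray | None, tol: float,
                       max_attempts: int = 2000) -> np.ndarray:
    """Grow one chain as a random walk with clash rejection (distance < tol)."""
    for _ in range(max_attempts):
        pos = np.empty((n, 3))
        pos[0] = start
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(50):
                v = rng.normal(size=3)
                v *= r0 / np.linalg.norm(v)
                cand = pos[i - 1] + v
                if np.any(cand < lo) or np.any(cand > hi):
                    continue
                d2 = np.sum((pos[:max(0, i - 1)] - cand) ** 2, axis=1)
                if d2.size and d2.min() < tol * tol:
                    continue
                if existing is not None and existing.size:
                    d2e = np.sum((existing - cand) ** 2, axis=1)
                    if d2e.min() < tol * tol:
                        continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise PackingError("could not place chain without overlaps")


def build_single_chain(seq: ProteinSequence, cfg: SimulationConfig,
                       ) -> tuple[CGTopology, np.ndarray]:
    """One self-avoiding chain started at the box center."""
    top = _chain_topology(seq, 1)
    box = np.asarray(cfg.box_nm)
    n = top.n_beads
    # a fully extended chain must fit the box diagonal
    if (n - 1) * top.bond_r0 > np.linalg.norm(box) * 4:
        raise PackingError("box too small for chain")
    rng = np.random.default_rng(cfg.seed)
    # keep the walk loosely inside the box around the center
    lo = box * 0.5 - box * 0.45
    hi = box * 0.5 + box * 0.45
    pos = _random_walk_chain(rng, n, top.bond_r0, box * 0.5, lo, hi, None, 0.35)
    return top, pos


def build_slab(seq: ProteinSequence, n_chains: int, cfg: SimulationConfig,
               overlap_tol: float = 0.35, max_retries: int = 50,
               central_fraction: float = 1.0 / 3.0, n_dilute: int = 0,
               ) -> tuple[CGTopology, np.ndarray]:
    """Pack n_chains into a central z-region of an elongated box.

    ``central_fraction`` is the fraction of the z-length used for initial
    placement (default: the central third).  A tighter initial layer
    condenses faster and sheds fewer satellite droplets in short
    desk-scale runs.  ``n_dilute`` of the chains (none by default) are
    placed in the outer region instead: seeding a small vapor lets short
    runs approach the coexistence densities from both directions
    (condensation of seeded chains vs evaporation from the layer) rather
    than waiting for rare evaporation events.
    """
    if n_chains < 2:
        raise ValueError("a slab needs at least 2 chains")
    if not 0 <= n_dilute < n_chains:
        raise ValueError("n_dilute must leave at least one chain in the layer")
    top = _chain_topology(seq, n_chains)
    box = np.asarray(cfg.box_nm)
    n = len(seq.residues)
    rng = np.random.default_rng(cfg.seed)
    half = 0.5 * central_fraction * box[2]
    lo = np.array([0.05 * box[0], 0.05 * box[1], box[2] / 2 - half])
    hi = np.array([0.95 * box[0], 0.95 * box[1], box[2] / 2 + half])
    # vapor chains go in the outer quarter on either side of the layer
    lo_gas = np.array([0.05 * box[0], 0.05 * box[1], 0.02 * box[2]])
    hi_gas = np.array([0.95 * box[0], 0.95 * box[1], 0.25 * box[2]])
    for _ in range(max_retries):
        coords: list[np.ndarray] = []
        try:
            for c in range(n_chains):
                gas = c >= n_chains - n_dilute
                if gas:
                    l, h = lo_gas.copy(), hi_gas.copy()
                    if (c - (n_chains - n_dilute)) % 2:  # alternate sides
                        l[2] = box[2] - hi_gas[2]
                        h[2] = box[2] - lo_gas[2]
                else:
                    l, h = lo, hi
                existing = np.concatenate(coords) if coords else np.empty((0, 3))
                start = l + rng.random(3) * (h - l)
                d2 = np.sum((existing - start) ** 2, axis=1) if existing.size else None
                if d2 is not None and d2.size and d2.min() < overlap_tol ** 2:
                    raise PackingError("seed bead clash")
                coords.append(_random_walk_chain(
                    rng, n, top.bond_r0, start, l, h, existing, overlap_tol))
        except PackingError:
            continue
        return top, np.concatenate(coords)
    raise PackingError(f"slab packing failed after {max_retries} retries")
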