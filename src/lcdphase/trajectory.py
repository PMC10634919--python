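"""Shared trajectory container.

A :class:`Trajectory` holds time-ordered coordinates (nm) with box vectors
and a :class:`Topology` labelling chain / residue / heavy-atom / amide-vector
membership.  It serves both the built-in coarse-grained simulator (one bead
per residue) and externally produced all-atom trajectories read through
mdtraj (PDB topology + DCD/XTC frames).

Coordinates produced by the built-in engine are stored *unwrapped*: periodic
boundaries enter only through minimum-image distances, so intra-chain
geometry (Rg, inter-residue distances) needs no unwrapping step.  Wrapped
input is detected by the analysis routines via bonds longer than half the
box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class Topology:
    """Per-atom labelling: names, residue membership, chains, masses."""

    atom_names: list[str]
    residue_index: np.ndarray          # (n_atoms,) -> residue ordinal
    residue_codes: list[str]           # (n_residues,) one-letter codes
    chain_of_residue: np.ndarray       # (n_residues,) -> chain ordinal
    masses: np.ndarray                 # (n_atoms,) amu
    heavy: np.ndarray                  # (n_atoms,) bool
    residue_numbers: np.ndarray | None = None  # residue numbering (start offset)
    bonds: np.ndarray | None = None    # (n_bonds, 2) atom indices

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.chain_of_residue = np.asarray(self.chain_of_residue, dtype=np.int64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.heavy = np.asarray(self.heavy, dtype=bool)
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, len(self.residue_codes) + 1)
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_codes)

    @property
    def n_chains(self) -> int:
        return int(self.chain_of_residue.max()) + 1

    @property
    def chain_of_atom(self) -> np.ndarray:
        return self.chain_of_residue[self.residue_index]

    def atoms_of_residue(self, res: int) -> np.ndarray:
        return np.nonzero(self.residue_index == res)[0]

    def atoms_of_chain(self, chain: int) -> np.ndarray:
        return np.nonzero(self.chain_of_atom == chain)[0]

    def amide_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Residues carrying a backbone amide N-H pair.

        Returns (residue ordinals, N atom indices, H atom indices).  Residues
        lacking either atom (e.g. the first residue or prolines in all-atom
        topologies, or any CG bead) are simply absent from the result.
        """
        res, n_idx, h_idx = [], [], []
        names = np.array(self.atom_names)
        for r in range(self.n_residues):
            atoms = self.atoms_of_residue(r)
            sel_n = atoms[names[atoms] == "N"]
            sel_h = atoms[(names[atoms] == "H") | (names[atoms] == "HN")]
            if len(sel_n) == 1 and len(sel_h) == 1:
                res.append(r)
                n_idx.append(sel_n[0])
                h_idx.append(sel_h[0])
        return (np.array(res, dtype=int), np.array(n_idx, dtype=int),
                np.array(h_idx, dtype=int))


@dataclass
class Trajectory:
    """Time-ordered frames of particle coordinates with box and topology."""

    topology: Topology
    xyz: np.ndarray                 # (n_frames, n_atoms, 3) nm
    time: np.ndarray                # (n_frames,) ps, strictly increasing
    box: np.ndarray | None = None   # (n_frames, 3) nm (orthorhombic)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate/topology atom-count mismatch")
        if len(self.time) != self.xyz.shape[0]:
            raise ValueError("time length must match frame count")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def __getitem__(self, key) -> "Trajectory":
        if isinstance(key, int):
            key = slice(key, key + 1)
        return Trajectory(
            self.topology,
            self.xyz[key],
            self.time[key],
            None if self.box is None else self.box[key],
        )

    def timestep_ps(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a timestep")
        return float(self.time[1] - self.time[0])

    # ------------------------------------------------------------------ I/O

    def to_mdtraj(self):
        """Convert to an ``mdtraj.Trajectory`` (CA-style records for beads)."""
        import mdtraj as md

        top = md.Topology()
        chains: dict[int, object] = {}
        residues: dict[int, object] = {}
        topo = self.topology
        for r in range(topo.n_residues):
            c = int(topo.chain_of_residue[r])
            if c not in chains:
                chains[c] = top.add_chain()
            residues[r] = top.add_residue(
                _one_to_three(topo.residue_codes[r]), chains[c],
                resSeq=int(topo.residue_numbers[r]))
        for a in range(topo.n_atoms):
            name = topo.atom_names[a]
            element = md.element.carbon if name.startswith("C") else (
                md.element.nitrogen if name.startswith("N") else (
                    md.element.hydrogen if name.startswith("H")
                    else md.element.carbon))
            top.add_atom(name, element, residues[int(topo.residue_index[a])])
        unitcell = None if self.box is None else self.box
        t = md.Trajectory(self.xyz.copy(), top, time=self.time.copy())
        if unitcell is not None:
            t.unitcell_lengths = unitcell.copy()
            t.unitcell_angles = np.full((self.n_frames, 3), 90.0)
        return t

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.pdb`` (topology + first frame) and ``<prefix>.dcd``."""
        prefix = Path(prefix)
        t = self.to_mdtraj()
        pdb = prefix.with_suffix(".pdb")
        dcd = prefix.with_suffix(".dcd")
        t[0].save_pdb(str(pdb))
        t.save_dcd(str(dcd))
        return pdb, dcd

    @classmethod
    def load(cls, topology_file: str | Path, trajectory_file: str | Path | None = None,
             ) -> "Trajectory":
        """Read a trajectory through mdtraj (PDB topology + DCD/XTC frames)."""
        import mdtraj as md

        if trajectory_file is None:
            t = md.load(str(topology_file))
        else:
            t = md.load(str(trajectory_file), top=str(topology_file))
        return cls.from_mdtraj(t)

    @classmethod
    def from_mdtraj(cls, t) -> "Trajectory":
        top = t.topology
        residue_codes, chain_of_residue, residue_numbers = [], [], []
        for res in top.residues:
            residue_codes.append(_three_to_one(res.name))
            chain_of_residue.append(res.chain.index)
            residue_numbers.append(res.resSeq)
        atom_names, residue_index, masses, heavy = [], [], [], []
        for atom in top.atoms:
            atom_names.append(atom.name)
            residue_index.append(atom.residue.index)
            masses.append(atom.element.mass if atom.element is not None else 12.0)
            heavy.append(atom.element is None or atom.element.symbol != "H")
        topo = Topology(atom_names, np.array(residue_index), residue_codes,
                        np.array(chain_of_residue), np.array(masses),
                        np.array(heavy), np.array(residue_numbers))
        time = np.asarray(t.time, dtype=float)
        if len(time) > 1 and np.any(np.diff(time) <= 0):
            time = np.arange(len(time), dtype=float)
        box = None if t.unitcell_lengths is None else np.asarray(t.unitcell_lengths)
        return cls(topo, np.asarray(t.xyz, dtype=float), time, box)


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_ONE = {v: k for k, v in _THREE.items()}


def _one_to_three(code: str) -> str:
    return _THREE.get(code, "UNK")


def _three_to_one(name: str) -> str:
    return _ONE.get(name.upper(), "G")


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return disp - box * np.round(disp / box)
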