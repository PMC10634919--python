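"""Shared fixtures: sequences and small deterministic trajectories."""

from pathlib import Path

import numpy as np
import pytest

from lcdphase.sequence import ProteinSequence, read_fasta
from lcdphase.trajectory import Topology, Trajectory

DATA_DIR = Path(__file__).resolve().parent.parent / "examples" / "data"

# model sequences used by the scaled-down simulation tests: a sticky
# tyrosine-rich 30-mer and a variant with two thirds of its tyrosines
# mutated to serine -- like the multi-YS constructs that essentially
# abolish phase separation, it gives an unambiguous Csat contrast at
# desk-scale sampling
STICKY_30MER = "YYS" * 10
WEAKENED_30MER = "YSS" * 10


@pytest.fixture(scope="session")
def ews_lcd() -> ProteinSequence:
    return read_fasta(DATA_DIR / "ews_lcd.fasta")[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def bead_trajectory(xyz: np.ndarray, codes=None, chain_of_residue=None,
                    box=None, masses=None, time=None) -> Trajectory:
    """Build a one-heavy-atom-per-residue trajectory from raw coordinates."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    n = xyz.shape[1]
    codes = list(codes) if codes is not None else ["G"] * n
    chain = (np.asarray(chain_of_residue) if chain_of_residue is not None
             else np.zeros(n, dtype=int))
    masses = (np.asarray(masses, dtype=float) if masses is not None
              else np.full(n, 100.0))
    bonds = np.array([(i, i + 1) for i in range(n - 1)
                      if chain[i] == chain[i + 1]]).reshape(-1, 2)
    topo = Topology(["CA"] * n, np.arange(n), codes, chain, masses,
                    np.ones(n, dtype=bool), bonds=bonds)
    t = np.arange(xyz.shape[0], dtype=float) if time is None else time
    if box is not None:
        box = np.tile(np.asarray(box, dtype=float), (xyz.shape[0], 1))
    return Trajectory(topo, xyz, t, box)
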