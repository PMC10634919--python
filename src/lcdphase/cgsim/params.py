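"""One-bead-per-residue force-field parameters (HPS-Urry style).

All model constants live here so they can be edited in one place: residue
masses (amu), net charges at neutral pH (e), van der Waals diameters sigma
(nm), and the Urry-scale hydropathies lambda in [0, 1] that scale the
attractive part of the Ashbaugh-Hatch pair potential.  Bonded terms are a
stiff harmonic spring between consecutive beads (r0 = 0.38 nm,
k = 8368 kJ mol^-1 nm^-2); electrostatics are Debye-Hueckel screened Coulomb
with relative permittivity 80 and a screening length set by ionic strength.
"""

from __future__ import annotations

import numpy as np

# Boltzmann constant, kJ mol^-1 K^-1 (MD units: kJ/mol, nm, ps, amu)
KB = 0.0083144621

# Coulomb constant e^2 N_A / (4 pi eps0), kJ mol^-1 nm
COULOMB_KJ_NM = 138.935458

# pair interaction strength of the short-range term, kJ/mol (0.2 kcal/mol)
EPSILON_HPS = 0.8368

# harmonic bond between consecutive beads
BOND_R0_NM = 0.38
BOND_K = 8368.0  # kJ mol^-1 nm^-2

# interaction cutoffs, nm
CUTOFF_HPS_NM = 2.0
CUTOFF_DH_NM = 3.5

# solvent relative permittivity for screened electrostatics
EPSILON_R = 80.0

MASS_AMU = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "Q": 128.1307, "E": 129.1155, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

CHARGE_E = {
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0, "E": -1.0,
    "G": 0.0, "H": 0.0, "I": 0.0, "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0,
    "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
}

SIGMA_NM = {
    "A": 0.504, "R": 0.656, "N": 0.568, "D": 0.558, "C": 0.548, "Q": 0.602,
    "E": 0.592, "G": 0.450, "H": 0.608, "I": 0.618, "L": 0.618, "K": 0.636,
    "M": 0.618, "F": 0.636, "P": 0.556, "S": 0.518, "T": 0.562, "W": 0.678,
    "Y": 0.646, "V": 0.586,
}

# Urry hydropathy scale rescaled to [0, 1] (Trp = 1, Glu = 0); tyrosine sits
# near the top, which is what makes tyrosine-rich LCDs sticky in this model.
LAMBDA_URRY = {
    "A": 0.602942, "R": 0.558824, "N": 0.588236, "D": 0.294118, "C": 0.647059,
    "Q": 0.558824, "E": 0.000000, "G": 0.573529, "H": 0.764707, "I": 0.705883,
    "L": 0.720589, "K": 0.382354, "M": 0.676471, "F": 0.823530, "P": 0.758824,
    "S": 0.588236, "T": 0.588236, "W": 1.000000, "Y": 0.897059, "V": 0.664707,
}

def debye_kappa_per_nm(ionic_strength_mM: float, temperature_K: float) -> float:
    """Inverse Debye screening length (nm^-1) for a 1:1 electrolyte."""
    if ionic_strength_mM <= 0:
        return 0.0
    NA = 6.02214076e23
    e = 1.602176634e-19
    eps0 = 8.8541878128e-12
    kB_J = 1.380649e-23
    ionic_m3 = ionic_strength_mM * NA  # mM -> mol/m^3 -> particles/m^3
    kappa_m = np.sqrt(2.0 * ionic_m3 * e * e /
                      (eps0 * EPSILON_R * kB_J * temperature_K))
    return float(kappa_m * 1e-9)


def bead_parameters(residues: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-bead (mass, charge, sigma, lambda) arrays for a residue string."""
    try:
        mass = np.array([MASS_AMU[a] for a in residues])
        charge = np.array([CHARGE_E[a] for a in residues])
        sigma = np.array([SIGMA_NM[a] for a in residues])
        lam = np.array([LAMBDA_URRY[a] for a in residues])
    except KeyError as exc:  # pragma: no cover - message only
        raise KeyError(f"unknown residue code {exc}") from exc
    return mass, charge, sigma, lam
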