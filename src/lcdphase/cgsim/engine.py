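"""Langevin dynamics for the bead-per-residue model.

Forces are the hydropathy-scaled Ashbaugh-Hatch short-range potential plus
Debye-Hueckel screened electrostatics (see :mod:`.params`) and stiff
harmonic bonds.  Integration uses a BAOAB Langevin splitting with a uniform
velocity relaxation rate 1/t_damp, i.e. per-bead friction coefficient
gamma_i = m_i / t_damp.  Minimum-image periodic boundaries act in all three
dimensions; stored coordinates are left unwrapped.

The O(N^2) force loop is JIT-compiled with numba; at desk-scale system sizes
(a few hundred beads) this outruns any neighbor-list bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from ..trajectory import Trajectory
from . import params as P
from .model import CGTopology, SimulationConfig


class SimulationBlowupError(RuntimeError):
    """Numerical blow-up: a coordinate became non-finite."""


P_KB = P.KB  # module-level constant resolved by the JIT kernels


@njit(cache=True)
def _pair_energy_force(r2, sig, lam, qq, eps, cut_hps2, cut_dh2, kappa, coul):
    """Energy and dU/dr / r for one nonbonded pair at squared distance r2."""
    e = 0.0
    fr = 0.0  # -(dU/dr)/r
    if r2 < cut_hps2:
        sr2 = sig * sig / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        lj = 4.0 * eps * (sr12 - sr6)
        dlj = 24.0 * eps * (2.0 * sr12 - sr6) / r2  # -(dLJ/dr)/r
        rmin2 = sig * sig * 2.0 ** (1.0 / 3.0)
        if r2 <= rmin2:
            e += lj + (1.0 - lam) * eps
            fr += dlj
        else:
            e += lam * lj
            fr += lam * dlj
    if qq != 0.0 and r2 < cut_dh2:
        r = np.sqrt(r2)
        sc = coul * qq * np.exp(-kappa * r) / r
        e += sc
        fr += sc * (1.0 / r2 + kappa / r)  # = -(dU/dr)/r
    return e, fr


@njit(cache=True)
def _forces(pos, box, chain_id, sigma, lam, charge, bonds, r0, kbond,
            eps, cut_hps2, cut_dh2, kappa, coul, nonbonded, forces):
    n = pos.shape[0]
    forces[:] = 0.0
    pe = 0.0
    if nonbonded:
        cut2 = max(cut_hps2, cut_dh2)
        for i in range(n - 1):
            for j in range(i + 1, n):
                if j == i + 1 and chain_id[i] == chain_id[j]:
                    continue  # bonded 1-2 pairs are excluded from nonbonded terms
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= cut2 or r2 <= 1e-12:
                    continue
                sig = 0.5 * (sigma[i] + sigma[j])
                lm = 0.5 * (lam[i] + lam[j])
                qq = charge[i] * charge[j]
                e, fr = _pair_energy_force(r2, sig, lm, qq, eps, cut_hps2,
                                           cut_dh2, kappa, coul)
                pe += e
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * kbond * (r - r0) ** 2
        fmag = -kbond * (r - r0) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return pe


@njit(cache=True)
def _integrate(pos, vel, mass, box, chain_id, sigma, lam, charge, bonds,
               r0, kbond, eps, cut_hps2, cut_dh2, kappa, coul, nonbonded,
               dt, c1, kT, n_steps, save_interval, seed):
    n = pos.shape[0]
    n_saves = n_steps // save_interval
    frames = np.empty((n_saves, n, 3))
    temps = np.empty(n_saves)
    pes = np.empty(n_saves)
    np.random.seed(seed)
    forces = np.zeros((n, 3))
    c2 = np.sqrt((1.0 - c1 * c1) * kT / mass)
    pe = _forces(pos, box, chain_id, sigma, lam, charge, bonds, r0, kbond,
                 eps, cut_hps2, cut_dh2, kappa, coul, nonbonded, forces)
    k = 0
    status = 0
    for step in range(n_steps):
        for i in range(n):
            inv_m = dt * 0.5 / mass[i]
            vel[i, 0] += inv_m * forces[i, 0]
            vel[i, 1] += inv_m * forces[i, 1]
            vel[i, 2] += inv_m * forces[i, 2]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2[i] * np.random.standard_normal()
            vel[i, 1] = c1 * vel[i, 1] + c2[i] * np.random.standard_normal()
            vel[i, 2] = c1 * vel[i, 2] + c2[i] * np.random.standard_normal()
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        pe = _forces(pos, box, chain_id, sigma, lam, charge, bonds, r0, kbond,
                     eps, cut_hps2, cut_dh2, kappa, coul, nonbonded, forces)
        for i in range(n):
            inv_m = dt * 0.5 / mass[i]
            vel[i, 0] += inv_m * forces[i, 0]
            vel[i, 1] += inv_m * forces[i, 1]
            vel[i, 2] += inv_m * forces[i, 2]
        if (step + 1) % save_interval == 0:
            if not np.all(np.isfinite(pos)):
                status = 1
                break
            frames[k] = pos
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                       + vel[i, 2] ** 2)
            temps[k] = 2.0 * ke / (3.0 * n * P_KB)
            pes[k] = pe
            k += 1
    return frames[:k], temps[:k], pes[:k], status


@njit(cache=True)
def _minimize(pos, box, chain_id, sigma, lam, charge, bonds, r0, kbond,
              eps, cut_hps2, cut_dh2, kappa, coul, nonbonded,
              n_steps, max_disp):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = _forces(pos, box, chain_id, sigma, lam, charge, bonds, r0, kbond,
                 eps, cut_hps2, cut_dh2, kappa, coul, nonbonded, forces)
    step = 0.001
    for _ in range(n_steps):
        fmax = 0.0
        for i in range(n):
            for k in range(3):
                if abs(forces[i, k]) > fmax:
                    fmax = abs(forces[i, k])
        if fmax < 1.0:
            break
        scale = step
        if scale * fmax > max_disp:
            scale = max_disp / fmax
        trial = pos + scale * forces
        pe_new = _forces(trial, box, chain_id, sigma, lam, charge, bonds, r0,
                         kbond, eps, cut_hps2, cut_dh2, kappa, coul,
                         nonbonded, forces)
        if pe_new < pe:
            pos[:] = trial
            pe = pe_new
            step *= 1.2
        else:
            step *= 0.5
            pe = _forces(pos, box, chain_id, sigma, lam, charge, bonds, r0,
                         kbond, eps, cut_hps2, cut_dh2, kappa, coul,
                         nonbonded, forces)
    return pe


def minimize_energy(topology: CGTopology, coordinates: np.ndarray,
                    cfg: SimulationConfig, n_steps: int = 500,
                    max_displacement_nm: float = 0.02,
                    nonbonded: bool = True) -> np.ndarray:
    """Steepest-descent relaxation of an initial configuration.

    Removes steric overlaps left by random packing so short thermostatted
    runs start near thermal potential energies; returns new coordinates.
    """
    pos = np.array(coordinates, dtype=np.float64)
    kappa = P.debye_kappa_per_nm(cfg.ionic_strength_mM, cfg.temperature_K)
    box = np.asarray(cfg.box_nm, dtype=np.float64)
    _minimize(pos, box, topology.chain_id, topology.sigma.astype(np.float64),
              topology.lam.astype(np.float64),
              topology.charge.astype(np.float64), topology.bonds,
              topology.bond_r0, topology.bond_k, P.EPSILON_HPS,
              P.CUTOFF_HPS_NM ** 2, P.CUTOFF_DH_NM ** 2, kappa,
              P.COULOMB_KJ_NM / P.EPSILON_R, nonbonded, n_steps,
              max_displacement_nm)
    return pos


def pair_potential(res_i: str, res_j: str, r_nm: float,
                   cfg: SimulationConfig | None = None,
                   lam_override: float | None = None) -> float:
    """Nonbonded pair energy (kJ/mol) between two residue types at r_nm.

    Hydropathy-scaled Ashbaugh-Hatch short-range term plus Debye-Hueckel
    screened electrostatics; continuous in r and truncated at the model
    cutoffs.
    """
    if r_nm <= 0:
        raise ValueError("distance must be positive")
    cfg = cfg or SimulationConfig()
    for code in (res_i, res_j):
        if code not in P.SIGMA_NM:
            raise KeyError(f"unknown residue code {code!r}")
    sig = 0.5 * (P.SIGMA_NM[res_i] + P.SIGMA_NM[res_j])
    lam = 0.5 * (P.LAMBDA_URRY[res_i] + P.LAMBDA_URRY[res_j])
    if lam_override is not None:
        lam = lam_override
    qq = P.CHARGE_E[res_i] * P.CHARGE_E[res_j]
    kappa = P.debye_kappa_per_nm(cfg.ionic_strength_mM, cfg.temperature_K)
    e = 0.0
    if r_nm < P.CUTOFF_HPS_NM:
        sr6 = (sig / r_nm) ** 6
        lj = 4.0 * P.EPSILON_HPS * (sr6 * sr6 - sr6)
        if r_nm <= 2.0 ** (1.0 / 6.0) * sig:
            e += lj + (1.0 - lam) * P.EPSILON_HPS
        else:
            e += lam * lj
    if qq != 0.0 and r_nm < P.CUTOFF_DH_NM:
        e += P.COULOMB_KJ_NM / P.EPSILON_R * qq * np.exp(-kappa * r_nm) / r_nm
    return float(e)


def run_langevin(topology: CGTopology, coordinates: np.ndarray,
                 cfg: SimulationConfig, nonbonded: bool = True,
                 initial_velocities: np.ndarray | None = None,
                 ) -> tuple[Trajectory, pd.DataFrame]:
    """Integrate Langevin dynamics; returns (trajectory, energy log).

    The log holds time (ps), instantaneous kinetic temperature (K) and
    potential energy (kJ/mol) at each saved frame.  Identical inputs
    (including cfg.seed) give bitwise-identical output on one platform.
    """
    pos = np.array(coordinates, dtype=np.float64)
    if pos.shape != (topology.n_beads, 3):
        raise ValueError("coordinates must be (n_beads, 3)")
    if not np.all(np.isfinite(pos)):
        raise SimulationBlowupError("non-finite initial coordinates")
    rng = np.random.default_rng(cfg.seed)
    kT = P.KB * cfg.temperature_K
    if initial_velocities is None:
        vel = rng.normal(size=pos.shape) * np.sqrt(kT / topology.mass)[:, None]
    else:
        vel = np.array(initial_velocities, dtype=np.float64)
    dt = cfg.timestep_ps
    c1 = float(np.exp(-dt / cfg.t_damp_ps))
    kappa = P.debye_kappa_per_nm(cfg.ionic_strength_mM, cfg.temperature_K)
    box = np.asarray(cfg.box_nm, dtype=np.float64)
    frames, temps, pes, status = _integrate(
        pos, vel, topology.mass.astype(np.float64), box,
        topology.chain_id, topology.sigma.astype(np.float64),
        topology.lam.astype(np.float64), topology.charge.astype(np.float64),
        topology.bonds, topology.bond_r0, topology.bond_k,
        P.EPSILON_HPS, P.CUTOFF_HPS_NM ** 2, P.CUTOFF_DH_NM ** 2,
        kappa, P.COULOMB_KJ_NM / P.EPSILON_R, nonbonded,
        dt, c1, kT, cfg.n_steps, cfg.save_interval,
        int(cfg.seed) % (2 ** 31 - 1),
    )
    if status != 0:
        raise SimulationBlowupError(
            f"coordinates became non-finite after {len(frames)} saved frames; "
            "reduce the timestep or check the initial configuration")
    n_saves = len(frames)
    times = dt * cfg.save_interval * np.arange(1, n_saves + 1)
    traj = Trajectory(topology.to_topology(), frames, times,
                      box=np.tile(box, (n_saves, 1)))
    log = pd.DataFrame({"time_ps": times, "temperature_K": temps,
                        "potential_kJ_mol": pes})
    return traj, log
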