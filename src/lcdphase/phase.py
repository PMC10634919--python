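"""Slab-coexistence analysis: density profiles, Csat/Cdense, binodals.

A slab simulation equilibrates a condensed protein layer against dilute
vapor-like regions in an elongated (z-long) box, so both coexisting
concentrations can be read off the z-resolved density profile.  The dilute
branch is the saturation concentration Csat; lower Csat means stronger
phase-separation propensity.  Errors come from block averaging (4 blocks by
default); the binodal closes at a critical temperature Tc estimated from
the density gap with the 3D-Ising exponent beta = 0.325 and the law of
rectilinear diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .trajectory import Trajectory

AMU_PER_NM3_TO_MG_PER_ML = 1.66053906660

ISING_BETA_3D = 0.325


@dataclass
class DensityProfile:
    """z-resolved concentration in a slab, with per-block profiles."""

    z_nm: np.ndarray                    # bin centers
    conc_mg_ml: np.ndarray              # time-averaged concentration per bin
    block_profiles: np.ndarray          # (n_blocks, n_bins)
    n_frames: int
    cross_section_nm2: float
    box_z_nm: float
    chain_mass_amu: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.conc_mg_ml < -1e-9):
            raise ValueError("concentrations must be non-negative")

    @property
    def bin_width_nm(self) -> float:
        return float(self.z_nm[1] - self.z_nm[0])

    @property
    def total_mass_amu(self) -> float:
        """Mass implied by the profile: sum over bins of conc x bin volume."""
        bin_vol = self.cross_section_nm2 * self.bin_width_nm
        return float(self.conc_mg_ml.sum() * bin_vol / AMU_PER_NM3_TO_MG_PER_ML)

    @property
    def conc_mM(self) -> np.ndarray:
        """Molar view; requires the chain molecular mass."""
        if self.chain_mass_amu is None:
            raise ValueError("chain mass unknown; molar view unavailable")
        return self.conc_mg_ml / self.chain_mass_amu * 1e3  # mg/mL / (g/mol) * 1e3 = mM

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z_nm, "conc_mg_ml": self.conc_mg_ml})


@dataclass
class CoexistencePoint:
    """(Csat, Cdense) with SEMs at one temperature; possibly single-phase."""

    temperature_K: float
    c_dilute: float
    c_dense: float
    c_dilute_sem: float
    c_dense_sem: float
    interface_width_nm: float
    converged: bool
    single_phase: bool = False

    def __post_init__(self) -> None:
        if self.converged and not self.single_phase:
            if self.c_dilute > self.c_dense + 1e-9:
                raise ValueError("dilute branch must not exceed dense branch")


@dataclass
class PhaseDiagram:
    points: list[CoexistencePoint]
    tc_K: float | None = None
    critical_density: float | None = None
    beta: float = ISING_BETA_3D
    gap_amplitude: float | None = None


def center_slab(traj: Trajectory) -> Trajectory:
    """Translate each frame along z so the dense region sits at box center.

    Uses the mass-weighted circular mean of the z-coordinates (z treated as
    an angle around the periodic box), which is deterministic and, for a
    uniform system, arbitrary but stable.  Coordinates are shifted, never
    wrapped, so chain continuity is preserved; applying the operation twice
    equals applying it once modulo the box, up to a bin.
    """
    if traj.box is None:
        raise ValueError("centering requires box information")
    masses = traj.topology.masses
    xyz = traj.xyz.copy()
    for f in range(traj.n_frames):
        lz = traj.box[f, 2]
        theta = 2.0 * np.pi * xyz[f, :, 2] / lz
        zc = lz / (2.0 * np.pi) * np.arctan2(
            np.average(np.sin(theta), weights=masses),
            np.average(np.cos(theta), weights=masses))
        xyz[f, :, 2] += lz / 2.0 - zc
    return Trajectory(traj.topology, xyz, traj.time.copy(), traj.box.copy())


def density_profile(traj: Trajectory, bin_width_nm: float = 0.5,
                    equilibration_ps: float = 0.0, n_blocks: int = 4,
                    ) -> DensityProfile:
    """Time-averaged mass density per z-bin, converted to mg/mL.

    The first ``equilibration_ps`` of the trajectory is discarded; the
    remaining frames are split into ``n_blocks`` contiguous blocks whose
    profiles provide block errors.  The profile integral reproduces the
    total system mass exactly (each bead lands in exactly one bin).
    """
    if traj.box is None:
        raise ValueError("density profile requires box information")
    lz = float(traj.box[0, 2])
    if bin_width_nm > lz:
        raise ValueError("bin width larger than the box")
    keep = traj.time > equilibration_ps
    if not np.any(keep):
        raise ValueError("equilibration cut leaves no frames")
    xyz = traj.xyz[keep]
    n_frames = xyz.shape[0]
    n_bins = max(int(round(lz / bin_width_nm)), 1)
    edges = np.linspace(0.0, lz, n_bins + 1)
    masses = traj.topology.masses
    area = float(traj.box[0, 0] * traj.box[0, 1])
    bin_vol = area * (lz / n_bins)
    z = xyz[:, :, 2] % lz
    hist = np.zeros((n_frames, n_bins))
    for f in range(n_frames):
        hist[f], _ = np.histogram(z[f], bins=edges, weights=masses)
    conc = hist / bin_vol * AMU_PER_NM3_TO_MG_PER_ML  # amu/nm^3 -> mg/mL
    blocks = np.array_split(conc, n_blocks)
    block_profiles = np.array([b.mean(axis=0) for b in blocks])
    centers = 0.5 * (edges[:-1] + edges[1:])
    chain_mass = None
    topo = traj.topology
    if topo.n_chains >= 1:
        chain_mass = float(masses[topo.chain_of_atom == 0].sum())
    return DensityProfile(centers, conc.mean(axis=0), block_profiles,
                          n_frames, area, lz, chain_mass)


# --------------------------------------------------------------- tanh fit

def _double_tanh(z, c_dil, c_den, z0, half_width, steep):
    return c_dil + 0.5 * (c_den - c_dil) * (
        np.tanh((half_width - np.abs(z - z0)) / steep) + 1.0)


def _fit_profile(z, rho, lz):
    span = rho.max() - rho.min()
    if span <= 0:
        return None
    p0 = (max(rho.min(), 1e-6), rho.max(), lz / 2.0,
          max(lz / 8.0, 1.5 * (z[1] - z[0])), max(lz / 40.0, z[1] - z[0]))
    bounds = ([0.0, 0.0, 0.0, 0.0, 1e-3], [np.inf, np.inf, lz, lz, lz])
    try:
        popt, _ = optimize.curve_fit(_double_tanh, z, rho, p0=p0,
                                     bounds=bounds, maxfev=20000)
    except RuntimeError:
        return None
    return popt


def window_average_densities(profile: DensityProfile,
                             dense_level: float = 0.9,
                             dilute_level: float = 0.1) -> tuple[float, float]:
    """Simple cross-check estimator: plateau averages away from interfaces.

    Dense = mean over bins above ``dense_level`` of the profile span,
    dilute = mean over bins below ``dilute_level`` of the span; interface
    bins in between are ignored.  For a flat profile both estimates
    coincide with the overall mean.
    """
    rho = profile.conc_mg_ml
    lo, span = rho.min(), float(np.ptp(rho))
    if span == 0:
        return float(rho.mean()), float(rho.mean())
    dense_mask = rho >= lo + dense_level * span
    dil_mask = rho <= lo + dilute_level * span
    # medians resist the interface shoulders that leak into either window
    return float(np.median(rho[dil_mask])), float(np.median(rho[dense_mask]))


def coexistence_densities(profile: DensityProfile,
                          temperature_K: float = np.nan,
                          gap_sem_factor: float = 2.0,
                          min_relative_gap: float = 0.05,
                          max_dilute_fraction: float = 0.2) -> CoexistencePoint:
    """Extract (Csat, Cdense) by fitting a symmetric double-tanh interface.

    Cdense comes from the central plateau, Csat from the far field; SEMs
    propagate from per-block fits.  The point is flagged single-phase when
    (a) the fitted density gap is indistinguishable from zero (smaller than
    ``gap_sem_factor`` block SEMs or ``min_relative_gap`` of the dense
    plateau), or (b) the robust plateau estimates are closer than
    ``max_dilute_fraction`` of each other — a dilute level above ~20% of
    the dense level means the "interfaces" are not separable from bulk
    density fluctuations of a single phase at these system sizes.
    Non-convergent fits are flagged with no numbers.

    The fitted far field is additionally cross-checked against the
    nonparametric plateau estimator: transient satellite droplets can pull
    the tanh baseline far above the true dilute density, in which case the
    robust estimate replaces it (with block errors recomputed the same
    way).
    """
    z, rho = profile.z_nm, profile.conc_mg_ml
    if len(z) < 20:
        raise ValueError("need at least 20 bins to resolve two interfaces")
    popt = _fit_profile(z, rho, profile.box_z_nm)
    if popt is None:
        mean_c = float(rho.mean())
        if np.allclose(rho, rho[0]):
            return CoexistencePoint(temperature_K, mean_c, mean_c, 0.0, 0.0,
                                    0.0, True, single_phase=True)
        return CoexistencePoint(temperature_K, np.nan, np.nan, np.nan, np.nan,
                                np.nan, False)
    c_dil, c_den, _z0, half_width, steep = popt
    block_dil, block_den = [], []
    for b in profile.block_profiles:
        pb = _fit_profile(z, b, profile.box_z_nm)
        if pb is not None:
            block_dil.append(pb[0])
            block_den.append(pb[1])
    if len(block_dil) >= 2:
        nb = len(block_dil)
        sem_dil = float(np.std(block_dil, ddof=1) / np.sqrt(nb))
        sem_den = float(np.std(block_den, ddof=1) / np.sqrt(nb))
    else:
        sem_dil = sem_den = 0.0
    # self-check the fitted far field against the nonparametric plateau
    # estimate: transient satellite droplets near the interface can pull the
    # tanh baseline up even when the true dilute region is essentially
    # empty; when the two estimators disagree materially the robust one wins
    dil_win, den_win = window_average_densities(profile)
    if abs(c_dil - dil_win) > max(min_relative_gap * c_den, 3.0 * sem_dil):
        c_dil = dil_win
        block_win = [window_average_densities(DensityProfile(
            z, b, b[None], profile.n_frames, profile.cross_section_nm2,
            profile.box_z_nm))[0] for b in profile.block_profiles]
        if len(block_win) >= 2:
            sem_dil = float(np.std(block_win, ddof=1)
                            / np.sqrt(len(block_win)))
    gap = c_den - c_dil
    gap_sem = np.hypot(sem_dil, sem_den)
    single = bool(gap <= max(gap_sem_factor * gap_sem,
                             min_relative_gap * max(c_den, 1e-12))
                  or dil_win >= max_dilute_fraction * max(den_win, 1e-12))
    if single:
        mean_c = float(rho.mean())
        return CoexistencePoint(temperature_K, mean_c, mean_c, sem_dil,
                                sem_den, 0.0, True, single_phase=True)
    return CoexistencePoint(temperature_K, float(c_dil), float(c_den),
                            sem_dil, sem_den, float(steep), True)


# ---------------------------------------------------------------- binodal

def phase_diagram(points: list[CoexistencePoint], beta: float = ISING_BETA_3D,
                  free_beta: bool = False) -> PhaseDiagram:
    """Assemble the binodal and fit Tc.

    The density gap is fitted to Delta(T) = A (1 - T/Tc)^beta with beta
    fixed at the 3D-Ising value (freeing it is opt-in); the critical density
    follows from the law of rectilinear diameters.
    """
    coex = [p for p in points if p.converged and not p.single_phase]
    if len(coex) < 3:
        raise ValueError("need at least 3 coexisting temperatures")
    T = np.array([p.temperature_K for p in coex])
    gap = np.array([p.c_dense - p.c_dilute for p in coex])
    mid = np.array([0.5 * (p.c_dense + p.c_dilute) for p in coex])
    tmax = T.max()

    if free_beta:
        def model(t, a, tc, b):
            return a * np.clip(1.0 - t / tc, 0.0, None) ** b
        p0 = (gap.max(), tmax * 1.05, beta)
        bounds = ([0, tmax, 0.05], [np.inf, 10 * tmax, 1.0])
    else:
        def model(t, a, tc):
            return a * np.clip(1.0 - t / tc, 0.0, None) ** beta
        p0 = (gap.max(), tmax * 1.05)
        bounds = ([0, tmax], [np.inf, 10 * tmax])
    popt, _ = optimize.curve_fit(model, T, gap, p0=p0, bounds=bounds,
                                 maxfev=20000)
    a, tc = popt[0], popt[1]
    fitted_beta = popt[2] if free_beta else beta
    # rectilinear diameters: (c_den + c_dil)/2 = c_c + s (tc - T)
    slope, intercept = np.polyfit(tc - T, mid, 1)
    return PhaseDiagram(list(points), tc_K=float(tc),
                        critical_density=float(intercept),
                        beta=float(fitted_beta), gap_amplitude=float(a))


def csat_compare(profiles: dict[str, DensityProfile],
                 temperature_K: float) -> pd.DataFrame:
    """Csat +- SEM per system at one temperature, ordered by Csat.

    Systems flagged single-phase are excluded from the comparison (their
    row carries the flag); pairwise significance uses block-based errors
    (two-sided z-score on the difference).
    """
    rows = []
    for label, prof in profiles.items():
        pt = coexistence_densities(prof, temperature_K)
        rows.append({"system": label, "csat_mg_ml": pt.c_dilute,
                     "csat_sem": pt.c_dilute_sem,
                     "cdense_mg_ml": pt.c_dense,
                     "single_phase": pt.single_phase,
                     "converged": pt.converged})
    df = pd.DataFrame(rows).set_index("system")
    coex = df[~df.single_phase & df.converged].sort_values("csat_mg_ml")
    zscores = {}
    labels = list(coex.index)
    for i, a in enumerate(labels):
        for b_ in labels[i + 1:]:
            diff = coex.loc[b_, "csat_mg_ml"] - coex.loc[a, "csat_mg_ml"]
            se = np.hypot(coex.loc[a, "csat_sem"], coex.loc[b_, "csat_sem"])
            zscores[(a, b_)] = diff / se if se > 0 else np.inf
    df = df.sort_values(["single_phase", "csat_mg_ml"])
    df.attrs["pairwise_z"] = zscores
    return df
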