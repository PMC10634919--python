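"""Contact-map, PRE-proxy and compaction analysis of trajectories.

Heavy-atom contacts at a distance cutoff (0.6 nm by default), aggregation
of contacts by residue type, the <r^-6>/<r^-6>_max proxy for paramagnetic
relaxation enhancement within a 3.5 nm cutoff, radius-of-gyration
statistics and correlation times, inter-residue distance scaling with
sequence separation, and per-segment compaction.

Intramolecular geometry assumes unwrapped chains (the built-in simulator
stores unwrapped coordinates); wrapped input is detected via bonds longer
than half the box.  Intermolecular distances use the minimum image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence import AMINO_ACIDS, ProteinSequence
from .trajectory import Trajectory, minimum_image


@dataclass
class ContactMap:
    """Residue-by-residue contact counts (cumulative and per-frame views)."""

    counts: np.ndarray          # (n_res, n_res) cumulative over frames
    mode: str                   # "intramolecular" | "intermolecular"
    n_frames: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact map must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @property
    def per_frame(self) -> np.ndarray:
        return self.counts / self.n_frames

    @property
    def total(self) -> float:
        """Grand total of unordered residue-pair contacts."""
        return float(np.triu(self.counts).sum())


def _check_wrapped(traj: Trajectory) -> None:
    topo = traj.topology
    if traj.box is None or topo.bonds is None or len(topo.bonds) == 0:
        return
    i, j = topo.bonds[:, 0], topo.bonds[:, 1]
    d = traj.xyz[:, i, :] - traj.xyz[:, j, :]
    if np.any(np.abs(d) > 0.5 * traj.box[:, None, :]):
        raise ValueError("chains appear wrapped across the periodic boundary; "
                         "unwrap the trajectory before intra-chain analysis")


def contact_map(traj: Trajectory, cutoff_nm: float = 0.6,
                mode: str = "intramolecular", exclusion: int = 1) -> ContactMap:
    """Heavy-atom contact counts per residue pair, accumulated over frames.

    A contact is any heavy-atom pair closer than the cutoff; the (i, j)
    entry sums over all heavy-atom pairs of residues i and j, so residues
    with longer sidechains can contribute more contacts.  Intramolecular
    mode counts pairs on the same chain excluding |i-j| <= exclusion;
    intermolecular mode counts pairs on different chains with minimum-image
    distances.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("intramolecular", "intermolecular"):
        raise ValueError(f"unknown mode {mode!r}")
    topo = traj.topology
    heavy = np.nonzero(topo.heavy)[0]
    res_of = topo.residue_index[heavy]
    chain_of = topo.chain_of_atom[heavy]
    n_res = topo.n_residues
    counts = np.zeros((n_res, n_res))
    iu, ju = np.triu_indices(len(heavy), k=1)
    same_chain = chain_of[iu] == chain_of[ju]
    if mode == "intramolecular":
        _check_wrapped(traj)
        keep = same_chain & (np.abs(res_of[iu] - res_of[ju]) > exclusion)
    else:
        keep = ~same_chain
    iu, ju = iu[keep], ju[keep]
    ai, aj = heavy[iu], heavy[ju]
    ri, rj = res_of[iu], res_of[ju]
    cut2 = cutoff_nm ** 2
    for f in range(traj.n_frames):
        d = traj.xyz[f, ai, :] - traj.xyz[f, aj, :]
        if mode == "intermolecular" and traj.box is not None:
            d = minimum_image(d, traj.box[f])
        within = np.einsum("ij,ij->i", d, d) < cut2
        np.add.at(counts, (ri[within], rj[within]), 1.0)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMap(counts, mode, traj.n_frames)


def residue_type_contacts(cmap: ContactMap, seq: ProteinSequence) -> pd.DataFrame:
    """Sum residue-pair contacts into a symmetric 20x20 type-pair table.

    The grand total of unordered pairs is conserved between views.
    """
    n = len(seq.residues)
    if cmap.counts.shape[0] % n != 0:
        raise ValueError("map dimension is not a multiple of the sequence length")
    codes = list(seq.residues) * (cmap.counts.shape[0] // n)
    idx = np.array([AMINO_ACIDS.index(c) for c in codes])
    table = np.zeros((20, 20))
    iu, ju = np.triu_indices(len(codes))
    for a, b, v in zip(idx[iu], idx[ju], cmap.counts[iu, ju]):
        if v:
            lo, hi = min(a, b), max(a, b)
            table[lo, hi] += v
    table = table + table.T - np.diag(np.diag(table))
    return pd.DataFrame(table, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


def per_residue_contacts(cmap: ContactMap) -> np.ndarray:
    """Row sums (excluding self) per frame: the average-contacts profile."""
    off = cmap.counts - np.diag(np.diag(cmap.counts))
    return off.sum(axis=1) / cmap.n_frames


@dataclass
class PREProxyProfile:
    """<r^-6>/<r^-6>_max profile from a label residue, with replica SEM."""

    label_residue: int
    residues: np.ndarray
    values: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-9:
            raise ValueError("normalized profile must lie in [0, 1]")


def pre_proxy(trajs: Trajectory | list[Trajectory], label_residue: int,
              cutoff_nm: float = 3.5) -> PREProxyProfile:
    """Ensemble <r^-6> from the label residue's heavy atoms, normalized.

    r^-6 is averaged over heavy-atom pairs (label x target) and frames
    first — pairs beyond the cutoff contribute zero — then the profile is
    normalized by its maximum.  With several replicas the replica mean is
    normalized and the standard error of the mean propagated.  The label
    residue itself (the attachment site) is reported as exactly 1.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    topo = trajs[0].topology
    n_res = topo.n_residues
    if not 0 <= label_residue < n_res:
        raise ValueError("label residue outside topology")
    heavy = np.nonzero(topo.heavy)[0]
    label_atoms = heavy[topo.residue_index[heavy] == label_residue]
    if len(label_atoms) == 0:
        raise ValueError("label residue has no heavy atoms")
    cut2 = cutoff_nm ** 2
    profiles = []
    for traj in trajs:
        raw = np.zeros(n_res)
        for r in range(n_res):
            if r == label_residue:
                continue
            atoms = heavy[topo.residue_index[heavy] == r]
            if len(atoms) == 0:
                raw[r] = np.nan
                continue
            d = (traj.xyz[:, label_atoms, None, :]
                 - traj.xyz[:, None, atoms, :])
            r2 = np.einsum("...i,...i->...", d, d)
            inv6 = np.where(r2 < cut2, 1.0 / np.maximum(r2, 1e-12) ** 3, 0.0)
            raw[r] = inv6.mean()
        profiles.append(raw)
    arr = np.array(profiles)
    mean = np.nanmean(arr, axis=0)
    sem = (np.nanstd(arr, axis=0, ddof=1) / np.sqrt(len(trajs))
           if len(trajs) > 1 else np.zeros(n_res))
    norm = np.nanmax(mean)
    values = mean / norm
    sem = sem / norm
    values[label_residue] = 1.0
    sem[label_residue] = 0.0
    return PREProxyProfile(label_residue, np.arange(n_res), values, sem)


# ------------------------------------------------------------- compaction

def radius_of_gyration(traj: Trajectory, atom_indices=None) -> pd.DataFrame:
    """Mass-weighted Rg (nm) per frame per chain.

    ``atom_indices`` restricts the selection (applied per chain).  Raises if
    chains appear wrapped across the periodic boundary.
    """
    _check_wrapped(traj)
    topo = traj.topology
    sel = (np.arange(topo.n_atoms) if atom_indices is None
           else np.asarray(atom_indices))
    if len(sel) == 0:
        raise ValueError("empty selection")
    out = {}
    for c in range(topo.n_chains):
        atoms = sel[topo.chain_of_atom[sel] == c]
        if len(atoms) == 0:
            continue
        m = topo.masses[atoms]
        xyz = traj.xyz[:, atoms, :]
        com = np.einsum("fai,a->fi", xyz, m) / m.sum()
        d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
        out[c] = np.sqrt(np.einsum("fa,a->f", d2, m) / m.sum())
    return pd.DataFrame(out, index=traj.time)


def rg_correlation_time(series: np.ndarray, dt_ps: float = 1.0) -> float:
    """Time at which the normalized Rg-fluctuation ACF decays to 1/e.

    Linear interpolation locates the first crossing.  Raises on a constant
    series; warns (via the returned value's context) when the series is
    shorter than ~10x the estimated correlation time.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has no correlation time")
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    F = np.fft.rfft(x, n=nfft)
    acf = np.fft.irfft(F * np.conj(F), n=nfft)[:n].real
    acf /= acf[0]
    target = np.exp(-1.0)
    below = np.nonzero(acf < target)[0]
    if len(below) == 0:
        raise ValueError("ACF never decays to 1/e within the series")
    k = below[0]
    if k == 0:
        return 0.0
    frac = (acf[k - 1] - target) / (acf[k - 1] - acf[k])
    tau = (k - 1 + frac) * dt_ps
    if n * dt_ps < 10 * tau:
        import warnings
        warnings.warn("series shorter than 10x the correlation time; "
                      "estimate may be unreliable", stacklevel=2)
    return float(tau)


@dataclass
class DistanceScaling:
    """Mean inter-residue distance vs sequence separation, with exponent."""

    separations: np.ndarray
    mean_distance_nm: np.ndarray
    exponent: float
    prefactor_nm: float
    fit_window: tuple[int, int]


def distance_scaling(traj: Trajectory, chain: int = 0,
                     fit_window: tuple[int, int] | None = None) -> DistanceScaling:
    """<r_ij> as a function of |i-j| for one chain, with a power-law fit.

    Residue positions are mass-weighted residue centers.  The exponent nu in
    <r(s)> = b s^nu is fitted log-log over ``fit_window`` (defaults to
    separations 2 .. N/2); nu ~ 0.5 marks ideal-chain statistics, 1.0 a rod.
    """
    _check_wrapped(traj)
    topo = traj.topology
    res = np.nonzero(topo.chain_of_residue == chain)[0]
    n = len(res)
    if n < 4:
        raise ValueError("chain too short for distance scaling")
    centers = np.empty((traj.n_frames, n, 3))
    for k, r in enumerate(res):
        atoms = topo.atoms_of_residue(r)
        m = topo.masses[atoms]
        centers[:, k, :] = np.einsum("fai,a->fi", traj.xyz[:, atoms, :], m) / m.sum()
    seps = np.arange(n)
    mean_r = np.zeros(n)
    for s in range(1, n):
        d = centers[:, s:, :] - centers[:, :-s, :]
        mean_r[s] = np.sqrt(np.einsum("fai,fai->fa", d, d)).mean()
    if fit_window is None:
        fit_window = (2, max(n // 2, 3))
    lo, hi = fit_window
    if hi <= lo or hi >= n:
        raise ValueError("fit window outside available separations")
    s_fit = seps[lo:hi + 1]
    nu, logb = np.polyfit(np.log(s_fit), np.log(mean_r[lo:hi + 1]), 1)
    return DistanceScaling(seps, mean_r, float(nu), float(np.exp(logb)),
                           (lo, hi))


def segment_compaction(traj: Trajectory, segments: list[tuple[int, int]],
                       chain: int = 0, strict: bool = True) -> pd.DataFrame:
    """Per-segment Rg samples (nm); segments are residue-number ranges.

    Returns a DataFrame with one column per segment labelled "lo-hi",
    ordered as given; ``.attrs['ranking']`` lists segments by ascending
    mean Rg (most compact first).
    """
    topo = traj.topology
    _check_wrapped(traj)
    numbers = topo.residue_numbers
    chain_res = topo.chain_of_residue
    cols = {}
    seen: list[tuple[int, int]] = []
    for lo, hi in segments:
        if strict:
            for plo, phi in seen:
                if lo <= phi and hi >= plo:
                    raise ValueError(f"segment {lo}-{hi} overlaps {plo}-{phi}")
        seen.append((lo, hi))
        res_sel = np.nonzero((chain_res == chain) & (numbers >= lo)
                             & (numbers <= hi))[0]
        if len(res_sel) == 0:
            raise ValueError(f"segment {lo}-{hi} outside the chain")
        atoms = np.nonzero(np.isin(topo.residue_index, res_sel))[0]
        m = topo.masses[atoms]
        xyz = traj.xyz[:, atoms, :]
        com = np.einsum("fai,a->fi", xyz, m) / m.sum()
        d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
        cols[f"{lo}-{hi}"] = np.sqrt(np.einsum("fa,a->f", d2, m) / m.sum())
    df = pd.DataFrame(cols, index=traj.time)
    df.attrs["ranking"] = list(df.mean().sort_values().index)
    return df
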