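"""Extraction of relaxation rates from NMR peak-intensity tables.

Covers the experimental side of backbone-dynamics analysis of a disordered
domain: mono-exponential T1/T1rho fits, conversion of rotating-frame R1rho
to R2 through the spin-lock tilt angle, steady-state heteronuclear NOE
ratios, the two-time-point estimate of amide-proton transverse rates used
for PRE measurements, paramagnetic-minus-diamagnetic Gamma2 differences,
and a solvent-PRE flatness summary.

Also hosts the synthetic peak-table generator: every fit here inverts the
generator exactly in the noiseless limit, which is how the fitting code is
validated without spectrometer data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

EXPERIMENT_KINDS = ("T1", "T1rho", "two_point_T2", "hetNOE_pair")

# delays printed for the T1 protocol (s); the T1rho protocol uses its own set
T1_DELAYS_S = np.array([0.040, 0.080, 0.120, 0.200, 0.280, 0.400, 0.600, 0.800])
T1RHO_DELAYS_S = np.array([0.001, 0.021, 0.031, 0.041, 0.061, 0.081, 0.121, 0.201])
# two-delay amide-proton T2 protocol (documented defaults; user-overridable)
TWO_POINT_DELAYS_S = (1e-6, 6e-4)


@dataclass
class PeakIntensityTable:
    """Per-residue peak intensities across delays for one experiment kind."""

    kind: str
    residues: np.ndarray                # (n_res,)
    delays: np.ndarray                  # (n_delays,) seconds, or labels
    intensities: np.ndarray             # (n_res, n_delays)
    noise: np.ndarray | None = None     # same shape as intensities

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        self.residues = np.asarray(self.residues)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        n_delays = self.intensities.shape[1]
        if self.kind in ("two_point_T2", "hetNOE_pair") and n_delays != 2:
            raise ValueError(f"{self.kind} requires exactly 2 columns")
        if self.kind in ("T1", "T1rho"):
            self.delays = np.asarray(self.delays, dtype=float)
            if len(self.delays) != n_delays:
                raise ValueError("delay count must match intensity columns")

    def to_csv(self, path: str | Path) -> None:
        cols = (list(map(str, self.delays)) if self.kind in ("T1", "T1rho")
                else (["Ta", "Tb"] if self.kind == "two_point_T2"
                      else ["saturated", "unsaturated"]))
        df = pd.DataFrame(self.intensities, columns=cols)
        df.insert(0, "residue", self.residues)
        df.to_csv(path, index=False)


@dataclass
class RelaxationProfile:
    """Per-residue R1/R2/NOE with uncertainties; experiment or simulation."""

    data: pd.DataFrame          # indexed by residue number
    field_mhz: float = 700.13
    source: str = "experiment"

    def __post_init__(self) -> None:
        for col in ("R1", "R2", "NOE"):
            if col not in self.data.columns:
                self.data[col] = np.nan
        defined = self.data[["R1", "R2"]].dropna()
        if (defined <= 0).any().any():
            raise ValueError("R1 and R2 must be positive where defined")

    @property
    def residues(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class PREProfile:
    """Per-residue PRE rate Gamma2 with broadened-out flags."""

    label_site: int | str
    residues: np.ndarray
    gamma2: np.ndarray
    gamma2_err: np.ndarray
    broadened: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues)
        self.gamma2 = np.asarray(self.gamma2, dtype=float)
        self.gamma2_err = np.asarray(self.gamma2_err, dtype=float)
        self.broadened = np.asarray(self.broadened, dtype=bool)
        bad = ~self.broadened & ~np.isfinite(self.gamma2)
        if np.any(bad):
            raise ValueError("non-flagged residues must carry finite Gamma2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "gamma2": self.gamma2,
                             "gamma2_err": self.gamma2_err,
                             "broadened": self.broadened})


# ----------------------------------------------------------------- fitting

def _fit_single_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Least squares of I(t) = I0 exp(-R t); returns (R, sigma_R, converged)."""
    if np.all(y > 0):
        slope, intercept = np.polyfit(t, np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    else:
        p0 = (float(y[0]), 1.0 / (t[-1] - t[0]))
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt), t, y, p0=p0, maxfev=10000)
    except RuntimeError:
        return np.nan, np.nan, False
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return float(popt[1]), err, True


def fit_monoexponential(table: PeakIntensityTable) -> pd.DataFrame:
    """Per-residue rate from I(t) = I0 exp(-R t) (T1 or T1rho tables).

    Returns a DataFrame (residue index) with columns rate, rate_err,
    converged.  Residues whose fit fails are flagged, not dropped.
    """
    if table.kind not in ("T1", "T1rho"):
        raise ValueError("fit_monoexponential expects a T1 or T1rho table")
    if len(table.delays) < 3:
        raise ValueError("need at least 3 delays for an exponential fit")
    rows = []
    for i, res in enumerate(table.residues):
        rate, err, ok = _fit_single_exponential(table.delays,
                                                table.intensities[i])
        rows.append((res, rate, err, ok))
    df = pd.DataFrame(rows, columns=["residue", "rate", "rate_err", "converged"])
    return df.set_index("residue")


def r2_from_r1rho(r1rho, r1, omega1: float, offset,
                  sin2_floor: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Invert R1rho = R1 cos^2(theta) + R2 sin^2(theta).

    theta = arctan(omega1/Omega) is the spin-lock tilt angle (omega1 = B1
    field strength, Omega = resonance offset, both rad/s).  On resonance
    (Omega = 0) theta = 90 deg and R1rho is returned unchanged.  Residues
    whose offset is so large that sin^2(theta) falls below ``sin2_floor``
    are flagged unreliable (NaN in the reliability mask sense).

    Returns (R2 array, reliable boolean array).
    """
    if omega1 <= 0:
        raise ValueError("spin-lock field strength omega1 must be positive")
    r1rho = np.atleast_1d(np.asarray(r1rho, dtype=float))
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    offset = np.broadcast_to(np.atleast_1d(np.asarray(offset, dtype=float)),
                             r1rho.shape)
    theta = np.arctan2(omega1, offset)
    sin2 = np.sin(theta) ** 2
    cos2 = np.cos(theta) ** 2
    reliable = sin2 >= sin2_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (r1rho - r1 * cos2) / sin2
    r2 = np.where(reliable, r2, np.nan)
    return r2, reliable


def hetnoe(table: PeakIntensityTable) -> pd.DataFrame:
    """NOE = I_saturated / I_unsaturated with first-order error propagation.

    Negative NOEs are legal (flexible residues); a non-positive unsaturated
    reference intensity is an error.
    """
    if table.kind != "hetNOE_pair":
        raise ValueError("hetnoe expects a hetNOE_pair table")
    sat = table.intensities[:, 0]
    unsat = table.intensities[:, 1]
    if np.any(unsat <= 0):
        raise ValueError("unsaturated intensities must be positive")
    noe = sat / unsat
    if table.noise is not None:
        s_sat, s_un = table.noise[:, 0], table.noise[:, 1]
        err = np.abs(noe) * np.sqrt((s_sat / np.where(sat == 0, np.inf, sat)) ** 2
                                    + (s_un / unsat) ** 2)
    else:
        err = np.full_like(noe, np.nan)
    return pd.DataFrame({"NOE": noe, "NOE_err": err},
                        index=pd.Index(table.residues, name="residue"))


def two_point_r2(i_ta, i_tb, delta_t: float) -> pd.DataFrame:
    """Two-delay transverse rate R = ln(I_Ta / I_Tb) / (Tb - Ta).

    Non-positive intensities mark a peak broadened out of the spectrum
    (flagged, no rate); negative rates (I_Tb > I_Ta) are retained but
    flagged noise-dominated rather than clamped.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    i_ta = np.atleast_1d(np.asarray(i_ta, dtype=float))
    i_tb = np.atleast_1d(np.asarray(i_tb, dtype=float))
    broadened = (i_ta <= 0) | (i_tb <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.log(i_ta / i_tb) / delta_t
    rate = np.where(broadened, np.nan, rate)
    return pd.DataFrame({"rate": rate, "broadened": broadened,
                         "noise_dominated": ~broadened & (rate < 0)})


def gamma2(r_para: pd.DataFrame | pd.Series, r_dia: pd.DataFrame | pd.Series,
           label_site: int | str = "unknown") -> PREProfile:
    """PRE rates: Gamma2 = R2,para - R2,dia on the residue intersection.

    Inputs are per-residue rate tables indexed by residue (columns ``rate``
    and optionally ``rate_err``).  Residues present diamagnetically but with
    a missing/non-finite paramagnetic rate are flagged broadened-out.
    Uncertainties add in quadrature.
    """
    para = _as_rate_frame(r_para)
    dia = _as_rate_frame(r_dia)
    both = para.index.intersection(dia.index)
    if len(both) == 0:
        raise ValueError("no residues shared between the two tables")
    residues = dia.index.to_numpy()
    g = np.full(len(residues), np.nan)
    ge = np.full(len(residues), np.nan)
    broad = np.ones(len(residues), dtype=bool)
    for k, res in enumerate(residues):
        if res in para.index and np.isfinite(para.loc[res, "rate"]):
            g[k] = para.loc[res, "rate"] - dia.loc[res, "rate"]
            ge[k] = np.sqrt(np.nan_to_num(para.loc[res, "rate_err"]) ** 2
                            + np.nan_to_num(dia.loc[res, "rate_err"]) ** 2)
            broad[k] = False
    return PREProfile(label_site, residues, g, ge, broad)


def _as_rate_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.Series):
        obj = obj.to_frame("rate")
    df = obj.copy()
    if "rate_err" not in df.columns:
        df["rate_err"] = 0.0
    return df


def solvent_baseline(profile: PREProfile, alpha: float = 0.05) -> dict:
    """Summary of a solvent-PRE profile: mean, sd, and a flatness test.

    Flatness is a linear trend test: the profile is called flat when the
    fitted slope against residue number is consistent with zero at level
    ``alpha``.  A flat profile near-uniform across the chain is the
    signature of a purely solvent (non-site-specific) enhancement.
    """
    mask = ~profile.broadened & np.isfinite(profile.gamma2)
    if mask.sum() < 10:
        raise ValueError("need at least 10 residues with Gamma2 values")
    x = profile.residues[mask].astype(float)
    y = profile.gamma2[mask]
    res = stats.linregress(x, y)
    sd = float(np.std(y, ddof=1))
    flat = bool(res.pvalue > alpha) if np.isfinite(res.pvalue) else sd == 0.0
    return {"mean": float(np.mean(y)), "sd": sd, "slope": float(res.slope),
            "slope_pvalue": float(res.pvalue), "flat": flat}


# ------------------------------------------------------------ generators

def generate_peak_tables(kind: str, residues, truth, *, delays=None,
                         i0: float = 1000.0, noise_fraction: float = 0.0,
                         seed: int = 0) -> PeakIntensityTable:
    """Synthetic peak tables with known ground truth.

    ``truth`` is the per-residue true rate (T1/T1rho/two_point_T2, s^-1) or
    the true NOE ratio (hetNOE_pair).  The noiseless limit is exactly
    invertible by the corresponding fit; noise is multiplicative Gaussian at
    ``noise_fraction`` and deterministic under ``seed``.
    """
    residues = np.asarray(residues)
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    if kind in ("T1", "T1rho"):
        if np.any(truth < 0):
            raise ValueError("relaxation rates must be non-negative")
        if delays is None:
            delays = T1_DELAYS_S if kind == "T1" else T1RHO_DELAYS_S
        delays = np.asarray(delays, dtype=float)
        clean = i0 * np.exp(-np.outer(truth, delays))
    elif kind == "two_point_T2":
        if delays is None:
            delays = TWO_POINT_DELAYS_S
        ta, tb = delays
        clean = np.column_stack([i0 * np.exp(-truth * ta),
                                 i0 * np.exp(-truth * tb)])
        delays = np.asarray(delays)
    elif kind == "hetNOE_pair":
        clean = np.column_stack([i0 * truth, np.full_like(truth, i0)])
        delays = np.array(["saturated", "unsaturated"], dtype=object)
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    noisy = clean * (1.0 + noise_fraction * rng.standard_normal(clean.shape))
    noise = (np.abs(clean) * noise_fraction if noise_fraction > 0 else None)
    return PeakIntensityTable(kind, residues, delays, noisy, noise=noise)


def read_peak_table(path: str | Path, kind: str) -> PeakIntensityTable:
    """Read a delimited peak table (residue column + one column per delay)."""
    df = pd.read_csv(path)
    residues = df["residue"].to_numpy()
    cols = [c for c in df.columns if c != "residue"]
    if kind in ("T1", "T1rho"):
        delays = np.array([float(c) for c in cols])
    elif kind == "two_point_T2":
        delays = np.asarray(TWO_POINT_DELAYS_S)
    else:
        delays = np.array(cols, dtype=object)
    return PeakIntensityTable(kind, residues, delays, df[cols].to_numpy())
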