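"""NMR rate extraction on synthetic peak tables with known ground truth.

Generates T1/T1rho relaxation series, a heteronuclear NOE pair, and the
two-time-point amide-proton T2 tables used for PRE measurements; fits each
and compares against the truth.  A flexible disordered chain shows R1 near
1.5 1/s, R2 near 3 1/s and small or negative NOEs; PRE rates (Gamma2) are
the paramagnetic-minus-diamagnetic difference.
"""

import numpy as np

from lcdphase import nmr_rates as nr

rng = np.random.default_rng(7)
residues = np.arange(1, 41)

# --- T1 / T1rho -> R1, R2 ------------------------------------------------
r1_true = 1.5 + 0.1 * np.sin(residues / 5)
r1rho_true = 3.0 + 0.4 * np.cos(residues / 7)
t1 = nr.generate_peak_tables("T1", residues, r1_true,
                             noise_fraction=0.02, seed=1)
t1rho = nr.generate_peak_tables("T1rho", residues, r1rho_true,
                                noise_fraction=0.02, seed=2)
r1 = nr.fit_monoexponential(t1)
r1rho = nr.fit_monoexponential(t1rho)
# spin-lock tilt correction at a 1400 Hz B1 field, small offsets
r2, ok = nr.r2_from_r1rho(r1rho["rate"].to_numpy(), r1["rate"].to_numpy(),
                          omega1=2 * np.pi * 1400.0,
                          offset=rng.uniform(-400, 400, len(residues)))
print(f"mean R1 = {r1['rate'].mean():.2f} 1/s "
      f"(truth {r1_true.mean():.2f}), "
      f"mean R2 = {np.nanmean(r2):.2f} 1/s (truth ~{r1rho_true.mean():.2f})")

# --- hetNOE ---------------------------------------------------------------
noe_true = -0.16 + 0.2 * np.tanh((residues - 20) / 10)
noe = nr.hetnoe(nr.generate_peak_tables("hetNOE_pair", residues, noe_true,
                                        noise_fraction=0.02, seed=3))
print(f"mean hetNOE = {noe['NOE'].mean():.3f} (truth {noe_true.mean():.3f}) "
      "- negative values mark fast backbone motion")

# --- two-point T2 -> Gamma2 (PRE) ----------------------------------------
delays = (0.001, 0.05)
dia_true = np.full(40, 5.0)
gamma_true = 10.0 * np.exp(-((residues - 12) / 6.0) ** 2)  # near label site
para = nr.generate_peak_tables("two_point_T2", residues,
                               dia_true + gamma_true, delays=delays,
                               noise_fraction=0.01, seed=4)
dia = nr.generate_peak_tables("two_point_T2", residues, dia_true,
                              delays=delays, noise_fraction=0.01, seed=5)
dt = delays[1] - delays[0]
rates_p = nr.two_point_r2(para.intensities[:, 0], para.intensities[:, 1], dt)
rates_d = nr.two_point_r2(dia.intensities[:, 0], dia.intensities[:, 1], dt)
import pandas as pd
prof = nr.gamma2(
    pd.DataFrame({"rate": rates_p["rate"].to_numpy()}, index=residues),
    pd.DataFrame({"rate": rates_d["rate"].to_numpy()}, index=residues),
    label_site=12)
peak = prof.residues[np.nanargmax(prof.gamma2)]
print(f"Gamma2 peaks at residue {peak} with "
      f"{np.nanmax(prof.gamma2):.1f} 1/s (truth 10.0 at residue 12)")

# --- solvent PRE baseline -------------------------------------------------
solvent = nr.PREProfile("solvent", residues,
                        2.0 + 0.2 * rng.standard_normal(40),
                        np.full(40, 0.2), np.zeros(40, dtype=bool))
base = nr.solvent_baseline(solvent)
print(f"solvent PRE baseline: mean {base['mean']:.2f} 1/s, "
      f"flat profile: {base['flat']} (slope p = {base['slope_pvalue']:.2f})")
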