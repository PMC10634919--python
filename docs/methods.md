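# Methods

`lcdphase` packages the computational side of a self-association and
phase-separation study of a tyrosine-rich low-complexity domain (LCD): the
264-residue N-terminal LCD of EWS (EWSR1) is the motivating system, but
every routine is generic over sequences.  This note records the models, the
parameters that matter, the synthetic-data generators that make the package
testable without experimental data, and the numerical choices.

## Sequence analysis

A `ProteinSequence` is a one-letter string with an explicit numbering
offset (cloning scars and purification tags are simply excluded from the
string, so residue numbers match the construct's scheme).  The tyrosine
motif scan classifies *pairs* of tyrosines by spacing: YxY (positions i,
i+2) and YxxY (i, i+3); a tyrosine may belong to several pairs, and
tyrosines in no pair are "isolated".  Counting pairs rather than residues
matches how aromatic patterning is described in the LLPS literature
("all other tyrosines separated by three or more residues").

The bundled `examples/data/ews_lcd.fasta` holds UniProt Q01844 residues
1–264.  On this sequence the scan yields 37 tyrosines, exactly one YxY
pair at (170, 172), four YxxY pairs at (6,9), (18,21), (41,44), (124,127),
and a tyrosine-free stretch spanning residues 128–157 — the linker region
whose low stickiness shows up throughout the analyses.  Mutant construction
(`MutationSet`) validates the origin residue at every position, so a wrong
numbering convention fails loudly rather than silently shifting sites.

## Coarse-grained simulator (`cgsim`)

One bead per residue, in the style of hydropathy-scale (HPS) models with
the Urry scale:

* **Short range**: Ashbaugh–Hatch form on a Lennard-Jones 12-6 with
  arithmetic-mean σ and λ; for r ≤ 2^(1/6)σ the potential is LJ + (1−λ)ε
  (purely repulsive at λ=0), beyond it λ·LJ.  ε = 0.8368 kJ/mol,
  cutoff 2.0 nm.
* **Electrostatics**: Debye–Hückel screened Coulomb, εr = 80, cutoff
  3.5 nm, screening length from the ionic strength (default 100 mM,
  κ⁻¹ ≈ 0.96 nm at 300 K).  Asp/Glu −1, Lys/Arg +1, His neutral.
* **Bonds**: harmonic, r0 = 0.38 nm, k = 8368 kJ mol⁻¹ nm⁻²; bonded 1–2
  pairs are excluded from nonbonded terms.

All constants live in `cgsim/params.py` and are plain dictionaries —
editing the hydropathy scale or diameters requires no code changes.

**Integration** is a BAOAB Langevin splitting with per-bead friction
γᵢ = mᵢ/t_damp (a uniform velocity relaxation rate 1/t_damp).  Defaults
follow the reference slab protocol: 10 fs timestep, t_damp
= 1000 ps.  The weak default coupling doubles as the fastest-mixing choice
for slab runs (diffusion scales with t_damp in the overdamped limit);
thermostat-calibration checks use t_damp = 10 ps instead so the kinetic
temperature relaxes well within a short run.  The damping time affects
kinetics only, not the sampled ensemble.  Minimum-image periodicity acts
in all three
dimensions; stored coordinates are left *unwrapped*, so intramolecular
geometry needs no unwrapping step and density profiles wrap z at analysis
time.  The O(N²) force loop is numba-compiled; at the package's desk-scale
sizes (≤ ~10³ beads) this outperforms neighbor lists.

Initial configurations are self-avoiding random walks (slabs: all chains in
the central third of an elongated box) followed by a capped steepest-descent
minimization — random packing leaves steric overlaps whose energy would
otherwise heat a short weakly-damped run far above the target temperature.

**Desk-scale study conditions.** The full-scale protocol (100 chains of a
264-mer, 5 μs, 17.5×17.5×122.5 nm box) is reachable through the same API
but is not the test default.  The scaled-down conditions used by the tests
and the acceptance script are: 10 chains of a sticky 30-mer ("YYS"×10,
mean λ ≈ 0.79) in an 8×8×40 nm box, 3.5–5 ns of dynamics with the first
half discarded, with a strongly weakened "mutant" ("YSS"×10, two thirds of
the tyrosines replaced by serine — mirroring the multi-YS constructs that
essentially abolish phase separation).  Two initialization details matter
for short runs and are exposed as `build_slab` options: the initial layer
is packed into the central fifth of the box (a loose layer sheds satellite
droplets that take longer than the run to coalesce), and two chains are
seeded into the vapor so that the coexistence densities are approached
from both directions — condensation of the seeded chains for the sticky
sequence, net evaporation for the weakened one — instead of waiting for
rare activated evaporation events.  Under these conditions the sticky
sequence holds a dense slab at 300 K (density contrast ≫ 5:1), disperses
completely at 1000 K, and the weakened variant's saturation concentration
exceeds the sticky one's; the dilute phase holds of order one chain, so
Csat values carry counting noise of several mg/mL and only orderings and
flags are meaningful at this scale.

## NMR rate extraction (`nmr_rates`)

* **T1/T1ρ**: per-residue least squares of I(t) = I₀e^(−Rt), uncertainties
  from the fit covariance.  The printed delay sets (eight delays, 40–800 ms
  for T1; 1–201 ms for T1ρ) are the generator defaults.
* **R1ρ → R2**: the rotating-frame relation R1ρ = R1cos²θ + R2sin²θ with
  tilt angle θ = arctan(ω₁/Ω).  On resonance sin²θ = 1 and R1ρ = R2.
  Residues with sin²θ below a floor (default 0.05) are flagged unreliable
  rather than extrapolated.
* **hetNOE**: I_sat/I_unsat with first-order error propagation; negative
  values are legal and meaningful (fast backbone motion).
* **Two-point T2**: R = ln(I_Ta/I_Tb)/ΔT.  Non-positive intensities flag a
  broadened-out peak; negative rates are kept but flagged noise-dominated —
  the noise floor matters downstream and clamping would hide it.
* **PRE**: Γ₂ = R₂,para − R₂,dia on the diamagnetic residue set;
  uncertainties in quadrature; missing paramagnetic peaks flagged
  broadened-out with no number.  The solvent-PRE summary reports mean, sd
  and a linear-trend flatness test (slope consistent with zero at α=0.05).

The synthetic generator emits tables whose noiseless limit is *exactly*
invertible by the corresponding fit (round trips are asserted to 1e-9),
with multiplicative Gaussian noise and full seed determinism.  It emulates
peak-intensity tables only — no lineshapes, overlap, or assignment errors —
so passing tests certify the fitting machinery, not spectral processing.

## Relaxation from trajectories (`md_relax`)

Per residue, the unit N→H vector's second-Legendre autocorrelation
C(τ) = ⟨P₂(û(t)·û(t+τ))⟩ is averaged over all time origins within
non-overlapping blocks (default 100 ns for real trajectories) and then over
blocks, using an FFT expansion of (û·û′)² into six quadratic products.
C(0) = 1 per block by construction (per-block normalization).

C(t) is fitted to a₁e^(−t/τ₁) + a₂e^(−t/τ₂) with non-negative amplitudes.
Two numerical guards matter:

* the fit window ends where a 5-point running mean of the ACF first drops
  below 0.01 — a pure-noise tail otherwise rewards a spurious tiny-amplitude,
  enormous-τ component that corrupts J(0) and hence R2 by orders of
  magnitude;
* time constants are bounded by 5× the window.

Amplitudes are not renormalized after fitting (a tiny overshoot of a₁+a₂
above 1 is clipped).  The spectral density is the analytic transform
J(ω) = Σ aᵢτᵢ/(1+ω²τᵢ²), and rates follow the standard dipolar + CSA
expressions with the 0.1/0.05 prefactors on
d² = [(μ0/4π)ħγHγN/r³]², CSA terms (2/15)ωN²Δσ²J(ωN) for R1 and
(1/45)ωN²Δσ²[4J(0)+3J(ωN)] for R2, and the NOE referencing R1 through the
signed γH/γN ratio (γN < 0 makes fast-motion NOEs negative).  Defaults:
700.15 MHz, r_NH = 1.02 Å, Δσ = −163 ppm, all overridable.  Frequencies
enter J as magnitudes.  The test suite checks the implementation against an
independently coded oracle to 1e-9 across τc = 10 ps–100 ns and against
closed-form extreme-narrowing limits (R1 = R2; NOE → 1 + γH/2γN ≈ −3.93).

The synthetic rotor generator produces unit vectors under isotropic
rotational diffusion (analytic ACF e^(−6D_r τ)) and wraps them into
amide-bearing trajectories; per-residue D_r arrays create mobility
gradients for ordering tests.

## Conformation analysis (`conformation`)

* **Contacts**: any heavy-atom pair (every bead is heavy in CG) closer than
  0.6 nm; residue-pair counts sum over atom pairs, so long sidechains can
  contribute more contacts.  Intramolecular mode excludes |i−j| ≤ 1
  (configurable); intermolecular mode uses minimum-image distances.  Both
  cumulative and per-frame views are exposed, and the residue-type 20×20
  aggregation conserves the unordered grand total.
* **PRE proxy**: ⟨r⁻⁶⟩ over (label × target) heavy-atom pairs and frames,
  pairs beyond 3.5 nm contributing zero (not dropped — the choice is
  switchable), then normalized by the profile maximum.  The label residue
  itself is reported as 1 by convention (attachment site).  Replicas are
  averaged with SEM.
* **Compaction**: mass-weighted Rg per frame per chain; Rg-fluctuation
  correlation time at the 1/e crossing (linear interpolation); ⟨r_ij⟩ vs
  |i−j| with a log-log power-law fit over a configurable window
  (defaults 2..N/2); per-segment Rg distributions with a compactness
  ranking.  Wrapped input is detected via bonds longer than half the box
  and rejected with a request to unwrap.

## Phase analysis (`phase`)

Profiles are mass histograms along z converted to mg/mL
(1 amu/nm³ = 1.6605 mg/mL), with the first 1 μs (CG) or 200 ns (all-atom)
discarded by default and block errors over 4 blocks, all configurable.
Slab centering uses the mass-weighted circular mean of z, which is
deterministic, shift-only (chain continuity preserved) and idempotent
modulo the box.  Mass conservation (profile integral = total mass) is exact
by construction and asserted to 1e-6.

Coexistence densities come from a symmetric double-tanh interface fit
ρ(z) = C_dil + (C_den−C_dil)/2·[tanh((w/2−|z−z0|)/d)+1]; C_den is the
plateau, C_sat the far field, SEMs from per-block fits.  A point is flagged
single-phase when the fitted gap is within 2 block-SEMs of zero or below 5%
of the dense plateau.  A threshold-median "window average" estimator (bins
above 90% / below 10% of the span) provides an independent cross-check.

A note on block counts: the default is 4 blocks (matching the protocol the
package emulates), but the Monte-Carlo calibration of SEM coverage uses 8
blocks, because a ±2·SEM interval built from n blocks covers at the
t_{n−1} rate — ~86% for n = 4 even with exactly Gaussian block noise, and
~91% for n = 8.  This is a property of Student's t, not of the estimator.

Binodals fit the density gap to A(1−T/Tc)^β with β fixed at the 3D-Ising
value 0.325 (freeing β is an explicit flag) and the critical density via
the law of rectilinear diameters.

## Known limitations

* The CG model's absolute Csat values are model quantities in mg/mL; only
  orderings and temperature trends are meaningful at desk scale, and runs
  of a few ns sample few chain-exchange events, so dilute-phase statistics
  are coarse.
* The relaxation pipeline assumes the bi-exponential form captures the ACF
  within a block; no reweighting toward experimental timescales and no
  model-free (S², τe) analysis is attempted.
* The synthetic generators emulate idealized data (clean exponentials,
  multiplicative noise, isotropic rotors); passing tests validate the
  estimators under those conditions, not robustness to spectral artifacts
  or force-field error.
* The PRE proxy is a geometric stand-in for spin-label physics: no rotamer
  sampling of the label, no dynamics in the PRE rates.
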