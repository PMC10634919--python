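"""Back-calculating R1/R2/NOE from a trajectory with a mobility gradient.

Builds a synthetic amide-bearing trajectory whose N-H vectors tumble by
rotational diffusion, fast at the termini and slow in the core (a cartoon
of a chain with rigid center and floppy tails), then runs the full
pipeline: P2 autocorrelation -> bi-exponential fit -> spectral density ->
relaxation rates at 700.15 MHz.
"""

import numpy as np

from lcdphase import md_relax as mr

n_res = 15
# rotational diffusion coefficient per residue (1/ps): fast tails, slow core
d_r = 0.002 + 0.02 * np.exp(-((np.arange(n_res) - 0) / 3.0) ** 2) \
    + 0.02 * np.exp(-((np.arange(n_res) - (n_res - 1)) / 3.0) ** 2)

vectors = mr.rotational_diffusion_vectors(n_res, d_r, n_frames=6000,
                                          dt_ps=1.0, seed=11)
traj = mr.amide_trajectory_from_vectors(vectors, dt_ps=1.0)

profile = mr.trajectory_relaxation(traj, block_length_ps=2000.0)
data = profile.data

print(f"field: {profile.field_mhz} MHz, source: {profile.source}\n")
print(data[["R1", "R2", "NOE"]].round(3).to_string())
core = data["R2"].iloc[n_res // 2]
tail = data["R2"].iloc[0]
print(f"\ncore R2 = {core:.2f} 1/s vs terminal R2 = {tail:.2f} 1/s: "
      "slower tumbling (more interactions) raises transverse relaxation, "
      "exactly how dense-phase or contact-rich regions are recognized.")
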