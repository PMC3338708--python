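"""Folding kinetics: first passage times and the folding rate constant.

Independent trajectories start from fresh random coils at the melting
temperature and stop on first reaching the native state.  The unfolded
population decays as a single exponential for a two-state folder; the rate
k (in inverse MC steps) is minus the slope of ln Pu(t).
"""

import numpy as np

import latticego as lg

parent = lg.hamiltonian_cycle_path((3, 3, 2))
model = lg.GoModel.from_conformation(parent.conformation)
T = 0.60  # close to this toy's melting temperature

records = [
    lg.run_folding_trajectory(model, T, seed=i, max_steps=10**8)
    for i in range(300)
]
ens = lg.FPTEnsemble.from_trajectories(records, label="toy18")
print(f"{ens.n} folding events, {ens.n_censored} censored")
print(f"median first passage time: {np.median(ens.fpts):,.0f} MC steps")

est = lg.estimate_rate(ens)
print(f"folding rate k  = {est.k:.3e} per MC step")
print(f"ln k            = {est.ln_k:.2f}")
print(f"fit residual    = {est.residual_rms:.3f} (single-exponential if small)")
print(f"reliable        = {est.reliable}")
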