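"""Transition-state ensemble and transition-state network of one permutant.

TSE members satisfy two criteria at once: their energy lies at the barrier
peak of the free-energy profile, and their commitment probability Pfold is
within a band around 1/2.  The ensemble yields CO_TSE (contact order of
the formed native contacts), RMSD_TSE (structural spread around the native
state) and the TSN: the native contacts present in at least half of the
TSE members.
"""

import numpy as np

import latticego as lg

parent = lg.hamiltonian_cycle_path((3, 3, 2))
model = lg.GoModel.from_conformation(parent.conformation)

# thermodynamics first: Tm and the barrier location
temps = np.geomspace(0.3, 1.3, 16)
pt = lg.PTConfig(temperatures=temps, n_sweeps=5000, steps_per_sweep=200,
                 burn_sweeps=500, seed=5)
res = lg.parallel_tempering(model, pt)
dos = lg.wham(temps, res.histograms(-model.n_native, 0), np.arange(-model.n_native, 1))
tm = lg.melting_temperature(dos, 0.3, 1.3)
barrier = lg.barrier_analysis(dos.free_energy_profile(tm))
print(f"Tm = {tm:.3f}, barrier at E = {barrier.e_barrier}")

# harvest barrier-window snapshots from kinetic runs at Tm
records = [
    lg.run_folding_trajectory(
        model, tm, seed=1000 + i, max_steps=10**8,
        snapshot_stride=300,
        snapshot_window=(barrier.e_barrier - 1, barrier.e_barrier + 1),
    )
    for i in range(150)
]
candidates = lg.harvest_candidates(records, barrier, window=1)[:60]
print(f"{len(candidates)} barrier-window candidates harvested")

pfolds = [
    lg.pfold(c.coords, model, tm, n_trials=100, seed=i, unfold_threshold=0.2)
    for i, c in enumerate(candidates)
]
tse = lg.select_tse(candidates, pfolds, temperature=tm, band=0.1, min_size=10)
print(f"TSE size = {tse.size} (|Pfold - 0.5| <= 0.1)")

co = lg.contact_order(model.native_contacts)
print(f"native CO = {co:.2f}")
print(f"CO_TSE    = {lg.co_tse(tse, model):.2f}  (typically below the native CO)")
print(f"RMSD_TSE  = {lg.rmsd_tse(tse, model):.2f} lattice units")

tsn = lg.transition_state_network(tse, model, p_star=0.5)
print(f"TSN: n = {tsn.n} contacts, CO_TSN = "
      f"{'undefined' if tsn.co_tsn is None else round(tsn.co_tsn, 2)}")
print(f"contact-range spectrum: {dict(sorted(tsn.range_spectrum.items()))}")
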