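"""Shared fixtures: toy systems, exact-enumeration references and
moderately expensive sampled objects reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import latticego as lg
from latticego import _kernels as K

import oracles


@pytest.fixture(scope="session")
def toy8_parent() -> lg.ParentStructure:
    return lg.hamiltonian_cycle_path((2, 2, 2))


@pytest.fixture(scope="session")
def toy8_model(toy8_parent) -> lg.GoModel:
    return lg.GoModel.from_conformation(toy8_parent.conformation)


@pytest.fixture(scope="session")
def toy18_parent() -> lg.ParentStructure:
    return lg.hamiltonian_cycle_path((3, 3, 2))


@pytest.fixture(scope="session")
def toy18_model(toy18_parent) -> lg.GoModel:
    return lg.GoModel.from_conformation(toy18_parent.conformation)


@pytest.fixture(scope="session")
def parent48() -> lg.ParentStructure:
    """A maximally compact 48-mer from homopolymer collapse."""
    return lg.collapse_homopolymer(48, (3, 4, 4), seed=1)


@pytest.fixture(scope="session")
def saw8_level_counts(toy8_model) -> dict:
    """Exact chain counts per Go energy level for the N=8 toy, from
    exhaustive enumeration of all self-avoiding 8-bead chains."""
    native_pairs = set(toy8_model.native_contacts.contacts)
    return oracles.exact_level_counts(8, native_pairs)


@pytest.fixture(scope="session")
def toy8_long_run(toy8_model):
    """Long single-temperature Metropolis run of the N=8 toy at T = 0.7:
    energy samples (stride 151) split into blocks for error estimation."""
    T = 0.7
    conf = lg.random_coil(8, seed=123)
    st = lg.mc.ChainState.for_model(conf, toy8_model, seed=321)
    stride = 151
    n_samples = 60_000
    e = np.empty(n_samples, dtype=np.int16)
    K.run_equilibrium(st.coords, st.grid, st.nat, st.nformed, T, stride * n_samples, st.rng, e, stride)
    return T, e


@pytest.fixture(scope="session")
def toy8_pt(toy8_model):
    """Parallel-tempering sampling of the N=8 toy over a wide ladder."""
    temps = np.geomspace(0.25, 1.4, 12)
    cfg = lg.PTConfig(
        temperatures=temps, n_sweeps=6000, steps_per_sweep=100,
        burn_sweeps=500, seed=7,
    )
    return temps, lg.parallel_tempering(toy8_model, cfg)


@pytest.fixture(scope="session")
def toy8_dos(toy8_model, toy8_pt):
    temps, res = toy8_pt
    hist = res.histograms(-toy8_model.n_native, 0)
    return lg.wham(temps, hist, np.arange(-toy8_model.n_native, 1))


@pytest.fixture(scope="session")
def toy18_dos(toy18_model):
    temps = np.geomspace(0.3, 1.3, 16)
    cfg = lg.PTConfig(
        temperatures=temps, n_sweeps=5000, steps_per_sweep=200,
        burn_sweeps=500, seed=5,
    )
    res = lg.parallel_tempering(toy18_model, cfg)
    hist = res.histograms(-toy18_model.n_native, 0)
    dos = lg.wham(temps, hist, np.arange(-toy18_model.n_native, 1))
    return dos


@pytest.fixture(scope="session")
def exp_fpt_recovery():
    """Rate-recovery simulation: 200 replications of n=500 synthetic
    exponential first passage times at k0 = 1e-5, fitted by the survival
    pipeline.  Returns (k0, array of estimates)."""
    k0 = 1e-5
    rng = np.random.default_rng(2024)
    ests = []
    for _ in range(200):
        fpts = np.ceil(rng.exponential(1.0 / k0, size=500)).astype(np.int64)
        ens = lg.FPTEnsemble(fpts=fpts, n_censored=0, temperature=1.0)
        ests.append(lg.estimate_rate(ens).k)
    return k0, np.array(ests)
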