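"""End-to-end study driver and family-level statistics.

Ties the pipeline together for one circular-permutant family: equilibrium
sampling (parallel tempering) -> WHAM -> Tm, free-energy profile and
barrier -> folding kinetics at Tm -> rate fit -> transition-state ensemble
and network -> a per-permutant table and the correlation battery
(ln k vs activation free energy, ln k vs CO, ln k vs CO_TSE, CO vs CO_TSE,
CO vs CO_TSN, TSN size vs CO), with a high-CO split variant of each fit.

Permutants whose free-energy profile is not two-state are kept in the
table but excluded from every regression.  All tunables live in
``StudyConfig`` and a master seed deterministically spawns every
sub-stream, so a full study is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import FPTEnsemble, estimate_rate
from .lattice import GoModel, LatticeConformation
from .mc import PTConfig, _spawn_seed, parallel_tempering, run_folding_trajectory
from .structgen import (
    CPFamily,
    ParentStructure,
    build_family,
    collapse_homopolymer,
    contact_order,
    hamiltonian_cycle_path,
    max_contacts,
    serpentine_path,
)
from .thermo import barrier_analysis, melting_temperature, wham
from .tse import (
    co_tse,
    harvest_candidates,
    pfold,
    rmsd_tse,
    select_tse,
    transition_state_network,
)

__all__ = [
    "StudyConfig",
    "CPResult",
    "linear_fit",
    "LinearFit",
    "analyze_cp",
    "run_family_study",
    "build_family_report",
    "generate_fixtures",
    "Fixture",
]

log = logging.getLogger("latticego")


@dataclass(frozen=True)
class StudyConfig:
    """All tunables of a family study (reduced units throughout, kB = 1).

    Defaults are the full study conditions: ~50 replica temperatures, 500
    kinetic trajectories per permutant, Pfold from 100 trials (binomial SE
    <= 0.05 at p = 1/2), acceptance band |Pfold - 1/2| <= 0.1, unfold
    threshold Q <= 0.2, barrier harvest window of +/- 1 energy unit, TSN
    threshold p* = 0.5 and the CO > 18.5 split for the high-CO regime.
    Scaled-down runs override sampling sizes, never definitions.
    """

    # parallel tempering / thermodynamics
    t_lo: float = 0.45
    t_hi: float = 1.6
    n_temps: int = 50
    pt_sweeps: int = 4000
    pt_steps_per_sweep: int = 500
    pt_burn_sweeps: int = 400
    pt_sample_stride: int = 1
    intermediate_depth: float = 0.5
    # kinetics at Tm
    n_trajectories: int = 500
    max_steps: int = 10**9
    snapshot_stride: int = 1000
    max_censored_fraction: float = 0.05
    # transition-state ensemble
    harvest_window: int = 1
    max_candidates: int = 200
    pfold_trials: int = 100
    pfold_max_steps: int = 10**7
    unfold_threshold: float = 0.2
    pfold_band: float = 0.10
    pfold_se_max: float = 0.05
    tse_min_size: int = 100
    tsn_p_star: float = 0.5
    run_tse: bool = True
    # reporting
    co_split: float = 18.5

    def replace(self, **kw) -> "StudyConfig":
        return replace(self, **kw)


@dataclass
class CPResult:
    """Everything measured for one circular permutant."""

    label: str
    k_cut: int
    co: float
    n_contacts: int
    tm: float = np.nan
    dg_fold: float = np.nan
    dg_activation: float = np.nan       # reduced units at Tm
    dg_activation_thermal: float = np.nan  # units of Tm
    e_barrier: float = np.nan
    two_state: bool | None = None
    intermediate_energy: float = np.nan
    rate: float = np.nan
    ln_k: float = np.nan
    fit_residual: float = np.nan
    rate_reliable: bool | None = None
    n_folded: int = 0
    n_censored: int = 0
    tse_size: int = 0
    co_tse: float = np.nan
    rmsd_tse: float = np.nan
    n_tsn: int = 0
    co_tsn: float = np.nan
    max_contact_range: float = np.nan
    status: str = "ok"

    def as_row(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    n_points: int


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares with the closed-form Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_points=int(x.size),
    )


def _thermo_stage(model: GoModel, cfg: StudyConfig, seed: int):
    temps = np.geomspace(cfg.t_lo, cfg.t_hi, cfg.n_temps)
    pt = PTConfig(
        temperatures=temps,
        n_sweeps=cfg.pt_sweeps,
        steps_per_sweep=cfg.pt_steps_per_sweep,
        burn_sweeps=cfg.pt_burn_sweeps,
        sample_stride=cfg.pt_sample_stride,
        seed=seed,
        start="mixed",
    )
    result = parallel_tempering(model, pt)
    e_grid = np.arange(-model.n_native, 1)
    hist = result.histograms(-model.n_native, 0)
    dos = wham(temps, hist, e_grid)
    tm = melting_temperature(dos, cfg.t_lo, cfg.t_hi)
    profile = dos.free_energy_profile(tm)
    barrier = barrier_analysis(profile, intermediate_depth=cfg.intermediate_depth)
    return dos, tm, profile, barrier


def _kinetics_stage(model: GoModel, tm: float, barrier, cfg: StudyConfig, seed: int):
    records = []
    window = (barrier.e_barrier - cfg.harvest_window, barrier.e_barrier + cfg.harvest_window)
    for i in range(cfg.n_trajectories):
        rec = run_folding_trajectory(
            model,
            tm,
            seed=_spawn_seed(seed, 11, i),
            max_steps=cfg.max_steps,
            snapshot_stride=cfg.snapshot_stride,
            snapshot_window=window,
            max_snapshots=max(2, 4 * cfg.max_candidates // cfg.n_trajectories),
        )
        records.append(rec)
    ens = FPTEnsemble.from_trajectories(records)
    return records, ens


def _tse_stage(model: GoModel, tm: float, barrier, records, cfg: StudyConfig, seed: int):
    candidates = harvest_candidates(records, barrier, window=cfg.harvest_window)
    if len(candidates) > cfg.max_candidates:
        rng = np.random.default_rng(_spawn_seed(seed, 13))
        keep = rng.choice(len(candidates), size=cfg.max_candidates, replace=False)
        candidates = [candidates[i] for i in sorted(keep)]
    pfolds = [
        pfold(
            c.coords,
            model,
            tm,
            n_trials=cfg.pfold_trials,
            seed=_spawn_seed(seed, 17, i),
            unfold_threshold=cfg.unfold_threshold,
            max_steps=cfg.pfold_max_steps,
        )
        for i, c in enumerate(candidates)
    ]
    record = select_tse(
        candidates,
        pfolds,
        temperature=tm,
        band=cfg.pfold_band,
        se_max=cfg.pfold_se_max,
        min_size=cfg.tse_min_size,
    )
    return record


def analyze_cp(
    model: GoModel,
    label: str,
    k_cut: int,
    cfg: StudyConfig,
    seed: int,
) -> CPResult:
    """Full per-permutant pipeline; stage failures leave explicit NaN gaps
    (and a status note) rather than aborting the family."""
    res = CPResult(
        label=label,
        k_cut=k_cut,
        co=contact_order(model.native_contacts),
        n_contacts=model.n_native,
    )
    try:
        dos, tm, profile, barrier = _thermo_stage(model, cfg, _spawn_seed(seed, 1))
    except Exception as exc:  # noqa: BLE001 - reported in the table
        res.status = f"thermo failed: {exc}"
        log.warning("%s: %s", label, res.status)
        return res
    res.tm = tm
    res.dg_fold = barrier.dg_fold
    res.dg_activation = barrier.dg_activation
    res.dg_activation_thermal = barrier.dg_activation_thermal
    res.e_barrier = barrier.e_barrier
    res.two_state = barrier.two_state
    res.intermediate_energy = (
        np.nan if barrier.intermediate_energy is None else barrier.intermediate_energy
    )

    try:
        records, ens = _kinetics_stage(model, tm, barrier, cfg, _spawn_seed(seed, 2))
        res.n_folded = ens.n
        res.n_censored = ens.n_censored
        est = estimate_rate(ens, max_censored_fraction=cfg.max_censored_fraction)
        res.rate = est.k
        res.ln_k = est.ln_k
        res.fit_residual = est.residual_rms
        res.rate_reliable = est.reliable
    except Exception as exc:  # noqa: BLE001
        res.status = f"kinetics failed: {exc}"
        log.warning("%s: %s", label, res.status)
        return res

    if not cfg.run_tse:
        res.status = "ok"
        return res
    try:
        record = _tse_stage(model, tm, barrier, records, cfg, _spawn_seed(seed, 3))
        res.tse_size = record.size
        res.co_tse = co_tse(record, model)
        res.rmsd_tse = rmsd_tse(record, model)
        tsn = transition_state_network(record, model, p_star=cfg.tsn_p_star)
        res.n_tsn = tsn.n
        res.co_tsn = np.nan if tsn.co_tsn is None else tsn.co_tsn
        res.max_contact_range = (
            np.nan if tsn.max_contact_range is None else tsn.max_contact_range
        )
    except Exception as exc:  # noqa: BLE001
        res.status = f"tse failed: {exc}"
        log.warning("%s: %s", label, res.status)
    return res


def run_family_study(
    parent: ParentStructure,
    cfg: StudyConfig,
    seed: int,
    ks: list | None = None,
) -> pd.DataFrame:
    """Analyze the circular permutants of one parent (all N by default, or
    the subset ``ks``) and return the per-permutant FamilyTable."""
    family = build_family(parent)
    labels = family.labels()
    if ks is None:
        ks = list(range(family.n_members))
    rows = []
    for k in ks:
        model = family.models[k]
        log.info("analyzing %s (CO=%.2f)", labels[k], family.co_values[k])
        res = analyze_cp(model, labels[k], k, cfg, seed=_spawn_seed(seed, 100, k))
        rows.append(res.as_row())
    return pd.DataFrame(rows)


_PAIRS = [
    ("ln_k", "dg_activation_thermal"),
    ("ln_k", "co"),
    ("ln_k", "co_tse"),
    ("co", "co_tse"),
    ("co", "co_tsn"),
    ("co", "n_tsn"),
]


def build_family_report(table: pd.DataFrame, co_split: float = 18.5) -> pd.DataFrame:
    """Correlation battery over the two-state permutants of a family table.

    For each (y, x) pair the slope, intercept, Pearson r and point count
    are reported for the full two-state set and for the subset with
    CO <= ``co_split`` (the high-CO regime removed).  Note the pairs are
    reported as (y, x): e.g. ln k regressed on activation free energy.
    """
    ok = table[(table["two_state"] == True) & (table["status"] == "ok")]  # noqa: E712
    rows = []
    for y, x in _PAIRS:
        for subset, name in ((ok, "all_two_state"), (ok[ok["co"] <= co_split], f"co<={co_split}")):
            sub = subset[[x, y]].dropna()
            row = {"y": y, "x": x, "subset": name, "n_points": len(sub)}
            try:
                fit = linear_fit(sub[x], sub[y])
                row.update(slope=fit.slope, intercept=fit.intercept, r=fit.r)
            except ValueError as exc:
                row.update(slope=np.nan, intercept=np.nan, r=np.nan, note=str(exc))
            rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["n_excluded_not_two_state"] = int(
        ((table["two_state"] == False) | (table["status"] != "ok")).sum()  # noqa: E712
    )
    return report


@dataclass(frozen=True)
class Fixture:
    """A toy system with its analytically known contact count."""

    name: str
    box: tuple
    expected_contacts: int
    parent: ParentStructure | None
    conformation: LatticeConformation
    supports_permutation: bool


def generate_fixtures(size: str = "small", seed: int = 0) -> dict:
    """Deterministic toy systems for tests and examples.

    ``small`` emits the N=8 cube; ``medium`` adds N=18 (3x3x2) and N=27
    (3x3x3).  Contact counts follow the lattice edge-count law
    (a-1)bc + a(b-1)c + ab(c-1) - (N-1).  The all-odd 3x3x3 box cannot
    display adjacent termini (bipartite parity), so it is emitted as a
    compact conformation for contact counting only.
    """
    if size not in ("small", "medium"):
        raise ValueError("size must be 'small' or 'medium'")
    boxes = [(2, 2, 2)] if size == "small" else [(2, 2, 2), (3, 3, 2), (3, 3, 3)]
    out = {}
    for box in boxes:
        n = box[0] * box[1] * box[2]
        expected = max_contacts(box)
        all_odd = all(d % 2 for d in box)
        if all_odd:
            conf = serpentine_path(box)
            parent = None
        else:
            try:
                parent = collapse_homopolymer(n, box, seed=_spawn_seed(seed, n), label=f"fixture_n{n}")
            except RuntimeError:
                parent = hamiltonian_cycle_path(box)
            conf = parent.conformation
        out[n] = Fixture(
            name=f"n{n}",
            box=box,
            expected_contacts=expected,
            parent=parent,
            conformation=conf,
            supports_permutation=parent is not None,
        )
    return out
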