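"""Transition-state ensembles (TSE) and the transition-state network (TSN).

A TSE member must satisfy two independent criteria: its energy sits at the
peak of the free-energy profile (harvested from kinetic trajectory
snapshots inside a window around the barrier energy), and its commitment
probability Pfold — the chance that trajectories started from it reach the
native state before unfolding — is close to 1/2.  The ensemble is then
summarized by CO_TSE (mean contact order of the *formed native* contacts
of its members), RMSD_TSE (mean optimal-superposition RMSD to the native
structure, lattice units) and the TSN: the set of native contacts present
in the TSE with frequency at least p*, with its own mean separation CO_TSN
and contact-range spectrum.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .lattice import GoModel, LatticeConformation, compute_contacts
from .mc import _spawn_seed, run_folding_trajectory
from .thermo import BarrierSummary

__all__ = [
    "TSECandidate",
    "PfoldEstimate",
    "TSERecord",
    "TSN",
    "harvest_candidates",
    "pfold",
    "select_tse",
    "co_tse",
    "rmsd_to_native",
    "transition_state_network",
]


@dataclass(frozen=True)
class TSECandidate:
    """A barrier-window snapshot with provenance (trajectory and MC step)."""

    coords: np.ndarray
    energy: int
    run: int = -1
    step: int = -1


@dataclass(frozen=True)
class PfoldEstimate:
    p: float
    se: float
    n_fold: int
    n_unfold: int
    n_indeterminate: int
    flagged: bool

    @property
    def n_trials(self) -> int:
        return self.n_fold + self.n_unfold + self.n_indeterminate


@dataclass(frozen=True)
class TSN:
    contacts: frozenset
    chain_length: int

    @property
    def n(self) -> int:
        return len(self.contacts)

    @property
    def co_tsn(self) -> float | None:
        """Mean sequence separation of the network, undefined when empty."""
        if not self.contacts:
            return None
        return float(np.mean([j - i for i, j in self.contacts]))

    @property
    def range_spectrum(self) -> Counter:
        """Multiset of contact ranges |i - j| in the network."""
        return Counter(j - i for i, j in self.contacts)

    @property
    def max_contact_range(self) -> int | None:
        if not self.contacts:
            return None
        return max(j - i for i, j in self.contacts)


@dataclass
class TSERecord:
    """Pfold ~ 1/2, barrier-energy conformations of one circular permutant."""

    members: list
    pfolds: list
    temperature: float
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.members])


def harvest_candidates(
    records: list,
    barrier: BarrierSummary,
    window: int = 1,
) -> list:
    """Deduplicated trajectory snapshots with energy within ``window``
    reduced units of the barrier peak, keeping (run, step) provenance."""
    lo, hi = barrier.e_barrier - window, barrier.e_barrier + window
    out: list[TSECandidate] = []
    seen: set[bytes] = set()
    for run_id, rec in enumerate(records):
        for s in range(rec.snapshots.shape[0]):
            e = int(rec.snapshot_energies[s])
            if not (lo <= e <= hi):
                continue
            coords = rec.snapshots[s]
            key = coords.tobytes()
            if key in seen:
                continue
            seen.add(key)
            step = int(rec.snapshot_steps[s]) if rec.snapshot_steps.size else -1
            out.append(TSECandidate(coords=coords.copy(), energy=e, run=run_id, step=step))
    if not out:
        raise ValueError(
            f"no snapshot found in the barrier window [{lo}, {hi}]; "
            "use a denser snapshot stride or a wider window"
        )
    return out


def pfold(
    conf: LatticeConformation | np.ndarray,
    model: GoModel,
    T: float,
    n_trials: int = 100,
    seed: int = 0,
    unfold_threshold: float = 0.2,
    max_steps: int = 10**7,
    max_indeterminate_fraction: float = 0.10,
) -> PfoldEstimate:
    """Commitment probability by direct trial trajectories.

    Each of ``n_trials`` independent runs starts from ``conf`` at
    temperature T and terminates 'fold' on reaching Q = 1 or 'unfold' on
    dropping to Q <= unfold_threshold.  Returns the fold fraction with its
    binomial standard error; trials hitting ``max_steps`` count as
    indeterminate and flag the estimate beyond a 10% share.
    """
    if not isinstance(conf, LatticeConformation):
        conf = LatticeConformation(np.asarray(conf, dtype=np.int64))
    if not (0.0 < unfold_threshold < 1.0):
        raise ValueError("unfold_threshold must be in (0, 1)")
    n_fold = n_unfold = n_indet = 0
    for trial in range(n_trials):
        rec = run_folding_trajectory(
            model,
            T,
            seed=_spawn_seed(seed, 7, trial),
            max_steps=max_steps,
            start=conf,
            unfold_threshold=unfold_threshold,
        )
        if rec.reached:
            n_fold += 1
        elif rec.unfolded:
            n_unfold += 1
        else:
            n_indet += 1
    n_done = n_fold + n_unfold
    p = n_fold / n_done if n_done else float("nan")
    se = float(np.sqrt(p * (1 - p) / n_done)) if n_done else float("nan")
    return PfoldEstimate(
        p=p,
        se=se,
        n_fold=n_fold,
        n_unfold=n_unfold,
        n_indeterminate=n_indet,
        flagged=n_indet > max_indeterminate_fraction * n_trials,
    )


def select_tse(
    candidates: list,
    pfolds: list,
    temperature: float,
    band: float = 0.1,
    se_max: float = 0.05,
    min_size: int = 50,
    label: str = "",
) -> TSERecord:
    """TSE = candidates with |Pfold - 1/2| <= band, standard error <=
    ``se_max`` and an unflagged estimate.  Errors out when empty (with the
    Pfold distribution for diagnosis), warns below ``min_size``."""
    if len(candidates) != len(pfolds):
        raise ValueError("candidates and pfold results differ in length")
    members, kept = [], []
    for cand, pf in zip(candidates, pfolds):
        if pf.flagged or not np.isfinite(pf.p):
            continue
        if abs(pf.p - 0.5) <= band and pf.se <= se_max:
            members.append(cand)
            kept.append(pf)
    if not members:
        ps = np.array([pf.p for pf in pfolds if np.isfinite(pf.p)])
        qs = np.percentile(ps, [0, 25, 50, 75, 100]) if ps.size else []
        raise ValueError(
            f"empty TSE: no candidate within |Pfold - 0.5| <= {band}; "
            f"Pfold quartiles of {ps.size} candidates: {np.round(qs, 3)}"
        )
    if len(members) < min_size:
        warnings.warn(
            f"TSE has only {len(members)} members (< {min_size}); "
            "consider harvesting more candidates",
            stacklevel=2,
        )
    return TSERecord(members=members, pfolds=kept, temperature=temperature, label=label)


def _formed_native_contacts(coords: np.ndarray, model: GoModel) -> frozenset:
    formed = compute_contacts(LatticeConformation(coords))
    return formed.contacts & model.native_contacts.contacts


def co_tse(tse: TSERecord, model: GoModel) -> float:
    """Ensemble-average contact order over each member's formed native
    contacts (members with none are excluded with a warning)."""
    values = []
    skipped = 0
    for m in tse.members:
        formed = _formed_native_contacts(m.coords, model)
        if not formed:
            skipped += 1
            continue
        values.append(float(np.mean([j - i for i, j in formed])))
    if skipped:
        warnings.warn(f"{skipped} TSE members had no formed native contact", stacklevel=2)
    if not values:
        raise ValueError("no TSE member with formed native contacts")
    return float(np.mean(values))


def rmsd_to_native(
    conf: LatticeConformation | np.ndarray, native: LatticeConformation | np.ndarray
) -> float:
    """Minimum RMSD over translations and proper rotations (Kabsch
    superposition; reflections excluded), in lattice units."""
    p = conf.coords if isinstance(conf, LatticeConformation) else np.asarray(conf)
    q = native.coords if isinstance(native, LatticeConformation) else np.asarray(native)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    p = p.astype(float) - p.mean(axis=0)
    q = q.astype(float) - q.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = p @ r.T - q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_tse(tse: TSERecord, model: GoModel) -> float:
    """Ensemble-average RMSD of TSE members to the native structure."""
    if model.native_conformation is None:
        raise ValueError("model carries no native conformation")
    return float(
        np.mean([rmsd_to_native(m.coords, model.native_conformation) for m in tse.members])
    )


def contact_frequencies(tse: TSERecord, model: GoModel) -> dict:
    """Occurrence frequency of every native contact across TSE members."""
    if tse.size == 0:
        raise ValueError("empty TSE")
    counts: Counter = Counter()
    for m in tse.members:
        counts.update(_formed_native_contacts(m.coords, model))
    return {c: counts.get(c, 0) / tse.size for c in model.native_contacts.contacts}


def transition_state_network(tse: TSERecord, model: GoModel, p_star: float = 0.5) -> TSN:
    """Native contacts present in the TSE with frequency >= p*; monotone
    shrinking in p* and always a subset of the native map."""
    freqs = contact_frequencies(tse, model)
    members = frozenset(c for c, f in freqs.items() if f >= p_star)
    return TSN(contacts=members, chain_length=model.chain_length)


def tse_report_row(
    label: str,
    tse: TSERecord,
    model: GoModel,
    tsn: TSN,
    p_star: float,
    q_u: float,
    window: int,
) -> dict:
    """One TSE/TSN report row for a permutant, echoing the thresholds used."""
    from .structgen import contact_order

    return {
        "label": label,
        "tse_size": tse.size,
        "CO": contact_order(model.native_contacts),
        "CO_TSE": co_tse(tse, model),
        "RMSD_TSE": rmsd_tse(tse, model),
        "n_TSN": tsn.n,
        "CO_TSN": tsn.co_tsn,
        "max_contact_range": tsn.max_contact_range,
        "p_star": p_star,
        "q_u": q_u,
        "window": window,
    }


def write_range_spectrum(tsn: TSN, path) -> None:
    """TSN contact-range spectrum as (separation, count) rows."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["separation", "count"])
        for sep in sorted(tsn.range_spectrum):
            w.writerow([sep, tsn.range_spectrum[sep]])
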