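"""Folding rates from first-passage-time (FPT) ensembles.

Each trajectory contributes the MC step count at which the native state was
first reached.  The unfolded-population survival curve Pu(t) — the fraction
of trajectories not yet folded at time t — decays as a single exponential
for a two-state folder, so the folding rate k is obtained as minus the
slope of a weighted linear fit of ln Pu(t).  Rates are in inverse MC steps;
only comparisons within one study are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mc import TrajectoryRecord

__all__ = [
    "FPTEnsemble",
    "RateEstimate",
    "survival_curve",
    "fit_single_exponential",
    "estimate_rate",
]


@dataclass(frozen=True)
class FPTEnsemble:
    """First passage times of one circular permutant at one temperature.

    Censored trajectories (max_steps exhausted) are counted, never silently
    dropped; they are excluded from the survival fit and make the rate
    unreliable when they exceed ``max_censored_fraction`` downstream.
    """

    fpts: np.ndarray
    n_censored: int
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.fpts, dtype=np.int64)
        if arr.size and arr.min() <= 0:
            raise ValueError("first passage times must be positive")
        object.__setattr__(self, "fpts", arr)

    @property
    def n(self) -> int:
        return int(self.fpts.size)

    @property
    def censored_fraction(self) -> float:
        total = self.n + self.n_censored
        return self.n_censored / total if total else 0.0

    @classmethod
    def from_trajectories(
        cls, records: list, label: str = ""
    ) -> "FPTEnsemble":
        reached = [r.first_passage_time for r in records if r.reached]
        censored = sum(1 for r in records if not r.reached)
        temp = records[0].temperature if records else float("nan")
        return cls(np.array(reached, dtype=np.int64), censored, temp, label)


@dataclass(frozen=True)
class RateEstimate:
    k: float
    residual_rms: float
    n_used: int
    n_points: int
    reliable: bool = True

    @property
    def ln_k(self) -> float:
        return float(np.log(self.k))


def survival_curve(
    ensemble: FPTEnsemble, n_points: int = 80, min_events: int = 50
):
    """Unfolded-population survival Pu(t) on a logarithmically spaced time
    grid: Pu(t) = fraction of (uncensored) trajectories with FPT > t."""
    fpts = ensemble.fpts
    if fpts.size < min_events:
        raise ValueError(f"only {fpts.size} folding events; need >= {min_events}")
    t_grid = np.unique(
        np.concatenate(
            [
                [0],  # Pu(0) = 1 by construction
                np.round(np.geomspace(max(fpts.min(), 1), fpts.max(), n_points)).astype(np.int64),
            ]
        )
    )
    sorted_fpts = np.sort(fpts)
    pu = 1.0 - np.searchsorted(sorted_fpts, t_grid, side="right") / fpts.size
    return t_grid, pu


def fit_single_exponential(
    t: np.ndarray,
    pu: np.ndarray,
    n_trajectories: int,
    window: tuple = (0.05, 0.95),
    residual_threshold: float = 0.10,
    min_points: int = 5,
) -> RateEstimate:
    """Weighted least-squares fit of ln Pu(t) = -k t + c.

    Points with Pu inside ``window`` enter the fit, weighted by the inverse
    delta-method variance of ln Pu under binomial sampling,
    Var[ln Pu] ~ (1 - Pu) / (n Pu).  The weighted RMS residual is reported:
    values above ``residual_threshold`` flag visibly non-exponential decay
    (e.g. a rate mixture) via ``reliable=False``.
    """
    t = np.asarray(t, dtype=float)
    pu = np.asarray(pu, dtype=float)
    lo, hi = window
    m = (pu >= lo) & (pu <= hi)
    if m.sum() < min_points:
        raise ValueError(f"only {int(m.sum())} usable points in Pu window {window}")
    x = t[m]
    y = np.log(pu[m])
    w = n_trajectories * pu[m] / (1.0 - pu[m])
    wx = np.average(x, weights=w)
    wy = np.average(y, weights=w)
    cov = np.average((x - wx) * (y - wy), weights=w)
    var = np.average((x - wx) ** 2, weights=w)
    if var == 0:
        raise ValueError("degenerate time grid")
    slope = cov / var
    if slope >= 0:
        raise ValueError(f"non-negative slope {slope:g}: no measurable decay")
    resid = y - (wy + slope * (x - wx))
    resid_rms = float(np.sqrt(np.average(resid**2, weights=w)))
    return RateEstimate(
        k=float(-slope),
        residual_rms=resid_rms,
        n_used=int(n_trajectories),
        n_points=int(m.sum()),
        reliable=resid_rms <= residual_threshold,
    )


def estimate_rate(
    ensemble: FPTEnsemble,
    window: tuple = (0.05, 0.95),
    max_censored_fraction: float = 0.05,
    **fit_kwargs,
) -> RateEstimate:
    """Survival curve + exponential fit in one step, applying the censoring
    policy: censored trajectories are excluded from the fit and the rate is
    flagged unreliable when they exceed ``max_censored_fraction``."""
    t, pu = survival_curve(ensemble)
    est = fit_single_exponential(t, pu, ensemble.n, window=window, **fit_kwargs)
    if ensemble.censored_fraction > max_censored_fraction:
        est = RateEstimate(
            k=est.k,
            residual_rms=est.residual_rms,
            n_used=est.n_used,
            n_points=est.n_points,
            reliable=False,
        )
    return est


def write_kinetics_summary(entries, path) -> None:
    """Family kinetics CSV: one row (label, n_trajectories, n_censored, k,
    ln_k, fit_residual) per (ensemble, estimate) pair."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "n_trajectories", "n_censored", "k", "ln_k", "fit_residual"])
        for ens, est in entries:
            w.writerow([ens.label, ens.n, ens.n_censored, est.k, est.ln_k, est.residual_rms])
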