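"""Folding thermodynamics on the energy coordinate.

The Go energy is an integer, so the energy coordinate is a discrete grid
(bin width one reduced unit) and all equilibrium information is carried by
per-temperature integer-energy histograms.  The weighted histogram analysis
method (WHAM) combines those into a density-of-states estimate
``Omega(E)``, from which free-energy profiles ``F(E; T) = E - T ln Omega``
(kB = 1, additive constant arbitrary), reweighted averages, heat-capacity
curves and the melting temperature Tm (heat-capacity peak) all follow.

Free-energy profiles are classified as two-state (folded and unfolded
basins separated by one barrier) or not (an extra post-barrier intermediate
minimum with its own barrier above a depth threshold); non-two-state
permutants are excluded from family-level regressions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "HeatCapacityCurve",
    "DensityOfStates",
    "FreeEnergyProfile",
    "BarrierSummary",
    "heat_capacity",
    "wham",
    "barrier_analysis",
    "melting_temperature",
]


@dataclass(frozen=True)
class HeatCapacityCurve:
    temperatures: np.ndarray
    cv: np.ndarray
    tm: float


@dataclass(frozen=True)
class FreeEnergyProfile:
    """F(E) on the integer energy grid at one temperature (constant chosen
    so the minimum is zero); NaN where the energy was never sampled."""

    temperature: float
    energies: np.ndarray
    f: np.ndarray

    def shift(self, const: float) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.temperature, self.energies, self.f + const)


@dataclass(frozen=True)
class BarrierSummary:
    """Barrier geometry of a free-energy profile (all in reduced units at
    the profile's temperature)."""

    temperature: float
    e_folded: int
    e_unfolded: int
    e_barrier: int
    dg_fold: float       # F(folded) - F(unfolded)
    dg_activation: float  # F(barrier) - F(unfolded), >= 0
    two_state: bool
    intermediate_energy: int | None = None

    @property
    def dg_activation_thermal(self) -> float:
        """Activation free energy in units of the profile temperature."""
        return self.dg_activation / self.temperature


def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through the max point and neighbors."""
    p = int(np.argmax(y))
    if p == 0 or p == len(y) - 1:
        return float(x[p])
    x0, x1, x2 = x[p - 1], x[p], x[p + 1]
    y0, y1, y2 = y[p - 1], y[p], y[p + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1)
    return float(-b / (2 * a))


def heat_capacity(
    temperatures: np.ndarray,
    samples: list | np.ndarray,
    min_samples: int = 1000,
) -> HeatCapacityCurve:
    """Fluctuation heat capacity Cv(T) = (<E^2> - <E>^2) / T^2 from
    per-temperature energy samples; Tm is the parabolically interpolated
    peak of the curve."""
    temps = np.asarray(temperatures, dtype=float)
    if temps.size < 2:
        raise ValueError("need samples at >= 2 temperatures")
    counts = [len(s) for s in samples]
    if any(c < min_samples for c in counts):
        bad = {float(t): c for t, c in zip(temps, counts) if c < min_samples}
        raise ValueError(f"insufficient samples (need >= {min_samples}): {bad}")
    cv = np.array([np.var(np.asarray(s, dtype=float)) / t**2 for s, t in zip(samples, temps)])
    return HeatCapacityCurve(temperatures=temps, cv=cv, tm=_parabolic_peak(temps, cv))


@dataclass(frozen=True)
class DensityOfStates:
    """WHAM density-of-states estimate on the integer energy grid.

    ``ln_omega`` is defined up to an additive constant and NaN on bins with
    no counts in any input histogram.
    """

    energies: np.ndarray
    ln_omega: np.ndarray
    shifts: np.ndarray          # converged per-temperature dimensionless free energies
    temperatures: np.ndarray
    n_iterations: int
    residual: float

    def _finite(self):
        m = np.isfinite(self.ln_omega)
        return self.energies[m], self.ln_omega[m]

    def free_energy_profile(self, T: float) -> FreeEnergyProfile:
        f = self.energies - T * self.ln_omega
        return FreeEnergyProfile(T, self.energies, f - np.nanmin(f))

    def moments(self, T: float):
        e, lw = self._finite()
        logw = lw - e / T
        logz = logsumexp(logw)
        w = np.exp(logw - logz)
        mean = float(w @ e)
        var = float(w @ (e - mean) ** 2)
        return mean, var

    def mean_energy(self, T: float) -> float:
        return self.moments(T)[0]

    def heat_capacity_curve(self, temperatures: np.ndarray) -> HeatCapacityCurve:
        temps = np.asarray(temperatures, dtype=float)
        cv = np.array([self.moments(t)[1] / t**2 for t in temps])
        return HeatCapacityCurve(temperatures=temps, cv=cv, tm=_parabolic_peak(temps, cv))


def wham(
    temperatures: np.ndarray,
    histograms: np.ndarray,
    energies: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> DensityOfStates:
    """Multi-histogram WHAM on integer-energy histograms.

    ``histograms[t, e]`` are counts at ``temperatures[t]`` in energy bin
    ``energies[e]``.  Iterates the standard self-consistency equations in
    log space until the per-temperature shifts change by less than ``tol``.
    Adjacent temperatures (in sorted order) must share at least one
    populated bin, otherwise the density of states is undetermined across
    the gap.
    """
    temps = np.asarray(temperatures, dtype=float)
    hist = np.asarray(histograms, dtype=float)
    e_grid = np.asarray(energies, dtype=float)
    if hist.shape != (temps.size, e_grid.size):
        raise ValueError(f"histogram shape {hist.shape} != (n_temps, n_bins)")
    # overlap check between neighbors in temperature order
    order = np.argsort(temps)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise ValueError(
                f"histograms at T={temps[a]:g} and T={temps[b]:g} do not overlap: "
                "no shared populated energy bin"
            )
    n_t = hist.sum(axis=1)
    if np.any(n_t == 0):
        raise ValueError("empty histogram supplied")
    total = hist.sum(axis=0)
    populated = total > 0
    with np.errstate(divide="ignore"):
        log_total = np.where(populated, np.log(np.maximum(total, 1e-300)), -np.inf)
    beta = 1.0 / temps
    log_n = np.log(n_t)

    f = np.zeros(temps.size)
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # ln Omega(E) = ln sum_t H_t(E) - ln sum_t n_t exp(f_t - beta_t E)
        denom = logsumexp(log_n[:, None] + f[:, None] - beta[:, None] * e_grid[None, :], axis=0)
        ln_omega = log_total - denom
        new_f = -logsumexp(ln_omega[None, populated] - beta[:, None] * e_grid[None, populated], axis=1)
        new_f -= new_f[0]
        resid = float(np.max(np.abs(new_f - f)))
        f = new_f
        if resid < tol:
            break
    ln_omega = np.where(populated, ln_omega, np.nan)
    finite = ln_omega[populated]
    ln_omega = ln_omega - finite.max()
    return DensityOfStates(
        energies=e_grid.astype(int),
        ln_omega=ln_omega,
        shifts=f,
        temperatures=temps,
        n_iterations=it,
        residual=resid,
    )


def melting_temperature(
    dos: DensityOfStates, t_lo: float, t_hi: float, n_grid: int = 400
) -> float:
    """Tm = heat-capacity peak of the WHAM-reweighted Cv on a fine grid."""
    curve = dos.heat_capacity_curve(np.linspace(t_lo, t_hi, n_grid))
    return curve.tm


def _local_extrema(f: np.ndarray):
    """Indices of local minima and maxima of a 1D array, endpoints included."""
    n = len(f)
    minima, maxima = [], []
    for i in range(n):
        left = f[i - 1] if i > 0 else np.inf
        right = f[i + 1] if i < n - 1 else np.inf
        if f[i] < left and f[i] <= right:
            minima.append(i)
        left = f[i - 1] if i > 0 else -np.inf
        right = f[i + 1] if i < n - 1 else -np.inf
        if f[i] > left and f[i] >= right:
            maxima.append(i)
    return minima, maxima


def barrier_analysis(
    profile: FreeEnergyProfile,
    intermediate_depth: float = 0.5,
) -> BarrierSummary:
    """Locate the folded minimum (lowest-energy basin), the unfolded
    minimum (highest-energy basin) and the global barrier between them.

    Activation free energy is F(barrier) - F(unfolded); a profile is
    flagged non-two-state when an additional local minimum between the
    barrier and the folded minimum is protected by its own local barrier of
    at least ``intermediate_depth`` reduced units (the signature of a
    post-barrier intermediate).  The default 0.5 sits in the gap between
    the profile-roughness dips of sampled WHAM profiles (< ~0.4, a few
    noise sigma) and pronounced intermediate minima (> ~0.55); see the
    methods note.  Invariant under additive shifts of F.
    """
    mask = np.isfinite(profile.f)
    if mask.sum() < 3:
        raise ValueError("profile has fewer than 3 populated energy bins")
    idx = np.nonzero(mask)[0]
    # narrow interior gaps are tolerated (e.g. the one-broken-contact level
    # of a compact native state is geometrically near-unreachable); a wide
    # gap means the sampling never bridged the basins.
    gaps = np.diff(idx)
    if gaps.max(initial=1) > 4:
        raise ValueError(
            "profile has an unsampled energy gap wider than 3 bins; refine sampling"
        )
    e = np.asarray(profile.energies, dtype=float)[mask]
    f = profile.f[mask]

    minima, maxima = _local_extrema(f)
    if not minima:
        raise ValueError("no local minimum found on the profile")
    folded = minima[0]
    if minima[-1] == folded:
        raise ValueError("monotone free-energy profile: no two basins / no barrier")
    inner = [m for m in maxima if folded < m < minima[-1]]
    if not inner:
        raise ValueError("no barrier between the folded and unfolded minima")
    barrier = max(inner, key=lambda m: f[m])
    # unfolded basin: global minimum of F on the high-energy side of the barrier
    unfolded = barrier + 1 + int(np.argmin(f[barrier + 1 :]))

    # post-barrier intermediates: minima strictly between barrier and folded
    intermediate = None
    two_state = True
    for m in minima:
        if folded < m < barrier:
            left_peaks = [p for p in maxima if folded < p < m]
            right_peaks = [p for p in maxima if m < p <= barrier]
            if not left_peaks or not right_peaks:
                continue
            own_barrier = min(max(f[p] for p in left_peaks), max(f[p] for p in right_peaks)) - f[m]
            if own_barrier >= intermediate_depth:
                two_state = False
                if intermediate is None or f[m] < f[intermediate]:
                    intermediate = m

    return BarrierSummary(
        temperature=profile.temperature,
        e_folded=int(e[folded]),
        e_unfolded=int(e[unfolded]),
        e_barrier=int(e[barrier]),
        dg_fold=float(f[folded] - f[unfolded]),
        dg_activation=float(f[barrier] - f[unfolded]),
        two_state=two_state,
        intermediate_energy=None if intermediate is None else int(e[intermediate]),
    )


def write_profile_csv(profile: FreeEnergyProfile, path, barrier: "BarrierSummary | None" = None) -> None:
    """Free-energy profile as CSV rows (E, F, annotation); annotations mark
    the folded/unfolded minima, the barrier peak and any intermediate."""
    import csv

    marks = {}
    if barrier is not None:
        marks[barrier.e_folded] = "folded_min"
        marks[barrier.e_unfolded] = "unfolded_min"
        marks[barrier.e_barrier] = "barrier"
        if barrier.intermediate_energy is not None:
            marks[barrier.intermediate_energy] = "intermediate"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["E", "F", "annotation"])
        for e, f in zip(profile.energies, profile.f):
            w.writerow([int(e), "" if not np.isfinite(f) else f, marks.get(int(e), "")])
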