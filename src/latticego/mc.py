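"""Metropolis Monte Carlo engine: local move set, folding kinetics and
parallel tempering.

The move set is the classic local lattice set — end moves, corner flips and
two-bead crankshafts.  One attempted elementary move is one MC time unit;
null proposals and rejected proposals advance time like accepted ones, and
proposals are drawn symmetrically (uniform bead, uniform geometric
candidate, collision -> rejection) so Metropolis acceptance
``min(1, exp(-dE/T))`` with kB = 1 satisfies detailed balance.

Heavy loops are delegated to the numba kernels in ``_kernels``; everything
here is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .lattice import ContactMap, GoModel, LatticeConformation, validate_conformation

__all__ = [
    "MoveProposal",
    "TrajectoryRecord",
    "PTConfig",
    "PTResult",
    "ChainState",
    "random_coil",
    "enumerate_moves",
    "propose_move",
    "metropolis_step",
    "run_folding_trajectory",
    "parallel_tempering",
    "make_temperature_ladder",
]

_UNIT_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


def _spawn_seed(seed: int, *stream: int) -> int:
    """Derive a child seed deterministically from a master seed and stream ids."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(s) for s in stream))
    return int(ss.generate_state(1, dtype=np.uint64)[0] & np.uint64(0x7FFFFFFFFFFFFFFF))


def _full_matrix(n: int) -> np.ndarray:
    """Indicator of every possible non-bonded pair (homopolymer attraction)."""
    m = np.ones((n, n), dtype=np.uint8)
    idx = np.arange(n)
    m[np.abs(idx[:, None] - idx[None, :]) <= 1] = 0
    return m


@dataclass
class ChainState:
    """Mutable simulation state: coordinates, occupancy grid, running contact
    count and RNG stream.  Thin wrapper over the kernel arrays."""

    coords: np.ndarray
    grid: np.ndarray
    nat: np.ndarray
    nformed: np.ndarray
    rng: np.ndarray

    @classmethod
    def create(
        cls,
        conf: LatticeConformation,
        contact_matrix: np.ndarray,
        seed: int,
    ) -> "ChainState":
        coords = np.array(conf.coords, dtype=np.int64)
        grid = np.zeros(K.GRID_SIZE, dtype=np.int32)
        K.fill_grid(coords, grid)
        nat = np.ascontiguousarray(contact_matrix, dtype=np.uint8)
        nformed = np.array([K.count_formed(coords, grid, nat)], dtype=np.int64)
        return cls(coords=coords, grid=grid, nat=nat, nformed=nformed, rng=K.seed_rng(seed))

    @classmethod
    def for_model(cls, conf: LatticeConformation, model: GoModel, seed: int) -> "ChainState":
        return cls.create(conf, model.native_contacts.as_matrix(), seed)

    @property
    def energy(self) -> int:
        """Current energy in units of -epsilon (epsilon = 1)."""
        return -int(self.nformed[0])

    def conformation(self) -> LatticeConformation:
        return LatticeConformation(self.coords.copy())


def random_coil(n: int, seed: int) -> LatticeConformation:
    """Uniform self-avoiding walk of n beads by non-reversal growth with
    restart on collision (every SAW of length n is equally likely)."""
    if n < 4:
        raise ValueError("need at least 4 beads")
    rng = np.random.default_rng(seed)
    for _ in range(100_000):
        coords = np.zeros((n, 3), dtype=np.int64)
        occupied = {(0, 0, 0)}
        prev_step = None
        ok = True
        for b in range(1, n):
            if prev_step is None:
                step = _UNIT_STEPS[rng.integers(6)]
            else:
                choices = [s for s in _UNIT_STEPS if not np.array_equal(s, -prev_step)]
                step = choices[rng.integers(5)]
            pos = coords[b - 1] + step
            key = (int(pos[0]), int(pos[1]), int(pos[2]))
            if key in occupied:
                ok = False
                break
            coords[b] = pos
            occupied.add(key)
            prev_step = step
        if ok:
            return LatticeConformation(coords)
    raise RuntimeError(f"failed to grow a self-avoiding walk of length {n}")


@dataclass(frozen=True)
class MoveProposal:
    kind: str  # "end-move" | "corner-flip" | "crankshaft"
    beads: tuple
    new_coords: np.ndarray

    def self_avoiding(self, conf: LatticeConformation) -> bool:
        occupied = {tuple(map(int, row)) for k, row in enumerate(conf.coords) if k not in self.beads}
        new = [tuple(map(int, row)) for row in np.atleast_2d(self.new_coords)]
        return len(set(new)) == len(new) and not any(p in occupied for p in new)


def _rotate(v: np.ndarray, axis: np.ndarray, quarter_turns: int) -> np.ndarray:
    adv = int(axis @ v)
    cr = np.cross(axis, v)
    if quarter_turns == 1:
        return axis * adv + cr
    if quarter_turns == 2:
        return 2 * axis * adv - v
    return axis * adv - cr


def enumerate_moves(conf: LatticeConformation, i: int) -> list:
    """Geometric move candidates at bead i (occupancy NOT filtered: collision
    is handled as rejection, which keeps the proposal density symmetric)."""
    c = conf.coords
    n = conf.chain_length
    out: list[MoveProposal] = []
    if i == 0 or i == n - 1:
        anchor = 1 if i == 0 else n - 2
        for step in _UNIT_STEPS:
            cand = c[anchor] + step
            if not np.array_equal(cand, c[i]):
                out.append(MoveProposal("end-move", (i,), cand[None, :].copy()))
        return out
    d = c[i + 1] - c[i - 1]
    if int(d @ d) == 2:
        cand = c[i - 1] + c[i + 1] - c[i]
        out.append(MoveProposal("corner-flip", (i,), cand[None, :].copy()))
    if i + 2 < n:
        a = c[i + 2] - c[i - 1]
        if int(a @ a) == 1:
            for rot in (1, 2, 3):
                q1 = c[i - 1] + _rotate(c[i] - c[i - 1], a, rot)
                q2 = c[i - 1] + _rotate(c[i + 1] - c[i - 1], a, rot)
                out.append(MoveProposal("crankshaft", (i, i + 1), np.stack([q1, q2])))
    return out


def propose_move(conf: LatticeConformation, rng: np.random.Generator):
    """Pick a bead uniformly, then one geometric candidate uniformly; return
    it if self-avoiding, else None (also None when the bead has no legal
    move).  A None proposal still costs one MC time unit."""
    i = int(rng.integers(conf.chain_length))
    cands = enumerate_moves(conf, i)
    if not cands:
        return None
    mv = cands[int(rng.integers(len(cands)))]
    return mv if mv.self_avoiding(conf) else None


def metropolis_step(
    conf: LatticeConformation, model: GoModel, T: float, state_or_seed
) -> LatticeConformation:
    """One attempted MC move (convenience wrapper; for long runs use the
    trajectory/parallel-tempering drivers which keep state in place)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(state_or_seed, ChainState):
        st = state_or_seed
    else:
        st = ChainState.for_model(conf, model, int(state_or_seed))
    K.mc_attempt(st.coords, st.grid, st.nat, float(T), st.rng, st.nformed)
    return st.conformation()


@dataclass
class TrajectoryRecord:
    seed: int
    temperature: float
    max_steps: int
    first_passage_time: int | None
    reached: bool
    unfolded: bool = False
    steps_run: int = 0
    energies: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16))
    energy_stride: int = 0
    snapshots: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 3), dtype=np.int64))
    snapshot_energies: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16))
    snapshot_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    snapshot_stride: int = 0


def run_folding_trajectory(
    model: GoModel,
    T: float,
    seed: int,
    max_steps: int = 10**9,
    energy_stride: int = 0,
    max_energy_samples: int = 100_000,
    snapshot_stride: int = 0,
    snapshot_window: tuple | None = None,
    max_snapshots: int = 2000,
    start: LatticeConformation | None = None,
    unfold_threshold: float | None = None,
) -> TrajectoryRecord:
    """Run one folding trajectory at temperature T from a fresh random coil
    (or ``start``) until the native state (Q = 1) is reached.

    ``first_passage_time`` is the MC step index of first full nativeness;
    trajectories that exhaust ``max_steps`` are flagged, not dropped.  When
    ``snapshot_stride`` > 0, conformations with energy inside
    ``snapshot_window`` (inclusive, reduced units) are stored for later
    transition-state harvesting.  ``unfold_threshold`` (fraction of native
    contacts) adds an absorbing unfolded stop, used by Pfold trials.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    n = model.chain_length
    if start is None:
        start = random_coil(n, _spawn_seed(seed, 0))
    st = ChainState.for_model(start, model, _spawn_seed(seed, 1))
    e_series = np.empty(max_energy_samples if energy_stride > 0 else 0, dtype=np.int16)
    if snapshot_stride > 0:
        lo, hi = snapshot_window if snapshot_window is not None else (-model.n_native, 0)
        snaps = np.empty((max_snapshots, n, 3), dtype=np.int64)
        snap_e = np.empty(max_snapshots, dtype=np.int16)
        snap_t = np.empty(max_snapshots, dtype=np.int64)
    else:
        lo, hi = 0, -1
        snaps = np.empty((0, n, 3), dtype=np.int64)
        snap_e = np.empty(0, dtype=np.int16)
        snap_t = np.empty(0, dtype=np.int64)
    unfold_n = -1
    if unfold_threshold is not None:
        unfold_n = int(np.floor(unfold_threshold * model.n_native))
    status, steps, ns, nsnap = K.run_trajectory(
        st.coords, st.grid, st.nat, st.nformed, float(T), int(max_steps), st.rng,
        model.n_native, unfold_n,
        e_series, int(energy_stride),
        snaps, snap_e, snap_t, int(snapshot_stride), int(lo), int(hi),
    )
    return TrajectoryRecord(
        seed=seed,
        temperature=T,
        max_steps=int(max_steps),
        first_passage_time=int(steps) if status == 1 else None,
        reached=status == 1,
        unfolded=status == 2,
        steps_run=int(steps),
        energies=e_series[:ns].copy(),
        energy_stride=int(energy_stride),
        snapshots=snaps[:nsnap].copy(),
        snapshot_energies=snap_e[:nsnap].copy(),
        snapshot_steps=snap_t[:nsnap].copy(),
        snapshot_stride=int(snapshot_stride),
    )


def make_temperature_ladder(t_lo: float, t_hi: float, n: int = 50) -> np.ndarray:
    """Geometrically spaced temperature ladder."""
    if not (0 < t_lo < t_hi) or n < 2:
        raise ValueError("need 0 < t_lo < t_hi and n >= 2")
    return np.geomspace(t_lo, t_hi, n)


@dataclass
class PTConfig:
    """Parallel-tempering run parameters.

    ``steps_per_sweep`` MC attempts separate successive swap attempts;
    samples are recorded per temperature slot every ``sample_stride``
    sweeps after ``burn_sweeps``.
    """

    temperatures: np.ndarray
    n_sweeps: int = 2000
    steps_per_sweep: int = 500
    burn_sweeps: int = 200
    sample_stride: int = 1
    seed: int = 0
    start: str = "mixed"  # "native" | "coil" | "mixed"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("temperature ladder must be strictly increasing with >= 2 entries")
        self.temperatures = t


@dataclass
class PTResult:
    temperatures: np.ndarray
    samples: np.ndarray  # (n_temps, n_samples) int energies
    swap_attempts: np.ndarray
    swap_accepts: np.ndarray

    @property
    def swap_acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.swap_attempts > 0, self.swap_accepts / np.maximum(self.swap_attempts, 1), np.nan)

    def histograms(self, e_min: int, e_max: int = 0):
        """Per-temperature integer-energy histograms on [e_min, e_max]."""
        edges = np.arange(e_min - 0.5, e_max + 1.0)
        return np.stack([np.histogram(s, bins=edges)[0] for s in self.samples])


def parallel_tempering(model: GoModel, pt: PTConfig) -> PTResult:
    """Replica-exchange equilibrium sampling of a Go model.

    Each temperature slot advances independently between swap attempts;
    adjacent slots exchange configurations with the standard replica-exchange
    acceptance.  ``start='mixed'`` seeds the colder half of the ladder from
    the native conformation and the hotter half from random coils, which
    gives the histogram overlap WHAM needs with short burn-in.
    """
    temps = pt.temperatures
    ntemp = temps.size
    n = model.chain_length
    nat = model.native_contacts.as_matrix().astype(np.uint8)
    if pt.start in ("native", "mixed") and model.native_conformation is None:
        raise ValueError("model has no native conformation to start replicas from")

    coordss = np.empty((ntemp, n, 3), dtype=np.int64)
    grids = np.zeros((ntemp, K.GRID_SIZE), dtype=np.int32)
    nformeds = np.empty(ntemp, dtype=np.int64)
    for t in range(ntemp):
        use_native = pt.start == "native" or (pt.start == "mixed" and t < ntemp // 2)
        if use_native:
            conf = model.native_conformation
        else:
            conf = random_coil(n, _spawn_seed(pt.seed, 100, t))
        coordss[t] = conf.coords
        K.fill_grid(coordss[t], grids[t])
        nformeds[t] = K.count_formed(coordss[t], grids[t], nat)

    n_samples_max = max(1, (pt.n_sweeps - pt.burn_sweeps) // pt.sample_stride + 1)
    samples = np.zeros((ntemp, n_samples_max), dtype=np.int16)
    swap_att = np.zeros(ntemp - 1, dtype=np.int64)
    swap_acc = np.zeros(ntemp - 1, dtype=np.int64)
    rng = K.seed_rng(_spawn_seed(pt.seed, 1))
    ns = K.run_parallel_tempering(
        coordss, grids, nat, nformeds, temps.astype(np.float64), rng,
        int(pt.n_sweeps), int(pt.steps_per_sweep), int(pt.sample_stride),
        int(pt.burn_sweeps), samples, swap_att, swap_acc,
    )
    return PTResult(
        temperatures=temps,
        samples=samples[:, :ns].astype(np.int32),
        swap_attempts=swap_att,
        swap_accepts=swap_acc,
    )


def assert_valid_state(st: ChainState) -> None:
    """Debug check: kernel state is a valid conformation and the incremental
    contact count matches a from-scratch recount."""
    res = validate_conformation(st.coords)
    if not res.ok:
        raise AssertionError("; ".join(res.violations))
    grid = np.zeros(K.GRID_SIZE, dtype=np.int32)
    K.fill_grid(st.coords, grid)
    recount = K.count_formed(st.coords, grid, st.nat)
    if recount != int(st.nformed[0]):
        raise AssertionError(f"incremental count {int(st.nformed[0])} != recount {recount}")


def save_trajectory(record: TrajectoryRecord, path) -> None:
    """Columnar trajectory store: energy series, snapshots and first
    passage time of one run (NumPy .npz container)."""
    np.savez_compressed(
        path,
        seed=record.seed,
        temperature=record.temperature,
        max_steps=record.max_steps,
        first_passage_time=-1 if record.first_passage_time is None else record.first_passage_time,
        reached=record.reached,
        unfolded=record.unfolded,
        steps_run=record.steps_run,
        energies=record.energies,
        energy_stride=record.energy_stride,
        snapshots=record.snapshots,
        snapshot_energies=record.snapshot_energies,
        snapshot_steps=record.snapshot_steps,
        snapshot_stride=record.snapshot_stride,
    )


def load_trajectory(path) -> TrajectoryRecord:
    with np.load(path) as d:
        fpt = int(d["first_passage_time"])
        return TrajectoryRecord(
            seed=int(d["seed"]),
            temperature=float(d["temperature"]),
            max_steps=int(d["max_steps"]),
            first_passage_time=None if fpt < 0 else fpt,
            reached=bool(d["reached"]),
            unfolded=bool(d["unfolded"]),
            steps_run=int(d["steps_run"]),
            energies=d["energies"],
            energy_stride=int(d["energy_stride"]),
            snapshots=d["snapshots"],
            snapshot_energies=d["snapshot_energies"],
            snapshot_steps=d["snapshot_steps"],
            snapshot_stride=int(d["snapshot_stride"]),
        )


def write_trajectory_index(records, path) -> None:
    """Per-CP CSV index of kinetic runs: (seed, T, FPT, reached flag)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["seed", "temperature", "fpt", "reached"])
        for r in records:
            w.writerow([r.seed, r.temperature,
                        "" if r.first_passage_time is None else r.first_passage_time,
                        int(r.reached)])
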