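"""Numba kernels for lattice Monte Carlo.

Layout conventions shared by every kernel:

* ``coords``: ``int64 (N, 3)`` bead positions (absolute lattice units).
* ``grid``: flat ``int32`` occupancy array over a 64^3 torus indexed by the
  low 6 bits of each coordinate, storing ``bead_index + 1`` (0 = empty).
  Because any two beads of an N<=48 chain differ by < 64 in every
  coordinate, wrapped overlap/adjacency tests are exact.
* ``nat``: ``uint8 (N, N)`` symmetric indicator of the favorable contact
  pairs; the tracked energy is ``-nformed`` where ``nformed`` counts formed
  favorable contacts (epsilon = 1 internally; callers rescale).
* ``rng``: ``uint64[1]`` xorshift64* state, advanced in place, so identical
  seeds reproduce trajectories bit for bit.

The move set is the local lattice set: end moves (terminal bead relocated
to one of the 5 other sites adjacent to its neighbor), corner flips
(diagonal bead of a right angle moved to the opposite corner) and
crankshafts (beads i, i+1 rotated by 90/180/270 degrees about the axis
through beads i-1 and i+2 when those are lattice neighbors).  For each
selected bead the geometric candidate count is invariant under the move
itself, so the proposal density is symmetric and plain Metropolis
acceptance preserves detailed balance.  Null proposals and rejections
consume one MC time unit like any other attempt.
"""

import numpy as np
from numba import njit

GRID_BITS = 6
GRID_MASK = np.int64(63)
GRID_SIZE = 1 << (3 * GRID_BITS)

_XMUL = np.uint64(2685821657736338717)


@njit(cache=True, inline="always")
def _rng_next(rng):
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    return x * _XMUL


@njit(cache=True, inline="always")
def _rand_u(rng):
    return (_rng_next(rng) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_below(rng, n):
    # modulo bias is ~n / 2^64, irrelevant for n <= a few hundred
    return np.int64(_rng_next(rng) % np.uint64(n))


@njit(cache=True)
def seed_rng(seed):
    """splitmix64 of the seed -> nonzero xorshift64* state."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x2545F4914F6CDD1D)
    out = np.empty(1, dtype=np.uint64)
    out[0] = z
    return out


@njit(cache=True, inline="always")
def _cell(x, y, z):
    return ((x & GRID_MASK) << 12) | ((y & GRID_MASK) << 6) | (z & GRID_MASK)


@njit(cache=True)
def fill_grid(coords, grid):
    grid[:] = 0
    for b in range(coords.shape[0]):
        grid[_cell(coords[b, 0], coords[b, 1], coords[b, 2])] = b + 1


@njit(cache=True, inline="always")
def _contacts_at(b, x, y, z, grid, nat):
    """Favorable contacts bead b has/would have at (x,y,z) with non-adjacent beads."""
    c = 0
    for axis in range(3):
        for s in range(2):
            if axis == 0:
                idx = _cell(x + 1 - 2 * s, y, z)
            elif axis == 1:
                idx = _cell(x, y + 1 - 2 * s, z)
            else:
                idx = _cell(x, y, z + 1 - 2 * s)
            j = grid[idx] - 1
            if j >= 0:
                dj = j - b
                if dj > 1 or dj < -1:
                    c += nat[b, j]
    return c


@njit(cache=True)
def count_formed(coords, grid, nat):
    total = 0
    for b in range(coords.shape[0]):
        total += _contacts_at(b, coords[b, 0], coords[b, 1], coords[b, 2], grid, nat)
    return total // 2


@njit(cache=True, inline="always")
def _accept(d_formed, T, rng):
    # energy change is -d_formed (epsilon = 1)
    if d_formed >= 0:
        return True
    return _rand_u(rng) < np.exp(d_formed / T)


@njit(cache=True, inline="always")
def _move_single(b, nx, ny, nz, coords, grid, nat, T, rng, nformed):
    """Attempt to relocate one bead to (nx, ny, nz); returns 1 if accepted."""
    if grid[_cell(nx, ny, nz)] != 0:
        return 0
    ox, oy, oz = coords[b, 0], coords[b, 1], coords[b, 2]
    lost = _contacts_at(b, ox, oy, oz, grid, nat)
    gained = _contacts_at(b, nx, ny, nz, grid, nat)
    if not _accept(gained - lost, T, rng):
        return 0
    grid[_cell(ox, oy, oz)] = 0
    grid[_cell(nx, ny, nz)] = b + 1
    coords[b, 0], coords[b, 1], coords[b, 2] = nx, ny, nz
    nformed[0] += gained - lost
    return 1


@njit(cache=True)
def mc_attempt(coords, grid, nat, T, rng, nformed):
    """One attempted elementary move (one MC time unit). Returns 1 if the
    conformation changed, else 0."""
    n = coords.shape[0]
    i = _rand_below(rng, n)
    if i == 0 or i == n - 1:
        # end move: 5 candidate sites adjacent to the anchoring neighbor
        anchor = 1 if i == 0 else n - 2
        qx, qy, qz = coords[anchor, 0], coords[anchor, 1], coords[anchor, 2]
        r = _rand_below(rng, 5)
        k = -1
        nx, ny, nz = qx, qy, qz
        for axis in range(3):
            for s in range(2):
                if axis == 0:
                    cx, cy, cz = qx + 1 - 2 * s, qy, qz
                elif axis == 1:
                    cx, cy, cz = qx, qy + 1 - 2 * s, qz
                else:
                    cx, cy, cz = qx, qy, qz + 1 - 2 * s
                if cx == coords[i, 0] and cy == coords[i, 1] and cz == coords[i, 2]:
                    continue
                k += 1
                if k == r:
                    nx, ny, nz = cx, cy, cz
        return _move_single(i, nx, ny, nz, coords, grid, nat, T, rng, nformed)

    # interior bead: corner flip and/or crankshaft of (i, i+1)
    dx = coords[i + 1, 0] - coords[i - 1, 0]
    dy = coords[i + 1, 1] - coords[i - 1, 1]
    dz = coords[i + 1, 2] - coords[i - 1, 2]
    flip_ok = (dx * dx + dy * dy + dz * dz) == 2
    crank_ok = False
    ax = np.int64(0)
    ay = np.int64(0)
    az = np.int64(0)
    if i + 2 < n:
        ax = coords[i + 2, 0] - coords[i - 1, 0]
        ay = coords[i + 2, 1] - coords[i - 1, 1]
        az = coords[i + 2, 2] - coords[i - 1, 2]
        crank_ok = (ax * ax + ay * ay + az * az) == 1
    m = (1 if flip_ok else 0) + (3 if crank_ok else 0)
    if m == 0:
        return 0
    r = _rand_below(rng, m)
    if flip_ok and r == 0:
        # opposite corner of the square: prev + next - current
        nx = coords[i - 1, 0] + coords[i + 1, 0] - coords[i, 0]
        ny = coords[i - 1, 1] + coords[i + 1, 1] - coords[i, 1]
        nz = coords[i - 1, 2] + coords[i + 1, 2] - coords[i, 2]
        return _move_single(i, nx, ny, nz, coords, grid, nat, T, rng, nformed)

    rot = r - (1 if flip_ok else 0) + 1  # quarter turns: 1, 2 or 3
    ox, oy, oz = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
    # rotate beads i and i+1 about the unit axis (ax,ay,az) through bead i-1
    q1x, q1y, q1z = 0, 0, 0
    q2x, q2y, q2z = 0, 0, 0
    for which in range(2):
        b = i + which
        vx = coords[b, 0] - ox
        vy = coords[b, 1] - oy
        vz = coords[b, 2] - oz
        adv = ax * vx + ay * vy + az * vz
        cxx = ay * vz - az * vy
        cyy = az * vx - ax * vz
        czz = ax * vy - ay * vx
        if rot == 1:
            wx, wy, wz = ax * adv + cxx, ay * adv + cyy, az * adv + czz
        elif rot == 2:
            wx, wy, wz = 2 * ax * adv - vx, 2 * ay * adv - vy, 2 * az * adv - vz
        else:
            wx, wy, wz = ax * adv - cxx, ay * adv - cyy, az * adv - czz
        if which == 0:
            q1x, q1y, q1z = ox + wx, oy + wy, oz + wz
        else:
            q2x, q2y, q2z = ox + wx, oy + wy, oz + wz

    occ1 = grid[_cell(q1x, q1y, q1z)] - 1
    if occ1 >= 0 and occ1 != i and occ1 != i + 1:
        return 0
    occ2 = grid[_cell(q2x, q2y, q2z)] - 1
    if occ2 >= 0 and occ2 != i and occ2 != i + 1:
        return 0
    if (
        q1x == coords[i, 0] and q1y == coords[i, 1] and q1z == coords[i, 2]
        and q2x == coords[i + 1, 0] and q2y == coords[i + 1, 1] and q2z == coords[i + 1, 2]
    ):
        return 0  # both beads on the rotation axis: identity proposal
    lost = _contacts_at(i, coords[i, 0], coords[i, 1], coords[i, 2], grid, nat)
    lost += _contacts_at(i + 1, coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2], grid, nat)
    gained = _contacts_at(i, q1x, q1y, q1z, grid, nat)
    gained += _contacts_at(i + 1, q2x, q2y, q2z, grid, nat)
    if not _accept(gained - lost, T, rng):
        return 0
    grid[_cell(coords[i, 0], coords[i, 1], coords[i, 2])] = 0
    grid[_cell(coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2])] = 0
    grid[_cell(q1x, q1y, q1z)] = i + 1
    grid[_cell(q2x, q2y, q2z)] = i + 2
    coords[i, 0], coords[i, 1], coords[i, 2] = q1x, q1y, q1z
    coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = q2x, q2y, q2z
    nformed[0] += gained - lost
    return 1


@njit(cache=True)
def run_equilibrium(coords, grid, nat, nformed, T, nsteps, rng, e_series, e_stride):
    """Fixed-temperature sampling; records -nformed every e_stride attempts."""
    ns = 0
    for step in range(nsteps):
        mc_attempt(coords, grid, nat, T, rng, nformed)
        if e_stride > 0 and (step + 1) % e_stride == 0 and ns < e_series.shape[0]:
            e_series[ns] = -nformed[0]
            ns += 1
    return ns


@njit(cache=True)
def run_trajectory(
    coords, grid, nat, nformed, T, max_steps, rng,
    fold_n, unfold_n,
    e_series, e_stride,
    snaps, snap_e, snap_t, snap_stride, snap_lo, snap_hi,
):
    """Kinetic run with stopping conditions.

    Stops when nformed == fold_n (status 1, folded) or nformed <= unfold_n
    (status 2, unfolded; pass -1 to disable) or after max_steps (status 0).
    Returns (status, steps_taken, n_energy_samples, n_snapshots).
    Snapshots of the full conformation are taken every snap_stride attempts
    while the energy -nformed lies in [snap_lo, snap_hi].
    """
    ns = 0
    nsnap = 0
    if nformed[0] == fold_n:
        return 1, 0, ns, nsnap
    if unfold_n >= 0 and nformed[0] <= unfold_n:
        return 2, 0, ns, nsnap
    for step in range(max_steps):
        mc_attempt(coords, grid, nat, T, rng, nformed)
        t = step + 1
        if e_stride > 0 and t % e_stride == 0 and ns < e_series.shape[0]:
            e_series[ns] = -nformed[0]
            ns += 1
        if snap_stride > 0 and t % snap_stride == 0 and nsnap < snaps.shape[0]:
            e = -nformed[0]
            if snap_lo <= e <= snap_hi:
                for b in range(coords.shape[0]):
                    snaps[nsnap, b, 0] = coords[b, 0]
                    snaps[nsnap, b, 1] = coords[b, 1]
                    snaps[nsnap, b, 2] = coords[b, 2]
                snap_e[nsnap] = e
                snap_t[nsnap] = t
                nsnap += 1
        if nformed[0] == fold_n:
            return 1, t, ns, nsnap
        if unfold_n >= 0 and nformed[0] <= unfold_n:
            return 2, t, ns, nsnap
    return 0, max_steps, ns, nsnap


@njit(cache=True)
def run_parallel_tempering(
    coordss, grids, nat, nformeds, temps, rng,
    n_sweeps, steps_per_sweep, sample_stride, burn_sweeps,
    samples, swap_att, swap_acc,
):
    """Replica-exchange MC.

    ``temps`` is the strictly increasing ladder; temperature slot t is held
    by replica ``rhold[t]``.  Between swap attempts every replica advances
    ``steps_per_sweep`` attempts at its current temperature.  Adjacent-slot
    swaps alternate parity sweep by sweep and are accepted with
    min(1, exp((1/T_t - 1/T_{t+1}) (E_t - E_{t+1}))).  After ``burn_sweeps``
    the energy at each temperature slot is recorded every ``sample_stride``
    sweeps into ``samples[t, :]``.  Returns the number of samples per slot.
    """
    ntemp = temps.shape[0]
    rhold = np.arange(ntemp)
    ns = 0
    for sweep in range(n_sweeps):
        for t in range(ntemp):
            r = rhold[t]
            c = coordss[r]
            g = grids[r]
            nf = nformeds[r : r + 1]
            T = temps[t]
            for _ in range(steps_per_sweep):
                mc_attempt(c, g, nat, T, rng, nf)
        start = sweep % 2
        for t in range(start, ntemp - 1, 2):
            ra = rhold[t]
            rb = rhold[t + 1]
            ea = -nformeds[ra]
            eb = -nformeds[rb]
            arg = (1.0 / temps[t] - 1.0 / temps[t + 1]) * (ea - eb)
            swap_att[t] += 1
            if arg >= 0.0 or _rand_u(rng) < np.exp(arg):
                rhold[t] = rb
                rhold[t + 1] = ra
                swap_acc[t] += 1
        if sweep >= burn_sweeps and (sweep - burn_sweeps + 1) % sample_stride == 0:
            if ns < samples.shape[1]:
                for t in range(ntemp):
                    samples[t, ns] = -nformeds[rhold[t]]
                ns += 1
    return ns


@njit(cache=True)
def run_annealing(
    coords, grid, nat, nformed, temps, steps_per_temp, rng, target
):
    """Annealing schedule for homopolymer collapse.

    Runs each temperature stage in turn; returns (reached, stage, step)
    where reached is True the moment nformed hits ``target``.
    """
    for stage in range(temps.shape[0]):
        T = temps[stage]
        for step in range(steps_per_temp):
            mc_attempt(coords, grid, nat, T, rng, nformed)
            if nformed[0] >= target:
                return True, stage, step + 1
    return False, temps.shape[0], 0
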