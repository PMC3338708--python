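"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

STEPS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_force_contacts(coords: np.ndarray) -> set:
    """O(N^2) pair scan for non-bonded unit-distance pairs."""
    n = len(coords)
    out = set()
    for i in range(n):
        for j in range(i + 2, n):
            d = coords[i] - coords[j]
            if int(d @ d) == 1:
                out.add((i, j))
    return out


def enumerate_saws(n_beads: int):
    """Every self-avoiding chain of n_beads beads with bead 0 at the origin
    (translation classes; rotations/reflections counted as distinct, exactly
    the state space of the lattice MC chain)."""
    chains = []
    coords = [(0, 0, 0)]
    occupied = {(0, 0, 0)}

    def grow():
        if len(coords) == n_beads:
            chains.append(np.array(coords, dtype=np.int64))
            return
        x, y, z = coords[-1]
        for dx, dy, dz in STEPS:
            pos = (x + dx, y + dy, z + dz)
            if pos in occupied:
                continue
            coords.append(pos)
            occupied.add(pos)
            grow()
            coords.pop()
            occupied.remove(pos)

    grow()
    return chains


def go_energy_of(coords: np.ndarray, native_pairs: set) -> int:
    return -len(brute_force_contacts(coords) & native_pairs)


def exact_level_counts(n_beads: int, native_pairs: set) -> dict:
    """Exact number of chains at each Go energy level (enumeration)."""
    counts: dict[int, int] = {}
    for chain in enumerate_saws(n_beads):
        e = go_energy_of(chain, native_pairs)
        counts[e] = counts.get(e, 0) + 1
    return counts


def boltzmann_level_probs(level_counts: dict, T: float) -> dict:
    es = np.array(sorted(level_counts))
    ws = np.array([level_counts[e] for e in es], dtype=float) * np.exp(
        -(es - es.min()) / T
    )
    ws /= ws.sum()
    return dict(zip(es.tolist(), ws.tolist()))


def proper_rotations():
    """The 24 proper rotation matrices of the cubic lattice."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    assert len(mats) == 24
    return mats


def brute_force_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Min RMSD over the 24 proper lattice rotations after centroid
    alignment (valid oracle for lattice conformations, whose optimal
    proper rotation is a lattice rotation)."""
    pc = p.astype(float) - p.mean(axis=0)
    qc = q.astype(float) - q.mean(axis=0)
    best = np.inf
    for r in proper_rotations():
        d = pc @ r.T - qc
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


def schottky_cv(T: float, gap: float, g: float) -> float:
    """Heat capacity of a two-level system with degeneracies (1, g)."""
    b = np.exp(-gap / T)
    return (gap / T) ** 2 * g * b / (1 + g * b) ** 2


def two_level_mean(T: float, gap: float, g: float, e0: float = 0.0) -> float:
    b = g * np.exp(-gap / T)
    return e0 + gap * b / (1 + b)
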