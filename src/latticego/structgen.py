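"""Generation of maximally compact parent structures and circular-permutant
families.

A *parent* is a Hamiltonian path of a lattice cuboid (every site occupied,
maximal contact number) whose termini sit on neighboring sites, so the
chain can be closed into a cycle and re-cut at any bond.  Cutting after
bead k-1 yields circular permutant k: the same point set and the same
number of contacts, but different backbone connectivity and hence a
different contact order (CO), the mean sequence separation of the native
contacts.  A family is the full set of N permutants of one parent.

Parents are produced by simulated annealing of a homopolymer (every
non-bonded adjacency worth -1) until the chain reaches the maximal contact
count of the target box; deterministic constructions (serpentine path,
comb Hamiltonian cycle) are provided for fixtures and fallbacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as K
from .lattice import (
    ContactMap,
    GoModel,
    LatticeConformation,
    compute_contacts,
    write_conformation,
    write_contact_map,
)
from .mc import ChainState, _full_matrix, _spawn_seed, random_coil

__all__ = [
    "ParentStructure",
    "CPFamily",
    "max_contacts",
    "collapse_homopolymer",
    "select_parents_by_co",
    "circular_permute",
    "contact_order",
    "build_family",
    "serpentine_path",
    "hamiltonian_cycle_path",
    "write_family_manifest",
]


def max_contacts(box: tuple) -> int:
    """Non-bonded contacts of any Hamiltonian path of an a x b x c cuboid:
    lattice edge count (a-1)bc + a(b-1)c + ab(c-1) minus the N-1 bonds."""
    a, b, c = box
    n = a * b * c
    edges = (a - 1) * b * c + a * (b - 1) * c + a * b * (c - 1)
    return edges - (n - 1)


@dataclass(frozen=True)
class ParentStructure:
    """A maximally compact conformation filling ``box``, termini adjacent
    unless the box has all-odd dimensions (bipartite parity forbids it)."""

    conformation: LatticeConformation
    box: tuple
    label: str = "parent"

    def __post_init__(self) -> None:
        a, b, c = self.box
        coords = self.conformation.coords
        n = coords.shape[0]
        if n != a * b * c:
            raise ValueError(f"chain length {n} != box volume {a * b * c}")
        mins = coords.min(axis=0)
        spans = tuple(sorted((coords.max(axis=0) - mins + 1).tolist()))
        if spans != tuple(sorted((a, b, c))):
            raise ValueError(f"conformation spans {spans}, expected box {self.box}")
        if len({tuple(r) for r in (coords - mins).tolist()}) != n:
            raise ValueError("conformation does not fill the box")

    @property
    def chain_length(self) -> int:
        return self.conformation.chain_length

    @property
    def termini_adjacent(self) -> bool:
        d = self.conformation.coords[0] - self.conformation.coords[-1]
        return int(d @ d) == 1

    def contact_map(self) -> ContactMap:
        return compute_contacts(self.conformation)

    def contact_order(self) -> float:
        return contact_order(self.contact_map())


def contact_order(cmap: ContactMap) -> float:
    """Absolute contact order: mean sequence separation |i - j| over the
    contact set.  (At fixed chain length the relative CO differs only by
    the constant factor 1/N.)"""
    if len(cmap) == 0:
        raise ValueError("contact order is undefined for an empty contact map")
    return float(np.mean(cmap.separations()))


def serpentine_path(box: tuple) -> LatticeConformation:
    """Deterministic boustrophedon Hamiltonian path of the box (termini not
    necessarily adjacent; contact-count fixture)."""
    a, b, c = box
    coords = []
    for z in range(c):
        ys = range(b) if z % 2 == 0 else range(b - 1, -1, -1)
        for y in ys:
            flip = (y + z) % 2 == 1
            xs = range(a - 1, -1, -1) if flip else range(a)
            for x in xs:
                coords.append((x, y, z))
    return LatticeConformation(np.array(coords, dtype=np.int64))


def hamiltonian_cycle_path(box: tuple, cut: int = 0) -> ParentStructure:
    """Deterministic Hamiltonian *cycle* of the box, opened at bond ``cut``,
    so the termini are adjacent by construction.

    Requires an even number of sites (a bipartite grid with an odd site
    count has no Hamiltonian cycle).  Built as a comb: a 2D Hamiltonian
    cycle over two dimensions whose product is even, with each of its cells
    expanded into a full column along the third dimension.
    """
    a, b, c = box
    n = a * b * c
    if n % 2:
        raise ValueError(f"box {box} has an odd site count; no Hamiltonian cycle exists")
    # choose base plane (two dims with even product); comb along the remaining dim
    dims = [0, 1, 2]
    base_pair = None
    for i in range(3):
        for j in range(i + 1, 3):
            if (box[i] * box[j]) % 2 == 0 and box[i] >= 2 and box[j] >= 2:
                base_pair = (i, j)
                break
        if base_pair:
            break
    if base_pair is None:
        raise ValueError(f"box {box} admits no comb construction")
    i, j = base_pair
    k = [d for d in dims if d not in base_pair][0]
    base_cycle = _grid_cycle(box[i], box[j])
    depth = box[k]
    coords = []
    for idx, (u, v) in enumerate(base_cycle):
        ws = range(depth) if idx % 2 == 0 else range(depth - 1, -1, -1)
        for w in ws:
            site = [0, 0, 0]
            site[i], site[j], site[k] = u, v, w
            coords.append(tuple(site))
    arr = np.array(coords, dtype=np.int64)
    arr = np.roll(arr, -cut, axis=0)
    conf = LatticeConformation(arr)
    return ParentStructure(conformation=conf, box=box, label=f"cycle{box[0]}x{box[1]}x{box[2]}")


def _grid_cycle(p: int, q: int) -> list:
    """Hamiltonian cycle of a p x q grid graph (pq even, p, q >= 2):
    snake through columns v >= 1 and return along column v = 0.  The snake
    needs an even row count, so for odd p the transposed cycle is used."""
    if (p * q) % 2 or p < 2 or q < 2:
        raise ValueError("grid cycle needs pq even and both dims >= 2")
    if p % 2:
        return [(u, v) for (v, u) in _grid_cycle(q, p)]
    cells = [(0, 0)]
    for u in range(p):
        vs = range(1, q) if u % 2 == 0 else range(q - 1, 0, -1)
        for v in vs:
            cells.append((u, v))
    for u in range(p - 1, 0, -1):
        cells.append((u, 0))
    return cells


def collapse_homopolymer(
    n: int,
    box: tuple,
    seed: int,
    t_start: float = 2.0,
    t_end: float = 0.30,
    n_stages: int = 60,
    steps_per_stage: int = 200_000,
    max_attempts: int = 200,
    require_termini_adjacent: bool = True,
    label: str | None = None,
) -> ParentStructure:
    """Maximally compact parent by simulated annealing of homopolymer
    collapse.

    Starting from a random coil, every non-bonded adjacency is worth -1 and
    the temperature is annealed geometrically from ``t_start`` to ``t_end``
    until the chain reaches the maximal contact count of the box; runs not
    reaching it (or, when required, not displaying adjacent termini) are
    retried with fresh sub-seeds.  Deterministic given ``seed``.
    """
    a, b, c = box
    if a * b * c != n:
        raise ValueError(f"box volume {a * b * c} != chain length {n}")
    if n < 8:
        raise ValueError("need n >= 8")
    if require_termini_adjacent and a % 2 and b % 2 and c % 2:
        raise ValueError(
            f"box {box} has an odd site count: a Hamiltonian path can never "
            "have adjacent termini (bipartite parity); pass "
            "require_termini_adjacent=False for a plain compact structure"
        )
    target = max_contacts(box)
    nat = _full_matrix(n)
    temps = np.geomspace(t_start, t_end, n_stages)
    attempts = 0
    stats = {"anneals": 0, "reached_compact": 0, "termini_failures": 0}
    for attempt in range(max_attempts):
        attempts += 1
        stats["anneals"] += 1
        coil = random_coil(n, _spawn_seed(seed, 2, attempt))
        st = ChainState.create(coil, nat, _spawn_seed(seed, 3, attempt))
        reached, _, _ = K.run_annealing(
            st.coords, st.grid, st.nat, st.nformed, temps, int(steps_per_stage),
            st.rng, int(target),
        )
        if not reached:
            continue
        stats["reached_compact"] += 1
        conf = st.conformation()
        try:
            parent = ParentStructure(
                conformation=_normalize_origin(conf),
                box=box,
                label=label or f"collapse_n{n}_s{seed}",
            )
        except ValueError:
            # degenerate geometry: some boxes share their maximal contact
            # count with non-cuboid compact shapes (e.g. 2x3x4 vs a 3x3x3
            # cube missing a tromino) -- not a valid parent, try again
            stats["wrong_shape"] = stats.get("wrong_shape", 0) + 1
            continue
        if require_termini_adjacent and not parent.termini_adjacent:
            stats["termini_failures"] += 1
            continue
        return parent
    raise RuntimeError(
        f"homopolymer collapse failed after {attempts} attempts "
        f"(stats: {stats}); increase steps_per_stage or max_attempts"
    )


def _normalize_origin(conf: LatticeConformation) -> LatticeConformation:
    coords = conf.coords - conf.coords.min(axis=0)
    return LatticeConformation(coords)


def select_parents_by_co(candidates: list, mode: str) -> ParentStructure:
    """Candidate with maximal ('high') or minimal ('low') contact order;
    ties broken by lexicographic coordinate order."""
    if not candidates:
        raise ValueError("empty candidate list")
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    sign = -1.0 if mode == "high" else 1.0
    return min(
        candidates,
        key=lambda p: (sign * p.contact_order(), p.conformation.coords.tolist()),
    )


def circular_permute(parent: ParentStructure, k: int):
    """Circular permutant k: bead j of the permutant is bead (j + k) mod N
    of the parent.

    Conceptually the parent's termini are covalently joined and the
    backbone re-cut after parent bead k-1: that bond becomes a non-bonded
    contact and the old terminus-terminus contact becomes a bond, so the
    contact count is conserved.  Returns (conformation, GoModel) with the
    native map recomputed from the re-indexed coordinates.
    """
    n = parent.chain_length
    if not (0 <= k < n):
        raise ValueError(f"cut index {k} out of range [0, {n})")
    if not parent.termini_adjacent:
        raise ValueError("parent termini are not adjacent; cannot circularly permute")
    coords = np.roll(parent.conformation.coords, -k, axis=0)
    conf = LatticeConformation(coords)
    return conf, GoModel.from_conformation(conf)


@dataclass(frozen=True)
class CPFamily:
    """A parent plus its N circular permutants (k = 0 is the parent)."""

    parent: ParentStructure
    conformations: tuple
    models: tuple
    co_values: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.models)

    def labels(self) -> list:
        width = len(str(self.n_members - 1))
        return [f"{self.parent.label}_cp{k:0{width}d}" for k in range(self.n_members)]


def build_family(parent: ParentStructure) -> CPFamily:
    """All N circular permutants of a parent, with per-permutant contact
    order; verifies contact-count conservation across the family."""
    n = parent.chain_length
    confs, models, cos = [], [], []
    n_contacts = len(parent.contact_map())
    for k in range(n):
        conf, model = circular_permute(parent, k)
        if model.n_native != n_contacts:
            raise AssertionError(
                f"permutant {k} has {model.n_native} contacts, parent has {n_contacts}"
            )
        confs.append(conf)
        models.append(model)
        cos.append(contact_order(model.native_contacts))
    return CPFamily(
        parent=parent,
        conformations=tuple(confs),
        models=tuple(models),
        co_values=np.array(cos),
    )


def write_family_manifest(family: CPFamily, outdir: str | Path) -> pd.DataFrame:
    """Write conformations, contact maps and a CSV manifest for a family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, label in enumerate(family.labels()):
        conf_file = f"{label}.xyz.txt"
        cmap_file = f"{label}.contacts.txt"
        write_conformation(family.conformations[k], outdir / conf_file, label=label)
        write_contact_map(family.models[k].native_contacts, outdir / cmap_file)
        rows.append(
            {
                "label": label,
                "k": k,
                "CO": family.co_values[k],
                "n_contacts": family.models[k].n_native,
                "conformation_file": conf_file,
                "contacts_file": cmap_file,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "family_manifest.csv", index=False)
    return manifest
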