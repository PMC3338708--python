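"""Cubic-lattice chain conformations, contact maps and the Go potential.

A protein is a self-avoiding chain of N beads on the simple cubic lattice;
consecutive beads sit on neighboring lattice sites (bond length = lattice
spacing).  A non-bonded *contact* is a pair of chain-nonadjacent beads at
unit distance.  The Go potential assigns energy ``-epsilon`` to every formed
*native* contact and zero to everything else, so energies are integers in
``[-epsilon * n_native, 0]`` (reduced units, kB = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LatticeConformation",
    "ContactMap",
    "GoModel",
    "validate_conformation",
    "compute_contacts",
    "go_energy",
    "fraction_native",
    "read_conformation",
    "write_conformation",
    "read_contact_map",
    "write_contact_map",
    "write_pseudo_pdb",
]


def _as_coords(coords: Sequence | np.ndarray) -> np.ndarray:
    arr = np.asarray(coords, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"coords must be an (N, 3) integer array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class LatticeConformation:
    """Ordered integer coordinates of an N-bead self-avoiding lattice chain."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_coords(self.coords)
        object.__setattr__(self, "coords", arr)
        arr.setflags(write=False)
        result = validate_conformation(arr)
        if not result.ok:
            raise ValueError("invalid lattice conformation: " + "; ".join(result.violations))

    @property
    def chain_length(self) -> int:
        return self.coords.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LatticeConformation):
            return NotImplemented
        return np.array_equal(self.coords, other.coords)

    def __hash__(self) -> int:
        return hash(self.coords.tobytes())


@dataclass(frozen=True)
class ContactMap:
    """Set of unordered non-bonded contact pairs (i, j), stored with i < j."""

    contacts: frozenset
    chain_length: int

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.contacts)
        for i, j in pairs:
            if not (0 <= i < j < self.chain_length):
                raise ValueError(f"contact pair ({i}, {j}) out of range for N={self.chain_length}")
            if j - i < 2:
                raise ValueError(f"pair ({i}, {j}) is chain-adjacent, not a contact")
        object.__setattr__(self, "contacts", pairs)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(sorted(self.contacts))

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.contacts

    def separations(self) -> np.ndarray:
        """Sequence separations j - i of all contacts (unsorted pairs sorted)."""
        return np.array([j - i for i, j in sorted(self.contacts)], dtype=np.int64)

    def as_matrix(self) -> np.ndarray:
        """Symmetric boolean (N, N) indicator matrix of the contact set."""
        m = np.zeros((self.chain_length, self.chain_length), dtype=bool)
        for i, j in self.contacts:
            m[i, j] = m[j, i] = True
        return m


@dataclass(frozen=True)
class GoModel:
    """A native structure's contact map plus the uniform interaction energy.

    Only native contacts are energetically favorable (``-epsilon`` each);
    non-native adjacencies are energetically silent.  This isolates the
    effect of native topology from any sequence signal.
    """

    native_contacts: ContactMap
    epsilon: float = 1.0
    native_conformation: LatticeConformation | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def chain_length(self) -> int:
        return self.native_contacts.chain_length

    @property
    def n_native(self) -> int:
        return len(self.native_contacts)

    @property
    def native_energy(self) -> float:
        """Energy of the fully native conformation, -epsilon * n_native."""
        return -self.epsilon * self.n_native

    @classmethod
    def from_conformation(
        cls, conf: LatticeConformation, epsilon: float = 1.0
    ) -> "GoModel":
        return cls(
            native_contacts=compute_contacts(conf),
            epsilon=epsilon,
            native_conformation=conf,
        )


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    violations: tuple

    def __bool__(self) -> bool:
        return self.ok


def validate_conformation(coords: Sequence | np.ndarray) -> ValidationResult:
    """Check chain-geometry invariants, reporting every violation found.

    Verifies unit bond lengths between consecutive beads and global
    self-avoidance; diagnostic (never raises on a bad chain).
    """
    arr = _as_coords(coords)
    n = arr.shape[0]
    violations: list[str] = []
    if n < 4:
        violations.append(f"chain length {n} < 4")
    diffs = np.diff(arr, axis=0)
    bad_bonds = np.nonzero(np.sum(diffs * diffs, axis=1) != 1)[0]
    for k in bad_bonds:
        violations.append(f"bond length != 1 at ({k}, {k + 1})")
    seen: dict[bytes, int] = {}
    for k in range(n):
        key = arr[k].tobytes()
        if key in seen:
            violations.append(f"overlap at indices ({seen[key]}, {k})")
        else:
            seen[key] = k
    return ValidationResult(ok=not violations, violations=tuple(violations))


def compute_contacts(conf: LatticeConformation | np.ndarray) -> ContactMap:
    """All non-bonded contacts of a conformation.

    A pair (i, j) with j > i + 1 is a contact when the beads occupy
    neighboring lattice sites.  On the cubic lattice the two sublattice
    parities force every contact to have odd sequence separation >= 3.
    """
    if isinstance(conf, LatticeConformation):
        arr = conf.coords
    else:
        arr = _as_coords(conf)
        result = validate_conformation(arr)
        if not result.ok:
            raise ValueError("invalid conformation: " + "; ".join(result.violations))
    n = arr.shape[0]
    # O(N^2) all-pairs squared distance; N <= a few hundred in practice.
    d = arr[:, None, :] - arr[None, :, :]
    dist2 = np.sum(d * d, axis=2)
    iu, ju = np.nonzero(np.triu(dist2 == 1, k=2))
    pairs = frozenset(zip(iu.tolist(), ju.tolist()))
    return ContactMap(contacts=pairs, chain_length=n)


def _formed_native(conf: LatticeConformation, model: GoModel) -> int:
    if conf.chain_length != model.chain_length:
        raise ValueError(
            f"chain length mismatch: conformation N={conf.chain_length}, "
            f"model N={model.chain_length}"
        )
    formed = compute_contacts(conf)
    return len(formed.contacts & model.native_contacts.contacts)


def go_energy(conf: LatticeConformation, model: GoModel) -> float:
    """Go energy: -epsilon per formed native contact; non-native pairs free."""
    return -model.epsilon * _formed_native(conf, model)


def fraction_native(conf: LatticeConformation, model: GoModel) -> float:
    """Fraction Q of native contacts formed, in [0, 1]."""
    return _formed_native(conf, model) / model.n_native


# ---------------------------------------------------------------------------
# Plain-text serialization


def write_conformation(conf: LatticeConformation, path: str | Path, label: str = "") -> None:
    """Write one "x y z" line per bead; '#' header lines carry N and label."""
    path = Path(path)
    lines = [f"# N {conf.chain_length}"]
    if label:
        lines.append(f"# label {label}")
    lines.extend(" ".join(str(v) for v in row) for row in conf.coords)
    path.write_text("\n".join(lines) + "\n")


def read_conformation(path: str | Path) -> LatticeConformation:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([int(v) for v in line.split()])
    return LatticeConformation(np.array(rows, dtype=np.int64))


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """One "i j" pair per line, lexicographically sorted."""
    lines = [f"# N {cmap.chain_length}"]
    lines.extend(f"{i} {j}" for i, j in sorted(cmap.contacts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_map(path: str | Path) -> ContactMap:
    n = None
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("# N"):
            n = int(line.split()[-1])
        elif line and not line.startswith("#"):
            i, j = line.split()
            pairs.append((int(i), int(j)))
    if n is None:
        n = max(j for _, j in pairs) + 1
    return ContactMap(contacts=frozenset(pairs), chain_length=n)


def write_pseudo_pdb(
    conf: LatticeConformation, path: str | Path, scale: float = 3.8
) -> None:
    """CA-only pseudo-PDB export, lattice units scaled to ~3.8 A per bond."""
    lines = []
    for k, (x, y, z) in enumerate(conf.coords, start=1):
        lines.append(
            f"ATOM  {k:5d}  CA  ALA A{k:4d}    "
            f"{x * scale:8.3f}{y * scale:8.3f}{z * scale:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
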