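"""Sequences, contact potentials, folds, and the exhaustive SAW oracle.

This module defines lattice-space ground truth: the energy of a fold is
the sum of pairwise contact energies over non-bonded nearest-neighbor
pairs, and :func:`ground_truth_minimum` minimizes it exactly over all
self-avoiding walks at small chain lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence as Seq, Tuple

from . import lattice as lat
from .lattice import CARTESIAN, DIAMOND, Coord, InvalidSequenceError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HP_ALPHABET = "HP"

#: Default enumeration guards (bead counts) for exhaustive SAW scans.
SAW_GUARD = {CARTESIAN: 10, DIAMOND: 14}


@dataclass(frozen=True)
class Sequence:
    """Residue string over the 20-letter alphabet or {H, P}."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise InvalidSequenceError(
                f"need at least 2 residues, got {len(self.residues)}"
            )
        bad = set(self.residues) - set(AA20)
        if bad:
            raise InvalidSequenceError(
                f"unknown residue letters {sorted(bad)} (alphabet {AA20})"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]


class InteractionMatrix:
    """Symmetric pairwise contact energies over a residue alphabet."""

    def __init__(self, alphabet: str, energies: Dict[Tuple[str, str], float]):
        self.alphabet = alphabet
        self._eps: Dict[Tuple[str, str], float] = {}
        for (a, b), e in energies.items():
            if a not in alphabet or b not in alphabet:
                raise ValueError(f"pair ({a}, {b}) outside alphabet {alphabet!r}")
            self._eps[(a, b)] = e
            self._eps[(b, a)] = e

    def __call__(self, a: str, b: str) -> float:
        return self._eps.get((a, b), 0.0)

    def max_abs(self) -> float:
        return max((abs(v) for v in self._eps.values()), default=0.0)

    @classmethod
    def hp(cls, hh_energy: float = -1.0) -> "InteractionMatrix":
        """The HP preset: eps(H,H) = -1, every other pair 0."""
        return cls(HP_ALPHABET, {("H", "H"): hh_energy})

    @classmethod
    def from_csv(cls, text: str) -> "InteractionMatrix":
        """Parse a square CSV matrix with residue letters as header row/column.

        The body must be symmetric; asymmetry is a validation error.
        """
        rows = [r.strip() for r in text.strip().splitlines() if r.strip()]
        header = [c.strip() for c in rows[0].split(",") if c.strip()]
        alphabet = "".join(header)
        if len(rows) - 1 != len(header):
            raise ValueError(
                f"matrix has {len(rows) - 1} body rows but {len(header)} header columns"
            )
        energies: Dict[Tuple[str, str], float] = {}
        table: Dict[Tuple[str, str], float] = {}
        for r, line in enumerate(rows[1:]):
            cells = [c.strip() for c in line.split(",")]
            row_letter = cells[0]
            if row_letter != header[r]:
                raise ValueError(
                    f"row {r + 1}: row letter {row_letter!r} != header {header[r]!r}"
                )
            if len(cells) - 1 != len(header):
                raise ValueError(f"row {r + 1}: expected {len(header)} values")
            for c, cell in enumerate(cells[1:]):
                table[(row_letter, header[c])] = float(cell)
        for (a, b), v in table.items():
            if table[(b, a)] != v:
                raise ValueError(
                    f"matrix not symmetric at ({a}, {b}): {v} != {table[(b, a)]}"
                )
            energies[(a, b)] = v
        return cls(alphabet, energies)

    def to_csv(self) -> str:
        letters = list(self.alphabet)
        lines = ["," + ",".join(letters)]
        for a in letters:
            lines.append(a + "," + ",".join(repr(self(a, b)) for b in letters))
        return "\n".join(lines) + "\n"


@dataclass
class Fold:
    """Ordered bead coordinates on a lattice of a given kind.

    Connectivity (consecutive beads adjacent) is an invariant checked on
    construction; self-avoidance is a *computed* property so that
    self-intersecting configurations remain representable.
    """

    kind: str
    coordinates: List[Coord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = [tuple(c) for c in self.coordinates]
        for a, b in zip(self.coordinates, self.coordinates[1:]):
            if not lat.infinite_adjacent(self.kind, a, b):
                raise ValueError(f"beads at {a} and {b} are not lattice neighbors")

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def is_valid(self) -> bool:
        """True iff all beads occupy distinct sites (self-avoidance)."""
        return len(set(self.coordinates)) == len(self.coordinates)

    def translated(self, offset: Seq[int]) -> "Fold":
        ox, oy, oz = offset
        return Fold(self.kind, [(x + ox, y + oy, z + oz) for x, y, z in self.coordinates])

    def to_xyz(self, sequence: Optional[Sequence] = None) -> str:
        n = len(self.coordinates)
        lines = [str(n), f"lattice={self.kind}"]
        for i, (x, y, z) in enumerate(self.coordinates):
            el = sequence[i] if sequence is not None else "C"
            lines.append(f"{el} {x:.3f} {y:.3f} {z:.3f}")
        return "\n".join(lines) + "\n"

    def to_pdb(self, sequence: Optional[Sequence] = None) -> str:
        """CA-only PDB-like records (one ATOM line per bead)."""
        lines = []
        for i, (x, y, z) in enumerate(self.coordinates):
            res = (sequence[i] if sequence is not None else "G").ljust(3)
            lines.append(
                f"ATOM  {i + 1:5d}  CA  {res}A{i + 1:4d}    "
                f"{float(x):8.3f}{float(y):8.3f}{float(z):8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def contact_energy(fold: Fold, seq: Sequence, eps: InteractionMatrix) -> float:
    """Sum of eps(a_i, a_j) over non-bonded nearest-neighbor pairs.

    A pair (i, j) contributes iff the beads occupy adjacent sites and
    ``|i - j| > 1``.  Overlapping beads are never adjacent to themselves,
    so self-intersecting folds still have a well-defined energy.
    """
    if len(fold) != len(seq):
        raise ValueError(f"fold has {len(fold)} beads but sequence has {len(seq)}")
    coords = fold.coordinates
    total = 0.0
    for i in range(len(coords)):
        for j in range(i + 2, len(coords)):
            if lat.infinite_adjacent(fold.kind, coords[i], coords[j]):
                total += eps(seq[i], seq[j])
    return total


def enumerate_saws(
    n_beads: int,
    kind: str,
    symmetry_reduced: bool = False,
    guard_override: bool = False,
) -> Iterator[Fold]:
    """Yield every self-avoiding walk of ``n_beads`` beads from the origin.

    With ``symmetry_reduced`` the first step is fixed to the first step
    direction, cutting the point-group degeneracy of that step.  Order is
    deterministic (depth-first over the fixed step-direction order).
    """
    if n_beads < 1:
        raise InvalidSequenceError("need at least 1 bead")
    if n_beads > SAW_GUARD[kind] and not guard_override:
        raise ValueError(
            f"n_beads={n_beads} exceeds enumeration guard {SAW_GUARD[kind]} "
            "for the {kind} lattice; pass guard_override=True to force"
        )
    origin: Coord = (0, 0, 0)
    path: List[Coord] = [origin]
    occupied = {origin}

    def extend(depth: int) -> Iterator[Fold]:
        if depth == n_beads:
            yield Fold(kind, list(path))
            return
        steps = lat.infinite_steps(kind, path[-1])
        if depth == 1 and symmetry_reduced:
            steps = steps[:1]
        x, y, z = path[-1]
        for dx, dy, dz in steps:
            nxt = (x + dx, y + dy, z + dz)
            if nxt in occupied:
                continue
            path.append(nxt)
            occupied.add(nxt)
            yield from extend(depth + 1)
            path.pop()
            occupied.remove(nxt)

    return extend(1)


def has_contact(fold: Fold) -> bool:
    """True iff some pair with ``|i - j| > 1`` occupies adjacent sites."""
    coords = fold.coordinates
    for i in range(len(coords)):
        for j in range(i + 2, len(coords)):
            if lat.infinite_adjacent(fold.kind, coords[i], coords[j]):
                return True
    return False


def min_contact_length(kind: str) -> int:
    """Smallest N for which some SAW has a non-bonded nearest-neighbor contact.

    Determined by exhaustive enumeration (symmetry-reduced; contact
    existence is invariant under the point group).
    """
    for n in range(2, SAW_GUARD[kind] + 1):
        if any(has_contact(f) for f in enumerate_saws(n, kind, symmetry_reduced=True)):
            return n
    raise RuntimeError("no contact found within the enumeration guard")


def ground_truth_minimum(
    seq: Sequence,
    kind: str,
    eps: InteractionMatrix,
    return_argmins: bool = False,
    guard_override: bool = False,
) -> Tuple[float, List[Fold]] | float:
    """Exact minimum contact energy over all valid SAWs of ``len(seq)`` beads.

    When ``return_argmins`` is true, all minimizing folds are returned
    (from the full, non-symmetry-reduced enumeration); otherwise the
    symmetry-reduced enumeration is used, which preserves the minimum.
    """
    best = float("inf")
    argmins: List[Fold] = []
    for fold in enumerate_saws(
        len(seq), kind, symmetry_reduced=not return_argmins, guard_override=guard_override
    ):
        e = contact_energy(fold, seq, eps)
        if e < best - 1e-12:
            best = e
            argmins = [fold] if return_argmins else []
        elif return_argmins and e < best + 1e-12:
            argmins.append(fold)
    if return_argmins:
        return best, argmins
    return best
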