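"""Finite Cartesian and tetrahedral (diamond) lattices.

The diamond lattice is built from two interleaved FCC sublattices in
quarter-cell integer units: sublattice A is spanned by the primitive
vectors (0,2,2), (2,0,2), (2,2,0); sublattice B is A shifted by (1,1,1).
A site in A is adjacent to the four B sites reached by the bond vectors
(1,1,1), (1,-1,-1), (-1,1,-1), (-1,-1,1); bonds from B are the negations.
All arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

Coord = Tuple[int, int, int]

CARTESIAN = "cartesian"
DIAMOND = "diamond"

#: Bond vectors leaving sublattice A (sign product +1); B uses the negations.
DIAMOND_BONDS: Tuple[Coord, ...] = ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))

#: FCC primitive vectors spanning sublattice A (quarter-cell units).
FCC_PRIMITIVE: Tuple[Coord, ...] = ((0, 2, 2), (2, 0, 2), (2, 2, 0))

CARTESIAN_STEPS: Tuple[Coord, ...] = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


class InvalidSpecError(ValueError):
    """Raised for non-positive extents or unknown lattice kinds."""


class InvalidSequenceError(ValueError):
    """Raised when a sequence is too short or over the wrong alphabet."""


@dataclass(frozen=True)
class LatticeSpec:
    """Finite lattice description.

    ``extents`` is ``(L_x, L_y, L_z)`` for the Cartesian lattice and
    ``(l_1, l_2)`` for the diamond lattice (cells per FCC sublattice,
    each sublattice holding ``l^3`` sites).
    """

    kind: str
    extents: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in (CARTESIAN, DIAMOND):
            raise InvalidSpecError(f"unknown lattice kind {self.kind!r}")
        expected = 3 if self.kind == CARTESIAN else 2
        if len(self.extents) != expected:
            raise InvalidSpecError(
                f"{self.kind} lattice needs {expected} extents, got {self.extents}"
            )
        if any(e < 1 for e in self.extents):
            raise InvalidSpecError(f"extents must be positive, got {self.extents}")

    @property
    def site_count(self) -> int:
        if self.kind == CARTESIAN:
            lx, ly, lz = self.extents
            return lx * ly * lz
        l1, l2 = self.extents
        return l1**3 + l2**3

    @staticmethod
    def cartesian(lx: int, ly: int | None = None, lz: int | None = None) -> "LatticeSpec":
        ly = lx if ly is None else ly
        lz = lx if lz is None else lz
        return LatticeSpec(CARTESIAN, (lx, ly, lz))

    @staticmethod
    def diamond(l1: int, l2: int | None = None) -> "LatticeSpec":
        return LatticeSpec(DIAMOND, (l1, l1 if l2 is None else l2))


class Lattice:
    """Realized finite lattice: site index map plus adjacency.

    Site ids are assigned deterministically: lexicographic on coordinates
    for the Cartesian lattice, sublattice-major (all of A, then all of B)
    with lexicographic cell order within each sublattice for diamond.
    """

    def __init__(self, spec: LatticeSpec) -> None:
        self.spec = spec
        self.coordinates: List[Coord] = []
        self._by_coord: Dict[Coord, int] = {}
        self._parity: List[int] = []
        if spec.kind == CARTESIAN:
            lx, ly, lz = spec.extents
            for x in range(lx):
                for y in range(ly):
                    for z in range(lz):
                        self._add((x, y, z), (x + y + z) % 2)
        else:
            l1, l2 = spec.extents
            for sub, (l, shift) in enumerate(((l1, (0, 0, 0)), (l2, (1, 1, 1)))):
                cells = sorted(
                    tuple(
                        i * a + j * b + k * c + s
                        for a, b, c, s in zip(*FCC_PRIMITIVE, shift)
                    )
                    for i in range(l)
                    for j in range(l)
                    for k in range(l)
                )
                for coord in cells:
                    self._add(coord, sub)
        self.adjacency: List[Tuple[int, ...]] = [
            tuple(
                self._by_coord[nb]
                for nb in self._neighbor_coords(coord)
                if nb in self._by_coord
            )
            for coord in self.coordinates
        ]

    def _add(self, coord: Coord, parity: int) -> None:
        self._by_coord[coord] = len(self.coordinates)
        self.coordinates.append(coord)
        self._parity.append(parity)

    def _neighbor_coords(self, coord: Coord) -> List[Coord]:
        x, y, z = coord
        if self.spec.kind == CARTESIAN:
            steps = CARTESIAN_STEPS
        else:
            sign = 1 if self._parity[self._by_coord[coord]] == 0 else -1
            steps = [(sign * a, sign * b, sign * c) for a, b, c in DIAMOND_BONDS]
        return [(x + dx, y + dy, z + dz) for dx, dy, dz in steps]

    # -- queries --------------------------------------------------------

    @property
    def site_count(self) -> int:
        return len(self.coordinates)

    def site_id(self, coord: Sequence[int]) -> int:
        try:
            return self._by_coord[tuple(coord)]
        except KeyError:
            raise IndexError(f"coordinate {tuple(coord)} is not a lattice site") from None

    def contains(self, coord: Sequence[int]) -> bool:
        return tuple(coord) in self._by_coord

    def neighbors(self, site_id: int) -> Tuple[int, ...]:
        self._check(site_id)
        return self.adjacency[site_id]

    def parity(self, site_id: int) -> int:
        self._check(site_id)
        return self._parity[site_id]

    def parity_class(self, parity: int) -> Tuple[int, ...]:
        return tuple(i for i, p in enumerate(self._parity) if p == parity)

    def adjacent(self, a: int, b: int) -> bool:
        return b in self.adjacency[a]

    def _check(self, site_id: int) -> None:
        if not 0 <= site_id < self.site_count:
            raise IndexError(f"site id {site_id} out of range [0, {self.site_count})")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        edges = sorted(
            (i, j) for i, nbrs in enumerate(self.adjacency) for j in nbrs if i < j
        )
        return {
            "kind": self.spec.kind,
            "extents": list(self.spec.extents),
            "sites": [
                {"id": i, "xyz": list(c), "parity": p}
                for i, (c, p) in enumerate(zip(self.coordinates, self._parity))
            ],
            "edges": [list(e) for e in edges],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_lattice(spec: LatticeSpec) -> Lattice:
    """Construct the site index map and adjacency for ``spec``."""
    return Lattice(spec)


def _ceil_cbrt(value: int) -> int:
    """Exact integer ceiling cube root (avoids float cube-root drift)."""
    r = round(value ** (1.0 / 3.0))
    while r**3 < value:
        r += 1
    while (r - 1) ** 3 >= value:
        r -= 1
    return r


def min_grid(sequence_length: int, kind: str) -> LatticeSpec:
    """Smallest symmetric lattice used for a chain of ``sequence_length`` beads.

    Cartesian: ``L = ceil(N^(1/3)) + 1``.  Diamond (per sublattice):
    ``l = ceil((N/2)^(1/3)) + 1``.
    """
    if sequence_length < 2:
        raise InvalidSequenceError(
            f"sequence length must be >= 2, got {sequence_length}"
        )
    if kind == CARTESIAN:
        side = _ceil_cbrt(sequence_length) + 1
        return LatticeSpec.cartesian(side)
    if kind == DIAMOND:
        # ceil((N/2)^(1/3)) == ceil_cbrt(ceil(N/2)) for integer N
        side = _ceil_cbrt((sequence_length + 1) // 2) + 1
        return LatticeSpec.diamond(side)
    raise InvalidSpecError(f"unknown lattice kind {kind!r}")


def infinite_parity(kind: str, coord: Sequence[int]) -> int:
    """Parity of a coordinate on the infinite lattice of the given kind."""
    x, y, z = coord
    if kind == CARTESIAN:
        return (x + y + z) % 2
    # diamond in quarter-cell units: A sites have all-even coordinates,
    # B sites all-odd.
    return x & 1


def infinite_adjacent(kind: str, a: Sequence[int], b: Sequence[int]) -> bool:
    """Nearest-neighbor test on the infinite lattice (no boundaries)."""
    dx = b[0] - a[0]
    dy = b[1] - a[1]
    dz = b[2] - a[2]
    if kind == CARTESIAN:
        return abs(dx) + abs(dy) + abs(dz) == 1
    if abs(dx) != 1 or abs(dy) != 1 or abs(dz) != 1:
        return False
    sign = 1 if infinite_parity(DIAMOND, a) == 0 else -1
    return dx * dy * dz == sign


def infinite_steps(kind: str, coord: Sequence[int]) -> List[Coord]:
    """Step vectors available from ``coord`` on the infinite lattice."""
    if kind == CARTESIAN:
        return list(CARTESIAN_STEPS)
    sign = 1 if infinite_parity(DIAMOND, coord) == 0 else -1
    return [(sign * a, sign * b, sign * c) for a, b, c in DIAMOND_BONDS]
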