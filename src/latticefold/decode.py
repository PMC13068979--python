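"""Map solver bitstrings back to folds, with feasibility bookkeeping.

Infeasible assignments decode to partial bead placements plus flags
rather than raising: self-intersecting configurations are first-class
results here, because demonstrating the turn-model overlap flaw requires
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import lattice as lat
from .encoders.base import (
    COORD_CARTESIAN,
    COORD_TETRAHEDRAL,
    TURN_CARTESIAN,
    TURN_TETRAHEDRAL,
    EncodedModel,
)
from .encoders.turns import layout_for
from .fold import Fold, InteractionMatrix, Sequence, contact_energy
from .lattice import build_lattice
from .reduction import ReductionRecord, strip_ancillas
from .solvers.exact import TurnSpaceResult, turn_space_exact


@dataclass
class DecodedSolution:
    """A decoded assignment: bead placements, feasibility flags, energies."""

    coordinates: List[Optional[Tuple[int, int, int]]]
    fold: Optional[Fold]
    onehot_ok: bool
    connectivity_ok: bool
    self_avoiding: bool
    invalid_turn_codes: bool
    ancilla_consistent: bool
    model_energy: float
    contact_energy: Optional[float]
    interaction_bits: Dict[Tuple[int, int], int] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return (
            self.onehot_ok
            and self.connectivity_ok
            and self.self_avoiding
            and not self.invalid_turn_codes
            and self.ancilla_consistent
        )

    def to_dict(self) -> dict:
        return {
            "coordinates": [list(c) if c else None for c in self.coordinates],
            "onehot_ok": self.onehot_ok,
            "connectivity_ok": self.connectivity_ok,
            "self_avoiding": self.self_avoiding,
            "invalid_turn_codes": self.invalid_turn_codes,
            "ancilla_consistent": self.ancilla_consistent,
            "feasible": self.feasible,
            "model_energy": self.model_energy,
            "contact_energy": self.contact_energy,
            "interaction_bits": {f"{i},{j}": q for (i, j), q in self.interaction_bits.items()},
        }


def decode(
    assignment: Dict[int, int],
    encoded: EncodedModel,
    reduction: Optional[ReductionRecord] = None,
) -> DecodedSolution:
    """Decode a (possibly reduced) assignment into a bead placement."""
    ancilla_ok = True
    if reduction is not None:
        assignment, ancilla_ok = strip_ancillas(assignment, reduction)
    missing = [v for v in encoded.decoder_map if v not in assignment]
    if missing:
        raise ValueError(f"assignment is missing model variables {missing[:5]}")
    model_energy = encoded.poly.evaluate(assignment)

    if encoded.model_kind in (COORD_CARTESIAN, COORD_TETRAHEDRAL):
        sol = _decode_coordinate(assignment, encoded)
    else:
        sol = _decode_turns(assignment, encoded)

    sol.ancilla_consistent = ancilla_ok
    sol.model_energy = model_energy
    if sol.fold is not None:
        sol.contact_energy = contact_energy(
            sol.fold, encoded.sequence, encoded.interactions
        )
    return sol


def _decode_coordinate(assignment: Dict[int, int], encoded: EncodedModel) -> DecodedSolution:
    lattice = build_lattice(encoded.lattice)
    n = len(encoded.sequence)
    registers: List[List[int]] = [[] for _ in range(n)]
    for v, info in encoded.decoder_map.items():
        if info["role"] == "site" and assignment[v] == 1:
            registers[info["bead"]].append(info["site"])
    onehot_ok = all(len(r) == 1 for r in registers)
    coords: List[Optional[Tuple[int, int, int]]] = [
        lattice.coordinates[r[0]] if len(r) == 1 else None for r in registers
    ]
    connectivity_ok = all(
        a is not None
        and b is not None
        and lat.infinite_adjacent(encoded.lattice_kind, a, b)
        for a, b in zip(coords, coords[1:])
    )
    placed = [c for c in coords if c is not None]
    self_avoiding = len(set(placed)) == len(placed) and len(placed) == n
    fold = (
        Fold(encoded.lattice_kind, [c for c in coords])  # type: ignore[arg-type]
        if connectivity_ok and onehot_ok
        else None
    )
    return DecodedSolution(
        coordinates=coords,
        fold=fold,
        onehot_ok=onehot_ok,
        connectivity_ok=connectivity_ok,
        self_avoiding=self_avoiding,
        invalid_turn_codes=False,
        ancilla_consistent=True,
        model_energy=0.0,
        contact_energy=None,
    )


def _decode_turns(assignment: Dict[int, int], encoded: EncodedModel) -> DecodedSolution:
    layout = layout_for(encoded)
    n_turns = layout.n_turns
    directions: List[Optional[int]] = [None] * n_turns
    for k, d in layout.fixed.items():
        directions[k] = d
    onehot_ok = True
    invalid = False
    if encoded.flavor == "sparse":
        hot: Dict[int, List[int]] = {k: [] for k in layout.turn_vars if layout.turn_vars[k]}
        for v, info in encoded.decoder_map.items():
            if info["role"] == "turn" and assignment[v] == 1:
                hot[info["turn"]].append(info["direction"])
        for k, dirs in hot.items():
            if len(dirs) == 1:
                directions[k] = dirs[0]
            else:
                onehot_ok = False
    else:
        codes: Dict[int, int] = {k: 0 for k in layout.turn_vars if layout.turn_vars[k]}
        for v, info in encoded.decoder_map.items():
            if info["role"] == "turn" and assignment[v] == 1:
                codes[info["turn"]] += 1 << info["bit"]
        n_dirs = 4 if encoded.model_kind == TURN_TETRAHEDRAL else 6
        for k, code in codes.items():
            if code < n_dirs:
                directions[k] = code
            else:
                invalid = True

    interaction_bits = {
        tuple(info["pair"]): assignment[v]
        for v, info in encoded.decoder_map.items()
        if info["role"] == "interaction"
    }

    coords: List[Optional[Tuple[int, int, int]]] = [(0, 0, 0)]
    fold = None
    if all(d is not None for d in directions):
        steps = layout.step_vectors([d for d in directions])  # type: ignore[list-item]
        pos = (0, 0, 0)
        for dx, dy, dz in steps:
            pos = (pos[0] + dx, pos[1] + dy, pos[2] + dz)
            coords.append(pos)
        fold = Fold(encoded.lattice_kind, coords)  # type: ignore[arg-type]
    else:
        coords = coords + [None] * n_turns

    placed = [c for c in coords if c is not None]
    return DecodedSolution(
        coordinates=coords,
        fold=fold,
        onehot_ok=onehot_ok,
        connectivity_ok=fold is not None,
        self_avoiding=fold.is_valid if fold is not None else False,
        invalid_turn_codes=invalid,
        ancilla_consistent=True,
        model_energy=0.0,
        contact_energy=None,
        interaction_bits=interaction_bits,
    )


def fold_to_assignment(encoded: EncodedModel, fold: Fold) -> Dict[int, int]:
    """Feasible coordinate-model assignment hosting ``fold`` (re-encoding).

    The fold is translated onto the finite lattice respecting the
    bead-parity register structure; raises if no translation fits.
    """
    if encoded.model_kind not in (COORD_CARTESIAN, COORD_TETRAHEDRAL):
        raise ValueError("fold_to_assignment applies to coordinate models")
    if len(fold) != len(encoded.sequence):
        raise ValueError("fold/sequence length mismatch")
    lattice = build_lattice(encoded.lattice)
    coords = fold.coordinates
    if encoded.lattice_kind == "cartesian":
        lx, ly, lz = encoded.lattice.extents
        mins = [min(c[d] for c in coords) for d in range(3)]
        maxs = [max(c[d] for c in coords) for d in range(3)]
        shift = None
        for dx in range(-mins[0], lx - maxs[0]):
            for dy in range(-mins[1], ly - maxs[1]):
                for dz in range(-mins[2], lz - maxs[2]):
                    if (dx + dy + dz) % 2 == lat.infinite_parity(
                        "cartesian", coords[0]
                    ):  # bead 0 must land on parity class 0
                        shift = (dx, dy, dz)
                        break
                if shift:
                    break
            if shift:
                break
        if shift is None:
            raise ValueError("fold does not fit the lattice")
        placed = [(x + shift[0], y + shift[1], z + shift[2]) for x, y, z in coords]
    else:
        # diamond: translate by an A-sublattice vector in cell coordinates
        cells = []
        for t, (x, y, z) in enumerate(coords):
            p = lat.infinite_parity("diamond", (x, y, z))
            if p != t % 2:
                raise ValueError("bead parity does not match register parity")
            x, y, z = x - p, y - p, z - p
            i, j, k = (y + z - x) // 4, (x + z - y) // 4, (x + y - z) // 4
            cells.append((i, j, k, p))
        l1 = encoded.lattice.extents[0]
        shift3 = []
        for d in range(3):
            lo = min(c[d] for c in cells)
            hi = max(c[d] for c in cells)
            if hi - lo >= l1:
                raise ValueError("fold does not fit the lattice")
            shift3.append(-lo)
        placed = [
            (2 * (j + shift3[1]) + 2 * (k + shift3[2]) + p,
             2 * (i + shift3[0]) + 2 * (k + shift3[2]) + p,
             2 * (i + shift3[0]) + 2 * (j + shift3[1]) + p)
            for i, j, k, p in cells
        ]
    assignment = {}
    site_ids = [lattice.site_id(c) for c in placed]
    for v, info in encoded.decoder_map.items():
        assignment[v] = int(info["site"] == site_ids[info["bead"]])
    return assignment


def directions_to_assignment(
    encoded: EncodedModel, directions: Tuple[int, ...]
) -> Dict[int, int]:
    """Feasible turn-model assignment for a full direction tuple.

    Interaction variables take their conditionally optimal values and
    slack registers their exact residuals, reproducing the turn-space
    enumeration energy when the polynomial is evaluated.
    """
    layout = layout_for(encoded)
    for k, d in layout.fixed.items():
        if directions[k] != d:
            raise ValueError(f"turn {k} is symmetry-fixed to direction {d}")
    assignment: Dict[int, int] = {}
    for v, info in encoded.decoder_map.items():
        if info["role"] == "turn":
            d = directions[info["turn"]]
            if "bit" in info:
                assignment[v] = (d >> info["bit"]) & 1
            else:
                assignment[v] = int(info["direction"] == d)
    # bead positions in count space (diamond) / coordinates (cartesian)
    steps = layout.step_vectors(list(directions))
    pos = [(0, 0, 0)]
    for dx, dy, dz in steps:
        x, y, z = pos[-1]
        pos.append((x + dx, y + dy, z + dz))

    def sq_dist(i: int, j: int) -> int:
        d2 = sum((pos[j][c] - pos[i][c]) ** 2 for c in range(3))
        if encoded.lattice_kind == lat.DIAMOND:
            # count-space distance: Euclidean^2 = 4 D - (j - i odd)
            return (d2 + ((j - i) % 2)) // 4
        return d2

    pen = encoded.penalties
    seq, eps = encoded.sequence, encoded.interactions
    n = len(seq)
    for v, info in encoded.decoder_map.items():
        if info["role"] != "interaction":
            continue
        i, j = info["pair"]
        bracket = eps(seq[i], seq[j]) + pen.lambda1 * (sq_dist(i, j) - 1)
        for r in (j - 1, j + 1):
            if 0 <= r < n and r != i:
                bracket += pen.lambda2 * (2 - sq_dist(*sorted((i, r))))
        for m in (i - 1, i + 1):
            if 0 <= m < n and m != j:
                bracket += pen.lambda2 * (2 - sq_dist(*sorted((m, j))))
        assignment[v] = int(bracket < 0)
    for v, info in encoded.decoder_map.items():
        if info["role"] == "slack":
            j, k = info["pair"]
            residual = max(sq_dist(j, k) - 1, 0)
            assignment[v] = (residual >> info["bit"]) & 1
    return assignment


@dataclass
class OverlapFlawReport:
    """Partition of a turn model's exact minimizers by self-avoidance."""

    min_energy: float
    valid_folds: List[Fold]
    overlapping_folds: List[Fold]
    valid_q: List[Dict[Tuple[int, int], int]]
    overlapping_q: List[Dict[Tuple[int, int], int]]

    @property
    def flaw_demonstrated(self) -> bool:
        """True iff valid and self-intersecting minimizers coexist."""
        return bool(self.valid_folds) and bool(self.overlapping_folds)


def demonstrate_overlap_flaw(
    encoded: EncodedModel, guard_override: bool = False
) -> OverlapFlawReport:
    """Exhaustively partition a turn model's ground states by validity."""
    result: TurnSpaceResult = turn_space_exact(encoded, guard_override=guard_override)
    valid_folds, overlapping_folds = [], []
    valid_q, overlapping_q = [], []
    for fold, q in zip(result.folds, result.q_choices):
        if fold.is_valid:
            valid_folds.append(fold)
            valid_q.append(q)
        else:
            overlapping_folds.append(fold)
            overlapping_q.append(q)
    return OverlapFlawReport(
        result.min_energy, valid_folds, overlapping_folds, valid_q, overlapping_q
    )
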