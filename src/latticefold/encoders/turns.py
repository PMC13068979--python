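"""Turn-based encodings on the Cartesian and tetrahedral lattices.

A conformation is the list of step directions between consecutive beads.
Directions are encoded either one-hot ("sparse") or in binary ("dense");
the first two turns are fixed to remove rotational degeneracy.  Squared
bead-bead distances are built from per-turn direction polynomials:

* tetrahedral: four direction-count axes with bead-parity alternating
  signs, ``D(i,j) = sum_a (sum_k (-1)^k t_a(k))^2`` — adjacency is
  ``D = 1``, overlap is ``D = 0``;
* Cartesian: the three coordinate deltas, ``D`` the squared Euclidean
  distance.

Contacts enter through one interaction variable per eligible bead pair
multiplying its energy plus distance-guard penalties; the Cartesian model
additionally excludes overlaps for every same-parity pair through a
slack-encoded inequality ``D > 0``, while the tetrahedral model penalizes
overlaps only inside the interaction guards (its known flaw).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence as Seq, Tuple

from ..fold import InteractionMatrix, Sequence
from ..lattice import CARTESIAN, CARTESIAN_STEPS, DIAMOND, DIAMOND_BONDS
from ..polynomial import BinaryPolynomial, multilinear_fit
from .base import (
    TURN_CARTESIAN,
    TURN_TETRAHEDRAL,
    EncodedModel,
    PenaltyConfig,
    default_penalties,
    eligible_interaction_pairs,
)

#: Symmetry-fixed directions for the first two turns.
FIXED_DIRECTIONS = {DIAMOND: (0, 1), CARTESIAN: (0, 2)}  # (+x then +y on Cartesian

N_DIRECTIONS = {DIAMOND: 4, CARTESIAN: 6}
DENSE_BITS = {DIAMOND: 2, CARTESIAN: 3}


def _dense_direction_tables(lattice_kind: str) -> List[List[float]]:
    """Per-axis value tables over the dense bit codes of one turn.

    Tetrahedral: four direction-indicator axes (all 4 codes valid).
    Cartesian: three coordinate-delta axes over 8 codes; codes 6 and 7 are
    invalid and their table values are chosen to cancel the cubic
    coefficient, keeping each delta polynomial quadratic (the invalid
    codes carry their own penalty, so their delta values are free).
    """
    if lattice_kind == DIAMOND:
        return [[1.0 if code == a else 0.0 for code in range(4)] for a in range(4)]
    tables = []
    for axis in range(3):
        values = [float(CARTESIAN_STEPS[code][axis]) for code in range(6)] + [0.0, 0.0]
        top = _cubic_coefficient(values)
        values[6] += top  # cancels the degree-3 term (see multilinear Möbius signs)
        tables.append(values)
    return tables


def _cubic_coefficient(values: Seq[float]) -> float:
    """Coefficient of b0*b1*b2 in the multilinear fit of an 8-entry table."""
    total = 0.0
    for code, v in enumerate(values):
        bits = bin(code).count("1")
        total += v if (3 - bits) % 2 == 0 else -v
    return total


class TurnLayout:
    """Variable layout and per-turn axis polynomials for a turn model."""

    def __init__(self, n_beads: int, lattice_kind: str, flavor: str) -> None:
        if flavor not in ("dense", "sparse"):
            raise ValueError(f"unknown encoding flavor {flavor!r}")
        self.n_beads = n_beads
        self.lattice_kind = lattice_kind
        self.flavor = flavor
        self.n_turns = n_beads - 1
        ndir = N_DIRECTIONS[lattice_kind]
        self.fixed: Dict[int, int] = {
            k: d for k, d in enumerate(FIXED_DIRECTIONS[lattice_kind]) if k < self.n_turns
        }
        self.decoder: Dict[int, dict] = {}
        self.turn_vars: Dict[int, List[int]] = {}
        v = 0
        for k in range(self.n_turns):
            if k in self.fixed:
                self.turn_vars[k] = []
                continue
            nbits = DENSE_BITS[lattice_kind] if flavor == "dense" else ndir
            bits = []
            for b in range(nbits):
                if flavor == "dense":
                    self.decoder[v] = {"role": "turn", "turn": k, "bit": b}
                else:
                    self.decoder[v] = {"role": "turn", "turn": k, "direction": b}
                bits.append(v)
                v += 1
            self.turn_vars[k] = bits
        self.next_var = v

        # per-turn axis polynomials (constants for the fixed turns)
        if lattice_kind == DIAMOND:
            dense_tables = _dense_direction_tables(DIAMOND)
            self.n_axes = 4
        else:
            dense_tables = _dense_direction_tables(CARTESIAN)
            self.n_axes = 3
        self.axis_polys: List[List[BinaryPolynomial]] = []
        for k in range(self.n_turns):
            per_axis = []
            for axis in range(self.n_axes):
                per_axis.append(self._axis_poly(k, axis, dense_tables))
            self.axis_polys.append(per_axis)

    def _axis_value_of_direction(self, direction: int, axis: int) -> float:
        if self.lattice_kind == DIAMOND:
            return 1.0 if direction == axis else 0.0
        return float(CARTESIAN_STEPS[direction][axis])

    def _axis_poly(
        self, turn: int, axis: int, dense_tables: List[List[float]]
    ) -> BinaryPolynomial:
        sign = -1.0 if (self.lattice_kind == DIAMOND and turn % 2 == 1) else 1.0
        if turn in self.fixed:
            return BinaryPolynomial(
                offset=sign * self._axis_value_of_direction(self.fixed[turn], axis)
            )
        bits = self.turn_vars[turn]
        if self.flavor == "sparse":
            poly = BinaryPolynomial()
            if self.lattice_kind == DIAMOND:
                poly.add_term((bits[axis],), sign)
            else:
                for d, var in enumerate(bits):
                    val = self._axis_value_of_direction(d, axis)
                    if val != 0.0:
                        poly.add_term((var,), val)
            return poly
        fitted = multilinear_fit(dense_tables[axis], len(bits))
        poly = BinaryPolynomial(offset=sign * fitted.offset)
        for mono, coeff in fitted.terms.items():
            poly.add_term(tuple(bits[b] for b in mono), sign * coeff)
        return poly

    # -- distance machinery ---------------------------------------------

    def squared_distance(self, i: int, j: int) -> BinaryPolynomial:
        """Polynomial squared distance between beads ``i < j``.

        Built from the turn window ``[i, j)``; degree is twice the axis
        polynomial degree (cross terms of distinct turns).
        """
        if not 0 <= i < j < self.n_beads:
            raise ValueError(f"invalid bead pair ({i}, {j})")
        total = BinaryPolynomial()
        for axis in range(self.n_axes):
            net = BinaryPolynomial()
            for k in range(i, j):
                net.add_polynomial(self.axis_polys[k][axis])
            total.add_polynomial(net * net)
        return total

    def step_vectors(self, directions: Seq[int]) -> List[Tuple[int, int, int]]:
        """Geometric step vectors for a full direction assignment."""
        steps = []
        for k, d in enumerate(directions):
            if self.lattice_kind == DIAMOND:
                sign = -1 if k % 2 else 1
                vec = DIAMOND_BONDS[d]
                steps.append((sign * vec[0], sign * vec[1], sign * vec[2]))
            else:
                steps.append(CARTESIAN_STEPS[d])
        return steps


def _interaction_terms(
    poly: BinaryPolynomial,
    layout: TurnLayout,
    seq: Sequence,
    eps: InteractionMatrix,
    penalties: PenaltyConfig,
    decoder: Dict[int, dict],
) -> None:
    """Add one guarded interaction variable per eligible bead pair.

    The term is ``q_ij * (eps_ij + l1 (D(i,j) - 1)
    + sum_{r in nbr(j)} l2 (2 - D(i,r)) + sum_{m in nbr(i)} l2 (2 - D(m,j)))``
    with ``nbr`` the sequence neighbors clipped at the chain ends.
    """
    n = layout.n_beads
    v = layout.next_var
    for i, j in eligible_interaction_pairs(seq, eps, layout.lattice_kind):
        bracket = BinaryPolynomial(offset=eps(seq[i], seq[j]))
        d_ij = layout.squared_distance(i, j)
        d_ij.offset -= 1.0
        bracket.add_polynomial(d_ij, scale=penalties.lambda1)
        for r in (j - 1, j + 1):
            if 0 <= r < n and r != i:
                guard = layout.squared_distance(*sorted((i, r)))
                guard_term = BinaryPolynomial(offset=2.0)
                guard_term.add_polynomial(guard, scale=-1.0)
                bracket.add_polynomial(guard_term, scale=penalties.lambda2)
        for m in (i - 1, i + 1):
            if 0 <= m < n and m != j:
                guard = layout.squared_distance(*sorted((m, j)))
                guard_term = BinaryPolynomial(offset=2.0)
                guard_term.add_polynomial(guard, scale=-1.0)
                bracket.add_polynomial(guard_term, scale=penalties.lambda2)
        q = BinaryPolynomial({(v,): 1.0})
        poly.add_polynomial(q * bracket)
        decoder[v] = {"role": "interaction", "pair": [i, j]}
        poly.labels[v] = f"q[{i},{j}]"
        v += 1
    layout.next_var = v


def _onehot_turn_penalties(
    poly: BinaryPolynomial, layout: TurnLayout, lam: float
) -> None:
    for k, bits in layout.turn_vars.items():
        if not bits:
            continue
        poly.offset += lam
        for a, var_a in enumerate(bits):
            poly.add_term((var_a,), -lam)
            for var_b in bits[a + 1 :]:
                poly.add_term((var_a, var_b), 2.0 * lam)


def encode_turn_tetrahedral(
    seq: Sequence,
    eps: InteractionMatrix,
    flavor: str = "dense",
    penalties: Optional[PenaltyConfig] = None,
) -> EncodedModel:
    """Turn model on the tetrahedral lattice (4 directions per turn).

    Dense flavor uses 2 bits per free turn (all codes valid), sparse uses
    a 4-way one-hot.  Overlaps are only penalized inside the interaction
    guards; the model's feasible space therefore contains
    self-intersecting folds.
    """
    if penalties is None:
        penalties = default_penalties(seq, eps, "tuned", DIAMOND)
    layout = TurnLayout(len(seq), DIAMOND, flavor)
    decoder = dict(layout.decoder)
    poly = BinaryPolynomial(labels=_turn_labels(decoder))
    if flavor == "sparse":
        _onehot_turn_penalties(poly, layout, penalties.lambda_onehot)
    _interaction_terms(poly, layout, seq, eps, penalties, decoder)
    return EncodedModel(
        poly=poly,
        model_kind=TURN_TETRAHEDRAL,
        flavor=flavor,
        lattice=None,
        decoder_map=decoder,
        penalties=penalties,
        sequence=seq,
        interactions=eps,
        fixed_turns=[layout.fixed[k] for k in sorted(layout.fixed)],
    )


def encode_turn_cartesian(
    seq: Sequence,
    eps: InteractionMatrix,
    flavor: str = "dense",
    penalties: Optional[PenaltyConfig] = None,
) -> EncodedModel:
    """Turn model on the Cartesian lattice (6 directions per turn).

    Dense flavor uses 3 bits per free turn with the two invalid codes
    penalized; sparse uses a 6-way one-hot.  Every same-parity bead pair
    gets a slack-encoded overlap constraint ``D > 0``.
    """
    if penalties is None:
        penalties = default_penalties(seq, eps, "tuned", CARTESIAN)
    n = len(seq)
    layout = TurnLayout(n, CARTESIAN, flavor)
    decoder = dict(layout.decoder)
    poly = BinaryPolynomial(labels=_turn_labels(decoder))

    if flavor == "sparse":
        _onehot_turn_penalties(poly, layout, penalties.lambda_onehot)
    else:
        # invalid codes 6 and 7 share the two high bits set
        for k, bits in layout.turn_vars.items():
            if bits:
                poly.add_term((bits[1], bits[2]), penalties.lambda_invalid)

    _interaction_terms(poly, layout, seq, eps, penalties, decoder)

    # overlap exclusion D(j,k) > 0 for every same-parity pair, via the
    # slack expansion (D - 1 - sum_l 2^l s_l)^2 with 2^mu >= max D
    for j in range(n):
        for k in range(j + 2, n, 2):
            d_poly = layout.squared_distance(j, k)
            d_max = (k - j) ** 2
            mu = max(1, (d_max - 1).bit_length())
            constraint = d_poly.copy()
            constraint.offset -= 1.0
            for l in range(mu):
                var = layout.next_var
                layout.next_var += 1
                decoder[var] = {"role": "slack", "pair": [j, k], "bit": l}
                poly.labels[var] = f"slack[{j},{k}]#{l}"
                constraint.add_term((var,), -float(2**l))
            poly.add_polynomial(constraint * constraint, scale=penalties.lambda_selfavoid)

    return EncodedModel(
        poly=poly,
        model_kind=TURN_CARTESIAN,
        flavor=flavor,
        lattice=None,
        decoder_map=decoder,
        penalties=penalties,
        sequence=seq,
        interactions=eps,
        fixed_turns=[layout.fixed[k] for k in sorted(layout.fixed)],
    )


def _turn_labels(decoder: Dict[int, dict]) -> Dict[int, str]:
    labels = {}
    for v, info in decoder.items():
        if info["role"] == "turn":
            tag = f"bit={info['bit']}" if "bit" in info else f"dir={info['direction']}"
            labels[v] = f"turn[{info['turn']},{tag}]"
    return labels


def layout_for(model: EncodedModel) -> TurnLayout:
    """Rebuild the turn layout of an encoded turn model (for decoding)."""
    from .base import LATTICE_OF_MODEL

    return TurnLayout(
        len(model.sequence), LATTICE_OF_MODEL[model.model_kind], model.flavor
    )
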