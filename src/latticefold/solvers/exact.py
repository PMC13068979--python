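"""Exhaustive oracles: full-state enumeration and turn-space enumeration."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

from ..encoders.base import EncodedModel, eligible_interaction_pairs
from ..encoders.turns import TurnLayout, layout_for
from ..fold import Fold
from ..lattice import CARTESIAN, DIAMOND, DIAMOND_BONDS, CARTESIAN_STEPS
from ..polynomial import BinaryPolynomial, QuadraticModel

EXACT_GUARD = 24
TURN_GUARD = 9


def exact_solve(
    model: Union[QuadraticModel, BinaryPolynomial],
    guard_override: bool = False,
    atol: float = 1e-9,
) -> Tuple[float, List[Dict[int, int]]]:
    """Exhaustive minimum over all Boolean states; returns all argmins."""
    if isinstance(model, QuadraticModel):
        poly = model.to_polynomial()
    else:
        poly = model
    variables = poly.variables()
    n = len(variables)
    if n > EXACT_GUARD and not guard_override:
        raise ValueError(
            f"{n} variables exceeds the exhaustive guard ({EXACT_GUARD}); "
            "pass guard_override=True to force"
        )
    pos = {v: k for k, v in enumerate(variables)}
    terms = [
        (np.array([pos[v] for v in mono], dtype=np.int64), c)
        for mono, c in poly.terms.items()
    ]
    if n == 0:
        return poly.offset, [{}]
    best = np.inf
    argmin_codes: List[int] = []
    chunk_bits = min(n, 20)
    codes_low = np.arange(1 << chunk_bits, dtype=np.int64)
    bits_low = ((codes_low[:, None] >> np.arange(chunk_bits)) & 1).astype(np.float64)
    for high in range(1 << (n - chunk_bits)):
        bits = np.empty((1 << chunk_bits, n))
        bits[:, :chunk_bits] = bits_low
        for k in range(chunk_bits, n):
            bits[:, k] = (high >> (k - chunk_bits)) & 1
        energy = np.full(1 << chunk_bits, poly.offset)
        for mono, c in terms:
            energy += c * bits[:, mono].prod(axis=1)
        chunk_min = energy.min()
        if chunk_min < best - atol:
            best = chunk_min
            argmin_codes = []
        if chunk_min < best + atol:
            where = np.nonzero(energy < best + atol)[0]
            argmin_codes.extend(int(c) | (high << chunk_bits) for c in where)
    argmins = []
    for code in argmin_codes:
        argmins.append({variables[k]: (code >> k) & 1 for k in range(n)})
    return float(best), argmins


@dataclass
class TurnSpaceResult:
    """Exact feasible-space minimum of a turn model."""

    min_energy: float
    folds: List[Fold]
    q_choices: List[Dict[Tuple[int, int], int]] = field(default_factory=list)
    directions: List[Tuple[int, ...]] = field(default_factory=list)


def turn_space_exact(
    model: EncodedModel, guard_override: bool = False, atol: float = 1e-9
) -> TurnSpaceResult:
    """Enumerate all direction assignments of a turn model exactly.

    Every interaction variable is set to its conditionally optimal value
    (1 iff its guarded bracket is negative) and every slack register to
    its optimal value, giving the exact minimum of the encoded objective
    over the feasible space (one-hot / valid-code conformations).
    """
    if model.model_kind not in ("turn_cartesian", "turn_tetrahedral"):
        raise ValueError("turn_space_exact requires a turn model")
    layout = layout_for(model)
    free = sorted(k for k, bits in layout.turn_vars.items() if bits)
    if len(free) > TURN_GUARD and not guard_override:
        raise ValueError(
            f"{len(free)} free turns exceeds the enumeration guard ({TURN_GUARD})"
        )
    kind = layout.lattice_kind
    ndir = 4 if kind == DIAMOND else 6
    n_turns = layout.n_turns
    n_beads = layout.n_beads
    n_assign = ndir ** len(free)

    directions = np.zeros((n_assign, n_turns), dtype=np.int8)
    for k, d in layout.fixed.items():
        directions[:, k] = d
    codes = np.arange(n_assign, dtype=np.int64)
    for idx, k in enumerate(free):
        directions[:, k] = (codes // (ndir**idx)) % ndir

    # distance prefixes: count-space axes (diamond) or coordinate deltas
    if kind == DIAMOND:
        axes = np.zeros((n_assign, n_turns, 4), dtype=np.int32)
        for k in range(n_turns):
            sign = -1 if k % 2 else 1
            for a in range(4):
                axes[:, k, a] = sign * (directions[:, k] == a)
    else:
        step_lut = np.array(CARTESIAN_STEPS, dtype=np.int32)
        axes = step_lut[directions]  # (n_assign, n_turns, 3)
    pref = np.zeros((n_assign, n_beads, axes.shape[2]), dtype=np.int32)
    np.cumsum(axes, axis=1, out=pref[:, 1:])

    def sq_dist(i: int, j: int) -> np.ndarray:
        diff = pref[:, j] - pref[:, i]
        return (diff * diff).sum(axis=1)

    energy = np.zeros(n_assign)
    pen = model.penalties
    seq, eps = model.sequence, model.interactions
    pairs = eligible_interaction_pairs(seq, eps, kind)
    brackets = {}
    for i, j in pairs:
        bracket = np.full(n_assign, eps(seq[i], seq[j]))
        bracket += pen.lambda1 * (sq_dist(i, j) - 1)
        for r in (j - 1, j + 1):
            if 0 <= r < n_beads and r != i:
                bracket += pen.lambda2 * (2 - sq_dist(*sorted((i, r))))
        for m in (i - 1, i + 1):
            if 0 <= m < n_beads and m != j:
                bracket += pen.lambda2 * (2 - sq_dist(*sorted((m, j))))
        brackets[(i, j)] = bracket
        energy += np.minimum(bracket, 0.0)

    if kind == CARTESIAN:
        for j in range(n_beads):
            for k in range(j + 2, n_beads, 2):
                energy += pen.lambda_selfavoid * (sq_dist(j, k) == 0)

    best = energy.min()
    winners = np.nonzero(energy < best + atol)[0]

    # geometric positions for the winning assignments
    if kind == DIAMOND:
        bond = np.array(DIAMOND_BONDS, dtype=np.int32)
        positions = pref[winners] @ bond  # counts -> coordinates
    else:
        positions = pref[winners]

    folds, q_choices, dir_tuples = [], [], []
    for row, w in enumerate(winners):
        folds.append(Fold(kind, [tuple(int(c) for c in p) for p in positions[row]]))
        q_choices.append(
            {pair: int(brackets[pair][w] < 0) for pair in pairs}
        )
        dir_tuples.append(tuple(int(d) for d in directions[w]))
    return TurnSpaceResult(float(best), folds, q_choices, dir_tuples)
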