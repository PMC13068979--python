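"""One-hot coordinate encodings on Cartesian and interleaved-FCC diamond grids.

Bead ``t`` carries a one-hot register over the lattice sites of parity
``t mod 2`` — consecutive beads live on opposite parity classes, which
halves the register sizes and makes connectivity a pairwise predicate.
The resulting objective is natively quadratic.
"""

from __future__ import annotations

from typing import Dict, Optional

from ..fold import InteractionMatrix, Sequence
from ..lattice import CARTESIAN, LatticeSpec, build_lattice, min_grid
from ..polynomial import BinaryPolynomial
from .base import (
    COORD_CARTESIAN,
    COORD_TETRAHEDRAL,
    CapacityError,
    EncodedModel,
    PenaltyConfig,
    default_penalties,
    eligible_interaction_pairs,
)


def encode_coordinate(
    seq: Sequence,
    lattice_spec: Optional[LatticeSpec],
    eps: InteractionMatrix,
    penalties: Optional[PenaltyConfig] = None,
    anchor_first_bead: bool = False,
) -> EncodedModel:
    """Build the coordinate-based model for ``seq`` on ``lattice_spec``.

    ``lattice_spec`` may be a Cartesian or diamond spec; ``None`` selects
    the minimal Cartesian grid.  With ``anchor_first_bead`` the register
    of bead 0 is restricted to a single site, cutting translational
    degeneracy at the cost of exact register-size bookkeeping.
    """
    n = len(seq)
    if lattice_spec is None:
        lattice_spec = min_grid(n, CARTESIAN)
    lattice = build_lattice(lattice_spec)
    if penalties is None:
        penalties = default_penalties(seq, eps, "tuned", lattice_spec.kind)

    classes = (lattice.parity_class(0), lattice.parity_class(1))
    for p in (0, 1):
        beads_on_p = (n + 1 - p) // 2  # beads with t % 2 == p
        if len(classes[p]) < beads_on_p:
            raise CapacityError(
                f"parity class {p} has {len(classes[p])} sites but must host "
                f"{beads_on_p} beads"
            )

    # variable allocation: bead-major, site order within the parity class
    decoder: Dict[int, dict] = {}
    registers = []  # per bead: list of (var, site_id)
    v = 0
    for t in range(n):
        sites = classes[t % 2]
        if t == 0 and anchor_first_bead:
            sites = sites[:1]
        reg = []
        for site in sites:
            decoder[v] = {"role": "site", "bead": t, "site": site}
            reg.append((v, site))
            v += 1
        registers.append(reg)

    poly = BinaryPolynomial(
        labels={v: f"x[bead={i['bead']},site={i['site']}]" for v, i in decoder.items()}
    )

    # one-hot: lambda * (sum_f x_tf - 1)^2 per bead
    lam = penalties.lambda_onehot
    for reg in registers:
        poly.offset += lam
        for a, (var_a, _) in enumerate(reg):
            poly.add_term((var_a,), -lam)
            for var_b, _ in reg[a + 1 :]:
                poly.add_term((var_a, var_b), 2.0 * lam)

    # connectivity: penalize consecutive beads on non-adjacent site pairs
    for t in range(n - 1):
        for var_f, f in registers[t]:
            for var_g, g in registers[t + 1]:
                if not lattice.adjacent(f, g):
                    poly.add_term((var_f, var_g), penalties.lambda_conn)

    # self-avoidance: same-parity beads may not share a site
    for t in range(n):
        occupancy: Dict[int, list] = {}
        for var_f, f in registers[t]:
            occupancy[f] = var_f
        for u in range(t + 2, n, 2):
            for var_g, g in registers[u]:
                if g in occupancy:
                    poly.add_term((occupancy[g], var_g), penalties.lambda_selfavoid)

    # interactions: eps(a_i, a_j) when eligible beads sit on adjacent sites
    for i, j in eligible_interaction_pairs(seq, eps, lattice_spec.kind):
        e = eps(seq[i], seq[j])
        for var_f, f in registers[i]:
            for var_g, g in registers[j]:
                if lattice.adjacent(f, g):
                    poly.add_term((var_f, var_g), e)

    kind = COORD_CARTESIAN if lattice_spec.kind == CARTESIAN else COORD_TETRAHEDRAL
    return EncodedModel(
        poly=poly,
        model_kind=kind,
        flavor=None,
        lattice=lattice_spec,
        decoder_map=decoder,
        penalties=penalties,
        sequence=seq,
        interactions=eps,
        anchored=anchor_first_bead,
    )
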