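"""Shared encoder types: penalty configuration and the encoded-model container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ..fold import InteractionMatrix, Sequence
from ..lattice import CARTESIAN, DIAMOND, LatticeSpec
from ..polynomial import BinaryPolynomial

COORD_CARTESIAN = "coord_cartesian"
COORD_TETRAHEDRAL = "coord_tetrahedral"
TURN_CARTESIAN = "turn_cartesian"
TURN_TETRAHEDRAL = "turn_tetrahedral"

MODEL_KINDS = (COORD_CARTESIAN, COORD_TETRAHEDRAL, TURN_CARTESIAN, TURN_TETRAHEDRAL)

#: Lattice kind underlying each model.
LATTICE_OF_MODEL = {
    COORD_CARTESIAN: CARTESIAN,
    COORD_TETRAHEDRAL: DIAMOND,
    TURN_CARTESIAN: CARTESIAN,
    TURN_TETRAHEDRAL: DIAMOND,
}

#: Smallest sequence separation at which a non-bonded contact is possible.
MIN_CONTACT_SEPARATION = {CARTESIAN: 3, DIAMOND: 5}


class CapacityError(ValueError):
    """Lattice too small to host the chain."""


@dataclass
class PenaltyConfig:
    """Positive penalty strengths for the constraint families.

    Coordinate models use ``lambda_onehot`` / ``lambda_conn`` /
    ``lambda_selfavoid``; turn models use ``lambda1`` (contact distance)
    and ``lambda2`` (neighbor-distance guard), plus ``lambda_onehot`` for
    sparse one-hot turns, ``lambda_invalid`` for dense Cartesian invalid
    codes and ``lambda_selfavoid`` for the slack-encoded overlap
    inequalities.
    """

    lambda_onehot: float = 1.0
    lambda_conn: float = 1.0
    lambda_selfavoid: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda_invalid: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "lambda_onehot",
            "lambda_conn",
            "lambda_selfavoid",
            "lambda1",
            "lambda2",
            "lambda_invalid",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "lambda_onehot": self.lambda_onehot,
            "lambda_conn": self.lambda_conn,
            "lambda_selfavoid": self.lambda_selfavoid,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda_invalid": self.lambda_invalid,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PenaltyConfig":
        return cls(**data)


def eligible_interaction_pairs(
    seq: Sequence, eps: InteractionMatrix, lattice_kind: str
) -> List[Tuple[int, int]]:
    """Bead pairs that can realize a non-bonded contact with nonzero energy.

    On both (bipartite) lattices adjacency forces odd sequence
    separation; the minimum separation is 3 (Cartesian) or 5 (diamond).
    Pairs with zero interaction energy are skipped: they cannot change
    the objective.
    """
    min_sep = MIN_CONTACT_SEPARATION[lattice_kind]
    n = len(seq)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + min_sep, n, 2)
        if eps(seq[i], seq[j]) != 0.0
    ]


def default_penalties(
    seq: Sequence,
    eps: InteractionMatrix,
    mode: str = "tuned",
    lattice_kind: str = CARTESIAN,
) -> PenaltyConfig:
    """Package penalty defaults.

    ``worst_case`` sets the base strength to ``1 + sum |eps|`` over the
    eligible interaction pairs (the worst-case bound applied per
    constraint family); ``tuned`` uses ``1 + max |eps|``.

    The contact-distance strength ``lambda1`` is set to five times the
    base: each interaction bracket contains up to four neighbor-distance
    guards whose ``2 - D`` terms decrease roughly linearly in the contact
    distance, so ``lambda1 > 4 lambda2`` is required for the bracket to
    be minimized at an actual contact (``D = 1``) instead of rewarding
    stretched conformations.
    """
    if mode == "worst_case":
        lam = 1.0 + sum(
            abs(eps(seq[i], seq[j]))
            for i, j in eligible_interaction_pairs(seq, eps, lattice_kind)
        )
    elif mode == "tuned":
        lam = 1.0 + eps.max_abs()
    else:
        raise ValueError(f"unknown penalty mode {mode!r}")
    return PenaltyConfig(lam, lam, lam, 5.0 * lam, lam, lam)


@dataclass
class EncodedModel:
    """A binary objective plus the metadata needed to decode solutions."""

    poly: BinaryPolynomial
    model_kind: str
    flavor: Optional[str]  # dense | sparse for turn models, None otherwise
    lattice: Optional[LatticeSpec]
    decoder_map: Dict[int, dict]
    penalties: PenaltyConfig
    sequence: Sequence
    interactions: InteractionMatrix
    fixed_turns: List[int] = field(default_factory=list)
    anchored: bool = False

    @property
    def lattice_kind(self) -> str:
        return LATTICE_OF_MODEL[self.model_kind]

    @property
    def n_variables(self) -> int:
        return len(self.decoder_map)

    def variables_with_role(self, role: str) -> List[int]:
        return sorted(v for v, info in self.decoder_map.items() if info["role"] == role)

    @property
    def conformation_variables(self) -> List[int]:
        return self.variables_with_role("site") + self.variables_with_role("turn")

    @property
    def free_turns(self) -> List[int]:
        """Indices of turns carrying variables (not symmetry-fixed)."""
        return sorted(
            {info["turn"] for info in self.decoder_map.values() if info["role"] == "turn"}
        )

    def bits_per_turn(self) -> float:
        free = self.free_turns
        if not free:
            raise ValueError("model has no free turns")
        return len(self.variables_with_role("turn")) / len(free)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "poly": self.poly.to_dict(),
            "decoder": {
                "model_kind": self.model_kind,
                "flavor": self.flavor,
                "lattice": (
                    {"kind": self.lattice.kind, "extents": list(self.lattice.extents)}
                    if self.lattice is not None
                    else None
                ),
                "var_roles": {str(v): info for v, info in self.decoder_map.items()},
                "penalties": self.penalties.to_dict(),
                "sequence": self.sequence.residues,
                "interaction_csv": self.interactions.to_csv(),
                "fixed_turns": list(self.fixed_turns),
                "anchored": self.anchored,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, data: dict) -> "EncodedModel":
        dec = data["decoder"]
        lattice = None
        if dec["lattice"] is not None:
            lattice = LatticeSpec(dec["lattice"]["kind"], tuple(dec["lattice"]["extents"]))
        return cls(
            poly=BinaryPolynomial.from_dict(data["poly"]),
            model_kind=dec["model_kind"],
            flavor=dec["flavor"],
            lattice=lattice,
            decoder_map={int(v): info for v, info in dec["var_roles"].items()},
            penalties=PenaltyConfig.from_dict(dec["penalties"]),
            sequence=Sequence(dec["sequence"]),
            interactions=InteractionMatrix.from_csv(dec["interaction_csv"]),
            fixed_turns=list(dec["fixed_turns"]),
            anchored=dec.get("anchored", False),
        )
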