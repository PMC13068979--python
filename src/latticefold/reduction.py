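"""HUBO -> QUBO reduction by iterated pair substitution.

Each round replaces the most frequent variable pair occurring in
monomials of degree >= 3 by a fresh ancilla variable, adding the penalty
``alpha * (b_i b_j - 2 a (b_i + b_j) + 3 a)`` which vanishes exactly when
``a = b_i b_j`` and costs at least ``alpha`` otherwise.  With the
worst-case ``alpha`` the reduced model reproduces the original energy for
every original assignment after minimizing over the ancillas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .polynomial import BinaryPolynomial, QuadraticModel


@dataclass
class ReductionRecord:
    """Bookkeeping for one HUBO -> QUBO reduction."""

    ancillas: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    alpha: float = 0.0
    original_degree: int = 0
    final_degree: int = 0

    @property
    def ancilla_count(self) -> int:
        return len(self.ancillas)

    def to_dict(self) -> dict:
        return {
            "ancillas": {str(a): list(p) for a, p in self.ancillas.items()},
            "alpha": self.alpha,
            "original_degree": self.original_degree,
            "final_degree": self.final_degree,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReductionRecord":
        return cls(
            ancillas={int(a): (p[0], p[1]) for a, p in data["ancillas"].items()},
            alpha=data["alpha"],
            original_degree=data["original_degree"],
            final_degree=data["final_degree"],
        )


def rosenberg_penalty(pair: Tuple[int, int], ancilla: int, alpha: float) -> BinaryPolynomial:
    """Penalty ``alpha (b_i b_j - 2 a (b_i + b_j) + 3 a)``.

    Zero iff the ancilla equals the product of the pair; >= alpha otherwise.
    """
    if alpha <= 0:
        raise ValueError(f"penalty strength must be positive, got {alpha}")
    i, j = pair
    poly = BinaryPolynomial()
    poly.add_term((i, j), alpha)
    poly.add_term((i, ancilla), -2.0 * alpha)
    poly.add_term((j, ancilla), -2.0 * alpha)
    poly.add_term((ancilla,), 3.0 * alpha)
    return poly


def worst_case_alpha(poly: BinaryPolynomial) -> float:
    """``1 + sum of |coefficient|`` over all (non-constant) terms."""
    return 1.0 + sum(abs(c) for c in poly.terms.values())


def _most_frequent_pair(poly: BinaryPolynomial) -> Tuple[int, int]:
    counts: Dict[Tuple[int, int], int] = {}
    for mono in poly.terms:
        if len(mono) < 3:
            continue
        ordered = sorted(mono)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                key = (ordered[a], ordered[b])
                counts[key] = counts.get(key, 0) + 1
    # max count, ties broken by lowest variable indices
    return min(counts, key=lambda p: (-counts[p], p))


def reduce_to_quadratic(
    poly: BinaryPolynomial, alpha: float | None = None
) -> Tuple[QuadraticModel, ReductionRecord]:
    """Reduce a HUBO to degree <= 2.

    ``alpha`` defaults to the worst-case value computed from the input.
    Each distinct pair is substituted by a single (re-used) ancilla.
    """
    record = ReductionRecord(
        alpha=worst_case_alpha(poly) if alpha is None else float(alpha),
        original_degree=poly.degree(),
    )
    if record.alpha <= 0:
        raise ValueError(f"penalty strength must be positive, got {record.alpha}")
    work = poly.copy()
    next_var = max(work.variables(), default=-1) + 1
    pair_to_ancilla: Dict[Tuple[int, int], int] = {}
    while work.degree() > 2:
        pair = _most_frequent_pair(work)
        if pair in pair_to_ancilla:  # re-used pair: substitute without a new penalty
            ancilla = pair_to_ancilla[pair]
            fresh = False
        else:
            ancilla = next_var
            next_var += 1
            pair_to_ancilla[pair] = ancilla
            record.ancillas[ancilla] = pair
            fresh = True
        i, j = pair
        replaced = BinaryPolynomial(offset=work.offset, labels=work.labels)
        for mono, coeff in work.terms.items():
            if len(mono) >= 3 and i in mono and j in mono:
                replaced.add_term((mono - {i, j}) | {ancilla}, coeff)
            else:
                replaced.add_term(mono, coeff)
        if fresh:
            replaced.add_polynomial(rosenberg_penalty(pair, ancilla, record.alpha))
            replaced.labels[ancilla] = f"ancilla[{i}*{j}]"
        work = replaced
    record.final_degree = work.degree()
    return work.to_quadratic(), record


def strip_ancillas(
    assignment: Dict[int, int], record: ReductionRecord
) -> Tuple[Dict[int, int], bool]:
    """Drop ancilla variables; report whether each equals its parent product."""
    consistent = True
    stripped = dict(assignment)
    for ancilla, (i, j) in record.ancillas.items():
        val = stripped.pop(ancilla)
        if val != assignment[i] * assignment[j]:
            consistent = False
    return stripped, consistent
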