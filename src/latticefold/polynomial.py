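"""Multilinear Boolean objectives (HUBO), quadratic models, and Ising twins.

A :class:`BinaryPolynomial` maps monomials (frozensets of variable indices)
to real coefficients.  Multilinearity (``b*b == b``) is enforced on
construction by collapsing repeated indices into sets.  Quadratic models and
Ising models are thin specializations used by the solvers and diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Tuple

import numpy as np

Monomial = FrozenSet[int]


class BinaryPolynomial:
    """A multilinear polynomial over Boolean variables ``b_i in {0, 1}``.

    Parameters
    ----------
    terms
        Mapping from variable-index collections to real coefficients.
        Repeated indices are collapsed (``b_i^2 = b_i``); an empty
        collection contributes to the constant offset.
    offset
        Constant added to every evaluation.
    labels
        Optional mapping ``index -> human-readable label`` recording what
        each variable means (bead/site, turn/bit, interaction pair, ...).
    """

    __slots__ = ("terms", "offset", "labels")

    def __init__(
        self,
        terms: Mapping[Iterable[int], float] | None = None,
        offset: float = 0.0,
        labels: Mapping[int, str] | None = None,
    ) -> None:
        self.terms: Dict[Monomial, float] = {}
        self.offset = float(offset)
        self.labels: Dict[int, str] = dict(labels) if labels else {}
        if terms:
            for key, coeff in terms.items():
                self.add_term(key, coeff)

    # -- construction ---------------------------------------------------

    def add_term(self, variables: Iterable[int], coeff: float) -> None:
        """Accumulate ``coeff * prod(b_v for v in variables)``."""
        mono = frozenset(int(v) for v in variables)
        if not mono:
            self.offset += coeff
            return
        new = self.terms.get(mono, 0.0) + coeff
        if new == 0.0:
            self.terms.pop(mono, None)
        else:
            self.terms[mono] = new

    def add_polynomial(self, other: "BinaryPolynomial", scale: float = 1.0) -> None:
        self.offset += scale * other.offset
        for mono, coeff in other.terms.items():
            self.add_term(mono, scale * coeff)
        for idx, lab in other.labels.items():
            self.labels.setdefault(idx, lab)

    def __mul__(self, other: "BinaryPolynomial | float") -> "BinaryPolynomial":
        if isinstance(other, (int, float)):
            out = BinaryPolynomial(offset=self.offset * other, labels=self.labels)
            for mono, coeff in self.terms.items():
                out.add_term(mono, coeff * other)
            return out
        out = BinaryPolynomial(labels={**self.labels, **other.labels})
        out.offset = self.offset * other.offset
        for mono, coeff in self.terms.items():
            out.add_term(mono, coeff * other.offset)
        for mono, coeff in other.terms.items():
            out.add_term(mono, coeff * self.offset)
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                out.add_term(m1 | m2, c1 * c2)
        return out

    __rmul__ = __mul__

    def __add__(self, other: "BinaryPolynomial") -> "BinaryPolynomial":
        out = self.copy()
        out.add_polynomial(other)
        return out

    def copy(self) -> "BinaryPolynomial":
        out = BinaryPolynomial(offset=self.offset, labels=self.labels)
        out.terms = dict(self.terms)
        return out

    # -- queries --------------------------------------------------------

    def variables(self) -> Tuple[int, ...]:
        seen = set()
        for mono in self.terms:
            seen.update(mono)
        return tuple(sorted(seen))

    def variable_count(self) -> int:
        return len(self.variables())

    def degree(self) -> int:
        """Maximum monomial size (0 for a constant polynomial)."""
        return max((len(m) for m in self.terms), default=0)

    def evaluate(self, assignment: Mapping[int, int] | Sequence[int]) -> float:
        """Exact value of the polynomial at a Boolean assignment.

        ``assignment`` is either a dict ``{index: 0/1}`` covering every
        variable or a dense sequence indexed by variable number.
        """
        getter = assignment.__getitem__
        total = self.offset
        for mono, coeff in self.terms.items():
            for v in mono:
                val = getter(v)
                if val not in (0, 1):
                    raise ValueError(f"variable {v} has non-Boolean value {val!r}")
                if val == 0:
                    break
            else:
                total += coeff
        return total

    # -- conversion -----------------------------------------------------

    def to_quadratic(self) -> "QuadraticModel":
        if self.degree() > 2:
            raise ValueError(
                f"polynomial has degree {self.degree()}; reduce to degree <= 2 first"
            )
        linear: Dict[int, float] = {}
        quadratic: Dict[Tuple[int, int], float] = {}
        for mono, coeff in self.terms.items():
            if len(mono) == 1:
                (i,) = mono
                linear[i] = linear.get(i, 0.0) + coeff
            else:
                i, j = sorted(mono)
                quadratic[(i, j)] = quadratic.get((i, j), 0.0) + coeff
        return QuadraticModel(linear, quadratic, self.offset, dict(self.labels))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": {str(i): lab for i, lab in sorted(self.labels.items())},
            "terms": [
                {"vars": sorted(m), "coeff": c}
                for m, c in sorted(self.terms.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
            ],
            "offset": self.offset,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BinaryPolynomial":
        poly = cls(offset=data.get("offset", 0.0))
        poly.labels = {int(k): v for k, v in data.get("variables", {}).items()}
        for term in data["terms"]:
            poly.add_term(term["vars"], term["coeff"])
        return poly

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"BinaryPolynomial({len(self.terms)} terms, degree={self.degree()}, "
            f"offset={self.offset})"
        )


@dataclass
class QuadraticModel:
    """Degree <= 2 Boolean objective: ``E(b) = sum b_i Q_ij b_j + offset``."""

    linear: Dict[int, float] = field(default_factory=dict)
    quadratic: Dict[Tuple[int, int], float] = field(default_factory=dict)
    offset: float = 0.0
    labels: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # normalize: upper-triangular keys, no zero or diagonal entries
        fixed: Dict[Tuple[int, int], float] = {}
        for (i, j), coeff in self.quadratic.items():
            if i == j:
                self.linear[i] = self.linear.get(i, 0.0) + coeff
                continue
            key = (min(i, j), max(i, j))
            fixed[key] = fixed.get(key, 0.0) + coeff
        self.quadratic = {k: v for k, v in fixed.items() if v != 0.0}
        self.linear = {k: v for k, v in self.linear.items() if v != 0.0}

    def variables(self) -> Tuple[int, ...]:
        seen = set(self.linear)
        for i, j in self.quadratic:
            seen.add(i)
            seen.add(j)
        return tuple(sorted(seen))

    def variable_count(self) -> int:
        return len(self.variables())

    def evaluate(self, assignment: Mapping[int, int] | Sequence[int]) -> float:
        get = assignment.__getitem__
        total = self.offset
        for i, coeff in self.linear.items():
            total += coeff * get(i)
        for (i, j), coeff in self.quadratic.items():
            total += coeff * get(i) * get(j)
        return total

    def to_polynomial(self) -> BinaryPolynomial:
        poly = BinaryPolynomial(offset=self.offset, labels=self.labels)
        for i, c in self.linear.items():
            poly.add_term((i,), c)
        for (i, j), c in self.quadratic.items():
            poly.add_term((i, j), c)
        return poly

    # -- dense/sparse views ----------------------------------------------

    def index_map(self) -> Dict[int, int]:
        """Variable index -> contiguous position used by array views."""
        return {v: k for k, v in enumerate(self.variables())}

    def to_arrays(self):
        """Dense linear vector and symmetric CSR coupling matrix.

        Returns ``(variables, linear, csr)`` where ``csr`` stores each
        coupling in both directions (row i holds Q_ij for all neighbors j).
        """
        from scipy.sparse import coo_matrix

        variables = self.variables()
        pos = {v: k for k, v in enumerate(variables)}
        n = len(variables)
        lin = np.zeros(n)
        for i, c in self.linear.items():
            lin[pos[i]] = c
        rows, cols, vals = [], [], []
        for (i, j), c in self.quadratic.items():
            rows += [pos[i], pos[j]]
            cols += [pos[j], pos[i]]
            vals += [c, c]
        mat = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return variables, lin, mat

    def to_coo_text(self) -> str:
        """COO text serialization: one ``i j value`` line per entry.

        Diagonal entries carry the linear coefficients.
        """
        lines = []
        for i in sorted(self.linear):
            lines.append(f"{i} {i} {self.linear[i]!r}")
        for (i, j) in sorted(self.quadratic):
            lines.append(f"{i} {j} {self.quadratic[(i, j)]!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_coo_text(cls, text: str, offset: float = 0.0) -> "QuadraticModel":
        linear: Dict[int, float] = {}
        quadratic: Dict[Tuple[int, int], float] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'i j value', got {line!r}")
            i, j, val = int(parts[0]), int(parts[1]), float(parts[2])
            if i == j:
                linear[i] = linear.get(i, 0.0) + val
            else:
                key = (min(i, j), max(i, j))
                quadratic[key] = quadratic.get(key, 0.0) + val
        return cls(linear, quadratic, offset)


@dataclass
class IsingModel:
    """Spin formulation over ``s_i in {-1, +1}``."""

    fields: Dict[int, float] = field(default_factory=dict)
    couplings: Dict[Tuple[int, int], float] = field(default_factory=dict)
    offset: float = 0.0

    def evaluate(self, assignment: Mapping[int, int] | Sequence[int]) -> float:
        get = assignment.__getitem__
        for v in self.variables():
            if get(v) not in (-1, 1):
                raise ValueError(f"spin {v} has value {get(v)!r}, expected -1/+1")
        total = self.offset
        for i, h in self.fields.items():
            total += h * get(i)
        for (i, j), J in self.couplings.items():
            total += J * get(i) * get(j)
        return total

    def variables(self) -> Tuple[int, ...]:
        seen = set(self.fields)
        for i, j in self.couplings:
            seen.add(i)
            seen.add(j)
        return tuple(sorted(seen))


def qubo_to_ising(model: QuadraticModel) -> IsingModel:
    """Exact change of variables ``b_i = (1 + s_i) / 2``.

    Energies of corresponding states agree exactly, offset included.
    """
    h: Dict[int, float] = {}
    J: Dict[Tuple[int, int], float] = {}
    offset = model.offset
    for i, c in model.linear.items():
        h[i] = h.get(i, 0.0) + c / 2.0
        offset += c / 2.0
    for (i, j), c in model.quadratic.items():
        J[(i, j)] = J.get((i, j), 0.0) + c / 4.0
        h[i] = h.get(i, 0.0) + c / 4.0
        h[j] = h.get(j, 0.0) + c / 4.0
        offset += c / 4.0
    return IsingModel(
        {k: v for k, v in h.items() if v != 0.0},
        {k: v for k, v in J.items() if v != 0.0},
        offset,
    )


def ising_to_qubo(model: IsingModel) -> QuadraticModel:
    """Inverse transform ``s_i = 2 b_i - 1``; exact round trip."""
    linear: Dict[int, float] = {}
    quadratic: Dict[Tuple[int, int], float] = {}
    offset = model.offset
    for i, h in model.fields.items():
        linear[i] = linear.get(i, 0.0) + 2.0 * h
        offset -= h
    for (i, j), J in model.couplings.items():
        quadratic[(i, j)] = quadratic.get((i, j), 0.0) + 4.0 * J
        linear[i] = linear.get(i, 0.0) - 2.0 * J
        linear[j] = linear.get(j, 0.0) - 2.0 * J
        offset += J
    return QuadraticModel(linear, quadratic, offset)


def multilinear_fit(values: Sequence[float], nbits: int) -> BinaryPolynomial:
    """Unique multilinear interpolation of a table over ``{0,1}^nbits``.

    ``values[code]`` is the target value at the assignment whose bit ``k``
    is ``(code >> k) & 1``.  Used by the dense turn encoders to turn
    direction tables into Boolean polynomials.
    """
    if len(values) != 1 << nbits:
        raise ValueError("values must cover every bit pattern")
    # Möbius transform: coefficient of a subset S is the alternating sum
    # of values over subsets of S.
    coeffs = list(values)
    for k in range(nbits):
        bit = 1 << k
        for code in range(1 << nbits):
            if code & bit:
                coeffs[code] = coeffs[code] - coeffs[code ^ bit]
    poly = BinaryPolynomial()
    for code, c in enumerate(coeffs):
        if c != 0:
            poly.add_term([k for k in range(nbits) if code & (1 << k)], c)
    return poly
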