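"""Seeded random-sequence dataset generator with nested length prefixes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .fold import AA20, HP_ALPHABET, Sequence

ALPHABETS = {"AA20": AA20, "HP": HP_ALPHABET}

#: Optional hydrophobicity mapping, applied only on explicit request.
HYDROPHOBIC = set("ACFILMVWY")


@dataclass(frozen=True)
class DatasetSpec:
    """Random benchmark set: ``n_instances`` sequences of ``max_length``."""

    n_instances: int = 100
    max_length: int = 10
    alphabet: str = "AA20"
    min_prefix: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(
                f"unknown alphabet {self.alphabet!r}; choose from {sorted(ALPHABETS)}"
            )
        if not 2 <= self.min_prefix <= self.max_length:
            raise ValueError("need 2 <= min_prefix <= max_length")


@dataclass
class DatasetInstance:
    name: str
    sequence: Sequence

    def prefixes(self, min_length: int) -> List[Sequence]:
        """Nested subsections of increasing length up to the full sequence."""
        return [
            Sequence(self.sequence.residues[:n])
            for n in range(min_length, len(self.sequence) + 1)
        ]


def generate_dataset(spec: DatasetSpec) -> List[DatasetInstance]:
    """Uniform random sequences, deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    letters = ALPHABETS[spec.alphabet]
    out = []
    for idx in range(spec.n_instances):
        residues = "".join(letters[i] for i in rng.integers(0, len(letters), spec.max_length))
        out.append(DatasetInstance(f"instance_{idx:04d}", Sequence(residues)))
    return out


def to_hp(seq: Sequence) -> Sequence:
    """Map a 20-letter sequence onto the H/P alphabet (explicit opt-in)."""
    return Sequence("".join("H" if r in HYDROPHOBIC else "P" for r in seq.residues))


def dataset_to_fasta(instances: List[DatasetInstance]) -> str:
    lines = []
    for inst in instances:
        lines.append(f">{inst.name}")
        lines.append(inst.sequence.residues)
    return "\n".join(lines) + "\n"
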