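"""Solver results: states with energies and run metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np


@dataclass
class SampleSet:
    """States sampled by a solver, coldest-best bookkeeping included.

    ``states`` has one row per record over ``variables`` (sorted model
    variable indices); ``energies`` are the exact model energies (offset
    included).
    """

    variables: Tuple[int, ...]
    states: np.ndarray
    energies: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.states.shape[0] != self.energies.shape[0]:
            raise ValueError("states/energies length mismatch")

    def __len__(self) -> int:
        return len(self.energies)

    @property
    def best_energy(self) -> float:
        return float(self.energies.min())

    def best_assignment(self) -> Dict[int, int]:
        row = self.states[int(np.argmin(self.energies))]
        return {v: int(b) for v, b in zip(self.variables, row)}

    def assignment(self, index: int) -> Dict[int, int]:
        return {v: int(b) for v, b in zip(self.variables, self.states[index])}

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "states": self.states.tolist(),
            "energies": self.energies.tolist(),
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, data: dict) -> "SampleSet":
        return cls(
            tuple(data["variables"]),
            np.array(data["states"], dtype=np.int8),
            np.array(data["energies"], dtype=np.float64),
            data.get("metadata", {}),
        )
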