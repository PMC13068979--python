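"""Parallel tempering (replica exchange) over quadratic models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..polynomial import BinaryPolynomial, QuadraticModel
from . import _kernels
from .coloring import color_order
from .sampleset import SampleSet


@dataclass
class PTConfig:
    """Replica ladder and sweep budget.

    Temperatures are distributed geometrically between ``t_min`` and
    ``t_max``.  ``thermalization`` sweeps are discarded before any state
    trace is recorded.
    """

    n_replicas: int = 16
    t_min: float = 0.1
    t_max: float = 10.0
    sweeps: int = 2000
    thermalization: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("need at least two replicas")
        if not 0 < self.t_min < self.t_max:
            raise ValueError(f"need 0 < t_min < t_max, got {self.t_min}, {self.t_max}")
        if not 0 <= self.thermalization < self.sweeps:
            raise ValueError("thermalization must be shorter than the sweep budget")

    def ladder(self) -> np.ndarray:
        """Strictly increasing geometric temperature ladder."""
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


def swap_probability(e1: float, e2: float, t1: float, t2: float) -> float:
    """Replica swap acceptance ``min(1, exp((E - E')(1/T - 1/T')))``."""
    arg = (e1 - e2) * (1.0 / t1 - 1.0 / t2)
    return 1.0 if arg >= 0 else float(np.exp(arg))


def parallel_tempering(
    model: QuadraticModel | BinaryPolynomial,
    config: Optional[PTConfig] = None,
    record_trace: bool = False,
) -> Tuple[SampleSet, Optional[np.ndarray]]:
    """Run PT; returns the final replica states plus best-found record.

    The returned sample set holds one row per replica (coldest first,
    final sweep) with the best state found anywhere prepended.  With
    ``record_trace`` the per-sweep states of the lowest-temperature
    replica after thermalization are returned as an int8 array.
    """
    config = config or PTConfig()
    if isinstance(model, BinaryPolynomial):
        model = model.to_quadratic()
    variables, lin, csr = model.to_arrays()
    n = len(variables)
    pos = {v: k for k, v in enumerate(variables)}
    edges = [(pos[i], pos[j]) for i, j in model.quadratic]
    order = np.array(color_order(range(n), edges), dtype=np.int64)
    betas = (1.0 / config.ladder()).astype(np.float64)  # coldest first
    best_state, best_energy, states, energies, trace = _kernels.pt_run(
        csr.indptr,
        csr.indices,
        csr.data,
        lin,
        order,
        betas,
        config.sweeps,
        config.thermalization,
        config.seed % (2**32),
        record_trace,
    )
    all_states = np.vstack([best_state[None, :], states])
    all_energies = np.concatenate([[best_energy], energies]) + model.offset
    sample_set = SampleSet(
        variables,
        all_states,
        all_energies,
        metadata={
            "solver": "parallel_tempering",
            "seed": config.seed,
            "n_replicas": config.n_replicas,
            "t_min": config.t_min,
            "t_max": config.t_max,
            "sweeps": config.sweeps,
            "thermalization": config.thermalization,
        },
    )
    return sample_set, (trace if record_trace else None)
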