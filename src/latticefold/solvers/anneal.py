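"""Simulated annealing with exponential cooling and automatic start temperature."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ..polynomial import BinaryPolynomial, QuadraticModel
from . import _kernels
from .coloring import color_order
from .sampleset import SampleSet

Model = Union[QuadraticModel, BinaryPolynomial]


@dataclass
class AnnealSchedule:
    """Exponential cooling: ``T_{i+1} = zeta * T_i`` applied once per sweep."""

    t0: Optional[float] = None  # None -> automatic start temperature
    zeta: float = 0.99
    sweeps: int = 1000
    t_min: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.zeta < 1.0:
            raise ValueError(f"cooling rate must be in (0, 1), got {self.zeta}")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError(f"start temperature must be positive, got {self.t0}")
        if self.sweeps < 1:
            raise ValueError("need at least one sweep")
        if self.t_min <= 0:
            raise ValueError("temperature floor must be positive")


def metropolis_accept(d_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept a move: always if downhill, else with probability e^(-dE/T)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if d_e <= 0:
        return True
    return rng.random() < math.exp(-d_e / temperature)


def _as_quadratic(model: Model) -> QuadraticModel:
    if isinstance(model, BinaryPolynomial):
        return model.to_quadratic()
    return model


def auto_start_temperature(
    model: Model, n_probe: int = 1000, seed: int = 0
) -> float:
    """Start temperature from single-flip probes on a uniform random state.

    ``n_probe`` flips are probed; a probe counts as flipped iff its
    energy change is <= 0, and the mean and sample standard deviation are
    taken over the uphill probes.  ``T0 = (mean + 3 s) / ln(1 / chi)``
    with the acceptance ratio ``chi`` clamped away from 0 and 1.  A model
    whose probes all have zero energy change falls back to ``T0 = 1``.
    """
    if n_probe < 100:
        raise ValueError("need at least 100 probe flips")
    quad = _as_quadratic(model)
    variables, lin, csr = quad.to_arrays()
    n = len(variables)
    if n == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    state = rng.integers(0, 2, size=n).astype(np.float64)
    field = lin + csr.dot(state)
    uphill = []
    n_flipped = 0
    any_change = False
    for _ in range(n_probe):
        i = int(rng.integers(0, n))
        d_e = (1.0 - 2.0 * state[i]) * field[i]
        if d_e != 0.0:
            any_change = True
        if d_e <= 0:
            n_flipped += 1
        else:
            uphill.append(d_e)
    if not any_change:
        return 1.0  # flat probe landscape: fall back to unit temperature
    if not uphill:
        scale = 1.0  # every probe was accepted; magnitude comes from the clamp
    else:
        mean = float(np.mean(uphill))
        std = float(np.std(uphill, ddof=1)) if len(uphill) > 1 else 0.0
        scale = mean + 3.0 * std
    if scale == 0.0:
        return 1.0
    chi = n_flipped / n_probe
    chi = min(max(chi, 1.0 / n_probe), 1.0 - 1.0 / n_probe)
    return scale / math.log(1.0 / chi)


def simulated_annealing(
    model: Model,
    schedule: Optional[AnnealSchedule] = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> SampleSet:
    """Multi-restart simulated annealing; returns every repeat's best state.

    Quadratic models run through the compiled color-ordered kernel;
    higher-order polynomials fall back to a sequential Python sweep.
    Fully reproducible from ``seed`` (repeat ``r`` uses ``seed + r``).
    """
    schedule = schedule or AnnealSchedule()
    if isinstance(model, BinaryPolynomial) and model.degree() > 2:
        return _sa_hubo(model, schedule, n_repeats, seed)
    quad = _as_quadratic(model)
    variables, lin, csr = quad.to_arrays()
    n = len(variables)
    pos = {v: k for k, v in enumerate(variables)}
    edges = [(pos[i], pos[j]) for i, j in quad.quadratic]
    order = np.array(color_order(range(n), edges), dtype=np.int64)
    t0 = schedule.t0 if schedule.t0 is not None else auto_start_temperature(quad, seed=seed)
    states = np.zeros((n_repeats, n), dtype=np.int8)
    energies = np.zeros(n_repeats)
    for r in range(n_repeats):
        best_state, best_energy = _kernels.sa_run(
            csr.indptr,
            csr.indices,
            csr.data,
            lin,
            order,
            schedule.sweeps,
            t0,
            schedule.zeta,
            schedule.t_min,
            (seed + r) % (2**32),
        )
        states[r] = best_state
        energies[r] = best_energy + quad.offset
    return SampleSet(
        variables,
        states,
        energies,
        metadata={
            "solver": "simulated_annealing",
            "seed": seed,
            "n_repeats": n_repeats,
            "t0": t0,
            "zeta": schedule.zeta,
            "sweeps": schedule.sweeps,
        },
    )


def _sa_hubo(
    poly: BinaryPolynomial, schedule: AnnealSchedule, n_repeats: int, seed: int
) -> SampleSet:
    """Sequential-sweep SA over a higher-order polynomial (small models)."""
    variables = poly.variables()
    n = len(variables)
    pos = {v: k for k, v in enumerate(variables)}
    terms = [(np.array([pos[v] for v in mono]), c) for mono, c in poly.terms.items()]
    by_var = [[] for _ in range(n)]
    for t_idx, (mono, _) in enumerate(terms):
        for v in mono:
            by_var[v].append(t_idx)
    states = np.zeros((n_repeats, n), dtype=np.int8)
    energies = np.zeros(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        state = rng.integers(0, 2, size=n).astype(np.int8)
        energy = sum(c for mono, c in terms if state[mono].all())
        best_energy, best_state = energy, state.copy()
        temp = schedule.t0 if schedule.t0 is not None else auto_start_temperature(
            poly.to_quadratic() if poly.degree() <= 2 else _linearized(poly), seed=seed
        )
        for _ in range(schedule.sweeps):
            for i in range(n):
                d_e = 0.0
                flip_to = 1 - state[i]
                for t_idx in by_var[i]:
                    mono, c = terms[t_idx]
                    others = state[mono].sum() - state[i]
                    if others == len(mono) - 1:  # all other factors are 1
                        d_e += c if flip_to == 1 else -c
                if d_e <= 0 or rng.random() < math.exp(-d_e / temp):
                    state[i] = flip_to
                    energy += d_e
                    if energy < best_energy:
                        best_energy, best_state = energy, state.copy()
            temp = max(temp * schedule.zeta, schedule.t_min)
        states[r] = best_state
        energies[r] = best_energy + poly.offset
    return SampleSet(
        variables,
        states,
        energies,
        metadata={"solver": "simulated_annealing", "seed": seed, "hubo": True},
    )


def _linearized(poly: BinaryPolynomial) -> QuadraticModel:
    """Degree-truncated view used only to seed the start temperature."""
    quad = BinaryPolynomial(offset=poly.offset)
    for mono, c in poly.terms.items():
        if len(mono) <= 2:
            quad.add_term(mono, c)
    return quad.to_quadratic()
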