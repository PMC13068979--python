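"""Numba single-flip Metropolis kernels for SA and PT.

Models are passed as dense linear vectors plus symmetric CSR couplings
(each pair stored in both directions).  Energies exclude the model
offset; callers add it back.  All randomness comes from the explicit
seed passed to each kernel, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _init_state(indptr, indices, data, lin, state, field):
    n = lin.shape[0]
    for i in range(n):
        state[i] = 1 if np.random.random() < 0.5 else 0
    for i in range(n):
        field[i] = lin[i]
    for i in range(n):
        if state[i] == 1:
            for ptr in range(indptr[i], indptr[i + 1]):
                field[indices[ptr]] += data[ptr]
    energy = 0.0
    for i in range(n):
        if state[i] == 1:
            # field - lin counts each coupling from both endpoints
            energy += lin[i] + 0.5 * (field[i] - lin[i])
    return energy


@njit(cache=False)
def sa_run(indptr, indices, data, lin, order, n_sweeps, t0, zeta, t_min, seed):
    """One simulated-annealing repeat; returns (best_state, best_energy).

    One attempted flip per variable per sweep, visited in ``order``
    (color-class grouped); the temperature is multiplied by ``zeta``
    after each full sweep, floored at ``t_min``.
    """
    np.random.seed(seed)
    n = lin.shape[0]
    state = np.zeros(n, dtype=np.int8)
    field = np.zeros(n, dtype=np.float64)
    energy = _init_state(indptr, indices, data, lin, state, field)
    best_energy = energy
    best_state = state.copy()
    temp = t0
    for _ in range(n_sweeps):
        for idx in range(n):
            i = order[idx]
            d_e = (1 - 2 * state[i]) * field[i]
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / temp):
                delta = 1 - 2 * state[i]
                state[i] = 1 - state[i]
                energy += d_e
                for ptr in range(indptr[i], indptr[i + 1]):
                    field[indices[ptr]] += delta * data[ptr]
                if energy < best_energy:
                    best_energy = energy
                    best_state[:] = state
        temp *= zeta
        if temp < t_min:
            temp = t_min
    return best_state, best_energy


@njit(cache=False)
def pt_run(
    indptr,
    indices,
    data,
    lin,
    order,
    betas,
    n_sweeps,
    n_therm,
    seed,
    record_trace,
):
    """Parallel tempering with adjacent temperature swaps.

    ``betas`` is ordered coldest first (largest beta at index 0).  After
    every full sweep of all replicas, adjacent pairs starting at
    ``sweep % 2`` attempt a swap with probability
    ``min(1, exp((E - E') (beta - beta')))``.  When ``record_trace`` is
    true, the state of the lowest-temperature slot is recorded for every
    sweep after the first ``n_therm``.
    """
    np.random.seed(seed)
    n_rep = betas.shape[0]
    n = lin.shape[0]
    states = np.zeros((n_rep, n), dtype=np.int8)
    fields = np.zeros((n_rep, n), dtype=np.float64)
    energies = np.zeros(n_rep, dtype=np.float64)
    for m in range(n_rep):
        energies[m] = _init_state(indptr, indices, data, lin, states[m], fields[m])
    best_energy = energies[0]
    best_state = states[0].copy()
    for m in range(n_rep):
        if energies[m] < best_energy:
            best_energy = energies[m]
            best_state[:] = states[m]
    n_rec = n_sweeps - n_therm if record_trace else 0
    trace = np.zeros((max(n_rec, 1), n), dtype=np.int8)
    for sweep in range(n_sweeps):
        for m in range(n_rep):
            beta = betas[m]
            for idx in range(n):
                i = order[idx]
                d_e = (1 - 2 * states[m, i]) * fields[m, i]
                if d_e <= 0.0 or np.random.random() < np.exp(-d_e * beta):
                    delta = 1 - 2 * states[m, i]
                    states[m, i] = 1 - states[m, i]
                    energies[m] += d_e
                    for ptr in range(indptr[i], indptr[i + 1]):
                        fields[m, indices[ptr]] += delta * data[ptr]
                    if energies[m] < best_energy:
                        best_energy = energies[m]
                        best_state[:] = states[m]
        for m in range(sweep % 2, n_rep - 1, 2):
            arg = (energies[m] - energies[m + 1]) * (betas[m] - betas[m + 1])
            if arg >= 0.0 or np.random.random() < np.exp(arg):
                for i in range(n):
                    tmp = states[m, i]
                    states[m, i] = states[m + 1, i]
                    states[m + 1, i] = tmp
                    tmpf = fields[m, i]
                    fields[m, i] = fields[m + 1, i]
                    fields[m + 1, i] = tmpf
                tmpe = energies[m]
                energies[m] = energies[m + 1]
                energies[m + 1] = tmpe
        if record_trace and sweep >= n_therm:
            trace[sweep - n_therm] = states[0]
    return best_state, best_energy, states, energies, trace
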