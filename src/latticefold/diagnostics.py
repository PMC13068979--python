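"""Hardness and resource diagnostics: spin-overlap distributions, barrier
classification, time-to-solution, and QUBO structure metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks

from .polynomial import BinaryPolynomial, QuadraticModel
from .solvers.anneal import AnnealSchedule, simulated_annealing
from .solvers.tempering import PTConfig, parallel_tempering

#: Desk-scale spin-overlap defaults; full-scale settings go through PTConfig.
SOD_DEFAULTS = PTConfig(n_replicas=64, sweeps=200_000, thermalization=160_000)

HISTOGRAM_BIN_WIDTH = 0.02
PEAK_PROMINENCE_FRACTION = 0.05


def spin_overlap(state_a: Sequence[int], state_b: Sequence[int]) -> float:
    """Normalized overlap ``q = (1/n) sum s_i^(1) s_i^(2)`` in spin space.

    Boolean states are converted with ``s = 2 b - 1`` first.
    """
    a = np.asarray(state_a)
    b = np.asarray(state_b)
    if a.shape != b.shape:
        raise ValueError(f"state shapes differ: {a.shape} vs {b.shape}")
    sa = np.where(a > 0, 1, -1)
    sb = np.where(b > 0, 1, -1)
    return float((sa * sb).mean())


@dataclass
class OverlapDistribution:
    """Samples of the overlap order parameter with a normalized histogram."""

    samples: np.ndarray
    bin_width: float = HISTOGRAM_BIN_WIDTH
    n_overlap_sweeps: int = 0
    thermalization: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size and (
            self.samples.min() < -1 - 1e-9 or self.samples.max() > 1 + 1e-9
        ):
            raise ValueError("overlap samples must lie in [-1, 1]")

    def histogram(self) -> Tuple[np.ndarray, np.ndarray]:
        """(bin centers, masses); masses sum to 1."""
        n_bins = int(round(2.0 / self.bin_width))
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        masses, _ = np.histogram(np.clip(self.samples, -1, 1), bins=edges)
        masses = masses / masses.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, masses

    def support(self) -> np.ndarray:
        """Distinct overlap values observed (one-hot structure makes few)."""
        return np.unique(self.samples)

    def to_dict(self) -> dict:
        centers, masses = self.histogram()
        return {
            "bin_width": self.bin_width,
            "bin_centers": centers.tolist(),
            "masses": masses.tolist(),
            "n_samples": int(self.samples.size),
            "n_overlap_sweeps": self.n_overlap_sweeps,
            "thermalization": self.thermalization,
        }


def estimate_sod(
    model: Union[QuadraticModel, BinaryPolynomial],
    config: Optional[PTConfig] = None,
    seeds: Tuple[int, int] = (0, 1),
) -> OverlapDistribution:
    """Overlap distribution from two independent PT instances.

    Both instances share the temperature ladder; after thermalization the
    overlap between their lowest-temperature replicas is recorded every
    sweep.
    """
    if seeds[0] == seeds[1]:
        raise ValueError("the two tempering instances need distinct seeds")
    config = config or SOD_DEFAULTS
    traces = []
    for seed in seeds:
        _, trace = parallel_tempering(
            model, replace(config, seed=seed), record_trace=True
        )
        traces.append(np.where(trace > 0, 1, -1).astype(np.int8))
    q = (traces[0] * traces[1]).mean(axis=1)
    return OverlapDistribution(
        q,
        n_overlap_sweeps=config.sweeps - config.thermalization,
        thermalization=config.thermalization,
    )


def classify_barriers(
    dist: OverlapDistribution,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
    threshold: float = 0.5,
) -> str:
    """``thin`` iff every histogram peak lies at ``|q| > threshold``.

    Peaks are local maxima of the zero-padded histogram with prominence
    at least ``prominence_fraction`` of the maximum bin mass.
    """
    if dist.samples.size == 0:
        raise ValueError("empty overlap distribution")
    centers, masses = dist.histogram()
    padded = np.concatenate([[0.0], masses, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * masses.max())
    peak_centers = centers[peaks - 1]
    if peak_centers.size == 0:  # flat histogram: treat the mode as the peak
        peak_centers = centers[[int(np.argmax(masses))]]
    return "thin" if np.all(np.abs(peak_centers) > threshold) else "thick"


@dataclass
class TtsResult:
    """Optimized time-to-solution over a schedule grid."""

    tau: float
    p_ground: float
    tts: float
    schedule: AnnealSchedule
    grid: List[dict] = field(default_factory=list)
    n_repeats: int = 0


def time_to_solution(tau: float, p_ground: float) -> float:
    """Expected work to reach the ground state with 99% confidence.

    ``tau * log(0.01) / log(1 - p_ground)``; a run that succeeds with
    probability >= 0.99 needs a single repetition, and zero success
    probability gives infinity.
    """
    if tau <= 0:
        raise ValueError(f"per-run cost must be positive, got {tau}")
    if not 0.0 <= p_ground <= 1.0:
        raise ValueError(f"success probability must be in [0, 1], got {p_ground}")
    if p_ground == 0.0:
        return math.inf
    if p_ground >= 0.99:
        return tau
    return tau * math.log(1.0 - 0.99) / math.log(1.0 - p_ground)


def optimize_tts(
    model: Union[QuadraticModel, BinaryPolynomial],
    ground_energy: float,
    schedule_grid: Sequence[AnnealSchedule],
    n_repeats: int = 100,
    seed: int = 0,
    atol: float = 1e-9,
) -> TtsResult:
    """Estimate and minimize TTS over a grid of annealing schedules.

    ``p_ground`` is the fraction of repeats whose best energy reaches the
    supplied ground energy; ``tau`` is measured in abstract work units
    (sweeps times variables), keeping the metric hardware-independent.
    """
    if not schedule_grid:
        raise ValueError("schedule grid is empty")
    n_vars = model.variable_count()
    best: Optional[TtsResult] = None
    grid_report = []
    for idx, schedule in enumerate(schedule_grid):
        samples = simulated_annealing(model, schedule, n_repeats, seed + idx * 7919)
        p = float(np.mean(samples.energies <= ground_energy + atol))
        tau = schedule.sweeps * max(n_vars, 1)
        tts = time_to_solution(tau, p)
        grid_report.append(
            {"sweeps": schedule.sweeps, "zeta": schedule.zeta, "p_ground": p, "tts": tts}
        )
        if best is None or tts < best.tts:
            best = TtsResult(tau, p, tts, schedule, n_repeats=n_repeats)
    best.grid = grid_report
    return best


@dataclass
class QuboMetrics:
    """Structural resource metrics of a quadratic model."""

    n_variables: int
    density: float
    couplers_per_variable: float
    coupler_resolution: float

    def to_dict(self) -> dict:
        return {
            "n_variables": self.n_variables,
            "density": self.density,
            "couplers_per_variable": self.couplers_per_variable,
            "coupler_resolution": self.coupler_resolution,
        }


def qubo_metrics(model: QuadraticModel) -> QuboMetrics:
    """Density, mean couplers per variable, and coupler resolution.

    Density is the fraction of realized off-diagonal pairs; resolution is
    ``max|Q_ij| / min nonzero |Q_ij|`` over the quadratic terms (1.0 for
    models without couplings).
    """
    n = model.variable_count()
    couplings = [abs(c) for c in model.quadratic.values() if c != 0.0]
    n_pairs = len(couplings)
    density = n_pairs / (n * (n - 1) / 2) if n > 1 else 0.0
    couplers = 2.0 * n_pairs / n if n else 0.0
    resolution = max(couplings) / min(couplings) if couplings else 1.0
    return QuboMetrics(n, density, couplers, resolution)
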