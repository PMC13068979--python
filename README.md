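# latticefold

Coarse-grained lattice protein folding as binary optimization: a comparative
framework for four model encodings, higher-order-to-quadratic reduction,
classical annealing solvers, and hardness/resource diagnostics.

## What it does

A protein is a chain of beads on a lattice; its energy is the sum of pairwise
contact energies over non-bonded nearest-neighbor pairs (HP preset or any
symmetric 20×20 CSV matrix). The package encodes the fold-search problem as a
Boolean objective in four ways:

| Model | Variables | Locality |
|---|---|---|
| Coordinate-based Cartesian | one-hot site register per bead (parity-split) | 2 |
| Coordinate-based tetrahedral | one-hot registers on two interleaved FCC grids | 2 |
| Turn-based Cartesian | 6 (sparse) / 3 (dense) bits per turn + slack + interaction bits | 4 / 8 |
| Turn-based tetrahedral | 4 (sparse) / 2 (dense) bits per turn + interaction bits | 3 / 5 |

Around the encoders:

- `lattice` / `fold` — finite Cartesian and diamond lattices with exact
  integer coordinates; exhaustive self-avoiding-walk oracles that define
  lattice-space ground truth for small chains.
- `polynomial` / `reduction` — multilinear Boolean objectives (HUBO),
  QUBO/Ising conversion, and iterated pair-substitution quadratization with an
  exactness guarantee (minimizing over ancillas reproduces every original
  energy).
- `solvers` — simulated annealing (exponential cooling, automatic start
  temperature, graph-coloring sweep order), parallel tempering with geometric
  temperature ladders, and exhaustive full-state / turn-space oracles. Inner
  loops are numba-compiled; everything is reproducible from explicit seeds.
- `diagnostics` — spin-overlap distributions from paired tempering runs,
  thin/thick barrier classification (peaks at |q| > 0.5), time-to-solution
  with schedule-grid optimization, and QUBO resource metrics (density,
  couplers per variable, coupler resolution).
- `decode` — bitstrings back to folds with feasibility flags; infeasible and
  self-intersecting configurations are first-class results. Includes the
  exhaustive demonstration that the turn-based tetrahedral model admits
  self-intersecting ground states degenerate with valid folds.
- `dataset` — seeded random benchmark sequences with nested length prefixes.

## Command line

```sh
latticefold gen-dataset --n 100 --length 10 --seed 7 --out dataset.fasta
latticefold encode --model coordt --seq HPPHPH --out model.json
latticefold solve-sa --model model.json --sweeps 2000 --zeta 0.999 \
    --repeats 100 --seed 1 --out samples.json
latticefold decode --model model.json --samples samples.json \
    --out report.json --xyz best.xyz
latticefold metrics --model model.json --out metrics.json
latticefold sod --model model.json --replicas 64 --sweeps 200000 \
    --overlap-sweeps 40000 --out sod.json
latticefold tts --model model.json --ground-energy -2 --out tts.json
latticefold flaw-demo --seq HPPPPHPPPPH --out flaw.json
```

Models with degree > 2 (`turnc`, `turnt`) are reduced to quadratic form
automatically by the solver commands, or explicitly with `latticefold reduce`.

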