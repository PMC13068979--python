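import itertools

import numpy as np
import pytest

from latticefold.decode import decode, fold_to_assignment
from latticefold.encoders import (
    CapacityError,
    PenaltyConfig,
    default_penalties,
    eligible_interaction_pairs,
    encode_coordinate,
    encode_turn_cartesian,
    encode_turn_tetrahedral,
)
from latticefold.fold import (
    InteractionMatrix,
    Sequence,
    contact_energy,
    enumerate_saws,
    ground_truth_minimum,
)
from latticefold.lattice import CARTESIAN, DIAMOND, LatticeSpec, build_lattice, min_grid
from latticefold.solvers import exact_solve


class TestDefaultPenalties:
    def test_all_p_worst_case(self, hp):
        pens = default_penalties(Sequence("PPPPPP"), hp, "worst_case", CARTESIAN)
        assert pens.lambda_onehot == 1.0
        assert pens.lambda2 == 1.0

    def test_worst_case_counts_eligible_pairs(self, hp):
        seq = Sequence("HPPHPPH")  # H-H pairs at separations 3, 3 (odd, >= 3)
        k = len(eligible_interaction_pairs(seq, hp, CARTESIAN))
        pens = default_penalties(seq, hp, "worst_case", CARTESIAN)
        assert pens.lambda_onehot == 1.0 + k

    def test_strictly_positive(self, hp):
        for mode in ("worst_case", "tuned"):
            pens = default_penalties(Sequence("PPPP"), hp, mode, DIAMOND)
            assert min(
                pens.lambda_onehot, pens.lambda_conn, pens.lambda_selfavoid,
                pens.lambda1, pens.lambda2, pens.lambda_invalid,
            ) > 0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(lambda_conn=0.0)


class TestEligiblePairs:
    def test_cartesian_min_separation_3(self, hp):
        seq = Sequence("HPPHPH")  # H at 0, 3, 5; (3, 5) has even separation
        assert eligible_interaction_pairs(seq, hp, CARTESIAN) == [(0, 3), (0, 5)]

    def test_diamond_min_separation_5(self, hp):
        seq = Sequence("HPPPPHPPPPH")
        assert eligible_interaction_pairs(seq, hp, DIAMOND) == [(0, 5), (5, 10)]

    def test_even_separation_excluded(self, hp):
        seq = Sequence("HPPPH")  # separation 4
        assert eligible_interaction_pairs(seq, hp, CARTESIAN) == []


class TestCoordinateEncoder:
    def test_variable_count_n10_l4(self, hp):
        seq = Sequence("HPHPPHPHPH")
        model = encode_coordinate(seq, min_grid(10, CARTESIAN), hp)
        assert model.n_variables == 320  # 10 beads x 32 parity-class sites

    def test_diamond_register_size_27(self, hp):
        seq = Sequence("HPPH")
        model = encode_coordinate(seq, LatticeSpec.diamond(3), hp)
        beads = {}
        for info in model.decoder_map.values():
            beads.setdefault(info["bead"], 0)
            beads[info["bead"]] += 1
        assert set(beads.values()) == {27}

    def test_degree_exactly_2(self, hp):
        model = encode_coordinate(Sequence("HPPH"), min_grid(4, CARTESIAN), hp)
        assert model.poly.degree() == 2

    def test_capacity_error(self, hp):
        with pytest.raises(CapacityError):
            encode_coordinate(Sequence("H" * 20), LatticeSpec.cartesian(2), hp)

    def test_anchoring_reduces_register(self, hp):
        seq = Sequence("HPPH")
        free = encode_coordinate(seq, min_grid(4, CARTESIAN), hp)
        anchored = encode_coordinate(
            seq, min_grid(4, CARTESIAN), hp, anchor_first_bead=True
        )
        assert anchored.n_variables < free.n_variables

    @pytest.mark.parametrize("kind", [CARTESIAN, DIAMOND])
    def test_feasible_assignments_hit_contact_energy(self, hp, kind):
        # re-encoded folds evaluate to their lattice contact energy exactly
        seq = Sequence("HPPHPH")
        model = encode_coordinate(seq, min_grid(6, kind), hp)
        checked = 0
        for fold in itertools.islice(
            enumerate_saws(6, kind, symmetry_reduced=True), 0, None, 7
        ):
            try:
                assignment = fold_to_assignment(model, fold)
            except ValueError:
                continue
            assert model.poly.evaluate(assignment) == contact_energy(fold, seq, hp)
            checked += 1
        assert checked > 10

    def test_full_space_minimum_small_grid(self, hp):
        # N=4 on the 2^3 grid: all 2^16 assignments vs the grid-restricted oracle
        seq = Sequence("HPPH")
        model = encode_coordinate(seq, LatticeSpec.cartesian(2), hp)
        assert model.n_variables == 16
        energy, argmins = exact_solve(model.poly)
        assert energy == -1.0  # the unit square fits the 2^3 grid
        for argmin in argmins[:20]:
            sol = decode(argmin, model)
            assert sol.feasible
            assert sol.contact_energy == energy

    def test_feasible_bijection_with_folds(self, hp):
        # every feasible assignment of the N=3 model on L=2 is a lattice walk
        seq = Sequence("HPH")
        model = encode_coordinate(seq, LatticeSpec.cartesian(2), hp)
        lattice = build_lattice(LatticeSpec.cartesian(2))
        n_feasible = 0
        n_vars = model.n_variables
        for code in range(1 << n_vars):
            assignment = {v: (code >> v) & 1 for v in range(n_vars)}
            sol = decode(assignment, model)
            if sol.feasible:
                n_feasible += 1
        # walks of 3 beads starting on parity class 0 (bead-parity registers)
        expected = sum(
            1
            for s in lattice.parity_class(0)
            for a in lattice.neighbors(s)
            for b in lattice.neighbors(a)
            if b != s
        )
        assert n_feasible == expected


class TestTurnTetrahedralEncoder:
    def test_dense_conformation_bits(self, hp, flaw_sequence):
        model = encode_turn_tetrahedral(flaw_sequence, hp, "dense")
        assert len(model.variables_with_role("turn")) == 16  # 2 x (10 - 2)
        assert model.bits_per_turn() == 2

    def test_sparse_conformation_bits(self, hp, flaw_sequence):
        model = encode_turn_tetrahedral(flaw_sequence, hp, "sparse")
        assert model.bits_per_turn() == 4

    def test_interaction_pairs(self, hp, flaw_sequence):
        model = encode_turn_tetrahedral(flaw_sequence, hp, "dense")
        pairs = sorted(
            tuple(i["pair"]) for i in model.decoder_map.values() if i["role"] == "interaction"
        )
        assert pairs == [(0, 5), (5, 10)]

    def test_max_degree_dense_5_sparse_3(self, hp, flaw_sequence):
        assert encode_turn_tetrahedral(flaw_sequence, hp, "dense").poly.degree() == 5
        assert encode_turn_tetrahedral(flaw_sequence, hp, "sparse").poly.degree() == 3

    def test_bracket_values(self, hp):
        # q = 0 contributes nothing; q = 1 at contact with guards at 2 gives eps
        from latticefold.decode import directions_to_assignment
        from latticefold.solvers import turn_space_exact

        seq = Sequence("HPPPPH")
        model = encode_turn_tetrahedral(seq, hp, "dense")
        result = turn_space_exact(model)
        assert result.min_energy == -1.0  # ring contact: bracket reduces to eps
        assignment = directions_to_assignment(model, result.directions[0])
        assert model.poly.evaluate(assignment) == -1.0
        # switching the interaction variable off removes the contribution
        q_var = model.variables_with_role("interaction")[0]
        assignment[q_var] = 0
        assert model.poly.evaluate(assignment) == 0.0


class TestTurnCartesianEncoder:
    def test_per_turn_bits(self, hp):
        seq = Sequence("HPPHPPH")
        assert encode_turn_cartesian(seq, hp, "sparse").bits_per_turn() == 6
        assert encode_turn_cartesian(seq, hp, "dense").bits_per_turn() == 3

    def test_max_degree_dense_8_sparse_4(self, hp):
        seq = Sequence("HPPHPPH")
        assert encode_turn_cartesian(seq, hp, "dense").poly.degree() == 8
        assert encode_turn_cartesian(seq, hp, "sparse").poly.degree() == 4

    def test_straight_chain_all_p_is_zero(self, hp):
        from latticefold.decode import directions_to_assignment

        seq = Sequence("PPPPP")
        for flavor in ("dense", "sparse"):
            model = encode_turn_cartesian(seq, hp, flavor)
            assignment = directions_to_assignment(model, (0, 2, 0, 0))
            assert model.poly.evaluate(assignment) == 0.0

    def test_slack_registers_cover_max_distance(self, hp):
        model = encode_turn_cartesian(Sequence("PPPPPP"), hp, "dense")
        slack_bits = {}
        for info in model.decoder_map.values():
            if info["role"] == "slack":
                pair = tuple(info["pair"])
                slack_bits[pair] = max(slack_bits.get(pair, 0), info["bit"] + 1)
        for (j, k), mu in slack_bits.items():
            assert 2**mu >= (k - j) ** 2

    def test_overlap_penalized(self, hp):
        from latticefold.decode import directions_to_assignment

        seq = Sequence("PPPP")
        model = encode_turn_cartesian(seq, hp, "dense")
        # +y then -y overlaps beads 1 and 3; the optimal slack still costs
        assignment = directions_to_assignment(model, (0, 2, 3))
        assert model.poly.evaluate(assignment) == model.penalties.lambda_selfavoid


class TestGroundStateCorrectness:
    @pytest.mark.parametrize("kind", [CARTESIAN, DIAMOND])
    def test_coordinate_feasible_minimum_matches_oracle(self, hp, kind, rng):
        for _ in range(3):
            n = int(rng.integers(4, 7))
            seq = Sequence("".join(rng.choice(["H", "P"], size=n)))
            model = encode_coordinate(seq, min_grid(n, kind), hp)
            oracle = ground_truth_minimum(seq, kind, hp)
            best = 0.0
            for fold in enumerate_saws(n, kind, symmetry_reduced=True):
                try:
                    assignment = fold_to_assignment(model, fold)
                except ValueError:
                    continue
                best = min(best, model.poly.evaluate(assignment))
            assert best == oracle
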