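"""Candidate generation and the greedy min-max selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from restraintgraph.errors import InputError, NoCandidatesError
from restraintgraph.oracles_benchmark import generate_toy_system
from restraintgraph.pair_restraints import (
    RestraintSet,
    SelectionParams,
    break_tie,
    generate_candidates,
    greedy_select,
    score_restraint_set,
)

from conftest import candidates_at, line_candidates, make_molecule

NO_RINGS = SelectionParams(restrict_to_rings=False)


def brute_force_candidates(mol_a, mol_b, d_res):
    """Independent oracle: exhaustive pair enumeration."""
    return sorted(
        (a.atom_id, b.atom_id)
        for a in mol_a.atoms
        for b in mol_b.atoms
        if np.linalg.norm(a.position - b.position) <= d_res
    )


class TestGenerateCandidates:
    def test_against_exhaustive_enumeration(self):
        mol_a = make_molecule("a", [[0.0, 0, 0], [0.05, 0, 0]])
        mol_b = make_molecule("b", [[0.04, 0, 0], [0.2, 0, 0]])
        cands = generate_candidates(mol_a, mol_b, NO_RINGS)
        got = [(c.atom_a.atom_id, c.atom_b.atom_id) for c in cands]
        assert got == brute_force_candidates(mol_a, mol_b, 0.1)
        # (0, 0.2) and (0.05, 0.2) are 0.20 and 0.15 nm apart: filtered out
        assert got == [(1, 1), (2, 1)]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_clouds(self, seed):
        system = generate_toy_system(14, seed)
        mol_a, mol_b = system.molecules
        cands = generate_candidates(mol_a, mol_b, NO_RINGS)
        got = [(c.atom_a.atom_id, c.atom_b.atom_id) for c in cands]
        assert got == brute_force_candidates(mol_a, mol_b, NO_RINGS.d_res)
        assert all(c.pair_distance <= NO_RINGS.d_res for c in cands)
        for c in cands:
            np.testing.assert_allclose(
                c.midpoint, (c.atom_a.position + c.atom_b.position) / 2
            )

    def test_superposed_rings_contain_identity_pairs(self, benzene_with_substituent):
        other = make_molecule(
            "copy",
            benzene_with_substituent.positions,
            [tuple(b) for b in benzene_with_substituent.bonds],
            element="C",
        )
        cands = generate_candidates(benzene_with_substituent, other)
        pairs = {(c.atom_a.atom_id, c.atom_b.atom_id) for c in cands}
        assert {(i, i) for i in range(1, 7)} <= pairs
        # ring filter active: substituent atom 7 is not eligible
        assert not any(7 in p for p in pairs)

    def test_distant_molecules_yield_nothing(self):
        mol_a = make_molecule("a", [[0, 0, 0]])
        mol_b = make_molecule("b", [[1.0, 0, 0]])
        assert generate_candidates(mol_a, mol_b, NO_RINGS) == []

    def test_same_molecule_twice_rejected(self):
        mol = make_molecule("a", [[0, 0, 0]])
        with pytest.raises(InputError, match="distinct"):
            generate_candidates(mol, mol, NO_RINGS)


class TestGreedySelect:
    def test_line_instance_selection_order(self):
        # hand evaluation: {0, 0.5} is the farthest pair; survivors get
        # min-distance weights 0.1 -> 0.1, 0.2 -> 0.2, 0.4 -> 0.1
        cands = line_candidates([0.0, 0.1, 0.2, 0.4, 0.5])
        rset = greedy_select(cands, SelectionParams(n_res=3))
        assert [c.midpoint[0] for c in rset.restraints] == pytest.approx(
            [0.0, 0.5, 0.2]
        )

    def test_exhaustion_returns_all_disjoint_candidates(self):
        rset = greedy_select(line_candidates([0.0, 0.3]), SelectionParams(n_res=4))
        assert len(rset) == 2

    def test_single_candidate_returned_alone(self):
        rset = greedy_select(line_candidates([0.2]), SelectionParams(n_res=4))
        assert len(rset) == 1

    def test_empty_candidates_raise_with_advice(self):
        with pytest.raises(NoCandidatesError, match="d_res"):
            greedy_select([], SelectionParams())

    @given(st.integers(0, 2**31 - 1))
    def test_feasibility_invariants_on_toy_systems(self, seed):
        params = SelectionParams(restrict_to_rings=False)
        system = generate_toy_system(16, seed)
        cands = generate_candidates(*system.molecules, params)
        if not cands:
            return
        rset = greedy_select(cands, params)
        # cutoff and atom-disjointness
        assert all(r.pair_distance <= params.d_res for r in rset.restraints)
        keys = [k for r in rset.restraints for k in r.atom_keys]
        assert len(set(keys)) == len(keys)
        assert len(rset) <= params.n_res

    @given(st.integers(0, 2**31 - 1))
    def test_first_step_is_maximally_separated_pair(self, seed):
        system = generate_toy_system(16, seed)
        cands = generate_candidates(*system.molecules, NO_RINGS)
        disjoint_pairs = [
            (p, q)
            for p, q in itertools.combinations(cands, 2)
            if not set(p.atom_keys) & set(q.atom_keys)
        ]
        if not disjoint_pairs:
            return
        rset = greedy_select(cands, NO_RINGS)
        if len(rset) < 2:
            return
        first_two = np.linalg.norm(
            rset.restraints[0].midpoint - rset.restraints[1].midpoint
        )
        best = max(
            np.linalg.norm(p.midpoint - q.midpoint) for p, q in disjoint_pairs
        )
        assert first_two == pytest.approx(best)

    @given(st.integers(0, 2**31 - 1))
    def test_deterministic_under_input_shuffling(self, seed):
        system = generate_toy_system(14, seed)
        cands = generate_candidates(*system.molecules, NO_RINGS)
        if not cands:
            return
        reference = greedy_select(cands, NO_RINGS)
        rng = np.random.default_rng(seed)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        again = greedy_select(shuffled, NO_RINGS)
        assert [r.atom_keys for r in again.restraints] == [
            r.atom_keys for r in reference.restraints
        ]


class TestBreakTie:
    def test_single_tied_candidate_is_identity(self):
        cands = line_candidates([0.0, 0.5])
        selected = RestraintSet.from_restraints(line_candidates([0.2]))
        assert break_tie([cands[0]], selected) is cands[0]

    def test_farthest_from_cog_wins(self):
        selected = RestraintSet.from_restraints(
            candidates_at([[0.1, 0, 0], [-0.1, 0, 0]])  # COG at origin
        )
        near, far = candidates_at([[0.30, 0, 0.2], [0.31, 0, 0.2]], gap=0.06)
        assert break_tie([near, far], selected) is far

    def test_residual_tie_falls_back_to_atom_ids(self):
        selected = RestraintSet.from_restraints(
            candidates_at([[0.1, 0, 0], [-0.1, 0, 0]])
        )
        left, right = candidates_at([[0.0, 0.3, 0], [0.0, -0.3, 0]], gap=0.06)
        # equidistant from the COG; candidate with smaller atom_a id wins
        assert break_tie([right, left], selected) is left
        assert break_tie([left, right], selected) is left

    def test_tie_window_applies_to_weights(self):
        # anchors at x = 0 and 0.6 nm (selection COG at (0.3, 0, 0));
        # candidate A has min-distance weight 0.424, candidate C 0.410:
        # within the 0.02 nm window, so the COG criterion decides, and C
        # is farther from the COG (0.372 vs 0.300 nm) despite the
        # smaller weight
        anchors = candidates_at([[0.0, 0, 0], [0.6, 0, 0]])
        cand_a = candidates_at([[0.3, 0.30, 0.0]], gap=0.06, start=10)[0]
        cand_c = candidates_at([[0.4, 0.0, 0.3579]], gap=0.06, start=20)[0]
        weights = [
            min(
                np.linalg.norm(c.midpoint - anchors[0].midpoint),
                np.linalg.norm(c.midpoint - anchors[1].midpoint),
            )
            for c in (cand_a, cand_c)
        ]
        assert weights[0] > weights[1]  # plain argmax would pick A
        assert weights[0] - weights[1] < 0.02  # but they are tied
        rset = greedy_select(anchors + [cand_a, cand_c], SelectionParams(n_res=3))
        assert rset.restraints[2].atom_keys == cand_c.atom_keys


class TestScoreRestraintSet:
    def test_single_restraint_scores_zero(self):
        assert score_restraint_set(line_candidates([0.1])) == (0.0, 0.0)

    def test_two_restraints_distance_only(self):
        dist, chv = score_restraint_set(line_candidates([0.0, 0.3]))
        assert dist == pytest.approx(0.3)
        assert chv == 0.0

    def test_regular_tetrahedron_closed_form(self):
        edge = 0.1
        verts = (
            np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
            * edge
            / (2 * np.sqrt(2))
        )
        dist, chv = score_restraint_set(candidates_at(verts, gap=0.05))
        assert dist == pytest.approx(6 * edge)
        assert chv == pytest.approx(edge**3 / (6 * np.sqrt(2)))
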