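"""Geometry primitives, ring perception and structure I/O."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from restraintgraph.chem_model import (
    center_of_geometry,
    convex_hull_volume,
    load_structures,
    midpoint,
    perceive_ring_atoms,
    write_structures,
)
from restraintgraph.errors import FormatError, InputError

from conftest import make_molecule

TETRAHEDRON = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestConvexHullVolume:
    def test_tetrahedron_closed_form(self):
        assert convex_hull_volume(TETRAHEDRON) == pytest.approx(1 / 6)

    @pytest.mark.parametrize(
        "points",
        [
            np.zeros((1, 3)),
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float),  # collinear
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float),  # coplanar
        ],
        ids=["single", "collinear", "coplanar"],
    )
    def test_degenerate_sets_have_zero_volume(self, points):
        assert convex_hull_volume(points) == 0.0

    def test_interior_point_does_not_change_cube_hull(self):
        cube = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        with_centroid = np.vstack([cube, [[0.5, 0.5, 0.5]]])
        assert convex_hull_volume(cube) == pytest.approx(1.0)
        assert convex_hull_volume(with_centroid) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(7, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        moved = points @ rot.T + shift
        v0, v1 = convex_hull_volume(points), convex_hull_volume(moved)
        assert v1 == pytest.approx(v0, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_point_addition(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(6, 3))
        extra = rng.normal(size=(2, 3))
        assert convex_hull_volume(np.vstack([points, extra])) >= convex_hull_volume(
            points
        ) - 1e-12


class TestCogAndMidpoint:
    def test_midpoint_of_two_atoms(self):
        mol = make_molecule("m", [[0, 0, 0], [0, 0, 0.1]])
        assert midpoint(mol.atoms[0], mol.atoms[1]) == pytest.approx([0, 0, 0.05])

    def test_cog_identity_and_tetrahedron(self):
        assert center_of_geometry([np.array([1.0, 2.0, 3.0])]) == pytest.approx(
            [1, 2, 3]
        )
        assert center_of_geometry(TETRAHEDRON) == pytest.approx([0.25, 0.25, 0.25])


class TestRingPerception:
    def test_single_ring_excludes_substituent(self, benzene_with_substituent):
        assert perceive_ring_atoms(benzene_with_substituent) == {1, 2, 3, 4, 5, 6}

    def test_acyclic_chain_has_no_ring_atoms(self):
        chain = make_molecule(
            "alkane", np.zeros((5, 3)) + np.arange(5)[:, None] * 0.15,
            bonds=[(i + 1, i + 2) for i in range(4)],
        )
        assert perceive_ring_atoms(chain) == set()

    def test_no_bonds_gives_empty_set(self):
        assert perceive_ring_atoms(make_molecule("cloud", np.zeros((4, 3)))) == set()

    def test_bridged_bicycle_matches_cycle_enumeration(self):
        # two fused rings sharing the 1-2 bond plus a pending tail atom
        bonds = [(1, 2), (2, 3), (3, 4), (4, 1), (2, 5), (5, 6), (6, 1), (4, 7)]
        mol = make_molecule("bicycle", np.random.default_rng(0).normal(size=(7, 3)), bonds)
        graph = nx.Graph(tuple(b) for b in mol.bonds)
        # independent oracle: explicit enumeration of all simple cycles
        on_cycle = set().union(*nx.simple_cycles(graph), set())
        assert perceive_ring_atoms(mol) == on_cycle == {1, 2, 3, 4, 5, 6}

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_atom_reordering(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        edges = {
            frozenset((int(i) + 1, int(j) + 1))
            for i, j in rng.integers(0, n, size=(10, 2))
            if i != j
        }
        coords = rng.normal(size=(n, 3))
        mol = make_molecule("g", coords, edges)
        perm = rng.permutation(n) + 1
        relabel = {old: int(new) for old, new in zip(range(1, n + 1), perm)}
        remapped_bonds = {frozenset(relabel[i] for i in b) for b in edges}
        coords2 = np.empty_like(coords)
        for old, new in relabel.items():
            coords2[new - 1] = coords[old - 1]
        mol2 = make_molecule("g2", coords2, remapped_bonds)
        assert {relabel[i] for i in perceive_ring_atoms(mol)} == perceive_ring_atoms(
            mol2
        )


class TestStructureIO:
    def test_toy_round_trip(self, tmp_path):
        from restraintgraph.oracles_benchmark import generate_toy_system

        system = generate_toy_system(13, seed=5)
        path = tmp_path / "cloud.toy"
        write_structures(list(system.molecules), path)
        back = load_structures(path)
        assert [len(m) for m in back] == [len(m) for m in system.molecules]
        for orig, rt in zip(system.molecules, back):
            np.testing.assert_allclose(rt.positions, orig.positions, atol=1e-8)
            assert rt.bonds == set()

    def test_pdb_round_trip_preserves_coordinates_and_bonds(
        self, tmp_path, benzene_with_substituent
    ):
        path = tmp_path / "benzene.pdb"
        write_structures([benzene_with_substituent], path)
        (back,) = load_structures(path)
        np.testing.assert_allclose(
            back.positions, benzene_with_substituent.positions, atol=1e-4
        )
        assert back.bonds == benzene_with_substituent.bonds

    def test_pdb_angstrom_to_nm_conversion(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "HETATM    1  C1  UNL     1       1.000   2.000   3.000"
            "  1.00  0.00           C  \n"
        )
        (mol,) = load_structures(path)
        np.testing.assert_allclose(mol.atoms[0].position, [0.1, 0.2, 0.3], atol=1e-6)

    def test_sdf_two_records(self, tmp_path):
        def record(name, n, element, bond_lines=""):
            atoms = "".join(
                f"    {i}.0000    2.0000    3.0000 {element:<2} 0  0  0  0  0"
                "  0  0  0  0  0  0  0\n"
                for i in range(n)
            )
            nb = bond_lines.count("\n")
            return (
                f"{name}\n  gen\n\n{n:>3}{nb:>3}  0  0  0  0  0  0  0  0999 V2000\n"
                f"{atoms}{bond_lines}M  END\n$$$$\n"
            )

        path = tmp_path / "two.sdf"
        path.write_text(
            record("first", 12, "C", "  1  2  1  0\n  2  3  1  0\n")
            + record("second", 14, "N")
        )
        mols = load_structures(path)
        assert [len(m) for m in mols] == [12, 14]
        assert mols[0].bonds == {frozenset((1, 2)), frozenset((2, 3))}
        np.testing.assert_allclose(mols[0].atoms[1].position, [0.1, 0.2, 0.3])

    def test_unparsable_toy_line_names_location(self, tmp_path):
        path = tmp_path / "bad.toy"
        path.write_text("A 1 0.0 0.0 0.0\nA 2 oops 0.0\n")
        with pytest.raises(FormatError, match="bad.toy:2"):
            load_structures(path)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError, match="no such"):
            load_structures(tmp_path / "absent.pdb")
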