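import numpy as np
import pytest
from hypothesis import settings

from restraintgraph.chem_model import Atom, Molecule
from restraintgraph.pair_restraints import RestraintCandidate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_molecule(mol_id, coords, bonds=(), element="X"):
    atoms = [
        Atom(
            atom_id=i + 1,
            element=element,
            name=f"{element}{i + 1}",
            position=np.asarray(pos, dtype=float),
            molecule_id=mol_id,
        )
        for i, pos in enumerate(coords)
    ]
    return Molecule(mol_id, atoms, {frozenset(b) for b in bonds})


def line_candidates(xs, gap=0.08):
    """Atom-disjoint candidates whose midpoints sit at (x, 0, 0)."""
    cands = []
    for k, x in enumerate(xs):
        a = Atom(k + 1, "X", f"A{k + 1}", np.array([x, 0.0, gap / 2]), "molA")
        b = Atom(k + 1, "X", f"B{k + 1}", np.array([x, 0.0, -gap / 2]), "molB")
        cands.append(RestraintCandidate.from_atoms(a, b))
    return cands


def candidates_at(midpoints, gap=0.08, start=1):
    """Atom-disjoint candidates with the given 3-D midpoints.

    ``start`` offsets the atom ids so candidates from separate calls can
    be combined without atom collisions.
    """
    cands = []
    for k, mid in enumerate(midpoints):
        mid = np.asarray(mid, dtype=float)
        off = np.array([0.0, 0.0, gap / 2])
        a = Atom(start + k, "X", f"A{start + k}", mid + off, "molA")
        b = Atom(start + k, "X", f"B{start + k}", mid - off, "molB")
        cands.append(RestraintCandidate.from_atoms(a, b))
    return cands


@pytest.fixture
def benzene_with_substituent():
    theta = np.linspace(0.0, 2 * np.pi, 7)[:6]
    coords = [[0.14 * np.cos(t), 0.14 * np.sin(t), 0.0] for t in theta]
    coords.append([0.3, 0.0, 0.0])
    bonds = [(i + 1, (i + 1) % 6 + 1) for i in range(6)] + [(1, 7)]
    return make_molecule("benzene", coords, bonds, element="C")
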