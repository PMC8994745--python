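"""Domain types, structure ingestion and elementary geometry.

All coordinates inside the package are in nanometres; Angstrom-based
formats (PDB, SDF) are converted at the I/O boundary.  A molecule is a
set of numbered atoms with optional bond connectivity.  Ring atoms —
atoms lying on at least one simple cycle of the bond graph — form the
default search space for restraint placement, because rings are the
relatively rigid parts of a small molecule and restraining them is
least likely to distort conformational sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import FormatError, InputError

__all__ = [
    "ANGSTROM_TO_NM",
    "Atom",
    "GeometryPoint",
    "Molecule",
    "center_of_geometry",
    "convex_hull_volume",
    "load_structures",
    "midpoint",
    "perceive_ring_atoms",
    "write_structures",
]

logger = logging.getLogger(__name__)

ANGSTROM_TO_NM = 0.1

#: A bare point in space (nm). Kept as a plain float64 array of shape (3,).
GeometryPoint = np.ndarray

#: Affine-degeneracy tolerance for convex hulls, far below coordinate
#: precision (nm).
HULL_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class Atom:
    """One atom (or toy particle) with its position in nm.

    ``atom_id`` is 1-based and unique within the owning molecule;
    ``element`` is a chemical symbol, or ``"X"`` for toy particles.
    """

    atom_id: int
    element: str
    name: str
    position: np.ndarray
    molecule_id: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InputError(
                f"atom {self.atom_id!r} of {self.molecule_id!r}: position "
                f"must be a finite 3-vector, got {self.position!r}"
            )
        pos.flags.writeable = False
        object.__setattr__(self, "position", pos)
        if self.atom_id < 1:
            raise InputError(f"atom_id must be a positive integer, got {self.atom_id}")

    @property
    def key(self) -> tuple[str, int]:
        """Globally unique identifier ``(molecule_id, atom_id)``."""
        return (self.molecule_id, self.atom_id)


@dataclass
class Molecule:
    """An identified set of atoms with optional bonds.

    ``bonds`` holds unordered ``(atom_id, atom_id)`` pairs; it may be
    empty (toy point clouds carry no connectivity).
    """

    molecule_id: str
    atoms: list[Atom]
    bonds: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError(f"molecule {self.molecule_id!r} has no atoms")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise InputError(f"molecule {self.molecule_id!r} has duplicate atom_ids")
        self.bonds = {frozenset(b) for b in self.bonds}
        known = set(ids)
        for bond in self.bonds:
            if len(bond) != 2 or not bond <= known:
                raise InputError(
                    f"molecule {self.molecule_id!r}: bond {sorted(bond)} does not "
                    "reference two distinct existing atoms"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm, in atom order."""
        return np.array([a.position for a in self.atoms])

    def atom_by_id(self, atom_id: int) -> Atom:
        for atom in self.atoms:
            if atom.atom_id == atom_id:
                return atom
        raise KeyError(f"no atom {atom_id} in molecule {self.molecule_id!r}")

    @property
    def ring_atom_ids(self) -> set[int]:
        """Atom ids lying on at least one simple cycle of the bond graph."""
        return perceive_ring_atoms(self)


def perceive_ring_atoms(mol: Molecule) -> set[int]:
    """Return the ids of atoms that lie on at least one simple cycle.

    An edge lies on a cycle iff it is not a bridge, and an atom lies on
    a cycle iff it has an incident non-bridge edge; so the ring atoms
    are the endpoints of the bond graph's non-bridge edges.  Acyclic
    graphs (and molecules without bonds) give the empty set.
    """
    if not mol.bonds:
        return set()
    graph = nx.Graph()
    graph.add_nodes_from(a.atom_id for a in mol.atoms)
    graph.add_edges_from(tuple(b) for b in mol.bonds)
    bridges = {frozenset(e) for e in nx.bridges(graph)}
    ring_ids: set[int] = set()
    for bond in mol.bonds:
        if bond not in bridges:
            ring_ids |= set(bond)
    return ring_ids


def center_of_geometry(points: Iterable[GeometryPoint]) -> GeometryPoint:
    """Unweighted arithmetic mean of a non-empty set of points (nm)."""
    arr = np.atleast_2d(np.asarray(list(points), dtype=float))
    if arr.size == 0:
        raise InputError("center_of_geometry needs at least one point")
    return arr.mean(axis=0)


def midpoint(a: Atom, b: Atom) -> GeometryPoint:
    """Midpoint of two atoms = COG of their positions (nm)."""
    return (a.position + b.position) / 2.0


def convex_hull_volume(points: Iterable[GeometryPoint]) -> float:
    """Volume (nm^3) of the 3-D convex hull of a point set.

    Fewer than four points, or any affinely degenerate configuration
    (collinear/coplanar within ``HULL_DEGENERACY_TOL``), has zero
    volume by convention rather than being an error: a restraint set
    whose midpoints are coplanar simply spans no volume.
    """
    arr = np.atleast_2d(np.asarray(list(points), dtype=float))
    if arr.size == 0:
        raise InputError("convex_hull_volume needs at least one point")
    if len(arr) < 4:
        return 0.0
    centred = arr - arr.mean(axis=0)
    # affine rank via singular values; degenerate sets crash Qhull
    if np.linalg.matrix_rank(centred, tol=HULL_DEGENERACY_TOL) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(arr).volume)
    except QhullError:  # near-degenerate beyond the rank test
        return 0.0


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

_FORMATS = ("pdb", "sdf", "toy")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix in ("sdf", "sd", "mol"):
        return "sdf"
    if suffix in ("toy", "xyz", "txt", "dat"):
        return "toy"
    raise InputError(
        f"cannot infer structure format from {path.name!r}; "
        f"pass format explicitly (one of {_FORMATS})"
    )


def load_structures(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read molecules from a PDB, SDF or whitespace toy file.

    Each PDB model / SDF record / toy entity becomes one :class:`Molecule`.
    Coordinates are converted to nm; atoms are renumbered contiguously
    from 1 preserving file order; bonds come from CONECT records or the
    SDF bond block when present.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such structure file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise InputError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "pdb":
        mols = _load_pdb(path)
    elif fmt == "sdf":
        mols = _load_sdf(path)
    else:
        mols = _load_toy(path)
    if not mols:
        raise FormatError(f"{path}: no molecules found")
    return mols


def _load_pdb(path: Path) -> list[Molecule]:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise FormatError(f"{path}: not a parsable PDB file: {exc}") from exc
    mols = []
    for model in range(1, n_models + 1):
        try:
            atoms = pdb.get_structure(model=model, include_bonds=True)
        except Exception as exc:
            raise FormatError(f"{path}: model {model}: {exc}") from exc
        mol_id = f"{path.stem}" if n_models == 1 else f"{path.stem}:{model}"
        out_atoms = []
        for i in range(atoms.array_length()):
            element = str(atoms.element[i]).capitalize() or "X"
            out_atoms.append(
                Atom(
                    atom_id=i + 1,
                    element=element,
                    name=str(atoms.atom_name[i]) or element,
                    position=atoms.coord[i] * ANGSTROM_TO_NM,
                    molecule_id=mol_id,
                )
            )
        bonds = set()
        if atoms.bonds is not None:
            for i, j, _ in atoms.bonds.as_array():
                bonds.add(frozenset((int(i) + 1, int(j) + 1)))
        mols.append(Molecule(mol_id, out_atoms, bonds))
    return mols


def _load_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for rec, rd_mol in enumerate(supplier):
        if rd_mol is None:
            raise FormatError(f"{path}: record {rec + 1} is not parsable V2000/V3000")
        if rd_mol.GetNumConformers() == 0 or rd_mol.GetNumAtoms() == 0:
            raise FormatError(f"{path}: record {rec + 1} has no atoms/coordinates")
        name = rd_mol.GetProp("_Name") if rd_mol.HasProp("_Name") else ""
        mol_id = name.strip() or f"{path.stem}:{rec + 1}"
        conf = rd_mol.GetConformer()
        out_atoms = []
        for i, rd_atom in enumerate(rd_mol.GetAtoms()):
            pos = conf.GetAtomPosition(i)
            symbol = rd_atom.GetSymbol() or "X"
            out_atoms.append(
                Atom(
                    atom_id=i + 1,
                    element=symbol,
                    name=f"{symbol}{i + 1}",
                    position=np.array([pos.x, pos.y, pos.z]) * ANGSTROM_TO_NM,
                    molecule_id=mol_id,
                )
            )
        bonds = {
            frozenset((b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1))
            for b in rd_mol.GetBonds()
        }
        mols.append(Molecule(mol_id, out_atoms, bonds))
    return mols


def _load_toy(path: Path) -> list[Molecule]:
    """Plain whitespace format, one particle per line (already in nm)::

        entity_id  atom_id  x  y  z
    """
    per_entity: dict[str, list[tuple[int, np.ndarray]]] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 'entity_id atom_id x y z', got {raw!r}"
                )
            entity, atom_id_s, *xyz = fields
            try:
                atom_id = int(atom_id_s)
                pos = np.array([float(v) for v in xyz])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not math.isfinite(pos.sum()):
                raise FormatError(f"{path}:{lineno}: non-finite coordinate")
            if entity not in per_entity:
                per_entity[entity] = []
                order.append(entity)
            per_entity[entity].append((atom_id, pos))
    mols = []
    for entity in order:
        atoms = [
            Atom(
                atom_id=i + 1,
                element="X",
                name=f"X{orig_id}",
                position=pos,
                molecule_id=entity,
            )
            for i, (orig_id, pos) in enumerate(per_entity[entity])
        ]
        mols.append(Molecule(entity, atoms))
    return mols


def write_structures(
    molecules: Sequence[Molecule], path: str | Path, format: str | None = None
) -> None:
    """Write molecules to a toy or PDB file (inverse of :func:`load_structures`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "toy":
        lines = []
        for mol in molecules:
            for atom in mol.atoms:
                x, y, z = atom.position
                lines.append(
                    f"{mol.molecule_id} {atom.atom_id} {x:.9f} {y:.9f} {z:.9f}"
                )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        _write_pdb(molecules, path)
    else:
        raise InputError(f"no writer for format {fmt!r} (use 'toy' or 'pdb')")


def _write_pdb(molecules: Sequence[Molecule], path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    arrays = []
    for mol in molecules:
        arr = struc.AtomArray(len(mol.atoms))
        arr.coord = mol.positions / ANGSTROM_TO_NM
        # "UNL" (unknown ligand) has no CCD template, so readers take the
        # connectivity from the CONECT records alone
        arr.res_name = np.full(len(mol.atoms), "UNL")
        arr.res_id = np.ones(len(mol.atoms), dtype=int)
        arr.hetero = np.ones(len(mol.atoms), dtype=bool)
        arr.atom_name = np.array([a.name[:4] for a in mol.atoms])
        arr.element = np.array([a.element.upper() for a in mol.atoms])
        id_to_index = {a.atom_id: i for i, a in enumerate(mol.atoms)}
        bond_array = np.array(
            [
                [id_to_index[i], id_to_index[j], int(struc.BondType.SINGLE)]
                for i, j in (sorted(b) for b in mol.bonds)
            ],
            dtype=np.uint32,
        ).reshape(-1, 3)
        arr.bonds = struc.BondList(len(mol.atoms), bond_array)
        arrays.append(arr)
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        stack = struc.stack(arrays)  # requires equal atom counts per model
        pdb.set_structure(stack)
    pdb.write(str(path))
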