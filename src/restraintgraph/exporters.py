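"""Restraint writers: GROMOS, GROMACS, and a JSON interchange format.

Selected restraints are back-mapped from candidate objects to atom
indices of a merged dual-topology system: molecule A keeps its indices,
molecule B is shifted by an offset (by default the atom count of A);
for rings the offsets accumulate over the molecules in ring order.

Column conventions (this package's dialect; the underlying physics is a
plain harmonic distance restraint, default force constant
5000 kJ/(mol nm^2), reference distance r0 = 0 nm):

GROMOS ``DISTANCERESSPEC`` block, one line per restraint::

    #   i  j  k  l  type    i  j  k  l  type    r0    w0   rah
      <i>  0  0  0     0  <j>  0  0  0     0  <r0>  <w0>  <rah>

with real-atom virtual-type code 0 on both sides, weight ``w0 = 1.0``
and ``rah = 0`` (attractive *and* repulsive, i.e. fully harmonic);
``r0`` and ``w0`` are fixed-point with 6 decimals; the block header
carries the GROMOS ``DISH``/``DISC`` carbon-hydrogen/carbon-carbon
virtual-site distances (0.1 / 0.153 nm).

GROMACS ``[ distance_restraints ]`` section, one line per restraint::

    ; ai  aj  funct  label  type'  low  up1  up2  fac
    <ai>  <aj>  1  <label>  1  0.0  <r0 + flat_width>  <r0 + flat_width + 0.1>  <fac>

labels enumerate restraints in selection order from 0; ``fac`` scales
the run-level ``disre-fc`` and is written as
``force_constant / disre_fc_reference`` (reference 1000 kJ/(mol nm^2)).

The JSON format stores both atoms of every restraint with coordinates
in nm and is lossless for atom identities, r0 and the force constant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .chem_model import Atom, Molecule
from .errors import InputError
from .pair_restraints import RestraintCandidate, RestraintSet

__all__ = [
    "ExportParams",
    "read_gromacs",
    "read_gromos",
    "read_json",
    "write_gromacs",
    "write_gromos",
    "write_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExportParams:
    """Force constant, reference distance and dialect switches.

    ``atom_offset_b`` is the merged-system index offset of molecule B;
    ``None`` means "derive it from the molecules" (atom count of A).
    """

    force_constant: float = 5000.0  # kJ/(mol nm^2)
    r0: float = 0.0  # nm
    atom_offset_b: int | None = None
    # GROMOS dialect
    dish: float = 0.1
    disc: float = 0.153
    w0: float = 1.0
    rah: int = 0
    # GROMACS dialect
    flat_width: float = 0.1  # nm; up1 = r0 + flat_width
    disre_fc_reference: float = 1000.0  # kJ/(mol nm^2)

    def __post_init__(self) -> None:
        if not self.force_constant > 0:
            raise InputError(
                f"force_constant must be positive, got {self.force_constant}"
            )
        if self.r0 < 0:
            raise InputError(f"r0 must be >= 0, got {self.r0}")


def _as_sets(sets: RestraintSet | Iterable[RestraintSet]) -> list[RestraintSet]:
    if isinstance(sets, RestraintSet):
        return [sets]
    out = list(sets)
    if not out:
        raise InputError("no restraint sets to export")
    return out


def _merged_offsets(
    sets: list[RestraintSet],
    params: ExportParams,
    molecules: Sequence[Molecule] | None,
) -> dict[str, int]:
    """Offset added to each molecule's atom ids in the merged system.

    With ``molecules`` given, offsets are cumulative atom counts in the
    given order.  Without them, only the two-molecule case is possible
    and requires an explicit ``atom_offset_b``.
    """
    if molecules is not None:
        offsets: dict[str, int] = {}
        running = 0
        for mol in molecules:
            offsets[mol.molecule_id] = running
            running += len(mol.atoms)
        if len(molecules) == 2 and params.atom_offset_b is not None:
            offsets[molecules[1].molecule_id] = params.atom_offset_b
        return offsets
    mol_ids: list[str] = []
    for rset in sets:
        for mol_id in rset.molecule_pair:
            if mol_id not in mol_ids:
                mol_ids.append(mol_id)
    if len(mol_ids) != 2:
        raise InputError(
            "exporting restraints over more than two molecules requires the "
            "molecule list to derive merged-index offsets"
        )
    if params.atom_offset_b is None:
        raise InputError(
            "atom_offset_b is required (or pass molecules=) to place "
            "molecule-B atoms in the merged system"
        )
    return {mol_ids[0]: 0, mol_ids[1]: params.atom_offset_b}


def _merged_pairs(
    sets: list[RestraintSet],
    params: ExportParams,
    molecules: Sequence[Molecule] | None,
) -> list[tuple[int, int]]:
    offsets = _merged_offsets(sets, params, molecules)
    pairs = []
    seen: dict[tuple[str, int], int] = {}
    for rset in sets:
        for restraint in rset.restraints:
            merged = []
            for atom in (restraint.atom_a, restraint.atom_b):
                if atom.molecule_id not in offsets:
                    raise InputError(
                        f"cannot resolve merged index for atom "
                        f"{atom.molecule_id}:{atom.atom_id} in {restraint!r}"
                    )
                idx = offsets[atom.molecule_id] + atom.atom_id
                if seen.setdefault(atom.key, idx) != idx:
                    raise InputError(f"merged index clash for atom {atom.key}")
                merged.append(idx)
            pairs.append((merged[0], merged[1]))
    collisions = {}
    for (key, idx) in seen.items():
        if idx in collisions and collisions[idx] != key:
            raise InputError(
                f"merged-index mapping is not injective: {key} and "
                f"{collisions[idx]} both map to {idx}"
            )
        collisions[idx] = key
    return pairs


def write_gromos(
    sets: RestraintSet | Iterable[RestraintSet],
    params: ExportParams | None = None,
    path: str | Path = "disres.dat",
    molecules: Sequence[Molecule] | None = None,
) -> None:
    """Write a GROMOS distance-restraint file (TITLE + DISTANCERESSPEC)."""
    params = params or ExportParams()
    sets = _as_sets(sets)
    pairs = _merged_pairs(sets, params, molecules)
    lines = [
        "TITLE",
        "inter-molecular distance restraints for a linked dual-topology setup",
        f"generated by restraintgraph (harmonic, k = {params.force_constant:g} "
        "kJ/(mol nm^2))",
        "END",
        "DISTANCERESSPEC",
        "# DISH  DISC",
        f"{params.dish:.6f} {params.disc:.6f}",
        "#    i    j    k    l  type     i    j    k    l  type"
        "          r0          w0  rah",
    ]
    for i, j in pairs:
        lines.append(
            f"{i:>6}{0:>5}{0:>5}{0:>5}{0:>6}"
            f"{j:>6}{0:>5}{0:>5}{0:>5}{0:>6}"
            f"{params.r0:>12.6f}{params.w0:>12.6f}{params.rah:>5}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gromos(path: str | Path) -> list[tuple[int, int, float]]:
    """Parse a GROMOS restraint file written by this package.

    Returns ``(i, j, r0)`` per restraint line.
    """
    inside = False
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line == "DISTANCERESSPEC":
            inside = True
            continue
        if not inside or not line or line.startswith("#"):
            continue
        if line == "END":
            inside = False
            continue
        fields = line.split()
        if len(fields) == 2:  # DISH/DISC header
            continue
        if len(fields) != 13:
            raise InputError(
                f"{path}:{lineno}: expected 13 fields in a DISTANCERESSPEC "
                f"line, got {len(fields)}"
            )
        out.append((int(fields[0]), int(fields[5]), float(fields[10])))
    return out


def write_gromacs(
    sets: RestraintSet | Iterable[RestraintSet],
    params: ExportParams | None = None,
    path: str | Path = "disres.itp",
    molecules: Sequence[Molecule] | None = None,
) -> None:
    """Write a GROMACS topology ``[ distance_restraints ]`` fragment."""
    params = params or ExportParams()
    sets = _as_sets(sets)
    pairs = _merged_pairs(sets, params, molecules)
    up1 = params.r0 + params.flat_width
    up2 = up1 + 0.1
    fac = params.force_constant / params.disre_fc_reference
    lines = [
        "; inter-molecular distance restraints (linked dual topology)",
        f"; harmonic k = {params.force_constant:g} kJ/(mol nm^2) => fac = "
        f"k / disre-fc with disre-fc = {params.disre_fc_reference:g}",
        "; convention: low = 0, up1 = r0 + flat_width, up2 = up1 + 0.1 nm",
        "[ distance_restraints ]",
        ";   ai    aj funct label type      low      up1      up2      fac",
    ]
    for label, (i, j) in enumerate(pairs):
        lines.append(
            f"{i:>6}{j:>6}{1:>6}{label:>6}{1:>5}"
            f"{0.0:>9.6f}{up1:>9.6f}{up2:>9.6f}{fac:>9.6f}"
        )
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gromacs(path: str | Path) -> list[tuple[int, int]]:
    """Parse the ``[ distance_restraints ]`` fragment written here.

    Returns the ``(ai, aj)`` merged atom-index pairs in file order.
    """
    inside = False
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            inside = line.replace(" ", "") == "[distance_restraints]"
            continue
        if not inside:
            continue
        fields = line.split()
        if len(fields) != 9:
            raise InputError(
                f"{path}:{lineno}: expected 9 fields in a distance_restraints "
                f"line, got {len(fields)}"
            )
        out.append((int(fields[0]), int(fields[1])))
    return out


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def _atom_obj(atom: Atom) -> dict:
    x, y, z = (float(v) for v in atom.position)
    return {
        "molecule_id": atom.molecule_id,
        "atom_id": atom.atom_id,
        "name": atom.name,
        "element": atom.element,
        "x": x,
        "y": y,
        "z": z,
    }


def write_json(
    sets: RestraintSet | Iterable[RestraintSet],
    params: ExportParams | None = None,
    path: str | Path = "restraints.json",
) -> None:
    """Write the JSON interchange file (coordinates in nm)."""
    params = params or ExportParams()
    try:
        sets = _as_sets(sets)
    except InputError:
        sets = []  # an empty selection is a valid (empty) JSON document
    obj = {
        "meta": {
            "tool": "restraintgraph",
            "version": __version__,
            "units": "nm",
            "parameters": {
                "force_constant": float(params.force_constant),
                "r0": float(params.r0),
            },
        },
        "restraints": [
            {
                "m1": _atom_obj(r.atom_a),
                "m2": _atom_obj(r.atom_b),
                "r0": float(params.r0),
                "force_constant": float(params.force_constant),
            }
            for rset in sets
            for r in rset.restraints
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


_ATOM_FIELDS = {
    "molecule_id": str,
    "atom_id": int,
    "name": str,
    "element": str,
    "x": (int, float),
    "y": (int, float),
    "z": (int, float),
}


def _check(condition: bool, json_path: str, message: str) -> None:
    if not condition:
        raise InputError(f"invalid restraint JSON at {json_path}: {message}")


def _parse_atom(obj: dict, json_path: str) -> Atom:
    _check(isinstance(obj, dict), json_path, "expected an object")
    for key, types in _ATOM_FIELDS.items():
        _check(key in obj, f"{json_path}.{key}", "missing field")
        _check(
            isinstance(obj[key], types) and not isinstance(obj[key], bool),
            f"{json_path}.{key}",
            f"expected {types}",
        )
    return Atom(
        atom_id=obj["atom_id"],
        element=obj["element"],
        name=obj["name"],
        position=np.array([obj["x"], obj["y"], obj["z"]], dtype=float),
        molecule_id=obj["molecule_id"],
    )


def read_json(path: str | Path) -> tuple[list[RestraintSet], ExportParams]:
    """Read the JSON interchange file back into restraint sets.

    Midpoints and set metrics are recomputed from the stored atom
    coordinates, never trusted from the file.
    """
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON: {exc}") from exc
    _check(isinstance(obj, dict), "$", "expected a top-level object")
    _check("meta" in obj, "$.meta", "missing field")
    _check("restraints" in obj, "$.restraints", "missing field")
    meta = obj["meta"]
    _check(isinstance(meta, dict), "$.meta", "expected an object")
    _check(meta.get("units") == "nm", "$.meta.units", "units must be 'nm'")
    parameters = meta.get("parameters", {})
    _check(isinstance(parameters, dict), "$.meta.parameters", "expected an object")
    params = ExportParams(
        force_constant=float(parameters.get("force_constant", 5000.0)),
        r0=float(parameters.get("r0", 0.0)),
    )
    _check(isinstance(obj["restraints"], list), "$.restraints", "expected an array")
    by_pair: dict[tuple[str, str], list[RestraintCandidate]] = {}
    for idx, entry in enumerate(obj["restraints"]):
        jp = f"$.restraints[{idx}]"
        _check(isinstance(entry, dict), jp, "expected an object")
        for side in ("m1", "m2"):
            _check(side in entry, f"{jp}.{side}", "missing field")
        atom_a = _parse_atom(entry["m1"], f"{jp}.m1")
        atom_b = _parse_atom(entry["m2"], f"{jp}.m2")
        cand = RestraintCandidate.from_atoms(atom_a, atom_b)
        by_pair.setdefault((atom_a.molecule_id, atom_b.molecule_id), []).append(cand)
    sets = [RestraintSet.from_restraints(cands) for cands in by_pair.values()]
    return sets, params
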