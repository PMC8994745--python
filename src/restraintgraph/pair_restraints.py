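"""Greedy min-max selection of distance restraints for one molecule pair.

Given two pre-aligned molecules, every cross-molecule ring-atom pair
closer than a cutoff ``d_res`` is a candidate restraint, represented by
the midpoint of its two atoms.  The candidates form the nodes of an
implicit complete graph whose edge weights are midpoint distances; the
selection is a max-min dispersion greedy on that graph:

1. start with the two candidates whose midpoints are farthest apart;
2. drop every candidate that shares an atom with the selection;
3. weight each survivor by its minimum midpoint distance to the
   selection and add the candidate with the largest weight;
4. repeat from 2 until ``n_res`` restraints are chosen or no candidate
   is left.

When the top weights in a step lie within a tie window (default
0.02 nm — alignment noise), the tie is broken in favour of the
candidate farthest from the centre of geometry of the already selected
midpoints, which pushes the selection outward; any residual exact tie
falls back to ascending atom ids, so the selection is deterministic
under arbitrary input ordering.

Spreading the restraints out serves dual-topology free-energy
calculations: maximally distant harmonic links suppress relative
translation *and* rotation of the two ligands while each link stays
short enough to be unstrained in the aligned pose.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem_model import (
    Atom,
    Molecule,
    center_of_geometry,
    convex_hull_volume,
    midpoint,
)
from .errors import InputError, NoCandidatesError

__all__ = [
    "RestraintCandidate",
    "RestraintSet",
    "SelectionParams",
    "break_tie",
    "generate_candidates",
    "greedy_select",
    "score_restraint_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class RestraintCandidate:
    """An ordered cross-molecule atom pair within the distance cutoff."""

    atom_a: Atom
    atom_b: Atom
    midpoint: np.ndarray
    pair_distance: float

    @classmethod
    def from_atoms(cls, atom_a: Atom, atom_b: Atom) -> "RestraintCandidate":
        if atom_a.molecule_id == atom_b.molecule_id:
            raise InputError(
                "restraint candidates pair atoms of two different molecules, "
                f"got {atom_a.molecule_id!r} twice"
            )
        return cls(
            atom_a=atom_a,
            atom_b=atom_b,
            midpoint=midpoint(atom_a, atom_b),
            pair_distance=float(np.linalg.norm(atom_a.position - atom_b.position)),
        )

    @property
    def atom_keys(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.atom_a.key, self.atom_b.key)

    @property
    def sort_key(self) -> tuple[int, int]:
        """Deterministic candidate order: ascending (atom_a.id, atom_b.id)."""
        return (self.atom_a.atom_id, self.atom_b.atom_id)

    def __repr__(self) -> str:  # compact: used in logs and error messages
        return (
            f"<{self.atom_a.molecule_id}:{self.atom_a.atom_id}"
            f"--{self.atom_b.molecule_id}:{self.atom_b.atom_id}"
            f" d={self.pair_distance:.4f}nm>"
        )


@dataclass(frozen=True)
class SelectionParams:
    """Tunable parameters of the pairwise selection.

    ``n_res``
        number of restraints to place (default 4; a handful suffices
        to pin two rigid bodies).
    ``d_res``
        atom-distance cutoff in nm (default 0.1): only atom pairs
        closer than this in the aligned pose are candidates.
    ``tie_tolerance``
        width of the tie window on the min-distance weights, nm
        (default 0.02).
    ``restrict_to_rings``
        keep only ring atoms as restraint anchors (default True);
        bypassed automatically for molecules without bond information.
    """

    n_res: int = 4
    d_res: float = 0.1
    tie_tolerance: float = 0.02
    restrict_to_rings: bool = True

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise InputError(f"n_res must be >= 1, got {self.n_res}")
        if not self.d_res > 0:
            raise InputError(f"d_res must be positive, got {self.d_res}")
        if self.tie_tolerance < 0:
            raise InputError(f"tie_tolerance must be >= 0, got {self.tie_tolerance}")


@dataclass(frozen=True)
class RestraintSet:
    """A selected set of restraints for one molecule pair, with metrics.

    ``restraints`` preserves selection order.  ``sum_midpoint_distance``
    is the sum of midpoint distances over all unordered restraint pairs;
    ``chv`` is the convex-hull volume of the midpoints.  Both are
    recomputable from the restraints (see :func:`score_restraint_set`).
    """

    restraints: tuple[RestraintCandidate, ...]
    molecule_pair: tuple[str, str]
    sum_midpoint_distance: float
    chv: float

    @classmethod
    def from_restraints(
        cls, restraints: Sequence[RestraintCandidate]
    ) -> "RestraintSet":
        if not restraints:
            raise InputError("a RestraintSet needs at least one restraint")
        keys = [k for r in restraints for k in r.atom_keys]
        if len(set(keys)) != len(keys):
            raise InputError("restraints are not atom-disjoint")
        pair = (restraints[0].atom_a.molecule_id, restraints[0].atom_b.molecule_id)
        dist, chv = score_restraint_set(restraints)
        return cls(tuple(restraints), pair, dist, chv)

    def __len__(self) -> int:
        return len(self.restraints)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([r.midpoint for r in self.restraints])


def score_restraint_set(
    restraints: "RestraintSet | Sequence[RestraintCandidate]",
) -> tuple[float, float]:
    """Recompute (sum-of-midpoint-distances, convex-hull-volume)."""
    if isinstance(restraints, RestraintSet):
        restraints = restraints.restraints
    if not restraints:
        raise InputError("cannot score an empty restraint set")
    mids = np.array([r.midpoint for r in restraints])
    total = 0.0
    for i, j in itertools.combinations(range(len(mids)), 2):
        total += float(np.linalg.norm(mids[i] - mids[j]))
    return total, convex_hull_volume(mids)


def _eligible_atoms(mol: Molecule, restrict_to_rings: bool) -> list[Atom]:
    if not restrict_to_rings:
        return list(mol.atoms)
    if not mol.bonds:
        logger.warning(
            "molecule %r has no bond information; ring filtering bypassed, "
            "all atoms eligible",
            mol.molecule_id,
        )
        return list(mol.atoms)
    ring_ids = mol.ring_atom_ids
    return [a for a in mol.atoms if a.atom_id in ring_ids]


def generate_candidates(
    mol_a: Molecule, mol_b: Molecule, params: SelectionParams | None = None
) -> list[RestraintCandidate]:
    """All cross-molecule (ring-)atom pairs within ``d_res`` of each other.

    The molecules must be pre-aligned in a common frame.  Candidates are
    returned in ascending ``(atom_a.atom_id, atom_b.atom_id)`` order; an
    empty result is not an error here (the selector reports it).
    """
    params = params or SelectionParams()
    if mol_a.molecule_id == mol_b.molecule_id:
        raise InputError(
            f"need two distinct molecules, got {mol_a.molecule_id!r} twice"
        )
    atoms_a = sorted(
        _eligible_atoms(mol_a, params.restrict_to_rings), key=lambda a: a.atom_id
    )
    atoms_b = sorted(
        _eligible_atoms(mol_b, params.restrict_to_rings), key=lambda a: a.atom_id
    )
    if not atoms_a or not atoms_b:
        return []
    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([b.position for b in atoms_b])
    dists = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    out = []
    for i, j in zip(*np.nonzero(dists <= params.d_res)):
        out.append(RestraintCandidate.from_atoms(atoms_a[i], atoms_b[j]))
    return out


def break_tie(
    tied: Sequence[RestraintCandidate],
    selected: "RestraintSet | Sequence[RestraintCandidate]",
) -> RestraintCandidate:
    """Resolve a weight tie: farthest midpoint from the selected-set COG.

    Residual exact ties (symmetric geometries) fall back to ascending
    ``(atom_a.atom_id, atom_b.atom_id)``.
    """
    if not tied:
        raise InputError("break_tie needs at least one tied candidate")
    sel = selected.restraints if isinstance(selected, RestraintSet) else selected
    if not sel:
        raise InputError("break_tie needs at least one selected restraint")
    cog = center_of_geometry([r.midpoint for r in sel])
    best = None
    best_rank: tuple[float, int, int] | None = None
    for cand in tied:
        dist = float(np.linalg.norm(cand.midpoint - cog))
        rank = (-dist, *cand.sort_key)
        if best_rank is None or rank < best_rank:
            best, best_rank = cand, rank
    return best


#: Tie window of the *initial* edge choice, nm.  Deliberately at
#: floating-point scale rather than the 0.02 nm iteration window: the
#: first step must realize the true maximum midpoint separation, and a
#: wider window here would trade that exactness away.
_INITIAL_TIE_EPS = 1e-9


def _initial_pair(
    candidates: Sequence[RestraintCandidate], tie_tolerance: float = _INITIAL_TIE_EPS
) -> tuple[int, int]:
    """Indices of the atom-disjoint candidate pair with maximal midpoint
    separation.

    Exactly tied pairs (equal separation within ``tie_tolerance``, a
    floating-point epsilon for symmetric geometries) are disambiguated
    by choosing the pair whose own midpoint-COG lies closest to the COG
    of all candidate midpoints (a seed centred in the cloud leaves the
    most room for the outward-pushing later steps), then by ascending
    atom ids.  The COG tie rule of the iteration steps needs an
    existing selection, so this first step carries its own
    deterministic rule.
    """
    mids = np.array([c.midpoint for c in candidates])
    m = len(candidates)
    dmat = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=-1)
    disjoint = np.ones((m, m), dtype=bool)
    for i in range(m):
        keys_i = set(candidates[i].atom_keys)
        for j in range(i + 1, m):
            if keys_i & set(candidates[j].atom_keys):
                disjoint[i, j] = disjoint[j, i] = False
    np.fill_diagonal(disjoint, False)
    if not disjoint.any():
        raise NoCandidatesError(
            "no two atom-disjoint candidates exist; all candidates share atoms"
        )
    masked = np.where(disjoint, dmat, -np.inf)
    dmax = masked.max()
    tied_idx = np.argwhere(masked >= dmax - tie_tolerance)
    tied_idx = [(int(i), int(j)) for i, j in tied_idx if i < j]
    if len(tied_idx) == 1:
        i, j = tied_idx[0]
    else:
        global_cog = mids.mean(axis=0)
        best_rank = None
        i = j = -1
        for p, q in tied_idx:
            pair_cog = (mids[p] + mids[q]) / 2.0
            # canonical orientation of the pair for the lexicographic part
            a, b = sorted((p, q), key=lambda k: candidates[k].sort_key)
            rank = (
                float(np.linalg.norm(pair_cog - global_cog)),
                *candidates[a].sort_key,
                *candidates[b].sort_key,
            )
            if best_rank is None or rank < best_rank:
                best_rank, (i, j) = rank, (a, b)
    if candidates[i].sort_key > candidates[j].sort_key:
        i, j = j, i
    return i, j


def greedy_select(
    candidates: Sequence[RestraintCandidate], params: SelectionParams | None = None
) -> RestraintSet:
    """Run the max-min dispersion greedy and return the scored selection.

    Returns fewer than ``n_res`` restraints (with a logged warning) when
    atom-disjointness exhausts the candidates first; raises
    :class:`NoCandidatesError` on an empty candidate collection.
    """
    params = params or SelectionParams()
    candidates = sorted(candidates, key=lambda c: c.sort_key)
    if not candidates:
        raise NoCandidatesError(
            "no restraint candidates: consider a larger d_res cutoff or a "
            "better alignment of the two molecules"
        )
    if len(candidates) == 1:
        return RestraintSet.from_restraints(candidates)

    try:
        i, j = _initial_pair(candidates)
        selected = [candidates[i], candidates[j]]
    except NoCandidatesError:
        # every pair shares an atom: a single restraint is the maximal set
        logger.warning("all candidates share atoms; returning a single restraint")
        return RestraintSet.from_restraints(candidates[:1])
    if params.n_res == 1:
        return RestraintSet.from_restraints(selected[:1])

    remaining = list(candidates)
    while len(selected) < params.n_res:
        used = {k for r in selected for k in r.atom_keys}
        remaining = [
            c for c in remaining if not (set(c.atom_keys) & used)
        ]
        if not remaining:
            break
        sel_mids = np.array([r.midpoint for r in selected])
        rem_mids = np.array([c.midpoint for c in remaining])
        weights = np.linalg.norm(
            rem_mids[:, None, :] - sel_mids[None, :, :], axis=-1
        ).min(axis=1)
        wmax = float(weights.max())
        tied = [
            c
            for c, w in zip(remaining, weights)
            if w >= wmax - params.tie_tolerance
        ]
        choice = tied[0] if len(tied) == 1 else break_tie(tied, selected)
        selected.append(choice)

    if len(selected) < params.n_res:
        logger.warning(
            "only %d of %d requested restraints are feasible under "
            "atom-disjointness",
            len(selected),
            params.n_res,
        )
    return RestraintSet.from_restraints(selected)


def select_pair_restraints(
    mol_a: Molecule, mol_b: Molecule, params: SelectionParams | None = None
) -> RestraintSet:
    """Convenience front door: candidates + greedy selection in one call."""
    params = params or SelectionParams()
    cands = generate_candidates(mol_a, mol_b, params)
    if not cands:
        raise NoCandidatesError(
            f"no atom pair of {mol_a.molecule_id!r}/{mol_b.molecule_id!r} lies "
            f"within d_res={params.d_res} nm: consider a larger cutoff or a "
            "better alignment"
        )
    logger.info(
        "%s/%s: %d candidates under d_res=%g nm",
        mol_a.molecule_id,
        mol_b.molecule_id,
        len(cands),
        params.d_res,
    )
    return greedy_select(cands, params)
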