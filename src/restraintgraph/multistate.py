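"""Chain M > 2 aligned end-states into a restraint ring.

Multi-state free-energy methods (EDS/RE-EDS, multi-site lambda
dynamics) simulate many ligands at once; restraining them works best as
a ring in which every molecule is tied to exactly two neighbours.  The
ring is built in four steps: (i) pairwise restraint sets for all
molecule pairs, (ii) each pair weighted by the convex-hull volume (CHV)
of its restraint midpoints — a proxy for how well the restraints span
the pair, (iii) a branch-free maximum spanning chain assembled by a
Kruskal-style greedy that takes edges in descending CHV while refusing
branches (degree > 2) and premature cycles, and (iv) ring closure by
joining the two chain endpoints, accepting that this final pair may
carry the weakest restraint set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .chem_model import Molecule
from .errors import ChainingError, InputError, NoCandidatesError, RingClosureError
from .pair_restraints import (
    RestraintSet,
    SelectionParams,
    generate_candidates,
    greedy_select,
)

__all__ = [
    "MultiStateRing",
    "PairMatrix",
    "build_chain",
    "build_pair_matrix",
    "close_ring",
    "make_ring",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    """Canonical unordered molecule-id pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PairMatrix:
    """Pairwise restraint sets and CHV weights over a molecule collection.

    Pairs that produced no candidates are simply absent — an empty pair
    cannot link two molecules, unlike a zero-CHV pair that still has
    restraints.
    """

    molecules: list[Molecule]
    pair_sets: dict[Pair, RestraintSet] = field(default_factory=dict)

    @property
    def weights(self) -> dict[Pair, float]:
        return {pair: rset.chv for pair, rset in self.pair_sets.items()}

    def molecule_by_id(self, mol_id: str) -> Molecule:
        for mol in self.molecules:
            if mol.molecule_id == mol_id:
                return mol
        raise KeyError(f"no molecule {mol_id!r} in the pair matrix")


@dataclass(frozen=True)
class MultiStateRing:
    """A cyclic molecule order with one restraint set per adjacent pair."""

    order: tuple[str, ...]
    edge_sets: dict[Pair, RestraintSet]
    closure_pair: Pair

    @property
    def edges(self) -> list[Pair]:
        n = len(self.order)
        return [_pair(self.order[i], self.order[(i + 1) % n]) for i in range(n)]


def build_pair_matrix(
    molecules: list[Molecule], params: SelectionParams | None = None
) -> PairMatrix:
    """Run the pairwise selection for every unordered molecule pair."""
    params = params or SelectionParams()
    if len(molecules) < 3:
        raise InputError(
            f"multi-state chaining needs at least 3 molecules, got {len(molecules)}"
        )
    ids = [m.molecule_id for m in molecules]
    if len(set(ids)) != len(ids):
        raise InputError("molecule_ids must be unique for multi-state chaining")
    matrix = PairMatrix(molecules=list(molecules))
    for mol_a, mol_b in itertools.combinations(molecules, 2):
        cands = generate_candidates(mol_a, mol_b, params)
        if not cands:
            logger.info(
                "pair %s/%s: no candidates, edge absent",
                mol_a.molecule_id,
                mol_b.molecule_id,
            )
            continue
        rset = greedy_select(cands, params)
        matrix.pair_sets[_pair(mol_a.molecule_id, mol_b.molecule_id)] = rset
    return matrix


def _greedy_chain(ids: list[str], edges: list[tuple[float, Pair]]) -> list[Pair] | None:
    """Kruskal-like pass: accept edges by descending weight unless they
    would branch (endpoint degree 2) or close a cycle early."""
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    degree = {i: 0 for i in ids}
    accepted: list[Pair] = []
    for _, pair in edges:
        a, b = pair
        if degree[a] >= 2 or degree[b] >= 2:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        degree[a] += 1
        degree[b] += 1
        accepted.append(pair)
        if len(accepted) == len(ids) - 1:
            return accepted
    return None


def _exhaustive_chain(ids: list[str], weights: dict[Pair, float]) -> list[Pair] | None:
    """Maximum-weight Hamiltonian path by enumeration (fallback, M <= 8)."""
    best_path: tuple[str, ...] | None = None
    best_total = -np.inf
    for perm in itertools.permutations(ids):
        if perm[0] > perm[-1]:  # each path once, canonical orientation
            continue
        pairs = [_pair(perm[i], perm[i + 1]) for i in range(len(perm) - 1)]
        if any(p not in weights for p in pairs):
            continue
        total = sum(weights[p] for p in pairs)
        if best_path is None or total > best_total or (
            total == best_total and perm < best_path
        ):
            best_total, best_path = total, perm
    if best_path is None:
        return None
    return [_pair(best_path[i], best_path[i + 1]) for i in range(len(best_path) - 1)]


def _path_from_edges(ids: list[str], accepted: list[Pair]) -> list[str]:
    adjacency: dict[str, list[str]] = {i: [] for i in ids}
    for a, b in accepted:
        adjacency[a].append(b)
        adjacency[b].append(a)
    ends = sorted(i for i, nbrs in adjacency.items() if len(nbrs) == 1)
    assert len(ends) == 2, "accepted edges do not form a single open path"
    path = [ends[0]]
    prev = None
    while len(path) < len(ids):
        nxt = [n for n in adjacency[path[-1]] if n != prev]
        prev = path[-1]
        path.append(nxt[0])
    return path


def build_chain(matrix: PairMatrix) -> list[str]:
    """Order the molecules along a branch-free maximum spanning chain.

    Edges are considered in descending CHV (ties: lexicographic
    molecule-id pair).  If the greedy pass dead-ends — possible on
    sparse or adversarial weight patterns even when a chain exists — an
    exhaustive maximum-weight Hamiltonian-path search takes over for up
    to 8 molecules.
    """
    ids = sorted(m.molecule_id for m in matrix.molecules)
    weights = matrix.weights
    present = {i for pair in weights for i in pair}
    isolated = [i for i in ids if i not in present]
    if isolated:
        raise ChainingError(
            f"molecules {isolated} have no feasible restraint pair with any "
            "other molecule; cannot build a chain"
        )
    edges = sorted(((w, p) for p, w in weights.items()), key=lambda e: (-e[0], e[1]))
    accepted = _greedy_chain(ids, edges)
    if accepted is None:
        logger.warning(
            "greedy chaining dead-ended; falling back to exhaustive "
            "Hamiltonian-path search"
        )
        if len(ids) > 8:
            raise ChainingError(
                "greedy chaining dead-ended and the exhaustive fallback is "
                f"limited to 8 molecules (got {len(ids)})"
            )
        accepted = _exhaustive_chain(ids, weights)
        if accepted is None:
            raise ChainingError(
                "no branch-free spanning chain exists over the available pairs"
            )
    return _path_from_edges(ids, accepted)


def close_ring(
    path: list[str], matrix: PairMatrix, params: SelectionParams | None = None
) -> MultiStateRing:
    """Close the open chain into a ring by joining its two endpoints.

    The endpoint pair reuses its precomputed restraint set when present;
    otherwise it is computed afresh, retrying once with a doubled
    ``d_res`` before giving up — the closure pair is allowed to be the
    weakest link.
    """
    params = params or SelectionParams()
    ids = {m.molecule_id for m in matrix.molecules}
    if set(path) != ids or len(path) != len(ids):
        raise InputError("path must visit every molecule exactly once")
    closure = _pair(path[0], path[-1])
    edge_sets: dict[Pair, RestraintSet] = {}
    for i in range(len(path) - 1):
        pair = _pair(path[i], path[i + 1])
        edge_sets[pair] = matrix.pair_sets[pair]
    if closure in matrix.pair_sets:
        edge_sets[closure] = matrix.pair_sets[closure]
    else:
        mol_a = matrix.molecule_by_id(closure[0])
        mol_b = matrix.molecule_by_id(closure[1])
        rset = None
        for factor in (1.0, 2.0):
            relaxed = replace(params, d_res=params.d_res * factor)
            try:
                cands = generate_candidates(mol_a, mol_b, relaxed)
                if cands:
                    rset = greedy_select(cands, relaxed)
                    if factor > 1.0:
                        logger.warning(
                            "ring closure %s used a relaxed cutoff "
                            "d_res=%g nm",
                            closure,
                            relaxed.d_res,
                        )
                    break
            except NoCandidatesError:
                continue
        if rset is None:
            raise RingClosureError(
                f"chain endpoints {closure} share no candidates even at "
                f"d_res={params.d_res * 2} nm; the open chain may be used "
                "instead"
            )
        edge_sets[closure] = rset
    return MultiStateRing(order=tuple(path), edge_sets=edge_sets, closure_pair=closure)


def make_ring(
    molecules: list[Molecule], params: SelectionParams | None = None
) -> MultiStateRing:
    """Full pipeline: pair matrix, chain, ring closure."""
    matrix = build_pair_matrix(molecules, params)
    path = build_chain(matrix)
    return close_ring(path, matrix, params)
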