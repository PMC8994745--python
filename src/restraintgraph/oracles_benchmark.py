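"""Brute-force reference selectors, random baseline, and toy benchmark.

The greedy selector is validated on toy systems: two overlapping point
clouds of 12-30 particles, no bonds, from which four restraints are
selected.  Two exhaustive oracles bound it from above — BF-maxD
maximises the sum of midpoint distances, BF-maxCHV the convex-hull
volume of the midpoints — and a uniform random selection (averaged over
100 trials) bounds it from below.  The oracles enumerate every
n_res-subset of the candidates, so they scale as O(N^4) for four
restraints and carry a subset-count guard.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_model import Atom, Molecule, convex_hull_volume
from .errors import ComplexityGuardError, InfeasibleError, InputError
from .pair_restraints import (
    RestraintCandidate,
    RestraintSet,
    SelectionParams,
    generate_candidates,
    greedy_select,
)

__all__ = [
    "ToySystem",
    "brute_force_max_chv",
    "brute_force_max_distance",
    "generate_toy_system",
    "random_select",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

#: Default cap on the number of enumerated subsets for the brute-force
#: oracles; C(m, n_res) above this raises :class:`ComplexityGuardError`.
DEFAULT_SUBSET_CAP = 2_000_000

#: Toy-cloud cube edge (nm).  With the default d_res = 0.1 nm this makes
#: the two clouds overlap strongly: a 12-particle system typically has
#: around ten candidate pairs, so selecting four restraints is feasible.
DEFAULT_BOX_EDGE = 0.2

_CHUNK = 500_000  # subsets per vectorised block (memory bound)


@dataclass(frozen=True)
class ToySystem:
    """Two bond-free point clouds standing in for a molecule pair."""

    molecules: tuple[Molecule, Molecule]
    n_particles: int
    seed: int


def generate_toy_system(
    n_particles: int, seed: int, box_edge: float = DEFAULT_BOX_EDGE
) -> ToySystem:
    """Particles i.i.d. uniform in a cube, split randomly into two entities.

    The split is balanced (entity sizes differ by at most one; for odd
    counts the seed decides which entity gets the extra particle).
    Fully reproducible from ``seed``.
    """
    if box_edge <= 0:
        raise InputError(f"box_edge must be positive, got {box_edge}")
    if n_particles < 2:
        raise InputError(f"need at least 2 particles, got {n_particles}")
    if n_particles < 8:
        logger.warning(
            "%d particles cannot support 4 atom-disjoint restraints", n_particles
        )
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_edge, size=(n_particles, 3))
    perm = rng.permutation(n_particles)
    n_a = n_particles // 2
    if n_particles % 2 and rng.integers(2):
        n_a += 1
    groups = {"toyA": perm[:n_a], "toyB": perm[n_a:]}
    mols = []
    for mol_id, indices in groups.items():
        atoms = [
            Atom(
                atom_id=i + 1,
                element="X",
                name=f"X{i + 1}",
                position=coords[p],
                molecule_id=mol_id,
            )
            for i, p in enumerate(indices)
        ]
        mols.append(Molecule(mol_id, atoms))
    return ToySystem((mols[0], mols[1]), n_particles, seed)


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------


def _subset_arrays(m: int, r: int) -> np.ndarray:
    """(C(m,r), r) int32 array of all r-subsets of range(m), lexicographic."""
    total = comb(m, r)
    flat = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(m), r)),
        dtype=np.int32,
        count=total * r,
    )
    return flat.reshape(total, r)


def _feasible_mask(subsets: np.ndarray, a_ids: np.ndarray, b_ids: np.ndarray) -> np.ndarray:
    """Atom-disjoint subsets: all A-side and all B-side atoms distinct."""
    a = np.sort(a_ids[subsets], axis=1)
    b = np.sort(b_ids[subsets], axis=1)
    return np.all(np.diff(a, axis=1) != 0, axis=1) & np.all(
        np.diff(b, axis=1) != 0, axis=1
    )


def _tet_volume(points: np.ndarray) -> np.ndarray:
    """Tetrahedron volumes for a (K, 4, 3) vertex array (= 4-point CHV)."""
    v = points[:, 1:, :] - points[:, :1, :]
    dets = np.einsum("kij,kij->k", v[:, 0:1, :], np.cross(v[:, 1, :], v[:, 2, :])[:, None, :])
    return np.abs(dets) / 6.0


def _brute_force(
    candidates: Sequence[RestraintCandidate],
    n_res: int,
    objective: str,
    subset_cap: int,
) -> tuple[RestraintSet, int]:
    if n_res < 1:
        raise InputError(f"n_res must be >= 1, got {n_res}")
    candidates = sorted(candidates, key=lambda c: c.sort_key)
    m = len(candidates)
    if m < n_res:
        raise InfeasibleError(
            f"brute force needs at least n_res={n_res} candidates, got {m}"
        )
    total = comb(m, n_res)
    if total > subset_cap:
        raise ComplexityGuardError(
            f"C({m}, {n_res}) = {total} subsets exceeds the cap of {subset_cap}; "
            "brute-force enumeration scales as O(N^4) — raise the cap "
            "explicitly or use the greedy selector"
        )
    mids = np.array([c.midpoint for c in candidates])
    key_index = {
        key: idx
        for idx, key in enumerate(
            sorted({k for c in candidates for k in c.atom_keys})
        )
    }
    a_ids = np.array([key_index[c.atom_a.key] for c in candidates], dtype=np.int32)
    b_ids = np.array([key_index[c.atom_b.key] for c in candidates], dtype=np.int32)
    dmat = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=-1)

    subsets = _subset_arrays(m, n_res)
    n_enumerated = len(subsets)
    best_value = -np.inf
    best_subset: tuple[int, ...] | None = None
    for start in range(0, n_enumerated, _CHUNK):
        block = subsets[start : start + _CHUNK]
        mask = _feasible_mask(block, a_ids, b_ids)
        if not mask.any():
            continue
        feas = block[mask]
        if objective == "distance":
            values = np.zeros(len(feas))
            for i, j in itertools.combinations(range(n_res), 2):
                values += dmat[feas[:, i], feas[:, j]]
        elif n_res == 4:
            values = _tet_volume(mids[feas])
        else:  # generic CHV, small instances only
            values = np.array(
                [convex_hull_volume(mids[list(s)]) for s in feas]
            )
        # near-exact ties (symmetric geometries) resolved lexicographically
        vmax = float(values.max())
        tol = max(abs(vmax), 1.0) * 1e-12
        for s in feas[values >= vmax - tol]:
            tup = tuple(int(x) for x in s)
            key = tuple(sorted(candidates[i].sort_key for i in tup))
            if (
                vmax > best_value + tol
                or (
                    vmax >= best_value - tol
                    and (best_subset is None or key < best_key)  # noqa: F821
                )
            ):
                best_value, best_subset, best_key = vmax, tup, key
    if best_subset is None:
        raise InfeasibleError(
            f"no atom-disjoint subset of size {n_res} exists among {m} candidates"
        )
    rset = RestraintSet.from_restraints([candidates[i] for i in best_subset])
    return rset, n_enumerated


def brute_force_max_distance(
    candidates: Sequence[RestraintCandidate],
    n_res: int = 4,
    subset_cap: int = DEFAULT_SUBSET_CAP,
    return_count: bool = False,
):
    """BF-maxD: exact maximiser of the sum of midpoint distances.

    Enumerates every ``n_res``-subset of the candidates (exactly
    ``C(m, n_res)`` of them) and keeps the atom-disjoint subset with the
    largest sum of pairwise midpoint distances; ties broken
    lexicographically on sorted atom-id tuples.  With
    ``return_count=True`` also returns the number of enumerated subsets.
    """
    rset, count = _brute_force(candidates, n_res, "distance", subset_cap)
    return (rset, count) if return_count else rset


def brute_force_max_chv(
    candidates: Sequence[RestraintCandidate],
    n_res: int = 4,
    subset_cap: int = DEFAULT_SUBSET_CAP,
    return_count: bool = False,
):
    """BF-maxCHV: exact maximiser of the midpoint convex-hull volume."""
    rset, count = _brute_force(candidates, n_res, "chv", subset_cap)
    return (rset, count) if return_count else rset


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------


def random_select(
    candidates: Sequence[RestraintCandidate],
    n_res: int,
    trials: int,
    seed: int,
    max_rejections: int = 10_000,
) -> list[RestraintSet]:
    """Uniform random atom-disjoint subsets, one per trial.

    Subsets are drawn by rejection sampling (uniform over candidate
    subsets, rejected unless atom-disjoint), which makes the accepted
    draws uniform over the feasible subsets.
    """
    if trials < 1:
        raise InputError(f"trials must be >= 1, got {trials}")
    if n_res < 1:
        raise InputError(f"n_res must be >= 1, got {n_res}")
    candidates = sorted(candidates, key=lambda c: c.sort_key)
    m = len(candidates)
    if m < n_res:
        raise InfeasibleError(f"cannot draw {n_res} restraints from {m} candidates")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(trials):
        for attempt in range(max_rejections):
            picks = [candidates[i] for i in rng.choice(m, size=n_res, replace=False)]
            keys = [k for c in picks for k in c.atom_keys]
            if len(set(keys)) == len(keys):
                out.append(RestraintSet.from_restraints(picks))
                break
        else:
            raise InfeasibleError(
                f"no atom-disjoint subset of size {n_res} found after "
                f"{max_rejections} rejections"
            )
    return out


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------


def run_benchmark(
    sizes: Sequence[int],
    replicates: int,
    params: SelectionParams | None = None,
    seed: int = 0,
    random_trials: int = 100,
    box_edge: float = DEFAULT_BOX_EDGE,
    subset_cap: int = 10_000_000,
) -> pd.DataFrame:
    """Run greedy, BF-maxD, BF-maxCHV and the random baseline on toy sweeps.

    For each particle count in ``sizes`` and each replicate, a fresh toy
    system is generated (ring filtering is irrelevant: toy particles
    carry no bonds), all four strategies run on the same candidate set,
    and one tidy row per (system, strategy) is emitted with both quality
    metrics.  The ``random`` rows carry metrics averaged over
    ``random_trials`` independent draws.  Failures are recorded in the
    ``status`` column without aborting the sweep.  Reproducible from
    ``seed`` (the ``runtime_s`` column aside).
    """
    params = params or SelectionParams()
    rows = []
    root = np.random.SeedSequence(seed)
    for size in sizes:
        for rep in range(replicates):
            child = np.random.SeedSequence(
                entropy=seed, spawn_key=(int(size), int(rep))
            )
            sys_seed, rand_seed = (
                int(s) for s in child.generate_state(2) % (2**31)
            )
            system = generate_toy_system(size, sys_seed, box_edge)
            cands = generate_candidates(*system.molecules, params)

            # All strategies select the same cardinality k: the number of
            # restraints the greedy actually places (= n_res except on
            # candidate-starved instances).  The greedy selection is then
            # itself a member of the oracle search spaces, so oracle
            # dominance holds instance by instance.
            def _one(rset: RestraintSet) -> tuple[float, float, int]:
                return rset.sum_midpoint_distance, rset.chv, len(rset)

            t_greedy = time.perf_counter()
            try:
                greedy_set = greedy_select(cands, params)
                k = len(greedy_set)
            except Exception:
                greedy_set, k = None, 0
            t_greedy = time.perf_counter() - t_greedy

            def _greedy() -> tuple[float, float, int]:
                if greedy_set is None:
                    greedy_select(cands, params)  # re-raise the failure
                return _one(greedy_set)

            def _random() -> tuple[float, float, int]:
                sets = random_select(cands, k, random_trials, rand_seed)
                return (
                    float(np.mean([s.sum_midpoint_distance for s in sets])),
                    float(np.mean([s.chv for s in sets])),
                    k,
                )

            strategies: dict[str, Callable[[], tuple[float, float, int]]] = {
                "greedy": _greedy,
                "bf_maxd": lambda: _one(
                    brute_force_max_distance(cands, k, subset_cap)
                ),
                "bf_maxchv": lambda: _one(
                    brute_force_max_chv(cands, k, subset_cap)
                ),
                "random": _random,
            }
            for name, run in strategies.items():
                t0 = time.perf_counter()
                try:
                    dist, chv, n_sel = run()
                    status = "ok"
                except Exception as exc:  # flagged, sweep continues
                    dist = chv = float("nan")
                    n_sel = 0
                    status = f"error: {type(exc).__name__}: {exc}"
                    logger.warning(
                        "size=%d rep=%d %s failed: %s", size, rep, name, exc
                    )
                runtime = time.perf_counter() - t0
                if name == "greedy":
                    runtime = t_greedy  # selection ran once, before the loop
                rows.append(
                    {
                        "algorithm": name,
                        "n_particles": size,
                        "replicate": rep,
                        "n_candidates": len(cands),
                        "n_selected": n_sel,
                        "sum_midpoint_distance": dist,
                        "chv": chv,
                        "runtime_s": runtime,
                        "status": status,
                    }
                )
    return pd.DataFrame(rows)
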