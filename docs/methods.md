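# Methods

## Model and assumptions

The package selects inter-molecular distance restraints for linked
dual-topology (and linked multi-topology) alchemical free-energy
setups. The physical model of a restraint is a harmonic potential
`V(r) = 1/2 k (r - r0)²` on the distance between one atom of each
molecule, with `k = 5000 kJ/(mol·nm²)` and `r0 = 0` by default: the
selected atom pairs are within `d_res` of each other in the aligned
pose by construction, so a zero reference distance keeps the restraints
essentially unstrained at the input geometry while suppressing relative
drift and rotation of the two molecules.

Assumptions baked into the selection:

- **Pre-aligned input.** The molecules share one coordinate frame and
  have been superimposed beforehand (maximum-common-substructure or
  volume-overlap alignment, done upstream). The package never moves
  coordinates; if nothing overlaps within `d_res`, selection fails with
  an explicit "no candidates" error rather than guessing.
- **Rigidity proxy.** Restraint anchors should not perturb internal
  conformational sampling, so by default only ring atoms are eligible.
  "Ring atom" is defined as *any atom on at least one simple cycle of
  the bond graph*, computed as the endpoints of non-bridge edges. This
  deliberately covers fused and bridged polycycles in full (every atom
  of both rings of a bicycle is eligible), which a smallest-set-of-
  smallest-rings membership test would also do, but the bridge-edge
  formulation is simpler and order-independent. Molecules without bond
  information (toy point clouds) bypass the filter with a logged
  warning; molecules with bonds but no cycles yield no candidates under
  the default filter, which is reported downstream.
- **Few restraints.** `n_res` (default 4) is assumed small relative to
  the molecule size; four non-collinear links suffice to pin two rigid
  bodies against relative translation and rotation.

## The pairwise selection

Candidates are all cross-molecule pairs of eligible atoms within
`d_res` (default 0.1 nm), each represented by the midpoint of its two
atoms. The complete midpoint-distance graph over the candidates is
kept implicit — weights are computed on demand — which leaves the
memory cost linear in the candidate count without changing any result.

Selection is a max-min dispersion greedy: seed with the atom-disjoint
candidate pair of maximal midpoint separation, then repeatedly discard
candidates sharing an atom with the selection and add the candidate
whose minimum distance to the selected midpoints is largest.
Atom-disjointness is strict: an atom anchors at most one restraint.
If the candidate pool exhausts before `n_res` restraints are placed,
the maximal feasible selection is returned with a warning rather than
an error — a short selection is still usable, and the caller can see
its size.

### Tie handling

Two tie rules operate at different scales, deliberately:

- **Iteration steps** use a window of `tie_tolerance = 0.02 nm` on the
  min-distance weights: candidates within the window count as tied, and
  the tie is resolved in favour of the candidate farthest from the COG
  of the already selected midpoints (pushing the selection outward).
  The window absorbs alignment noise, which is of that order.
- **The seed step** uses a floating-point epsilon (1e-9 nm), not the
  0.02 nm window. The seed pair must realise the *true* maximum
  midpoint separation — that exactness is a stated guarantee of the
  algorithm and is checked against O(m²) enumeration in the tests — so
  only genuinely tied (symmetric-geometry) pairs are disambiguated, by
  the pair whose own COG is closest to the COG of all candidate
  midpoints, then by atom ids.

All residual ties anywhere fall back to ascending
`(atom_a.atom_id, atom_b.atom_id)`, making the full selection a pure
function of the candidate *set* (any input ordering gives the same
result).

## Multi-state rings

For M ≥ 3 end-states the pairwise selector runs on every molecule
pair; each pair's restraint set is scored by the convex-hull volume
(CHV) of its midpoints, a single number that rewards spatial spread in
all three dimensions. A Kruskal-style greedy then assembles a
branch-free maximum spanning chain: edges in descending CHV, an edge
accepted only if neither endpoint already has two neighbours and no
cycle forms before all molecules are included. The chain is closed
into a ring by joining its endpoints, reusing that pair's precomputed
set when it exists and otherwise recomputing it, once with the normal
cutoff and once with `d_res` doubled — the closure pair is allowed to
be the weakest link, and a doubled cutoff is preferable to no ring.
Pairs with no candidates are *absent* edges, not zero-weight edges: a
zero-CHV pair that still has restraints can link two molecules, an
empty pair cannot.

The greedy acceptance can dead-end on adversarial weight patterns even
when a chain exists (e.g. a star-like weight structure saturates one
hub early). On dead-end the package falls back to exhaustive
maximum-weight Hamiltonian-path search for up to 8 molecules and
reports failure beyond that; at the intended scale (rings of order
10 with near-complete pair graphs) the greedy succeeds directly.

## Validation protocol and the toy generator

The selector is validated on toy systems: `n` particles (12–30) drawn
i.i.d. uniform in a cube and split randomly into two balanced
entities, no bonds, no pre-processing. The cube edge defaults to
0.2 nm so the two clouds overlap strongly: at 12 particles the default
`d_res = 0.1 nm` then yields ~10 candidate pairs on average, enough to
place four restraints, while at 30 particles the candidate count
(mean ≈ 64) keeps the exhaustive oracles enumerable. Each
(size, replicate) cell runs four strategies on the identical candidate
set:

- **greedy** — the selector under test;
- **BF-maxD** — exact maximiser of the summed midpoint distances over
  all C(m, k) subsets;
- **BF-maxCHV** — exact maximiser of the midpoint CHV;
- **random** — the mean over 100 uniform atom-disjoint subsets
  (rejection-sampled, hence uniform over feasible subsets).

All strategies use the same cardinality k = the size of the greedy
selection (= `n_res` except on candidate-starved instances); the
greedy selection is then itself a member of both oracle search spaces,
so oracle dominance is a per-instance guarantee, not a statistical
one. The brute-force subset counter is exposed and equals C(m, k)
exactly, which checks the O(N⁴) scaling structurally without wall-clock
assertions; runtimes are recorded in the output table but never
asserted. The standalone oracles guard against runaway enumeration
with a 2×10⁶-subset cap; the benchmark harness raises the cap to 10⁷,
which the 12–30-particle sweep never approaches but pathological
candidate counts could.

What the toys do *not* emulate: bonded structure (the ring filter is
bypassed), chemical element identity, alignment error structure
(uniform clouds have no correlated placement), and solvent or dynamics
of any kind. Passing the toy benchmark therefore demonstrates the
*combinatorial* quality of the selection — proximity to the exhaustive
optima and dominance over random choice — not the thermodynamic effect
of the restraints in simulation, which depends on the MD engine and
force field and is out of scope here.

A typical sweep (five sizes × 20 replicates, seed 1) gives: mean
greedy distance metric 0.936 nm versus 0.947 nm for BF-maxD (ratio
0.988) and 0.687 nm for random; greedy never exceeds either oracle on
its own metric, and beats the random mean on every instance. These
numbers are recomputed, not stored, by `scripts/acceptance.py`.

## Numerical choices

- Internal unit is nm throughout; Å→nm conversion (×0.1) happens only
  when reading/writing PDB and SDF.
- Convex-hull volumes use Qhull via scipy; point sets with affine rank
  < 3 (tolerance 1e-9 nm on the singular values) return volume 0.0 by
  convention instead of erroring, as do sets of fewer than four points.
  For exactly four points in the brute-force inner loop the hull
  volume is computed as a vectorised tetrahedron determinant.
- Brute-force near-ties are resolved lexicographically on sorted
  atom-id tuples inside a relative window of 1e-12, so symmetric
  instances (where several subsets score identically up to round-off)
  give one deterministic answer.
- Structure I/O goes through biotite (PDB, CONECT bonds) and RDKit
  (SDF, unsanitised so exotic valences survive); written PDB files use
  residue name `UNL`, whose lack of a chemical-component template
  guarantees that readers take connectivity from the CONECT records
  alone. The whitespace "toy" format (`entity_id atom_id x y z`, nm)
  is the package's own.
- Benchmark seeding derives one child seed per (size, replicate) cell
  from the master seed via `numpy` seed sequences, so sweeps are
  reproducible cell by cell and the four strategies of a cell always
  see the same system.

## Known limitations

- The greedy is locally optimal only; on the toy sweep it reaches ~99%
  of the exhaustive distance metric, but no approximation bound is
  proven.
- Ring perception needs bond information; PDB files without CONECT
  records degrade to the no-bond bypass (all atoms eligible, with a
  warning).
- The GROMOS/GROMACS column conventions implemented here are this
  package's documented dialect of the engines' distance-restraint
  formats; the `fac` column of the GROMACS writer assumes a run-level
  `disre-fc` of 1000 kJ/(mol·nm²).
- Restraint quality in actual simulations (conformational distortion,
  free-energy accuracy) is not assessed by this package.
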