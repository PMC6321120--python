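# Methods

This note records the conventions, parameter choices and limitations behind
each stage of the pipeline, in the order data flows through it.

## Coordinate and symmetry conventions

Fractional coordinates throughout; a symmetry operator acts as
x′ = R·x + t with R an integer matrix and t reduced to [0, 1). The
Cartesian frame is the standard monoclinic-capable orthogonalization:
**a** along x, **b** along y, **c** in the xz plane. Reciprocal basis
vectors carry no 2π factor, so d<sub>hkl</sub> = 1/|h**a**\* + k**b**\* +
l**c**\*| directly.

CIF support covers the minimal core subset: `_cell_length_*`,
`_cell_angle_*`, an operator loop (`_space_group_symop_operation_xyz` or
the older `_symmetry_equiv_pos_as_xyz`) or, failing that, a
Hermann–Mauguin symbol resolved through gemmi's symbol table; and the
fractional `_atom_site_` loop with optional `occupancy` and `charge`
columns. CIF has no standard partial-charge tag, so charges ride in an
extra column (default 0) — energetics must run on charge-free depositions.
Unknown tags are ignored. Symmetry expansion merges images of the same
source atom closer than 0.3 Å (Cartesian) as special-position duplicates,
a conventional crystallographic tolerance.

Molecules are connected components under the bond criterion
d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å with periodic minimum-image distances
(Cordero covalent radii). Components are unwrapped by following the bond
image shifts, so a molecule crossing a cell wall is geometrically
contiguous. If an atom is reachable from itself through two different
lattice offsets the component is an infinite periodic network (a polymer
or framework) and is reported as an error rather than silently cut.

## Lattice geometry

The Laue class is derived from the parsed operators — the rotation parts
closed under inversion — rather than from a symbol lookup, so multiplicity
and orbit calculations work for any operator list a CIF provides. Miller
indices transform covariantly (h′ = h·R). Form representatives are the
lexicographically greatest orbit member, which reproduces the conventional
labels (110), (002), (11-1), (111) for the monoclinic reference cell, and
the compact "11-1" notation is accepted on input.

Form enumeration is complete by construction: since h = g·**a**, any form
with d ≥ d_min satisfies |h| ≤ a/d_min (likewise k, l), an exact bound for
any cell shape. A candidate cap (2×10⁶ index triples) guards against
accidental sub-ångström d_min on large cells.

Systematic absences from translational symmetry (glides, centering) are
not filtered: face forms are Laue orbits. For the reference C2/c cell the
four published forms all satisfy the C-centering condition anyway, so the
distinction does not affect the worked example.

## Energetics

The pair potential is a generic transferable atom–atom model: 12-6
Lennard-Jones with UFF well depths and van der Waals distances (geometric
combining rules, as in UFF), plus optional point-charge Coulomb with a
relative dielectric. Both terms are shifted to vanish exactly at the
real-space cutoff (default 25 Å, minimum 10 Å); electrostatics use direct
summation, not Ewald, which is acceptable for neutral molecular growth
units at these cutoffs and is a documented approximation. The cutoff tail
scales as r_c⁻³, so halving/doubling the cutoff moves lattice sums by a
few tenths of a percent at the defaults.

Cohesive energy per growth unit is half the pair-energy sum between one
reference molecule and every other molecule image within reach, averaged
over the Z′ symmetry-independent molecules. The slice/attachment
partition assigns each *partner molecule as a whole* (by the projection of
its centroid onto the face normal, in units of d<sub>hkl</sub>) to the
reference slab (|Δ| < ½ d) or to the outside; atoms are never split across
slabs, matching the formula-unit picture of growth. The identity
E_slice + E_att = E_cr then holds to rounding error for every form, and is
tested, not assumed.

Because the potential is generic, *absolute* attachment energies are not
comparable with values from proprietary force fields; the decomposition
identity and the relative ordering of faces are the meaningful outputs.
The habit stage therefore accepts externally computed attachment energies
(CSV of hkl, E_att) on equal footing — that is how the shipped worked
example reproduces the published facet-area table.

## Habit construction

Half-space normals are unit reciprocal-lattice vectors (crystal planes,
not direct-lattice directions — the distinction matters in oblique cells);
distances are |E_att|/max|E_att| (the model is scale-free), expanded over
all Laue equivalents of each form. Boundedness is checked before
intersection: the normal set must positively span space (origin strictly
inside the convex hull of the unit normals), otherwise the uncovered
direction is named. The intersection itself uses scipy's
HalfspaceIntersection; facet polygons are recovered by collecting
intersection vertices lying on each generating plane (tolerance 10⁻⁷ on
unit-scale distances), ordering them counterclockwise about the outward
normal, and summing the polygon area. Fully occluded forms stay in the
report with zero area. The BFDH variant substitutes 1/d<sub>hkl</sub> for
|E_att| and needs no energies.

## Contact geometry

Hydrogen bonds: donors are H carriers among {N, O, F, S, C}; acceptors
{N, O, F, S}; geometric windows H···A ≤ 2.7 Å (2.8 Å for the weaker C–H
donors) and D–H···A ≥ 100°, all configurable. These defaults are
conventional report criteria — wide enough to include weak C–H donors at
bent angles. Acceptor images are generated from every space-group operator
combined with lattice translations of up to two cells, and every record
carries its generating symmetry code in the "1-x, 2-y, 1-z" style.

Rings: smallest set of smallest rings (greedy GF(2)-independent selection
from the size-sorted simple cycles, up to 6-membered by default); centroid
is the unweighted atom mean; the plane normal is the least-squares
(SVD) normal. Stacking pairs within Cg–Cg < 6.0 Å are π–π when the plane
dihedral is < 20° — then slippage = √(Cg² − d_⊥²) with d_⊥ the projection
of the centroid–centroid vector on ring i's normal — and T-shaped when the
dihedral ≥ 60° (published T-shaped contacts sit at 70–78°). Intermediate
dihedrals are reported unclassified with no slippage, the angle lying
outside the π–π calculation window. Records are directional: Cg(i)→Cg(j)
uses ring i's normal, so the two directions of a tilted pair differ, as
they do in published tables.

Cremer–Pople puckering uses the original prescription: mean plane through
the centroid with normal along R′×R″, giving Σz = 0 exactly; amplitude
and phase (q_m, φ_m) per the standard sums, plus the alternating q_{N/2}
for even rings. The phase origin is the first atom of the supplied ring
order; cyclic relabelling shifts φ₂ by 144° per step (N = 5), which is
why the canonical atom order of a report ring matters. Envelope phases
lie at multiples of 36°, twists at odd multiples of 18°; labels use the
nearest canonical phase (±9° window) and name the apex atom by largest
|z|. The ring fixture inverts this construction (placing the polygon
clockwise so the analysis normal is +z), so analysis must recover the
requested (q₂, φ₂) exactly — the round trip is tested to 10⁻⁶ Å/degrees.

Kabsch superposition: SVD with the determinant correction so only proper
rotations are returned; degenerate inputs (< 3 points, collinear sets)
are rejected. Atom pairing is an explicit argument since published RMSD
tables rarely state whether hydrogens were included.

## Packing and voids

The packing coefficient is the fraction of a fractional grid (default
0.20 Å spacing) covered by Bondi van der Waals spheres, periodic images
included. The void search inflates each radius by the probe (default
1.20 Å — the conventional solvent probe), takes the uncovered grid points,
and clusters them by 6-connectivity with periodic wrap; each cluster's
volume is its point count times the voxel volume. Both numbers are grid
estimates quoted with their resolution; the sphere-counting error shrinks
roughly quadratically with grid refinement but depends on sphere/grid
alignment, so convergence tests use well-resolved spheres. The
raw-vdW-sphere number is the packing-index analogue; a probe-shrunk
variant would be systematically smaller.

## Synthetic ground truth

Because deposited coordinates are not part of the package, every detector
is validated against structures whose answers are known by construction:

* a simple-cubic Lennard-Jones crystal (P1, one atom) whose lattice sums
  have an explicit double-loop oracle;
* a rigid three-atom molecular crystal in P1, P-1, P2₁/c or C2/c with an
  exact molecule count (operators × Z′); the default placement and
  orientation were chosen once so the default C2/c packing is clash-free
  and dispersion-bound (E_cr < 0, all attachment energies ≤ 0);
* rings built by inverse Cremer–Pople displacement;
* two-molecule boxes realizing exact hydrogen-bond and stacking
  geometries.

All fixtures are exact and seed-free by default; seeds only drive optional
jitter. These fixtures emulate the *geometry* of real molecular crystals,
not their chemistry: three-atom molecules cannot probe ring stacking in a
lattice, and the LJ parametrization is generic, so passing tests establish
the correctness of the geometric and bookkeeping machinery, not the
accuracy of any particular force field against experiment.

## Problem sizes

The default test and acceptance workloads are desk-scale by design: unit
cells of 8–16 small molecules, form enumerations of 50–160 orbits at
d_min = 2.5 Å, grids of ≤ 10⁵ points, and the 14-half-space reference
morphology. These sizes exercise every code path; the algorithms scale to
full structure-report inputs (hundreds of atoms per cell) with the same
settings.

## Known limitations

* No Ewald summation: charged or strongly polar lattices converge slowly
  with the shifted direct sum.
* No surface relaxation and 0 K energetics, inherent to the attachment-
  energy model; no solvent effects on morphology.
* Systematic-absence filtering is not applied to form enumeration.
* Occupancies are read but partial-occupancy disorder is not modelled in
  energetics or packing.
* The packing/void numbers are grid estimates; sub-grid channels can be
  missed at coarse resolution.
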