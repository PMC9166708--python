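# Methods

## Branch-migration model and the 36 immobile junctions

Arms are numbered 1–4 going around the junction; strand *i* runs 5′→3′ from
the distal end of arm *i*, through the branch point, to the distal end of
arm *i*+1. The branch-point pair of arm *j* therefore joins the
junction-proximal base of strand *j* (its 5′ half) with that of strand
*j*−1 (its 3′ half). A branch-point assignment is the quartet of reference
bases (P1…P4), giving 4⁴ = 256 assignments.

One-step migration along an opposing-arm axis is modeled explicitly: the
two branch-point pairs of the shrinking arms are broken and each freed
3′-side base is re-paired with the freed 5′-side base of the strand two
arms away (where the crossover lands after one step); the step is legal iff
both new pairs are Watson–Crick. Under this bookkeeping the oracle reduces
to an identity condition on the two junction-proximal reference bases of
the axis (P1 = P3 for one axis, P2 = P4 for the other); the package always
*runs* the re-pairing oracle, and the reduction is only asserted as a
cross-checked test property over all 512 (assignment, axis) cases. The
counts follow by inclusion–exclusion (256 − 64 − 64 + 16 = 144 immobile)
and Burnside-style orbit collapse under cyclic rotation: no immobile
assignment is fixed by a non-trivial rotation (a fixed point of rotation by
1 or 2 forces P1 = P3 or P2 = P4), so all orbits have size 4 and there are
144/4 = 36 classes. The enumeration verifies, rather than assumes, both
facts. Equivalence uses cyclic rotations only — reflections or strand-sense
reversal would merge distinct classes and change the count. Default class
labels are J1…J36 in canonical (lexicographic-minimum) order;
correspondence with any published numbering is a user-supplied table, since
that numbering is a figure convention, not derivable from the model.

## Signed interhelical angle (J_twist)

Base-pair reference points are the midpoints of the two C1′ atoms of each
pair; an axis is the first principal direction (total least squares) of the
ordered points of one stack, walked distal→branch→distal, oriented from the
stack's first to last pair. This estimator is parameter-free and exact for
straight stacks; its residual reports deviation from linearity. The angle
is arccos of the oriented dot product, in [0°, 180°).

Handedness needs a convention because the two axes alone are mirror-blind.
We use the inter-stack branch vector **w** (centroid of stack 2's
branch-pair C1′ atoms minus stack 1's), orthogonalized against both axes;
the junction is right-handed when the dot angle between **w** and
**d₁**×**d₂** is below 90° (equivalently det[**d₁**,**d₂**,**w**] > 0),
and left-handed angles are multiplied by −1. Tying **w** to stack order
makes the sign invariant under exchanging the two stacks (both **w** and
the cross product flip), while any improper operation flips exactly the
sign — properties the tests assert. The exact 90° tie is classified
right-handed with a warning (measure-zero case needing a deterministic
rule). Because the underlying perpendicular-vector construction is a
convention, only these symmetry properties — not equivalence with any other
software's angle — are claimed for real structures.

Population summaries use the sample standard deviation (n−1): the groups
this statistic is applied to are small samples of junctions or frames.

## Ion bridging and incidence

The two crossover strands (the strands whose halves lie in different
stacks) define the sites. For crossover strand *k*: the anionic oxygens
(OP1/OP2) of the phosphate of residue branch+1 — the phosphate right at the
strand exchange — plus the hydrogen-bond-acceptor base atoms of the two
adjacent branch-point base pairs (purines N7/O6/N3, pyrimidines O2/O4/N3;
table in `hjkit.ions.ACCEPTOR_ATOMS`). The two sites use disjoint atom sets
on opposite sides of the junction and swap labels under the strand
relabeling that exchanges the two crossover strands.

A bridging event requires *simultaneous* contact — at least one phosphate
oxygen and at least one base acceptor of the same site within the cutoff.
The default cutoff of 3.6 Å is a typical first-shell coordination distance
for K⁺/Na⁺ to O/N; no angular term is used, and divalent ions follow the
same rule. An ion bridging both sites in the same frame is counted once, at
the nearer site. Incidence = frames with ≥1 event / total frames, pooling
all frames of a trajectory equally. The minor-groove ion cluster that does
not contact the junction is deliberately not modeled.

## Cavity volumes and cell statistics

Cavity models are ideal solid prisms with no van der Waals subtraction of
the DNA walls: triangular (√3/4)·e²·h and hexagonal (3√3/2)·e²·h, edge and
height in nm, height conventionally the crystal c-axis. With the
characteristic parameters of the two lattice symmetries (3 nm/6.1 nm
triangular vs 6.4 nm/6.0 nm hexagonal) these give 23.8 vs 638.5 nm³, a
26.9-fold difference. Volumes for other lattices are accepted only as
user-supplied specs — no default prism parameters are shipped for them.
Cell-group statistics are per-axis mean, sample σ (absent for n = 1),
min and max, invariant under member permutation.

## Synthetic generator

The generator is a geometric oracle, not a physical model. A junction is
two rigid straight duplex stacks of 2·L base pairs (default L = 8 bp per
arm, the arm length used in solution-state junction simulations; helical
rise 3.38 Å/bp and twist 34.3°/bp, canonical B-DNA), crossing at the
requested angle with stack centers 20 Å apart along the common
perpendicular; the sign pattern of the axes makes det[d₁,d₂,c₂−c₁]
positive for a right-handed build, and mirror fixtures negate one
coordinate. Pseudo-pairs are planar with the two C1′ atoms placed
diametrically, so pair midpoints lie exactly on the construction axis and
the fitted axis reproduces the requested geometry exactly at zero noise.
The per-residue atom set is minimal but sufficient for every analysis
(P, OP1, OP2, C1′, and the identity-dependent acceptors); OP2 is placed on
the major-groove side so each crossover phosphate has an oxygen within
bridging range of the adjacent base acceptors, mimicking the cation-site
geometry. Trajectory frames add seeded isotropic Gaussian noise
(default test condition 0.3 Å); bound ions are placed at the midpoint of
the site's closest phosphate-oxygen/acceptor pair computed from the noisy
frame, which guarantees the bridge contacts by construction; unbound ions
are parked > 10 Å from both sites. Everything is deterministic under the
seed, and a ground-truth sidecar (true angle, handedness, bound frames)
accompanies every bundle.

What the generator does *not* emulate: sequence-dependent helical
structure, junction flexibility and inter-arm correlations, solvent and
counterion atmospheres, or crystal-lattice packing. Passing tests therefore
demonstrate that the estimators recover known geometric and occupancy
ground truth and respect their symmetry invariants — not that they
reproduce any particular experimental angle distribution or per-sequence
incidence, which depend on microsecond-scale sampling of real junctions.
Per-sequence MD incidence values, simulation angle medians, and
crystal-group angle means are in that sense not reproducible at desk scale;
the package instead validates the operations on constructions with exact
ground truth and provides the same operations for user-downloaded
structures and trajectories.

## Numerical and design choices

* Axis fit requires ≥ 4 base pairs per stack and nonzero spatial extent;
  SVD on centered points, residual = RMS perpendicular distance.
* Problem sizes: tests and examples use 8-bp arms (~400 atoms) and
  100-frame trajectories — small enough to run the full suite in seconds
  while exercising every code path at realistic geometry.
* Annotation preserves author (1-based) residue numbering; all APIs address
  residues as (chain, author index), matching deposited-structure
  conventions.
* A stack declaration pairing non-adjacent arms is accepted (the geometry
  is still computable) but warned about: with strand *i* spanning arms
  *i*, *i*+1, coaxial stacks necessarily pair adjacent arms ({1,2},{3,4} or
  {2,3},{4,1}), since the stacked helices are the ones traversed by the two
  continuous strands.
* Ion auto-flagging is a residue-name whitelist with a single-atom element
  fallback; cacodylate is treated as one ion-like site at its arsenic atom.
* The trajectory dialect is multi-model PDB: desk-scale, text-only, and
  readable by every structural-biology toolchain; binary formats are out of
  scope.

## Known limitations

* The stacking isomer (which arm pairs are coaxial) of a real structure
  must be declared by the user; it is not inferred from coordinates.
* The handedness reference vector is a documented convention; signed angles
  are internally consistent (mirror/rotation/stack-exchange properties) but
  not guaranteed to match other tools' sign conventions.
* Bridge detection is purely distance-based; no coordination-geometry or
  occupancy weighting.
* mmCIF support is read-only.
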