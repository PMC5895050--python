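# Methods

## Model and scope

The package evaluates, over torsional degrees of freedom only (bond lengths
and angles fixed), the energy and analytic gradient of:

1. permanent atomic multipole electrostatics through quadrupole–quadrupole
   terms, with per-atom parameters (charge q in e, dipole μ in e·Å, traceless
   symmetric quadrupole Θ in e·Å²) defined in anchor-based local frames;
2. a surface-tension term γ·SASA with the exact (arc-based) solvent-
   accessible surface area;
3. harmonic ring-closure restraints E = k·|r_virtual − r_real|².

Induced polarization, reaction-field solvation, periodic summation and
bond-angle/length degrees of freedom are out of scope.

## Conformation: the kinematic tree

Rigid units are the connected components of the bond graph after removing the
declared rotatable bonds and ring-closure bonds; the units form a tree rooted
at a chosen atom.  Each rotatable bond is a DOF with axis from its upstream
to its downstream bond atom; positive rotation is right-handed about that
direction, angles in degrees externally and radians internally.  Rotating a
DOF rigidly rotates its whole unit subtree; the downstream hinge atom lies on
the axis, so it belongs to the downstream subtree but its position is
invariant — the gradient accumulators therefore use the *moving set* =
subtree minus hinge.  Coordinates update incrementally; a root-to-leaf
rebuild from the stored build conformation is provided and tested equal.

Declared ring closures are cut and replaced by a virtual atom: a duplicate of
the atom on one side of the cut, carried rigidly by the unit on the other
side.  Virtual atoms carry no multipoles and no radius; they enter only the
harmonic restraint (default k = 100 kcal·mol⁻¹·Å⁻², a value stiff enough that
restraint-only minimization closes an opened five-ring to below 10⁻² Å while
remaining well-conditioned for quasi-Newton steps).

## Electrostatics

Energies use the vector-form multipole expansion; in reduced units, with
u = r₂ − r₁, r = |u|:

- q–q: q₁q₂/r
- q–μ: −q₁(μ₂·u)/r³ + q₂(μ₁·u)/r³
- μ–μ: (μ₁·μ₂)/r³ − 3(μ₁·u)(μ₂·u)/r⁵
- q–Θ: q₁(u·Θ₂·u)/r⁵ + q₂(u·Θ₁·u)/r⁵
- μ–Θ: −2(u·Θ₂·μ₁)/r⁵ + 2(u·Θ₁·μ₂)/r⁵ + 5(μ₁·u)(u·Θ₂·u)/r⁷
  − 5(μ₂·u)(u·Θ₁·u)/r⁷
- Θ–Θ: −20(u·Θ₁Θ₂·u)/(3r⁷) + 35(u·Θ₁·u)(u·Θ₂·u)/(3r⁹) + 2(ΣᵢⱼΘ₁ᶦʲΘ₂ᶦʲ)/(3r⁵)

This is exactly E = q₂φ + μ₂·∇φ + (1/3)Θ₂:∇∇φ for the source potential
φ = q₁/r + μ₁·d/r³ + d·Θ₁·d/r⁵; the implementation is verified term-class by
term-class against that expansion evaluated with numerical derivatives.  The
quadrupole enters with no extra normalization factor; parameter files using
other conventions must be converted by their author (the file format
documents the units).  The physical prefactor is 332.063714 kcal·Å·mol⁻¹·e⁻²;
a reduced-units mode (prefactor 1) is used by the worked examples and most
tests.  Bonded-exclusion scale factors keyed by bond separation (1-2, 1-3,
1-4) are configurable and default to full strength; no distance cutoff is
applied by default.

Local frames are `z-then-x` (z toward the z anchor, x the Gram–Schmidt
residual of the x-anchor direction) or `bisector`; anchors are bonded
neighbors.  Global moments are μ_g = Rμ, Θ_g = RΘRᵀ and are refreshed after
every coordinate change.  Collinearity of anchors is rejected at 10⁻⁸ on the
normalized cross product.

## Gradients in Gō form

For an energy term E(u) between atoms i and j, let W = ∂E/∂u and let O_i,
O_j be the orientational parts — the response to a rigid rotation of one
atom's frame, O = μ×(∂E/∂μ) plus, for every quadrupole contraction a·Θ·b,
(Θb)×a + (Θa)×b (the auxiliary-vector rule applied to Θ·u, Θ·μ, Θ₁Θ₂·u and
the basis-vector form of the element-wise Θ₁:Θ₂ term).  Each term becomes an
accumulator entry

    f = ½[(r_i + r_j)×W + O_j − O_i],   g = −W,   c = ½[u×W + O_i + O_j]

contributing s·(f·n + g·(n×r_α)) + m·(c·n) to a DOF, where s = [j moving] −
[i moving] and m = [j moving] + [i moving].  This reproduces the Cartesian
chain rule for every mobility combination, including pairs that co-rotate
rigidly (their relative vector still rotates: W·(n×u) = 2c·n).

For electrostatics the identity u×W + O_i + O_j = 0 holds exactly (rotation
invariance of the pair energy), so c ≡ 0 and one (f, g) pair serves every
separating torsion — the property the whole framework rests on, and a tested
invariant.  For SASA terms c is genuinely nonzero because one atom's area
depends on the directions to several neighbors at once; the c channel is what
keeps per-DOF totals exact there.

**Reference atoms.**  The naive bookkeeping assumes an atom's frame
co-rotates with its position.  That fails exactly at hinge atoms: a torsion
rotates the hinge's substituents (and hence its frame) while the hinge and
its distances to all partners stay fixed.  Every folding-path atom is
assigned a reference atom — first an attached hydrogen, else a bonded heavy
neighbor off the folding path, else the next downstream folding-path atom
(flagged for re-assignment if the fold direction changes; ties break on
lowest atom id).  For each pair and each folding-path member a with partner
b, the orientational vector O_a is subtracted from the pair (b, a) and added
to the pair (b, ref(a)), both as pure antisymmetric f-entries.  When a and
ref(a) move together the two edits cancel; when a is fixed but ref(a) moves,
the frame-rotation gradient is reinstated.  With bonded-neighbor anchors this
treatment is *exact* on tree topologies: the only anchors a torsion can
separate from their owner are across the torsion's own bond, where the owner
sits on the axis and its frame rotation equals the subtree rotation.

**Split frames.**  An anchor that lies across a ring cut breaks that
argument: rotating a ring torsion then changes the frame of an atom on the
same side of other bonds.  No special gradient handling is applied — the
harmonic closure restraint keeps the error bounded, and a diagnostic
(`split_frame_atoms`) flags affected atoms.  On a deliberately split-frame
ring fixture the per-DOF error is ~10⁻³ (reduced units)/deg, versus ~10⁻¹¹
for the clean ring.

**Accumulation.**  The naive accumulator loops entries per DOF (the
correctness oracle).  The recursive accumulator makes one leaf-to-root pass:
each entry adds (f, g) to its j atom and −(f, g) to its i atom and c to both;
per-DOF totals are unit-subtree sums minus the hinge atom's own totals.
Within-subtree pair contributions cancel pairwise (f, g) or sum to the
correct co-rotation term (c).  Storage is linear in system size and the
entry list is traversed once; equality with the naive loop is exact to
roundoff and property-tested.

## Solvent-accessible surface area

Each atom is a sphere of radius r_atom + r_probe (probe default 1.4 Å).
Boundary arcs of the exposed region are computed by direct pairwise circle
clipping: for each neighbor cap, the covered angular intervals from every
other cap are merged and complemented.  Exposed area per atom follows from
Gauss–Bonnet,

    A = ρ²[2πχ + Σ_arcs φ_k cosθ_k − Σ_vertices τ_v],

with arcs traversed exposed-on-left, τ the signed exterior angles at
vertices, χ = 2 − (number of boundary cycles) and the result reduced mod
4πρ² into (0, 4πρ²] (the component count is not tracked; the reduction is
unambiguous whenever any occlusion exists).  Closed forms (isolated sphere,
two-sphere caps), a dot-density oracle and rigid-motion invariance pin the
conventions.

The derivative of atom i's area with respect to a neighbor's relative
position u (d = |u|) has a radial and a sweep part:

    ∂A_i/∂u = Φ∥·u + Φ⊥·V
    Φ∥ = Σ_arcs φ_k ρ_i (1 − (ρ_i² − ρ_j²)/d²)/(2d),   Φ⊥ = ρ_i/d²,
    V  = Σ_arcs (v_end − v_start) × u

— the law-of-cosines cap derivative scaled per arc by φ/2π, and the area
swept at arc endpoints under distance-preserving rotation, which collapses to
the endpoint chords (∫t̂ ds = v_end − v_start).  Both parts were re-derived
from the two-contribution geometry and validated against Cartesian finite
differences of the arc-based area (agreement at FD noise, ~10⁻⁸ Å²/Å).
These directed gradients flow through the same (f, g, c) accumulator; the
SASA pair term is the one place the c channel is nonzero.

Degenerate contacts: exactly coincident centers raise an error; contacts
within 10⁻⁶ Å of tangency emit a warning (arc topology is
perturbation-sensitive there); the fixture generator keeps every contact at
least 10⁻³ Å from tangency at the probe radius it targets.  Buried atoms
contribute zero area and zero gradient.  Gradients are discontinuous when
contacts appear or vanish; the minimizer copes by line-search backtracking
only, with no smoothing.

## Validation protocol

Central differences only: each DOF is rotated ±0.001°, coordinates and global
multipoles fully rebuilt, and the energy difference divided by 0.002°;
reports are per degree.  Granularities: per DOF for any composite potential;
per (pair, DOF) for electrostatics, where the numeric side re-evaluates each
pair's energy independently and the analytic side uses the pair's own entry
plus its reference-correction entries (rows appear for combinations whose
entry set the DOF separates; decompositions sum to the per-DOF totals to
10⁻⁹); per (atom, DOF) for SASA, since areas are not pairwise decomposable.
A step-sensitivity table shows electrostatic agreement essentially unchanged
from 0.001° to 0.002° while SASA agreement degrades at 0.01° — larger
rotations change which atoms overlap.

## Synthetic fixtures

Fixtures are self-avoiding branched polymers: heavy atoms with 1.5 Å bonds
and tetrahedral angles, each carrying one or two hydrogens at 1.1 Å placed in
the angular gaps left by existing bonds — guaranteeing every folding-path
atom a hydrogen reference and giving every atom a frame (z anchor = tree
parent, x anchor = own hydrogen) that co-rotates exactly with the kinematics.
Multipole magnitudes default to q ∈ [−1, 1] e, |μ| ≤ 0.5 e·Å, |Θ| components
≤ 1 e·Å² — protein-scale, so gradient-agreement thresholds are meaningful.
Torsions are randomized and then greedily re-rolled until no nonbonded
contact is closer than 1.2 Å and no extended-sphere contact is within
10⁻³ Å of tangency.  Identical (spec, seed) inputs give bit-identical
fixtures.  A ring variant closes a planar five-ring through a virtual atom,
optionally anchoring the ring nitrogen's x axis across the cut to reproduce
the split-frame pathology; a minimal three-heavy-atom fixture realizes the
frame-rotation-at-constant-distance geometry used to demonstrate that the
reference-atom correction is necessary and sufficient.

What the fixtures do not emulate: real covalent geometry variation, chemical
atom typing, force-field parameter correlations, crystallographic packing.
Passing gradient checks here demonstrates mathematical correctness of the
derivatives and bookkeeping on arbitrary tree topologies and parameter
magnitudes — not force-field accuracy on real proteins.

## Problem sizes and defaults

The shipped validation runs use a 62-unit polymer (61 DOFs, ~160 atoms,
~13 000 interacting pairs, ~130 000 separated pair/DOF combinations), sizes
at which every statistic is stable and a full run takes a few minutes on one
CPU.  Agreement levels achieved there (means): electrostatics ~10⁻⁹
kcal·mol⁻¹·deg⁻¹ per DOF and ~10⁻¹² per pair; SASA ~10⁻⁹ Å²·deg⁻¹ per DOF
and ~10⁻¹⁰ per atom — finite-difference truncation noise, i.e. the analytic
gradients are exact to the resolution of the oracle.

Other defaults: probe 1.4 Å; surface tension γ = 0 unless enabled; L-BFGS-B
with gradient-max-norm tolerance 10⁻⁶ over angles in radians; reduced units
in tests, physical prefactor in the acceptance run.

## Known limitations

- Split coordinate frames (anchors across a ring cut) leave a bounded,
  restraint-controlled gradient error by design; redefining anchors to one
  side of the cut would remove it at the cost of changing the parameters.
- Arc stitching and turn angles assume transversal circle intersections;
  near-tangent triple contacts are not handled robustly (fixtures exclude
  them; runtime warns near tangency).
- The per-pair Gō property is exact for electrostatics but intrinsically
  inexact for SASA (handled by the c channel); per-pair SASA reporting is
  therefore replaced by per-atom reporting.
- Reference-atom re-assignment on fold-direction change is exposed as an
  operation but nothing in the package changes fold direction dynamically.
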