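# torgo

Torsion-space energies and **analytic gradients** for permanent atomic
multipole electrostatics (through quadrupole–quadrupole) and exact
solvent-accessible surface area (SASA), built on a kinematic tree of rigid
units, with a finite-difference validation harness.

Many macromolecular modeling programs parameterize conformation by the
dihedral angles of rotatable bonds rather than by Cartesian coordinates.
Efficient gradient accumulation in that representation writes each atom
pair's contribution to any separating torsion α as

    dE/dα = f·n_α + g·(n_α × r_α)

with the pair vectors **f**, **g** independent of which torsion is queried
(n_α the bond direction, r_α a point on its axis).  The classic recursion
that exploits this assumes isotropic (distance-only) potentials.  This
package implements the two extensions that anisotropic multipole
electrostatics needs, plus the SASA analogue:

- **f/g vectors for all 14 multipole interaction terms** (charge, dipole,
  traceless quadrupole), derived from the vector-form energies with the
  auxiliary-vector technique for rotating tensors (Θ·r₁₂, Θ·μ, Θ₁Θ₂·r₁₂
  contractions), validated against an independent potential-expansion oracle
  and against central finite differences;
- **reference atoms**: a stationary atom's local frame can rotate when a
  torsion moves its substituents; the orientation-only part of each pair
  gradient is subtracted from the pair and re-added on a mobile proxy atom,
  so pure frame rotation is captured by the same distance-based bookkeeping;
- **virtual-atom ring closure**: flexible rings are cut into a tree; a
  duplicate atom rides the far side of the cut under a harmonic restraint
  E = k·d², and the split-coordinate-frame pathology (a frame anchor across
  the cut) is detected and reported;
- **exact SASA and its torsion derivatives** from intersection-arc cycles
  (Gauss–Bonnet area; law-of-cosines radial term scaled per arc by φ/2π, and
  an arc-endpoint sweep term Φ⊥·V for distance-preserving rotations);
- a **single-pass recursive accumulator** over the tree (per-atom totals +
  subtree sums, linear storage) that agrees with the naive per-DOF loop to
  floating-point roundoff, and an L-BFGS torsion minimizer over the
  composite potential.

## Worked example

Everything runs on deterministic synthetic fixtures — branched polymers with
hydrogen satellites, randomized protein-scale multipoles (q ∈ [−1,1] e,
|μ| ≤ 0.5 e·Å, |Θ| ≤ 1 e·Å²) and clash/tangency-free conformations — so no
structure download is ever needed:

```
$ torgo make-fixture --seed 7 --n-units 8
fixture.pdb fixture.topology.yaml fixture.params.yaml (23 atoms, 7 dofs)

$ torgo gradcheck --structure fixture.pdb --topology fixture.topology.yaml \
      --params fixture.params.yaml --reduced-units --out gc.tsv
mean_abs_diff=2.67117e-11 max_abs_diff=8.17149e-11 n=7 (kcal/mol/deg)
```

The report compares the analytic gradient of every rotatable bond against a
±0.001° central finite difference; the mean absolute difference of ~3e−11
energy/deg is finite-difference noise — the analytic and numeric gradients
are identical to the precision of the comparison itself.

```
$ torgo energy --structure fixture.pdb --topology fixture.topology.yaml \
      --params fixture.params.yaml --reduced-units --breakdown | head -5
electrostatics  -0.4140966502
total           -0.4140966502
  q-q           -1.072887908
  q-mu2         0.04414900572
  mu1-q         0.273435704

$ torgo minimize --structure fixture.pdb --topology fixture.topology.yaml \
      --params fixture.params.yaml --reduced-units --max-iter 40
E: -0.41409665 -> -2.3222553 (17 iterations, converged=True)
```

`torgo sasa` prints per-atom exposed areas and the total;
`torgo gradcheck --granularity pair|atom` produces the fine-grained
per-(pair, DOF) and per-(atom, DOF) comparisons.  The library surface mirrors
the CLI: see `torgo.kinematics`, `torgo.electrostatics`, `torgo.sasa`,
`torgo.torsion_gradients`, `torgo.minimizer`, `torgo.validation`,
`torgo.fixtures`.

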