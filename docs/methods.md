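# Methods

This note records the models, conventions and design choices behind
`mdmech`, in the order the pipeline applies them.

## Units and conventions

All internal arithmetic uses the LAMMPS "real" convention: Å, fs, amu,
kcal/mol, charges in e.  Conversions applied at the reporting boundary:
1 kcal·mol⁻¹·Å⁻³ = 6947.7 MPa, 1 kcal·mol⁻¹·Å⁻¹ = 69.48 pN,
1 MPa·nm = 1 mN/m, k_B = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, Coulomb constant
332.0636 kcal·Å·mol⁻¹·e⁻².  Stress is tension-positive throughout: a
stretched bond contributes positive axial stress.  Symmetric tensors are
flattened in the order xx, yy, zz, xy, xz, yz.

Positions are taken as unwrapped when `xu yu zu` columns exist, otherwise
unwrapped from `x y z` plus image flags via the (possibly triclinic) cell
matrix; wrapped-only frames are accepted but flagged, and deformation
fitting refuses them, since an affine fit across a periodic wrap is
meaningless.

## Atom groups

Groups are Lagrangian: membership is decided once, on a designated
reference frame (by default the first frame of the run, configurable), and
frozen for all frames, so the analysis follows the same material particles
through rupture.  Geometric rules (cylinder, shell) measure in-plane radial
distance from an axis along the membrane normal; proximity rules use the
any-atom minimum distance to the target group (optionally heavy atoms
only).  The `by_molecule` flag promotes partially selected residues to full
membership so no lipid is cut in half.  Which reference atoms a radial
selection should use (head-group atom, center of mass, any atom) is not a
settled convention; the rules here operate on all atoms, with the
heavy-atom option exposed where it matters (proximity).

## Force-field evaluation

The CHARMM additive functional forms are implemented directly:
`E = k(b−b₀)²` bonds (so the bond tension is `2k(b−b₀)`), harmonic angles
with Urey–Bradley 1-3 springs, `k(1+cos(nφ−δ))` dihedrals with multi-term
and wildcard (`X-B-C-X`) resolution, harmonic impropers on the torsion
angle, and 12-6 LJ in `(ε, R_min)` form with Lorentz–Berthelot-style CHARMM
combining.  Exclusions are 1-2 and 1-3 by shortest bond path; 1-4 pairs use
dedicated 1-4 LJ parameters when the parameter file provides them and an
electrostatic scale factor of 1.0 by default (the additive-CHARMM
convention; configurable).

Electrostatics is switched cutoff Coulomb, sharing the CHARMM energy
switching function with LJ between `ctonnb` and `ctofnb`.  This deviates
deliberately from production PME settings: the stress machinery requires a
well-defined pairwise force decomposition, which a mesh method does not
possess.  Stress extracted with cutoff electrostatics from a
PME-equilibrated trajectory therefore carries a systematic electrostatic
truncation difference; for the bead-scale validation systems in this
package the effect is absent by construction (zero charges).

At geometric singularities (collinear angles, planar-degenerate torsion
frames) the angular gradient is undefined; the force of the affected term
is zeroed there (minimum-norm convention) rather than regularized with a
large finite value.

## Central-force decomposition

Every multibody term's per-atom forces are re-expressed as central pair
forces along the interatomic axes of the term's atoms: for an m-body term
the 3m force components are solved against the m(m−1)/2 pair directions by
least squares.  Because each isolated term exerts zero net force and zero
net torque, the system is generically exactly solvable (3 unknowns for 3
atoms, 6 for 4 atoms); degenerate geometries fall back to the minimum-norm
solution.  Reconstruction is enforced to 10⁻⁸ kcal·mol⁻¹·Å⁻¹ (relative).
Central decomposition is chosen over half-half partitioning because it
yields antisymmetric, torque-free pair forces — exactly what the moment
part of the stress-equivalence contract needs — and it makes the group
virial symmetric by construction.

## Internal stress

For a group of volume V the Cauchy stress is

σ = −(1/V) [ Σ_pairs w · r_ij ⊗ f_ij + Σ_{i∈g} m_i c_i ⊗ c_i ],

with `r_ij = x_i − x_j`, `f_ij` the force on i from j, `w = 1` when both
pair ends are in the group and `w = ½` when one is, and `c_i` the velocity
relative to the group's mass-weighted mean.  Half-weighting makes the
virials of disjoint groups tile the total system virial (conservation over
full attribution); peculiar velocities keep piston-induced bulk drift out
of the thermal stress; mass weighting of the mean is the momentum-carrying
choice.  Group volume is the 3-D convex hull by default, or projected hull
area × configured thickness ("slab") for thin membrane groups whose hull
would under-represent the solvated slab.

The construction is verified, not assumed: `equivalence_check` integrates
the traction `σ·n` of a constant or position-dependent stress field over
the group's triangulated hull with the three-point edge-midpoint rule
(exact for integrands quadratic in position, hence exact force and moment
for linear fields) and compares resultant force, moment about the centroid,
and — under an affine velocity model — power against their discrete
counterparts.

"Surface-averaged" axial stress is reported as the quadratic form `n·σ·n`
along the loading axis of the volume-averaged tensor; the full traction
vector `σ·n` is emitted alongside.

## Interaction stress

The mechanical interplay of two disjoint groups is the resultant of the
decomposed pair forces crossing between them (antisymmetric under group
swap to the last bit), normalized by their interface area.  The interface
is the *lateral* surface of the inner group — the rupture mode of interest
is in-plane separation of lipids from the inclusion — computed either as
projected-hull perimeter × normal extent ("cylinder") or as the in-plane
facing facets of the 3-D hull ("hull_band"); the two agree within a few
percent on dense clouds.  The area is re-evaluated per frame by default
(the footprint evolves under stretch); a frozen reference area is available
for sensitivity analysis.

One subtlety: for a *closed* interface under symmetric uniaxial tension the
resultant cross-group force cancels between the two axial poles even though
each half-interface carries real tensile traction.  The headline axial
interaction stress is therefore tension-resolved: cross-pair forces are
signed by which axial half-interface (relative to the inner group's
centroid) their inclusion-side atom lies on before summing and dividing by
the interface area.  For a one-sided interface this reduces exactly to the
axial component of resultant/area; for the symmetric case it equals the
mean axial traction magnitude, positive when the surroundings pull the
inclusion apart.

## Rupture detection

The rupture curve pairs the surrounding-lipid group's axial engineering
strain (from the fitted Green–Lagrange component, `λ = √(1+2E_aa)`,
`ε = λ−1`; the piston/box strain is recorded alongside) with the axial
interaction stress.  The stress series is smoothed by a centered moving
average (default 11 frames, odd for phase neutrality); the first local
maximum of the smoothed series whose prominence exceeds 10% of its range
(configurable) marks rupture; the rupture index is then localized as the
argmax of the *unsmoothed* series within one window of the smoothed peak
(smoothing both shifts and flattens sharp peaks), and all reported values —
rupture strain, rupture stress, areal strain at rupture — are read from
the unsmoothed series there.  A monotonically rising curve reports "no
rupture within the run" rather than an error.  First-prominent-maximum is
used instead of the global maximum because post-rupture fluctuations in
fragmented regimes can exceed the rupture peak.  Membrane tension is the
axial interaction stress × bilayer thickness (default 5 nm).  Across
loading rates, the coefficient of variation of rupture strain summarizes
rate (in)sensitivity; no further inferential statistics are attached.

## Synthetic data

The generators provide every input the analysis consumes, with exact
ground truth, and write genuine dump/PSF/PRM files so tests exercise the
real I/O path.

**Affine trajectories** move a random point cloud through a prescribed
F(t) schedule plus optional Gaussian displacement noise — ground truth for
the deformation fit.  **Toy systems** carry closed-form oracles: a
stretched spring dimer (axial virial `r·2k(r−r₀)/V`), a simple-cubic LJ
lattice at spacing R_min with the cutoff inside the second neighbour shell
(exactly force-free, zero virial), and an ideal gas with Maxwell velocities
at 310 K (kinetic pressure NkT/V; note a single N=512 draw has ~3.6%
Monte-Carlo spread).

**The mock membrane** is a quasi-static construction, not integrated
dynamics: two 15×15 bead leaflets at 8 Å spacing (z = ±10 Å), a central
inclusion of radius 20 Å, harmonic bonds along the lattice (lipid–lipid
k = 5, inclusion k = 50, cohesive inclusion–lipid k = 20 kcal·mol⁻¹·Å⁻²),
and a linear piston ramp to 30% axial strain over 150 frames with Poisson
contraction ν = 0.4.  Cohesive bonds exist only at the loading-axis
crossings of the inclusion boundary (the pole cohesive zone where uniaxial
load concentrates), so failure is a collective event.  Surrounding lipids
follow the affine stretch plus small thermal jitter (σ = 0.05 Å,
measurement noise); the inclusion follows a fraction α of it — α = 0 for
the rigid variant, which by definition also has zero conformational
fluctuation, and α = 0.65 plus conformational jitter (σ = 0.15 Å) for the
flexible one.  A cohesive bond detaches irreversibly the first frame its
instantaneous elongation exceeds its limit; the detached lipid bead then
rides at the rest length so the static PSF remains valid while the bond
carries zero force.  Two failure modes: *strain* (each tensile bond's limit
is its scheduled elongation at a programmed membrane strain ε★ — exact,
lever-independent ground truth for detection tests) and *length* (one
shared detach elongation, the physical mode for rigid/flexible
comparisons).  In length mode both orderings of the central comparison
emerge from the mechanism rather than from per-variant settings: the
compliance factor (1−α) divides the interface loading rate, so the rigid
variant reaches the detach length at a strictly smaller applied strain,
while the flexible inclusion's conformational fluctuations break bonds by
first passage slightly below the deterministic detach elongation, capping
its peak stress below the rigid one — the fluctuation-assisted bond
rupture familiar from single-molecule force spectroscopy.

What the mock membrane does *not* emulate: thermostatted dynamics, real
lipid force fields and charges, solvent, membrane undulations, or pore
nucleation.  Passing tests therefore demonstrate that the extraction
machinery recovers programmed continuum-level signatures exactly and
robustly — not that any particular biological membrane ruptures at a given
strain.  Desk-scale runs of this package make no claim of reproducing
absolute rupture values from production-scale MD, which require
hundreds of thousands of atoms per system.

## Numerical choices

* Deformation fit: closed-form normal equations on weighted
  centroid-removed coordinates; reference covariance with a relative
  eigenvalue below 10⁻¹² raises a rank-deficiency error naming the flat
  direction.  Per-frame fits are total-Lagrangian (always against the
  reference frame), avoiding incremental drift.
* Convex hulls via Qhull; degenerate geometries raise errors rather than
  returning zero areas/volumes.
* Switching function: CHARMM energy switch
  `S = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³`, applied to LJ and
  Coulomb alike; forces are continuous at both boundaries.
* Duplicate parameter lines: last occurrence wins, with a logged warning;
  multi-term dihedrals accumulate by multiplicity.
* Neighbour search: brute force under 400 atoms, k-d tree above; fixtures
  with all-zero ε and charges skip the nonbonded pass entirely.
* Determinism: all stochastic generators take explicit seeds;
  re-running the CLI with an identical configuration yields byte-identical
  outputs.

## Problem sizes

The shipped validation surface uses sizes chosen for exactness and speed:
100 random affine fits, a 12-atom all-term force-field system, 50-atom
bipartition sweeps, N = 512 ideal gas, 450-bead membranes over 150 frames
(20 detection runs plus 5 matched rigid/flexible pairs).  The full test
suite runs in well under a minute of compute plus ~20 s of membrane
synthesis; `scripts/acceptance.py` completes in ~20 s.

## Known limitations

* No CMAP cross-terms, Drude polarizability, or PME; stress from charged
  production systems inherits the cutoff-electrostatics caveat above.
* Only orthogonal and LAMMPS-triclinic cells; no DCD/XTC binary
  trajectories (text dumps only).
* Per-group tensors only — no spatially resolved (Hardy-kernel) stress
  fields or lateral pressure profiles.
* The interaction-stress surface definition (lateral hull) and the
  tension-resolved axial average are reconstructions of a quantity whose
  published operational definition is not available in detail; both the
  resultant-based and tension-resolved forms are emitted so either
  convention can be compared.
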