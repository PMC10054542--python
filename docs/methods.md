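# Methods

## The implicit membrane

The bilayer is represented by a one-dimensional environmental field rather
than explicit lipids.  The profile C(z) = 0.5 − (1 + exp(α(|z| − z₀)))⁻¹ is
even in z, bounded in (−0.5, 0.5), and crosses zero exactly at the headgroup
center z₀; the headgroup region has width β, and α is tied to β through
α = 2 ln(88.0145)/β.  The constant 88.0145 encodes the historical default
pairing (α = 1.99 for β = 4.5 Å): exp(1.99 · 4.5/2) ≈ 88.0145.  Exponentials
are clipped at ±500 so the profile saturates instead of overflowing.

**Frame convention.**  The membrane midplane is z = 0 and a particle's depth
is its signed z in the membrane frame; the protein's insertion depth is the
signed depth of its geometric center (the model carries no masses).  For a
planar membrane the frame is Cartesian; for a mesh membrane the depth is
measured to the nearest mesh vertex along its normal, and the normal side is
positive.

**Energy terms.**  E_int couples exposed area × per-area transfer energy to
the profile; E_lip is a scale-independent perturbation term with coefficient
a_lip = −0.018 kcal mol⁻¹ Å⁻².  Both are linear in their parameters, which
the calibration exploits.  All internal energies are kcal/mol; kJ↔kcal
conversion (factor 4.184) happens only at I/O boundaries.  Electrostatics,
lateral pressure and curvature stress are deliberately outside the model.

**Lipid presets.**  β, z₀, α are derived from measured hydrocarbon (2D_C)
and steric (D_B′) thicknesses.  z₀ and α are always computed from the
*unrounded* β: the printed reference values for the seven stored lipids are
only consistent with that chain (verified for all 21 derived numbers).
Presentation rounding uses decimal half-up (`round_half_up`), because the
derived z₀ values are quarter-sums of one-decimal inputs and frequently end
exactly in ...5, which binary floats would otherwise round down.  The preset
thicknesses only reshape the profile; they do not reparameterize the
energetics (that would need lipid-specific transfer-energy data, which is
not available), and no temperature-dependent or sterol parameter sets are
included.

## Transfer-energy prediction and calibration

The predicted transfer energy of a residue is E_IMP summed over its
side-chain particles with the side-chain centroid placed at z = 0.  This is
the *literal* z = 0 definition; because C spans ±0.5, E_IMP in bulk water is
nonzero, and `water_reference_energy` exposes that second number for anyone
who prefers a water-referenced difference.  Side-chain membership is decided
by atom name (backbone = N, CA, C, O and their hydrogens); glycine's "side
chain" is its two α-hydrogens so that every standard residue exposes
calibratable surface.

Because E_IMP is linear in the per-type energies E_t,

    E_pred = Σ_t A_t E_t + B,
    A_t = mean over conformations of −Σ_{i∈t} S_i C(z_i),
    B   = mean of a_lip Σ_i S_i C(z_i),

any finite target T is reached exactly in closed form.  Four update
strategies differ in which minimal change they make: `least_norm` (minimal
L2 change, E′ = E + A(T − E_pred)/‖A‖²), `proportional` (scales all type
energies, preserving their ratios — the natural choice when initial values
are far from the target's order of magnitude, as with partition-derived
coarse-grained energies), `single_type` (touches only the type with the
largest |A_t|), and `uniform_shift` (equal additive shift on all exposed
types).  `auto` runs all four and keeps the result with the smallest MAAPE,
(1/n) Σ arctan(|(U_i − I_i)/U_i|)·100 with the arctangent in radians — the
"fewest changes" selection.  A damped fixed-point mode is provided for
parity with iterative fitting; it converges to the same solutions, since the
constraint surface is a hyperplane.  No sign constraint is imposed on
adjusted energies.  Calibration is per-residue: the same type label may end
up with different energies in different residues.

The constraint is imposed on the conformation-*mean* prediction (the
database aggregation rule had to be chosen; the mean makes the linear form
exact).  The shipped conformation database holds one extended template per
residue built from ideal internal coordinates with a natural-extension
(NeRF) builder — textbook bond lengths and angles, trans χ angles, exact
planar rings.  These are synthetic idealized geometries: calibration
exactness does not depend on rotamer realism, but users wanting
ensemble-averaged surface areas can point `ConformationDB.from_directory` at
their own PDB conformations.

**One-bead representation.**  With one site per residue the constraint has a
single unknown and the closed form
E_tr = a_lip − T/(S·C(0)) reproduces any scale value exactly — all four
strategies coincide.  Coarse-grained correspondence tables take partition
free energies divided by bead surface areas ("computed" areas use the
isolated bead sphere); bead-class areas (e.g. Martini normal/small/tiny) are
user inputs, not constants.

## SASA and typing

Solvent-accessible surface areas use a Shrake–Rupley scheme with a
*deterministic* golden-spiral point set (default 960 points/atom, probe
1.4 Å) and a k-d-tree neighbor search, so calibrations are bit-reproducible;
an independent implementation agrees within the point-set discretization
(≈1 Å² per atom).  Radii are element-based (C 1.7, N 1.55, O 1.52, S 1.8,
H 1.2 Å); coarse bead radii default to 2.3 Å or come from the table.

Atoms are typed into seven classes — Csp3, Csp2 (double-bonded/aromatic
carbons, including the backbone carbonyl), Hnc (H on C), Hc (H on N/O/S), O,
N, S — via a per-residue name lookup.  Structures without hydrogens are
supported directly: the heavy-atom energies absorb hydrogen contributions
during calibration, which is why the shipped templates are heavy-atom (plus
glycine's Hα).  No protonation protocol is imposed.

## Double membranes

C_double(z) = C_main(z) + C_side(z)·C_side(−z), where C_main widens a single
membrane by the separation m and the C_side product carves the growing
aqueous gap.  At m = 0 the product term is ≤ exp(−α z₀) ≈ 10⁻¹⁴ inside
|z| ≤ 3z₀, so the single membrane is recovered to well below 1e−6.  Regimes
are classified by thresholds generalized to z₀ ∓ β/2 (13.5 and 18 Å for the
default geometry), which makes the classification meaningful for every lipid
preset.  Although each C_side factor individually ranges over (0, 1), the
composed profile stays within ±0.5 (asserted numerically over dense z and m
grids).  The object exposes the same depth/profile contract as the single
membrane, so energies, forces and Monte Carlo work unchanged, and
`set_separation` is stateless to support programmatic sweeps.  Hemifusion
physics (relevant at very small inter-membrane distances) is not modeled.

## Mesh membranes

Generated planar meshes are centered vertex grids at z = 0 with
xSize = floor(size/resolution) intervals per axis, (xSize+1)(ySize+1)
vertices and 2·xSize·ySize triangles wound so all normals share a side.
Spherical curvature sets vertex z to ±√(r² − x² − y²) − r and recomputes
normals; vertex normals are area-weighted incident-triangle normals
(renormalized) — the raw cross-product sum, which carries the area weight
for free.  Loaded OBJ/PLY meshes are cleaned (degenerate triangles dropped
with a logged count, inconsistent winding reoriented with a warning) and
their normals recomputed from the triangle geometry.

Nearest-vertex queries use a uniform spatial hash (cell size 2× the grid
resolution for generated meshes, the mean edge length for loaded ones) with
an expanding Chebyshev ring search that widens by the best distance found
before terminating, guaranteeing the true nearest vertex; ties break to the
lowest index.  Signed depth has two modes: **projection** (offset · normal;
exact on planar meshes at any resolution, the default) and **euclidean**
(full distance with a normal-side sign; overestimates |z| by up to the grid
half-diagonal, reproducing the resolution-dependent error of nearest-point
schemes, and is therefore the mode used by the mesh-resolution benchmark).
Insertion tilt is the angle between the declared insertion vector and the
normal at the center-of-mass's nearest vertex, folded into [0°, 90°].
Multiple membranes are simply multiple meshes; each particle uses the mesh
giving the smallest |z| (no cross-mesh combination rule is defined).  Only
the midplane mesh enters the computation — leaflet and interface surfaces
are visualization constructs.

## Sampling

Monte Carlo moves are uniform per-axis translations within ±1 Å and
rotations about a random axis through the center of geometry by a uniform
angle within ±5°, accepted by Metropolis with k_B = 0.0019872 kcal mol⁻¹ K⁻¹
at T = 300 K by default (these defaults are tunable; the rotation sampling
is axis-uniform rather than SO(3)-uniform, which is irrelevant for the
relative exploration done here).  Trajectories record pose, energy breakdown
and acceptance; identical seeds give bitwise-identical runs.  Minimization
is steepest descent on the rigid translation along the net membrane force
(or per-particle when an elastic network is attached), with step halving on
uphill proposals.  Because C(z) saturates, the core of the membrane is an
energy *plateau*: a lone particle relaxes into the core and reaches the
plateau energy, but no gradient method can pinpoint z = 0 itself — tests
assert plateau energy and core membership, not an exact coordinate.  The
elastic network places one harmonic spring (energy ½k(d − d₀)²) on every
particle pair within a single 9 Å cutoff, rest lengths taken at build time;
no non-bonded terms.

Roll is measured about the insertion vector relative to a declared reference
axis (default: the global +x axis projected perpendicular to the insertion
vector), reported in (−180°, 180°].  Per-residue depth profiles average
signed depths over a trajectory window and can be compared against a
user-supplied reference profile (e.g. depths from reference MD), giving
per-residue deviations.

## What the synthetic fixtures emulate — and what they do not

`toy_residue` gives well-separated spheres with analytically known areas;
`hydrophobic_helix` and `amphipathic_helix` are ideal α-geometries (rise
1.5 Å/residue, 100°/residue, 2.3 Å side-chain radius) of one-bead sites
carrying exact scale energies (Leu throughout, or a Leu face against a Lys
face); `barrel_shell` is a hollow particle cylinder with a hydrophobic belt.
A 1e−3 Å coordinate jitter breaks exact symmetries deterministically.  These
fixtures reproduce the *energetic* signatures of transmembrane and
surface-seeking peptides — the hydrophobic helix buries in the core, the
amphipathic helix binds the interface near z₀ — but they have no backbone
chemistry, no conformational flexibility, and ideal geometry; passing tests
demonstrate the energy model and samplers behave correctly, not that any
particular real peptide would behave identically.

## Problem sizes and numerical choices

Default test and benchmark sizes: 18-residue helices, 50 000 MC steps with
five seeds for equilibration checks, 100 random 20-residue scales for
calibration exactness, 1 Å mesh grids (8 281 vertices) for the fine-mesh
cross-checks.  Calibration tolerance is 1e−6 kcal/mol on the achieved
constraint; gradient checks compare against central differences (h = 10⁻⁴ Å)
relatively where the difference quotient is resolvable and absolutely in the
saturated tails, where finite differences are pure cancellation noise.  The
z = 0 kink of |z| is handled by defining sign(0) = 0 (zero force exactly at
the midplane).

## Known limitations

* No electrostatics, lateral pressure, curvature stress, or specific
  protein–lipid interactions; the model orients and ranks poses, it does not
  replace explicit-lipid free-energy calculations.
* Mixed-lipid membranes (per-particle random lipid assignment) and
  lipid-specific energetic reparameterization are not implemented — the
  required lipid-resolved transfer-energy scales do not exist yet.
* Mesh membranes are static; undulation dynamics and image-derived mesh
  segmentation are out of scope.
* The nearest-*vertex* depth (rather than nearest point on the triangulated
  surface) is the intended discretization; its error is bounded by the grid
  half-diagonal in euclidean mode and vanishes on planes in projection mode.
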