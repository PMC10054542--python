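# implimem

Implicit-membrane insertion energetics for proteins: a calibratable energy
model for positioning peptides and membrane proteins in implicit lipid
bilayers of planar, double, and arbitrary mesh-defined shape, at all-atom,
coarse-grained, and one-bead-per-residue resolution.

## Who this is for

Structural bioinformaticians and molecular modelers who need fast, tunable
predictions of how a protein sits in a membrane — insertion depth, tilt, and
per-residue depth profiles — without running explicit-lipid molecular
dynamics, and who want the model's energetics to reproduce a *chosen*
reference hydrophobicity scale exactly rather than approximately.

## The model

The bilayer is a continuum field.  A particle at signed depth z from the
membrane midplane experiences the sigmoidal profile

    C(z) = 0.5 − (1 + exp(α(|z| − z₀)))⁻¹

which runs from −0.5 in the acyl core (z = 0) to +0.5 in bulk water, crossing
0 at the headgroup center z₀.  For a protein of particles i with solvent-
exposed areas S_i (Å²) and per-area transfer energies E_tr(i)
(kcal mol⁻¹ Å⁻², negative = hydrophobic), the insertion energy is

    E_int = − Σᵢ S_i · E_tr(i) · C(z_i)
    E_lip = a_lip · Σᵢ S_i · C(z_i)
    E_IMP = E_int + E_lip

with a_lip = −0.018 kcal mol⁻¹ Å⁻².  The default geometry (α = 1.99,
z₀ = 15.75 Å, β = 4.5 Å) corresponds to a theoretical 36 Å bilayer; presets
for seven phospholipids (DLPG, DOPC, DMPC, DLPE, DOPG, POPG, DPPC) are
derived from measured hydrocarbon and steric thicknesses through

    β = (D_B′ − 2D_C)/2,   z₀ = (D_B′ − β)/2,   α = 2 ln(88.0145)/β.

Around this core the package provides:

* **Calibration** — E_IMP is linear in the per-type transfer energies, so for
  each residue the constraint "predicted side-chain transfer energy at z = 0
  equals the scale value" has closed-form solutions.  Four strategies
  (minimal-L2, proportional, single-type, uniform-shift) are solved exactly
  and the one with the smallest mean arctangent absolute percent error
  (MAAPE) against the initial parameters wins.  Any scale, any representation.
* **Double membranes** — an analytic two-bilayer profile
  C_double(z) = C_main(z) + C_side(z)·C_side(−z) with a separation parameter
  m sweeping continuously from one fused bilayer (m ≤ 13.5 Å by default)
  through merging interfaces to two separated bilayers (m > 18 Å).
* **Mesh membranes** — the midplane as a triangulated surface (generated
  grids, sphere-curved grids, or user OBJ/PLY); per-particle signed depth via
  a spatial-hash nearest-vertex search along vertex normals, so the same
  energy model works on arbitrarily shaped membranes.
* **Sampling & analytics** — rigid-body Metropolis Monte Carlo, steepest-
  descent relaxation, 9 Å-cutoff elastic networks for flexibility, insertion
  depth/tilt/roll, per-residue depth profiles, and insertion-energy scans.

## Worked example

Calibrate the shipped octanol/water-style reference scale onto the ideal
residue templates, then insert an 18-residue amphipathic helix by Monte
Carlo:

```python
import implimem as im
from implimem.structures import default_atom_params, make_fixture
from implimem.conformations import ConformationDB

params, report = im.calibrate_scale(
    im.builtin_scale(), ConformationDB.ideal(), default_atom_params()
)
print(report.head(4).to_string(index=False))

helix = make_fixture("amphipathic_helix", 18, seed=1)
traj = im.run_monte_carlo(helix, steps=50_000, seed=1, record_every=50)
tail = traj.to_dataframe().iloc[500:]
print(f"mean |depth| (last half): {tail['depth'].abs().mean():.2f} A")
print(f"mean E_IMP   (last half): {tail['e_imp'].mean():.2f} kcal/mol")
```

Output:

```
residue  target  initial_prediction  calibrated_prediction    strategy     maape
    ALA   -0.31            0.180012                  -0.31  least_norm 52.293098
    ARG    1.01            2.172964                   1.01 single_type 43.491688
    ASN    0.60            1.584071                   0.60 single_type 25.711920
    ASP    0.77            1.589163                   0.77 single_type 47.474320
mean |depth| (last half): 15.40 A
mean E_IMP   (last half): -18.63 kcal/mol
```

Every calibrated prediction matches its target to 1e−6 kcal/mol (the generic
starting parameters were off by up to a factor of several; the strategy
column shows which minimal-change update won).  The amphipathic helix settles
at |z| ≈ 15.4 Å — the headgroup interface (z₀ = 15.75 Å), hydrophobic face
toward the core — whereas the all-hydrophobic helix fixture buries itself in
the acyl core (|z| < 13.5 Å).

The same pipelines are available from the shell:

```sh
implimem params --lipid DOPC              # beta, z0, alpha as CSV
implimem calibrate --out calibrated.tsv --report report.csv
implimem insert --fixture amphipathic_helix --seed 1 --out run/
implimem mesh --size 90 90 --res 4 --sphere-radius 120 --out curved.obj
implimem doublemem --m 18 --scan -60:60:0.1
implimem benchmark-mesh --out bench.csv   # mesh-resolution accuracy sweep
```

## Layout

| module | contents |
| --- | --- |
| `membrane_params` | geometry derivation, lipid presets, scales, units |
| `energy_core` | C(z), energy terms, gradients, transfer-energy prediction |
| `multi_membrane` | analytic double membrane, regime classification |
| `mesh_membrane` | mesh generation/IO, spatial hash, signed depth, insertion geometry |
| `structures` | PDB I/O, 7-class atom typing, Shrake–Rupley SASA, coarse-graining, fixtures |
| `conformations` | ideal per-residue templates (NeRF builder), conformation DB |
| `calibration` | linearization, four strategies + auto/MAAPE, scale calibration |
| `sampling` | Monte Carlo, minimization, elastic networks, insertion analytics |
| `cli` | `implimem` command-line pipelines |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
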