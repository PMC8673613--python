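# dbsfield

Field-cable modeling of directional deep brain stimulation (DBS) electrodes:
how much do the engineering choices in a volume-conductor (VC) model — explicit
versus boundary-condition electrode geometry, and the implementation of the
current source — change predicted neural activation?

`dbsfield` builds parametric finite-element models of an 8-contact directional
DBS lead (one tip band, two rows of three 90° segments, one cylindrical ring)
inside a homogeneous brain domain with an encapsulation sheath, solves the
electrostatic potential ∇·(σ∇V_e) = 0 for fifteen admissible combinations of

* **current source**: point current, boundary current, current density,
  two-solve electric potential, floating potential, and
* **geometry representation**: explicit (meshed volumes with platinum/
  insulator conductivities) or boundary (labeled surfaces with boundary
  conditions) for the active contact, the inactive contacts and the shaft,

then drives myelinated axon cable models (nodes of Ranvier with fast/persistent
Na⁺, slow K⁺ and leak channels; passive single-cable internodes) with the
interpolated extracellular potentials scaled by a 60 µs cathodic pulse, and
bisects each axon's activation threshold (propagating action potential at both
fiber ends). Variants are compared against the fully explicit point-source
reference through voltage-difference maps, per-axon threshold errors,
current–distance curves, active-axon counts and activation volumes.

It is aimed at computational neurostimulation researchers who want a
transparent, dependency-light reimplementation of the standard DBS field-cable
pipeline with exactly controlled current sources: contact currents are
integrated with the variationally consistent interface jump, so every source
implementation delivers its commanded current to machine precision, and ideal
floating conductors (equipotential, zero net current) are built by exact node
merging rather than penalties.

Everything is generated in code — meshing is a deterministic structured
cylindrical lattice (no external mesher) whose active-contact surface
discretization is bitwise identical across all fifteen variants.

## Worked example

Solve the all-boundary variant (model 15: floating-potential source, every
lead component represented by boundary conditions) with directional contact
"a" as a 1 mA cathode:

```bash
python -m dbsfield solve --model 15 --contact a --out out/
```

prints the per-contact diagnostics of the solved field:

```
contact_id    current_mA  floating_V
       tip -1.338990e-14   -0.263583
        1a -1.000000e+00   -1.277239
        1b -1.951564e-15   -0.378068
        1c -1.250221e-15   -0.378150
        2a -6.293455e-16   -0.322211
        2b -9.351244e-16   -0.242964
        2c -8.923823e-16   -0.241927
      ring -4.348032e-15   -0.179430
    ground  1.000000e+00         NaN
```

The active contact (`1a`) delivers exactly the commanded −1 mA (surface
integral of the normal current density, jump convention); the seven inactive
contacts float at the local tissue potential (e.g. the adjacent segments `1b`,
`1c` at −0.378 V) while carrying zero net current (≤ 10⁻¹⁴ mA); the return
current leaves through the grounded patch. The solved field is written as
`out/field_model15.vtu` for ParaView.

The same pipeline from Python:

```python
from dbsfield import RunConfig, VariantSpec
from dbsfield.geometry import build_geometry, mesh_geometry
from dbsfield.solver import solve_variant
from dbsfield.population import build_grid, attach_grid_field, find_thresholds

cfg = RunConfig()                          # model #1, -1 mA, 60 us defaults
mesh = mesh_geometry(build_geometry(cfg.lead, cfg.domain, cfg.variant), cfg.mesh)
sol = solve_variant(mesh, cfg.conductivity, current_mA=-1.0)
grid = build_grid(cfg.grid, cfg.lead, cfg.domain, "1a", cfg.fiber)
attach_grid_field(grid, sol, i_ref_mA=-1.0)
thresholds = find_thresholds(grid, cfg.waveform)
```

Other CLI subcommands: `mesh` (VTU/MSH export), `thresholds` (per-axon CSV),
`matrix` (the full 15-variant comparison report), `report` (summarize). A YAML
config selects lead dimensions, conductivities, variant, mesh sizing, fiber
class, grid and waveform; an empty file means all defaults.

At the package's reduced test scale the 15-variant matrix shows the expected
structure: thresholds rise monotonically with electrode-to-axon distance
(Spearman ρ = 1.0 on the facing azimuth); the uniform-flux current-density
variant shifts individual axon thresholds by −18% to +10% against the
reference while the equipotential-contact variants (point, Dirichlet-scaled
and floating sources) agree with it to solver precision; and the
population-level metrics (active-axon count, activation volume) vary far less
across variants than individual thresholds do.

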