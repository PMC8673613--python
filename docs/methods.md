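# Methods

`dbsfield` couples a finite-element volume-conductor (VC) model of a
directional deep brain stimulation (DBS) lead to myelinated axon cable models,
and compares fifteen ways of representing the electrode contacts and the
current source. This note records the model, its assumptions, the numerical
choices, and what the synthetic study conditions do and do not show.

## Volume-conductor model

The extracellular potential obeys the electrostatic Laplace equation
∇·(σ∇V) = 0 on a bounded tissue domain with piecewise-constant isotropic
conductivity: brain 0.2 S/m, encapsulation sheath 0.13 S/m (0.5 mm thick),
platinum/iridium contacts 5.3·10⁶ S/m, insulating shaft 10⁻¹⁶ S/m. The lead
is an 8-contact directional design — one tip band, two rows of three 90°
segments separated by 30° gaps, one cylindrical ring — with 0.65 mm radius,
1.5 mm contact lengths and 0.5 mm inter-contact gaps (all configurable; these
are published dimensions of the directional-lead class, not vendor drawings).
The tip contact is modeled as a cylindrical band plus its exposed lower rim
annulus; the rounded tip cap itself is not modeled, which only perturbs the
field below the tip, away from the comparison region.

The surrounding anatomy is deliberately simple: a homogeneous brain cylinder
of radius and half-height 50 mm (≥ 75 lead radii), insulated except for either
(a) a 10 mm grounded patch on the face opposite the lead tip (the default
return electrode), or (b) an "absorbing" Robin condition
σ(∂V/∂n + (n̂·r̂)/|x−x₀| V) = 0 that is satisfied exactly by a free-space
monopole centered at x₀ — used for the lead-free analytic control, where the
solution must match I/(4πσr) rather than any bounded-domain solution. The
near-electrode comparison this package exists for is insensitive to the far
boundary; the domain shape (cylinder rather than a head) is a deliberate
reduction.

### Contact and source representations

Each lead component (active contact, inactive contacts, shaft) is either
**explicit** — meshed as a volume with its material conductivity (contacts as
0.1 mm radial shells) — or a **boundary** — removed from the mesh, with its
surface carrying the boundary condition. Only 15 of the 40 combinations are
admissible: point and boundary current sources need an explicit active
contact, the current-density source needs an exterior (boundary) one, and
inactive contacts are only boundary-represented together with the shaft.

The five current sources for the active contact:

* **point current** — a Dirac load at the mesh vertex nearest the contact
  domain center (the "weld point"); the snap offset is logged. The vertex on
  the inner shell surface is preferred, since a weld sits on the wire side.
* **boundary current** — consistent surface loads imposing a uniform flux
  I/A on the contact/tissue interface of the explicit contact.
* **current density** — the same uniform Neumann flux on the exterior surface
  of a boundary-represented contact.
* **electric potential** — two solves: Dirichlet 1 V on the contact, measure
  the delivered current I₁ by surface integration, re-solve with the Dirichlet
  value scaled by I_target/I₁. By linearity the second solve equals the first
  scaled pointwise; both solves are performed and the identity is tested.
* **floating potential** — a single equipotential unknown on the contact
  surface constrained to pass the commanded total current.

Inactive contacts are ideal floating conductors (equipotential, zero net
current). In boundary representation this is enforced exactly by merging all
surface nodes into one unknown — equipotentiality by construction, zero net
current because no load is applied there. Explicit inactive contacts rely on
the 7-orders-of-magnitude conductivity contrast of platinum, which floats them
physically without an extra constraint. Node merging is also how the floating
source is built (the commanded current is loaded onto the merged unknown);
it is an exact Lagrangian-style reduction, not a penalty.

A consequence worth stating plainly: with an ideal conductor, the point
current, electric potential and floating potential sources all produce an
equipotential contact carrying the same total current, so their exterior
fields coincide to solver precision, as do explicit versus merged-node
inactive contacts. In this implementation the variant matrix therefore splits
into an equipotential family (models 1–6, 8–15) with nearly identical fields
and the uncoupled uniform-flux model 7, which deviates substantially near the
contact. Commercial FEM stacks can show additional spread among the
equipotential family — their point-source, floating and terminal conditions
are discretized differently and surface currents are easily evaluated on the
wrong side of an interface — and quantifying the consequences of such
implementation choices is what a matrix comparison like this one is for; a
clean reimplementation reproduces the shared physics, not another solver's
discretization noise.

### Discretization and solver

Meshing is a deterministic structured lattice in cylindrical coordinates:
radial rings placed exactly on every material interface (shell inner radius,
lead radius, encapsulation boundary, then geometric growth, ratio 1.45, to the
domain wall), 24 azimuthal divisions (15°, resolving the 45°/75°/… segment
edges exactly), and axial planes on every contact band edge with 0.375 mm
near-field spacing, geometrically graded (1.55) beyond. Prisms (wedges at the
axis, split annulus quads elsewhere) are subdivided into tetrahedra with a
global smallest-vertex diagonal rule, which guarantees a conforming mesh
(verified by a face-parity test). The default lattice has ≈ 21 700 nodes and
≈ 124 000 tetrahedra.

Because the lattice depends only on the lead geometry and mesh settings — a
variant only selects which elements are kept and how surfaces are labeled —
the active-contact surface discretization is bitwise identical across all 15
variants (hash-checked), the structured-mesh equivalent of "mesh the active
surface first and reuse it".

Elements are P1 tetrahedra; the assembled system is solved with sparse LU
(SuperLU) by default, or Jacobi-preconditioned CG (relative tolerance 10⁻¹⁰)
for well-conditioned cases (no metal domains); the homogeneous oracle always
uses CG. Potentials are linear in the commanded current to solver precision.

**Contact currents** are computed with the variationally consistent flux: the
tissue-subdomain stiffness applied to the solution, summed over a surface's
nodes, which is the discrete surface integral of σ∂V/∂n evaluated as the
interface jump. It conserves current to machine precision at any resolution.
A raw one-sided facet quadrature and a side-averaged variant are provided as
diagnostics only; at the default mesh the side average mis-states the
point-source contact current by several percent, which is precisely why the
jump convention matters. Current-density maps report the consistent normal
density (exact for imposed Neumann fluxes), the tangential density from the
facet-plane potential gradient, and both one-sided raw densities; the
metal-side map is where a point-source weld vertex shows its characteristic
center peak, while the edge/corner enhancement of distributed sources appears
in the combined magnitude.

**Mesh convergence.** The working criterion is that refining the lattice
changes probed voltages by less than 2% (configurable). At default density a
2× refinement changes near-field probes by ≲ 1.6%; a deliberately coarse
lattice fails the criterion by a factor of four and is flagged. The analytic
monopole control uses a finer lattice (48 azimuthal divisions, 0.25 mm axial)
because the polygonal approximation of the spreading resistance near a point
source dominates its error budget; that mesh agrees with I/(4πσr) to within
1.6% over r ∈ [2, 25] mm.

## Axon model

Fibers are straight, perpendicular to the lead, and follow the standard
myelinated-axon compartmental architecture: nodes of Ranvier with fast Na⁺
(3 S/cm², m³h), persistent Na⁺ (0.01 S/cm², p³), slow K⁺ (0.08 S/cm², s) and
leak (0.007 S/cm²) channels (E_Na = 50 mV, E_K = −90 mV, rest −80 mV, 37 °C
rate constants), separated by passive internodes (MYSA attachment, FLUT
paranode, six STIN segments) whose axolemma and myelin stack (80 lamellae at
5.7 µm) are combined in series into a single-cable RC wall. Morphology
follows the published diameter table (500 µm node spacing at 5.7 µm; 7.3,
8.7 and 10 µm classes are tabulated). The default fiber is the 5.7 µm class
with 21 nodes (15 in the reduced test configurations). The leak reversal is
shifted at build time so the node rests exactly at −80 mV.

The single-cable internode reduction keeps the state compact and the
integrator tridiagonal; it makes fibers somewhat more excitable than the full
double-cable formulation (thresholds of order 0.1–4.5 mA across 1.5–8 mm at
60 µs here). Absolute thresholds are therefore not comparable to
double-cable published values; every metric in the comparison is relative
(between variants, radii, or azimuths), which the reduction preserves.

Extracellular coupling is the standard field-cable form: the VC solution is
interpolated at compartment centers once at the reference current (−1 mA
cathodic), scaled by the 60 µs monophasic rectangular waveform (100 µs onset
delay, 3 ms window), and injected through the axial difference operator —
so a spatially uniform Ve produces no drive and activation follows the second
spatial difference of the potential. Integration is Crank–Nicolson on the
cable with staggered exponential gate updates, dt = 2 µs; halving dt moves
thresholds by < 1%. An axon counts as activated when the membrane crosses
0 mV at both detector nodes (2nd node from each end) after stimulus onset —
a propagating action potential, not a local depolarization. A batched
integrator (vectorized Thomas solver across axons of one fiber class) runs
whole-population threshold searches in lockstep.

Thresholds come from bisection on the cathodic amplitude magnitude over
0.05–10 mA to 1% relative bracket width. Axons activating below the floor or
not activating at the ceiling are reported unconverged with the reason; this
includes fibers immediately adjacent to the lead that activate at the floor
yet block at the ceiling (conduction block at extreme amplitude), whose
threshold lies below the search range.

## Population grids and activation metrics

The axon grid is centered on the active contact: log-spaced radii (default
10 radii, 1.5–8 mm — starting outside the encapsulation) at 5 axial offsets
(±3 mm) in the plane facing the contact, plus a rotated subset (the central-
offset radius ladder at 12 × 30° azimuths; test configurations use 8 radii ×
8 azimuths × 1 offset). Current–distance curves use the Euclidean distance
from the axon center to the active-contact surface center and report a
Spearman monotonicity statistic. The activation count is the number of axons
with threshold ≤ amplitude. The activation volume revolves the per-azimuth
largest activated radius into sectors (½·Δθ·r²·Δz with a 1.5 mm slab per
plane); a convex-hull estimator is available behind a flag but inherits hull
artifacts on sparse grids.

## What the reduced-scale comparison shows

At the default test scale the matrix reproduces the structure of the
findings: current conservation holds for every source to machine precision;
thresholds rise monotonically with distance (Spearman ρ = 1.0 on the facing
azimuth); the uniform-flux variant produces individual threshold errors of
both signs (≈ −18% to +10% against the fully explicit reference) while the
equipotential-family variants agree with the reference to numerical
precision; and population metrics are damped relative to individual
thresholds — at this grid density the log-radius quantization absorbs model
7's threshold shifts entirely, so population errors are zero. The damping
direction is the finding; its exact magnitude depends on grid density, just
as the original error ranges depend on head anatomy and mesh.

What these conditions do **not** emulate: head-anatomy heterogeneity,
anisotropy, electrode–electrolyte interface impedance and capacitive
(time-dependent) effects, curved or branched axon trajectories, and fiber
diameter distributions. Passing tests certify the solver physics and the
pipeline's relative comparisons, not clinical field magnitudes.

## Numerical and design choices (summary)

* Units: mm, mA, V, S/m, µs externally; the solver works in mm/S·mm⁻¹/A/V.
* Direct solver default (metal conductivity contrast 2.6·10⁷ rules out plain
  CG); CG+Jacobi for homogeneous/no-metal systems.
* Floating conductors by node merging (exact), not penalties.
* Point-load singularity: comparisons near a point source exclude probes
  within a configurable radius of the load vertex (the default grids start
  ≳ 1 mm from the contact, far outside the singular neighborhood).
* Tie-breaks: the weld vertex prefers the inner shell ring; facet diagonals
  follow the global smallest-vertex rule; all meshing is deterministic, so
  repeated runs are bitwise reproducible.
* Timing of build/mesh/solve stages is logged for context only; it is
  hardware-dependent and never an acceptance quantity.
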