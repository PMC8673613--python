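"""Programmatic test fixtures: small meshes and analytic-field axon bundles.

These are the controlled inputs used by the test-suite oracles -- a lead-free
homogeneous mesh for comparison against the closed-form monopole potential, a
coarse explicit/boundary mesh pair for contact-surface matching, and a bundle
of axons driven by the analytic field so the cable stage can be exercised
without a finite-element solve.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .config import DomainSpec, FiberSpec, LeadSpec, MeshSettings, VariantSpec
from .geometry import MeshResult, REGION_BRAIN, build_geometry, mesh_geometry

#: Lattice used for the analytic-oracle control: finer than the default because
#: the monopole comparison is sensitive to the azimuthal polygonization of the
#: spreading resistance near the source.
ORACLE_MESH = MeshSettings(theta_divisions=48, axial_size=0.25,
                           radial_growth=1.25, axial_growth=1.45)

#: Coarse settings for quick structural tests (not for field accuracy).
COARSE_MESH = MeshSettings(axial_size=0.75, theta_divisions=24,
                           radial_growth=1.8, axial_growth=2.0)


def lead_free_mesh(domain: Optional[DomainSpec] = None,
                   settings: Optional[MeshSettings] = None) -> MeshResult:
    """Homogeneous lead-free mesh (all brain) with an absorbing outer boundary.

    The standard lattice is kept -- so near-field resolution matches the lead
    models -- but every element is brain tissue and no contact surfaces exist.
    """
    dom = domain or DomainSpec(outer_bc="absorbing")
    m = mesh_geometry(build_geometry(LeadSpec(), dom, VariantSpec.from_model_id(1)),
                      settings or ORACLE_MESH)
    m.region[:] = REGION_BRAIN
    m.contact_facets = {}
    if hasattr(m, "_solver_cache"):
        del m._solver_cache
    return m


def variant_pair(settings: Optional[MeshSettings] = None) -> tuple[MeshResult, MeshResult]:
    """Coarse Model #1 (fully explicit) and Model #15 (fully boundary) meshes of
    the same lead; their active-contact surface signatures must match."""
    lead, dom = LeadSpec(), DomainSpec()
    s = settings or COARSE_MESH
    m1 = mesh_geometry(build_geometry(lead, dom, VariantSpec.from_model_id(1)), s)
    m15 = mesh_geometry(build_geometry(lead, dom, VariantSpec.from_model_id(15)), s)
    return m1, m15


def axon_bundle(seed: int = 0, n_axons: int = 3, fiber: Optional[FiberSpec] = None):
    """Axons at staggered radial distances from an analytic monopole source.

    Returns (list of AxonInstance with Ve_static attached, source point, sigma).
    Deterministic for a fixed seed; drives the cable stage without any FEM.
    """
    from .axon import build_axon, attach_field  # local import: axon depends on config only
    from .solver import point_source_potential

    rng = np.random.default_rng(seed)
    fib = fiber or FiberSpec.mrg(5.7, n_nodes=15)
    source = np.array([0.0, 0.0, 0.0])
    sigma = 0.2
    axons = []
    radii = np.geomspace(1.5, 4.0, n_axons)
    for i, r in enumerate(radii):
        phi = float(rng.uniform(0, 2 * np.pi))
        center = np.array([r * np.cos(phi), r * np.sin(phi), 0.0])
        direction = np.array([-np.sin(phi), np.cos(phi), 0.0])
        length = (fib.n_nodes - 1) * fib.internode_length * 1e-3
        start = center - 0.5 * length * direction
        ax = build_axon(fib, start, direction, length)
        ax = attach_field(
            ax, lambda pts: point_source_potential(pts, source, -1.0, sigma), i_ref_mA=-1.0
        )
        axons.append(ax)
    return axons, source, sigma


def generate_fixtures(kind: str, seed: int = 0, out_dir: str | Path = "fixtures"):
    """Materialize a named fixture; CSV/mesh files are written under out_dir.

    kinds: ``sphere`` (lead-free analytic-oracle mesh), ``variant_pair``
    (coarse explicit/boundary mesh pair), ``axon_bundle`` (3 axons + analytic
    potentials as CSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "sphere":
        m = lead_free_mesh(settings=COARSE_MESH)
        from .io import write_vtu
        write_vtu(out / "lead_free.vtu", m)
        return m
    if kind == "variant_pair":
        m1, m15 = variant_pair()
        from .io import write_vtu
        write_vtu(out / "model01.vtu", m1)
        write_vtu(out / "model15.vtu", m15)
        return m1, m15
    if kind == "axon_bundle":
        from .axon import export_axon_csv
        axons, _, _ = axon_bundle(seed=seed)
        for i, ax in enumerate(axons):
            export_axon_csv(ax, out / f"axon_{i}.csv")
        return axons
    raise ValueError(f"unknown fixture kind {kind!r}")
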