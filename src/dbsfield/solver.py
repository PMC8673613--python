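"""P1 finite-element solver for Laplace's equation on the lead-in-brain mesh.

Solves div(sigma grad V) = 0 with the variant's boundary conditions and one of
the five current-source implementations for the active contact:

* point current source   -- Dirac load at the node nearest the active-contact
                            domain center (explicit contact only)
* boundary current source -- uniform flux I/A on the contact/tissue interface
                            of an explicit contact
* current density        -- uniform Neumann flux I/A on a boundary-represented
                            (exterior) contact surface
* electric potential     -- two solves: unit Dirichlet, measure the delivered
                            current, rescale the Dirichlet value
* floating potential     -- single equipotential unknown on the contact surface
                            constrained to carry the commanded total current

Inactive contacts in boundary representation are ideal floating conductors
(equipotential, zero net current), implemented by merging their surface nodes
into one unknown; explicitly meshed inactive contacts rely on the platinum
conductivity to float.  Contact currents are integrated with the variationally
consistent (flux-jump) boundary integral, not the facet average.

Internal units: mm, S/mm, A, V.  The public API uses mA and S/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import (
    CONTACT_IDS,
    ConductivityMap,
    InvalidVariantError,
    Rep,
    SolverSettings,
    SourceType,
    VariantSpec,
)
from .geometry import (
    MeshResult,
    REGION_BRAIN,
    REGION_CONTACT0,
    REGION_ENCAPSULATION,
    REGION_SHAFT,
)

log = logging.getLogger("dbsfield.solver")

MA_PER_A = 1e3
S_PER_MM = 1e-3  # S/m -> S/mm


class AssemblyError(RuntimeError):
    pass


class SolveError(RuntimeError):
    pass


def element_conductivity(mesh: MeshResult, cond: ConductivityMap) -> np.ndarray:
    """Per-element conductivity in S/mm."""
    sigma = np.empty(len(mesh.tets))
    r = mesh.region
    sigma[r == REGION_BRAIN] = cond.brain
    sigma[r == REGION_ENCAPSULATION] = cond.encapsulation
    sigma[r == REGION_SHAFT] = cond.shaft
    sigma[r >= REGION_CONTACT0] = cond.contact
    return sigma * S_PER_MM


def _stiffness(mesh: MeshResult, sigma_el: np.ndarray, row_map: np.ndarray,
               n_dofs: int, el_mask: Optional[np.ndarray] = None) -> sp.csr_matrix:
    """Assemble sum sigma * grad(Ni).grad(Nj) * vol over (a subset of) elements."""
    grads = mesh.shape_gradients()
    vols = mesh.tet_volumes()
    tets = mesh.tets
    if el_mask is not None:
        grads, vols, tets, sigma_el = grads[el_mask], vols[el_mask], tets[el_mask], sigma_el[el_mask]
    loc = np.einsum("eik,ejk->eij", grads, grads) * (sigma_el * vols)[:, None, None]
    dofs = row_map[tets]                                   # (M, 4)
    rows = np.repeat(dofs, 4, axis=1).ravel()
    cols = np.tile(dofs, (1, 4)).ravel()
    K = sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(n_dofs, n_dofs))
    return K.tocsr()


def tissue_stiffness(mesh: MeshResult, cond: ConductivityMap) -> sp.csr_matrix:
    """Stiffness of the conductive tissue (brain + encapsulation) alone, in node
    numbering -- the basis of the consistent contact-current integral."""
    key = ("tissue_K", cond.brain, cond.encapsulation)
    cache = getattr(mesh, "_solver_cache", None)
    if cache is None:
        cache = {}
        mesh._solver_cache = cache  # type: ignore[attr-defined]
    if key not in cache:
        sigma = element_conductivity(mesh, cond)
        mask = (mesh.region == REGION_BRAIN) | (mesh.region == REGION_ENCAPSULATION)
        ident = np.arange(len(mesh.vertices))
        cache[key] = _stiffness(mesh, sigma, ident, len(mesh.vertices), mask)
    return cache[key]


# ---------------------------------------------------------------------------
# assembled system


@dataclass
class LinearSystem:
    """Laplace system with the variant's constraints applied.

    Floating conductors are realized by merging all of a surface's nodes into a
    single unknown, which enforces the equipotential exactly and makes the
    conductor's net current the (zero) residual at that unknown.
    """

    mesh: MeshResult
    cond: ConductivityMap
    variant: VariantSpec
    sigma_el: np.ndarray
    dof_of_node: np.ndarray
    n_dofs: int
    K: sp.csr_matrix
    f: np.ndarray
    dirichlet: dict                      # dof -> value (V)
    floating_masters: dict               # contact_id -> dof
    source_info: dict = field(default_factory=dict)
    settings: SolverSettings = field(default_factory=SolverSettings)

    def active_facets(self) -> np.ndarray:
        return self.mesh.contact_facets[self.variant.active_contact_id]

    def active_surface_nodes(self) -> np.ndarray:
        return np.unique(self.active_facets())


def assemble(mesh: MeshResult, cond: ConductivityMap, variant: VariantSpec,
             settings: Optional[SolverSettings] = None) -> LinearSystem:
    """Assemble stiffness + boundary conditions for one variant.

    The grounded patch becomes Dirichlet V=0; the rest of the outer boundary is
    naturally insulated (or carries the absorbing Robin condition if the domain
    requests it); boundary-represented shaft surfaces are insulating by the
    natural condition; inactive boundary contacts become floating conductors.
    """
    if mesh.geometry.variant != variant:
        raise AssemblyError("mesh was built for a different variant")
    dom = mesh.geometry.domain
    if dom.outer_bc == "ground_patch" and len(mesh.ground_nodes) == 0:
        raise AssemblyError("mesh has no grounded patch on the outer boundary")

    n_nodes = len(mesh.vertices)
    sigma_el = element_conductivity(mesh, cond)

    # --- floating-conductor groups -> merged dofs
    rep_of = {cid: (variant.active_contact_rep if cid == variant.active_contact_id
                    else variant.inactive_contacts_rep) for cid in CONTACT_IDS}
    groups: dict[str, np.ndarray] = {}
    for cid in CONTACT_IDS:
        is_active = cid == variant.active_contact_id
        if is_active:
            if variant.source_type is SourceType.floating_potential:
                groups[cid] = np.unique(mesh.contact_facets[cid])
        elif rep_of[cid] is Rep.boundary:
            groups[cid] = np.unique(mesh.contact_facets[cid])

    rep = np.arange(n_nodes)
    for nodes in groups.values():
        rep[nodes] = nodes.min()
    # compress to contiguous dofs; nodes of removed (void) elements keep a dof
    # but are isolated -- they are pinned to zero below to keep K nonsingular
    used, dof_of_node = np.unique(rep, return_inverse=True)
    n_dofs = len(used)
    floating_masters = {cid: int(dof_of_node[nodes.min()]) for cid, nodes in groups.items()}

    K = _stiffness(mesh, sigma_el, dof_of_node, n_dofs)

    dirichlet: dict[int, float] = {}
    if dom.outer_bc == "ground_patch":
        for n in mesh.ground_nodes:
            dirichlet[int(dof_of_node[n])] = 0.0
    else:  # absorbing Robin boundary, exact for a monopole at the reference point
        ref = np.asarray(mesh.geometry.lead.contact_center(variant.active_contact_id))
        K = K + _absorbing_matrix(mesh, cond, dof_of_node, n_dofs, ref)

    # pin isolated dofs (nodes only attached to removed void elements)
    attached = np.zeros(n_dofs, dtype=bool)
    attached[dof_of_node[mesh.tets].ravel()] = True
    for d in np.nonzero(~attached)[0]:
        dirichlet[int(d)] = 0.0

    return LinearSystem(
        mesh=mesh, cond=cond, variant=variant, sigma_el=sigma_el,
        dof_of_node=dof_of_node, n_dofs=n_dofs, K=K, f=np.zeros(n_dofs),
        dirichlet=dirichlet, floating_masters=floating_masters,
        settings=settings or SolverSettings(),
    )


def _absorbing_matrix(mesh: MeshResult, cond: ConductivityMap, dof_of_node: np.ndarray,
                      n_dofs: int, ref_point: np.ndarray) -> sp.csr_matrix:
    """Robin matrix for the open-boundary condition dV/dn + (n.rhat/|x-x0|) V = 0,
    which the free-space monopole field centered at x0 satisfies exactly."""
    facets = mesh.outer_facets
    area, normal = mesh.facet_area_normals(facets)
    cent = mesh.vertices[facets].mean(axis=1)
    rvec = cent - ref_point
    dist = np.linalg.norm(rvec, axis=1)
    rhat = rvec / dist[:, None]
    ndotr = np.einsum("ij,ij->i", normal, rhat)
    # orient normals outward (domain is convex around the reference point)
    ndotr = np.abs(ndotr)
    beta = cond.brain * S_PER_MM * ndotr / dist            # S/mm^2
    m_loc = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    loc = beta[:, None, None] * area[:, None, None] * m_loc
    dofs = dof_of_node[facets]
    rows = np.repeat(dofs, 3, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    return sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(n_dofs, n_dofs)).tocsr()


# ---------------------------------------------------------------------------
# current sources


def apply_point_current_source(system: LinearSystem, current_mA: float) -> LinearSystem:
    """Dirac load at the mesh vertex nearest the active-contact domain center."""
    v = system.variant
    if v.active_contact_rep is not Rep.explicit:
        raise InvalidVariantError("a point current source needs an explicit active contact")
    mesh = system.mesh
    k = CONTACT_IDS.index(v.active_contact_id)
    el = np.nonzero(mesh.region == REGION_CONTACT0 + k)[0]
    cand = np.unique(mesh.tets[el])
    lead = mesh.geometry.lead
    z0, z1, arc = mesh.geometry.contact_extents[v.active_contact_id]
    rc = 0.5 * (mesh.geometry.inner_radius + lead.lead_radius)
    if arc is None:
        thc = 0.0
    else:
        th0, th1 = arc
        thc = np.radians(th0 + (np.mod(th1 - th0, 360.0) or 360.0) / 2.0)
    center = np.array([rc * np.cos(thc), rc * np.sin(thc), 0.5 * (z0 + z1)])
    d = np.linalg.norm(mesh.vertices[cand] - center, axis=1)
    # prefer a vertex that is not on the contact/tissue interface
    on_surface = np.isin(cand, system.active_surface_nodes())
    d = d + on_surface * 10.0 * lead.lead_radius
    node = int(cand[np.argmin(d)])
    offset = float(np.linalg.norm(mesh.vertices[node] - center))
    log.info("point source snapped to node %d, %.4f mm from the contact center", node, offset)
    system.f[system.dof_of_node[node]] += current_mA / MA_PER_A
    system.source_info = dict(type="point_current", node=node, snap_offset_mm=offset,
                              target_center=center.tolist(), current_mA=current_mA)
    return system


def _surface_load(system: LinearSystem, current_mA: float) -> tuple[float, np.ndarray]:
    """Consistent nodal loads for a uniform flux I/A over the active surface."""
    facets = system.active_facets()
    area, _ = system.mesh.facet_area_normals(facets)
    A = float(area.sum())
    if A <= 0:
        raise AssemblyError("active contact surface has zero area")
    flux = current_mA / MA_PER_A / A                       # A/mm^2
    loads = np.zeros(system.n_dofs)
    np.add.at(loads, system.dof_of_node[facets].ravel(),
              np.repeat(flux * area / 3.0, 3))
    return A, loads


def apply_boundary_current_source(system: LinearSystem, current_mA: float) -> LinearSystem:
    """Uniform flux-jump source I/A on the interior boundary of an explicit contact."""
    if system.variant.active_contact_rep is not Rep.explicit:
        raise InvalidVariantError("a boundary current source needs an explicit active contact")
    A, loads = _surface_load(system, current_mA)
    system.f += loads
    system.source_info = dict(type="boundary_current", surface_area_mm2=A,
                              flux_mA_per_mm2=current_mA / A, current_mA=current_mA)
    return system


def apply_current_density_source(system: LinearSystem, current_mA: float) -> LinearSystem:
    """Uniform Neumann flux I/A on an exterior (boundary-represented) contact."""
    if system.variant.active_contact_rep is not Rep.boundary:
        raise InvalidVariantError(
            "a current-density source is only applicable to exterior boundaries "
            "(boundary-represented active contact)"
        )
    A, loads = _surface_load(system, current_mA)
    system.f += loads
    system.source_info = dict(type="current_density", surface_area_mm2=A,
                              flux_mA_per_mm2=current_mA / A, current_mA=current_mA)
    return system


def apply_floating_potential_source(system: LinearSystem, current_mA: float) -> LinearSystem:
    """Equipotential active contact carrying the commanded total current."""
    cid = system.variant.active_contact_id
    if cid not in system.floating_masters:
        raise AssemblyError(
            "system was not assembled with a floating active contact; assemble() "
            "merges the active surface only for the floating_potential source"
        )
    master = system.floating_masters[cid]
    deg = system.K[master].getnnz()
    if deg <= 1:
        raise AssemblyError("floating contact is disconnected from the tissue")
    system.f[master] += current_mA / MA_PER_A
    system.source_info = dict(type="floating_potential", master_dof=master,
                              current_mA=current_mA)
    return system


def apply_dirichlet_contact(system: LinearSystem, value_V: float) -> LinearSystem:
    """Fix the active contact surface at a potential (electric-potential source)."""
    for n in system.active_surface_nodes():
        system.dirichlet[int(system.dof_of_node[n])] = value_V
    system.source_info = dict(type="electric_potential", dirichlet_V=value_V)
    return system


# ---------------------------------------------------------------------------
# solve + diagnostics


@dataclass
class ContactCurrent:
    """Signed current through a contact surface; positive leaves the contact
    into the tissue."""

    contact_id: str
    current_mA: float
    method: str
    area_mm2: float


@dataclass
class FieldSolution:
    """Solved extracellular voltage distribution.

    ``node_potentials`` is in volts on mesh vertices; ``interpolate`` evaluates
    V_e at arbitrary tissue points; ``contact_currents_mA`` holds the consistent
    surface-integrated current of all 8 contacts.
    """

    mesh: MeshResult
    cond: ConductivityMap
    variant: VariantSpec
    node_potentials: np.ndarray
    commanded_current_mA: float
    source_info: dict
    floating_values_V: dict
    contact_currents_mA: dict
    ground_current_mA: float

    def interpolate(self, points: np.ndarray, allow_outside: bool = False) -> np.ndarray:
        return self.mesh.interpolate_nodal(self.node_potentials, points, allow_outside)

    @property
    def active_current_mA(self) -> float:
        return self.contact_currents_mA[self.variant.active_contact_id]


def solve(system: LinearSystem) -> FieldSolution:
    """Direct sparse solve of the constrained system, with per-contact current
    diagnostics populated for all 8 contacts."""
    K, f = system.K, system.f
    fixed = np.array(sorted(system.dirichlet), dtype=int)
    vals = np.array([system.dirichlet[int(d)] for d in fixed])
    free = np.setdiff1d(np.arange(system.n_dofs), fixed, assume_unique=False)
    if len(free) == 0:
        raise SolveError("no free unknowns")
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - (K[free][:, fixed] @ vals if len(fixed) else 0.0)
    if system.settings.method == "cg":
        M = sp.diags(1.0 / Kff.diagonal())
        u_free, info = spla.cg(Kff, rhs, rtol=system.settings.rtol, M=M, maxiter=20000)
        if info != 0:
            raise SolveError(f"CG failed to converge (info={info})")
    else:
        try:
            u_free = spla.spsolve(Kff, rhs)
        except Exception as exc:  # pragma: no cover - singularity guard
            raise SolveError(f"direct solve failed: {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise SolveError("solver produced non-finite potentials")
    res = np.linalg.norm(Kff @ u_free - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and res / scale > max(1e-6, system.settings.rtol * 1e3):
        raise SolveError(f"large residual after solve: {res / scale:.2e}")

    u = np.zeros(system.n_dofs)
    u[free] = u_free
    if len(fixed):
        u[fixed] = vals
    u_node = u[system.dof_of_node]

    floating = {cid: float(u[d]) for cid, d in system.floating_masters.items()}
    sol = FieldSolution(
        mesh=system.mesh, cond=system.cond, variant=system.variant,
        node_potentials=u_node,
        commanded_current_mA=system.source_info.get("current_mA", np.nan),
        source_info=dict(system.source_info),
        floating_values_V=floating, contact_currents_mA={}, ground_current_mA=np.nan,
    )
    for cid in CONTACT_IDS:
        sol.contact_currents_mA[cid] = integrate_contact_current(sol, cid).current_mA
    sol.ground_current_mA = _boundary_current(sol)
    return sol


def _consistent_flux(sol: FieldSolution, nodes: np.ndarray) -> float:
    """Current (mA) entering the tissue across the surface spanned by ``nodes``,
    from the tissue-subdomain weak-form residual (flux-jump integral)."""
    Kt = tissue_stiffness(sol.mesh, sol.cond)
    r = Kt[nodes] @ sol.node_potentials
    return float(r.sum()) * MA_PER_A


def _boundary_current(sol: FieldSolution) -> float:
    """Current (mA) entering the tissue through the outer domain boundary
    (same into-tissue sign convention as the contact currents, so the sum over
    all contacts plus the ground flux vanishes)."""
    nodes = np.unique(sol.mesh.outer_facets)
    return _consistent_flux(sol, nodes)


def integrate_contact_current(sol: FieldSolution, contact_id: str,
                              method: str = "consistent") -> ContactCurrent:
    """Surface integral of the normal current density over a contact.

    ``consistent`` (default) evaluates the variationally consistent flux jump
    across the interface -- the discrete form of integrating sigma dV/dn with
    the correct side convention.  ``quadrature`` integrates the raw tissue-side
    element gradients over the facets and carries ordinary discretization error
    (provided as a diagnostic).  For the point source both enclose the contact
    domain, so the load is fully captured.
    """
    facets = sol.mesh.contact_facets[contact_id]
    area, _ = sol.mesh.facet_area_normals(facets)
    A = float(area.sum())
    if method == "consistent":
        current = _consistent_flux(sol, np.unique(facets))
    elif method == "quadrature":
        dens, areas = _facet_normal_density(sol, contact_id, side="tissue")
        current = float((dens * areas).sum())
    elif method == "average":
        # the side-averaged density of an interior boundary -- provided only to
        # demonstrate why averaging instead of taking the jump is wrong
        dt_, areas = _facet_normal_density(sol, contact_id, side="tissue")
        dm, _ = _facet_normal_density(sol, contact_id, side="metal")
        dens = np.where(np.isnan(dm), dt_, 0.5 * (dt_ + dm))
        current = float((dens * areas).sum())
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return ContactCurrent(contact_id=contact_id, current_mA=current, method=method,
                          area_mm2=A)


def _face_lookup(mesh: MeshResult, side: str) -> dict:
    """Map sorted facet vertex triple -> adjacent element on one side of the
    lead surface ('tissue': brain/encapsulation, 'metal': contact domains)."""
    cache = getattr(mesh, "_solver_cache", None)
    if cache is None:
        cache = {}
        mesh._solver_cache = cache  # type: ignore[attr-defined]
    key = f"face_lookup_{side}"
    if key not in cache:
        if side == "tissue":
            mask = (mesh.region == REGION_BRAIN) | (mesh.region == REGION_ENCAPSULATION)
        elif side == "metal":
            mask = mesh.region >= REGION_CONTACT0
        else:
            raise ValueError(side)
        els = np.nonzero(mask)[0]
        faces = np.sort(mesh.tets[els][:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]], axis=2)
        lookup = {}
        for e, f4 in zip(els, faces):
            for f in f4:
                lookup[tuple(f)] = int(e)
        cache[key] = lookup
    return cache[key]


def _facet_outward_normals(mesh: MeshResult, facets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Areas and normals oriented from the lead into the tissue (radially
    outward on the shaft wall, axially for cap facets)."""
    area, normal = mesh.facet_area_normals(facets)
    cent = mesh.vertices[facets].mean(axis=1)
    outward = cent.copy()
    outward[:, 2] = 0.0
    nr = np.linalg.norm(outward, axis=1)
    outward /= np.where(nr > 0, nr, 1.0)[:, None]
    flat = np.abs(np.einsum("ij,ij->i", normal, outward)) < 1e-6
    outward[flat] = [0.0, 0.0, -1.0]   # cap facets (tip annulus) face downward
    sign = np.sign(np.einsum("ij,ij->i", normal, outward))
    return area, normal * np.where(sign == 0, 1.0, sign)[:, None]


def _facet_normal_density(sol: FieldSolution, contact_id: str,
                          side: str = "tissue") -> tuple[np.ndarray, np.ndarray]:
    """Raw one-sided normal current density (mA/mm^2, positive out of the
    contact) from the adjacent element's P1 gradient, and facet areas.  Facets
    with no element on the requested side yield NaN."""
    mesh = sol.mesh
    facets = mesh.contact_facets[contact_id]
    lookup = _face_lookup(mesh, side)
    els = np.array([lookup.get(tuple(np.sort(f)), -1) for f in facets])
    area, normal = _facet_outward_normals(mesh, facets)
    dens = np.full(len(facets), np.nan)
    ok = els >= 0
    if ok.any():
        e = els[ok]
        grads = mesh.shape_gradients()[e]
        gradV = np.einsum("fij,fi->fj", grads, sol.node_potentials[mesh.tets[e]])
        sigma = element_conductivity(mesh, sol.cond)[e]
        dens[ok] = -sigma * np.einsum("fj,fj->f", gradV, normal[ok]) * MA_PER_A
    return dens, area


def surface_current_density_map(sol: FieldSolution, contact_id: Optional[str] = None) -> dict:
    """Per-facet current density on a contact surface (default: active contact).

    ``jn_mA_mm2`` is the variationally consistent normal density (nodal flux
    divided by nodal area share, averaged per facet) -- exact for imposed
    Neumann fluxes and accurate elsewhere.  ``jt_mA_mm2`` is the tangential
    density from the facet-plane potential gradient, and ``jmag_mA_mm2``
    combines the two: the edge/corner enhancement of distributed sources shows
    there.  ``jn_tissue_raw`` / ``jn_metal_raw`` are the one-sided element-
    gradient densities of an interior boundary; their disagreement (and the
    singular metal-side values around a point-source weld vertex) is why the
    interface jump, not the side average, must be used for contact currents.
    """
    cid = contact_id or sol.variant.active_contact_id
    mesh = sol.mesh
    facets = mesh.contact_facets[cid]
    area, normal = _facet_outward_normals(mesh, facets)

    # consistent nodal flux -> nodal density -> facet average
    nodes = np.unique(facets)
    Kt = tissue_stiffness(mesh, sol.cond)
    nodal_flux = np.asarray(Kt[nodes] @ sol.node_potentials).ravel() * MA_PER_A
    nodal_area = np.zeros(len(mesh.vertices))
    np.add.at(nodal_area, facets.ravel(), np.repeat(area / 3.0, 3))
    q = np.zeros(len(mesh.vertices))
    q[nodes] = nodal_flux / nodal_area[nodes]
    jn = q[facets].mean(axis=1)

    # tangential density from the in-plane gradient of the facet's nodal values
    p = mesh.vertices[facets]
    v = sol.node_potentials[facets]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    # solve for the in-plane gradient g with g.e1 = dv1, g.e2 = dv2, g.n = 0
    n = normal
    mats = np.stack([e1, e2, n], axis=1)
    rhs = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], np.zeros(len(facets))], axis=1)
    g = np.linalg.solve(mats, rhs[..., None])[..., 0]
    # conductivity of the tissue side
    lookup = _face_lookup(mesh, "tissue")
    els = np.array([lookup.get(tuple(np.sort(f)), -1) for f in facets])
    sigma = np.where(els >= 0, element_conductivity(mesh, sol.cond)[np.maximum(els, 0)],
                     sol.cond.brain * S_PER_MM)
    jt = sigma * np.linalg.norm(g, axis=1) * MA_PER_A

    jn_tissue, _ = _facet_normal_density(sol, cid, side="tissue")
    jn_metal, _ = _facet_normal_density(sol, cid, side="metal")
    return dict(contact_id=cid, centroids=p.mean(axis=1), areas_mm2=area,
                jn_mA_mm2=jn, jt_mA_mm2=jt,
                jmag_mA_mm2=np.hypot(jn, jt),
                jn_tissue_raw=jn_tissue, jn_metal_raw=jn_metal)


# ---------------------------------------------------------------------------
# variant drivers


def solve_electric_potential(mesh: MeshResult, cond: ConductivityMap, variant: VariantSpec,
                             current_mA: float = -1.0, seed_voltage_V: float = 1.0,
                             settings: Optional[SolverSettings] = None
                             ) -> tuple[FieldSolution, dict]:
    """Two-solve electric-potential source: Dirichlet seed, measure the output
    current, re-solve with the seed scaled by (commanded / measured)."""
    sys1 = assemble(mesh, cond, variant, settings)
    apply_dirichlet_contact(sys1, seed_voltage_V)
    sol1 = solve(sys1)
    i1 = sol1.active_current_mA
    if abs(i1) < 1e-12:
        raise SolveError("degenerate geometry: seed solve delivered no current")
    scale = current_mA / i1
    sys2 = assemble(mesh, cond, variant, settings)
    apply_dirichlet_contact(sys2, seed_voltage_V * scale)
    sol2 = solve(sys2)
    sol2.commanded_current_mA = current_mA
    sol2.source_info.update(current_mA=current_mA, seed_voltage_V=seed_voltage_V,
                            first_solve_current_mA=i1, scale=scale)
    info = dict(first_current_mA=i1, scale=scale, first_solution=sol1)
    return sol2, info


def solve_variant(mesh: MeshResult, cond: Optional[ConductivityMap] = None,
                  current_mA: float = -1.0, seed_voltage_V: float = 1.0,
                  settings: Optional[SolverSettings] = None) -> FieldSolution:
    """Solve the voltage distribution for the variant the mesh was built for."""
    cond = cond or ConductivityMap()
    variant = mesh.geometry.variant
    st = variant.source_type
    if st is SourceType.electric_potential:
        sol, _ = solve_electric_potential(mesh, cond, variant, current_mA,
                                          seed_voltage_V, settings)
        return sol
    system = assemble(mesh, cond, variant, settings)
    if st is SourceType.point_current:
        apply_point_current_source(system, current_mA)
    elif st is SourceType.boundary_current:
        apply_boundary_current_source(system, current_mA)
    elif st is SourceType.current_density:
        apply_current_density_source(system, current_mA)
    elif st is SourceType.floating_potential:
        apply_floating_potential_source(system, current_mA)
    else:  # pragma: no cover
        raise InvalidVariantError(f"unknown source type {st}")
    return solve(system)


@dataclass
class HomogeneousSolution:
    """Point-source solve in a lead-free homogeneous domain (analytic-oracle control)."""

    mesh: MeshResult
    node_potentials: np.ndarray     # V
    source_node: int
    source_point: np.ndarray        # snapped coordinates, mm
    current_mA: float
    sigma_S_per_m: float

    def interpolate(self, points: np.ndarray, allow_outside: bool = False) -> np.ndarray:
        return self.mesh.interpolate_nodal(self.node_potentials, points, allow_outside)

    def analytic(self, points: np.ndarray) -> np.ndarray:
        return point_source_potential(points, self.source_point, self.current_mA,
                                      self.sigma_S_per_m)


def solve_homogeneous_point_source(mesh: MeshResult, current_mA: float = -1.0,
                                   sigma_S_per_m: float = 0.2,
                                   source_point=(0.0, 0.0, 2.75),
                                   settings: Optional[SolverSettings] = None
                                   ) -> HomogeneousSolution:
    """Monopole in a homogeneous lead-free domain with the absorbing outer
    boundary; the FEM field should match I/(4 pi sigma r) away from the load."""
    if len(mesh.contact_facets):
        raise AssemblyError("expected a lead-free mesh (no contact surfaces)")
    settings = settings or SolverSettings()
    n = len(mesh.vertices)
    node = int(np.argmin(np.linalg.norm(mesh.vertices - np.asarray(source_point), axis=1)))
    src = mesh.vertices[node]
    sigma_el = np.full(len(mesh.tets), sigma_S_per_m * S_PER_MM)
    ident = np.arange(n)
    K = _stiffness(mesh, sigma_el, ident, n)
    cond = ConductivityMap(brain=sigma_S_per_m)
    K = (K + _absorbing_matrix(mesh, cond, ident, n, src)).tocsr()
    f = np.zeros(n)
    f[node] = current_mA / MA_PER_A
    # homogeneous SPD system: Jacobi-preconditioned CG is much faster than a
    # direct factorization at oracle-grade resolutions
    M = sp.diags(1.0 / K.diagonal())
    u, info = spla.cg(K, f, rtol=1e-10, atol=0.0, M=M, maxiter=20000)
    if info != 0:
        raise SolveError(f"CG failed to converge on the homogeneous system (info={info})")
    if not np.all(np.isfinite(u)):
        raise SolveError("solver produced non-finite potentials")
    return HomogeneousSolution(mesh=mesh, node_potentials=u, source_node=node,
                               source_point=src.copy(), current_mA=current_mA,
                               sigma_S_per_m=sigma_S_per_m)


def point_source_potential(points: np.ndarray, source: np.ndarray,
                           current_mA: float, sigma_S_per_m: float) -> np.ndarray:
    """Analytic monopole potential V = I / (4 pi sigma r) in an infinite
    homogeneous medium (V, with r in mm)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(p - np.asarray(source, dtype=float), axis=1)
    return (current_mA / MA_PER_A) / (4.0 * np.pi * sigma_S_per_m * S_PER_MM * r)
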