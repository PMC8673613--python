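"""Parametric lead-in-brain geometry and structured tetrahedral meshing.

The mesh is a deterministic structured lattice in cylindrical coordinates
(radial rings x azimuthal divisions x axial planes) whose surfaces coincide
exactly with every material interface of the lead model: the contact-shell
radius, the lead radius, the encapsulation boundary, the contact band edges
and the directional-segment arc edges.  Cells are triangular prisms (wedges
at the axis, split annulus quads elsewhere) subdivided into tetrahedra with
a global smallest-vertex diagonal rule, which guarantees a conforming mesh.

Because the lattice is independent of the model variant -- variants only
select which elements are kept and how surfaces are labeled -- the surface
discretization of the active contact is bitwise identical across all 15
variants, which is required for a fair comparison of the current sources.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import (
    CONTACT_IDS,
    DomainSpec,
    LeadSpec,
    MeshSettings,
    Rep,
    VariantSpec,
)

# region codes (element labels)
REGION_BRAIN = 0
REGION_ENCAPSULATION = 1
REGION_SHAFT = 2
REGION_CONTACT0 = 10  # contact k -> REGION_CONTACT0 + k

REGION_NAMES = {REGION_BRAIN: "brain", REGION_ENCAPSULATION: "encapsulation",
                REGION_SHAFT: "shaft"}
for _k, _cid in enumerate(CONTACT_IDS):
    REGION_NAMES[REGION_CONTACT0 + _k] = f"contact_{_cid}"


class GeometryError(ValueError):
    pass


class MeshingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# geometry model


@dataclass(frozen=True)
class Geometry:
    """Boundary representation: the lead/domain specs plus derived labeling data.

    ``explicit_regions`` lists the lead components that exist as meshed volumes
    for this variant; everything else on the lead is represented purely by
    labeled surfaces.
    """

    lead: LeadSpec
    domain: DomainSpec
    variant: VariantSpec
    contact_extents: dict
    explicit_regions: tuple[str, ...]

    @property
    def inner_radius(self) -> float:
        return self.lead.lead_radius - self.lead.contact_thickness

    @property
    def encap_radius(self) -> float:
        return self.lead.lead_radius + self.domain.encapsulation_thickness


def build_geometry(lead: LeadSpec, domain: DomainSpec, variant: VariantSpec) -> Geometry:
    """Assemble the labeled geometry for one model variant.

    Raises :class:`~dbsfield.config.InvalidVariantError` (at VariantSpec
    construction) for source/representation combinations outside the variant
    table, and :class:`GeometryError` for degenerate dimensions.
    """
    domain.validate_against(lead)
    extents = lead.contact_extents()
    # overlap check (guards against pathological overrides)
    bands = sorted((z0, z1) for z0, z1, _ in extents.values())
    for (a0, a1), (b0, b1) in zip(bands, bands[1:]):
        if b0 < a1 - 1e-12 and not np.isclose(a0, b0):
            raise GeometryError("contact bands overlap axially")
    ring_end = max(z1 for _, z1, _ in extents.values())
    if ring_end > lead.shaft_length:
        raise GeometryError("contacts extend beyond the shaft length")
    if domain.brain_radius <= lead.shaft_length + 2 * domain.encapsulation_thickness:
        raise GeometryError("domain too small to contain the lead")

    explicit = []
    if variant.shaft_rep is Rep.explicit:
        explicit.append("shaft")
    for cid in CONTACT_IDS:
        rep = (variant.active_contact_rep if cid == variant.active_contact_id
               else variant.inactive_contacts_rep)
        if rep is Rep.explicit:
            explicit.append(f"contact_{cid}")
    return Geometry(lead=lead, domain=domain, variant=variant,
                    contact_extents=extents, explicit_regions=tuple(explicit))


# ---------------------------------------------------------------------------
# mesh result


@dataclass
class MeshResult:
    """Labeled tetrahedral mesh of one variant's geometry.

    vertices in mm; ``region`` holds one code per tetrahedron; ``contact_facets``
    maps contact id -> (F, 3) vertex-index triangles on the lateral contact
    surface at the lead radius; ``ground_nodes`` are the Dirichlet nodes of the
    grounded patch; ``outer_facets`` triangulate the whole outer boundary.
    """

    geometry: Geometry
    settings: MeshSettings
    vertices: np.ndarray            # (N, 3) float
    tets: np.ndarray                # (M, 4) int
    region: np.ndarray              # (M,) int
    contact_facets: dict            # contact_id -> (F, 3) int
    ground_nodes: np.ndarray        # (G,) int
    outer_facets: np.ndarray        # (B, 3) int
    node_rz: np.ndarray             # (N, 2) int: (ring index, z-plane index)
    rings: np.ndarray               # ring radii, mm
    zplanes: np.ndarray             # axial plane coordinates, mm

    _kdtree: Optional[cKDTree] = field(default=None, repr=False, compare=False)
    _grads: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _vols: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    # -- derived quantities -------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        if self._vols is None:
            self._compute_grads()
        return self._vols

    def _compute_grads(self) -> None:
        v = self.vertices[self.tets]                     # (M, 4, 3)
        e = v[:, 1:] - v[:, :1]                          # (M, 3, 3)
        det = np.linalg.det(e)
        vol = det / 6.0
        if np.any(np.abs(vol) < 1e-14):
            raise MeshingError("degenerate (zero-volume) tetrahedra in mesh")
        # gradients of the 4 linear shape functions, (M, 4, 3)
        inv = np.linalg.inv(e)                           # columns give grads of 1..3
        g123 = np.transpose(inv, (0, 2, 1))              # (M, 3, 3): rows = grad N1..N3
        g0 = -g123.sum(axis=1, keepdims=True)
        self._grads = np.concatenate([g0, g123], axis=1)
        self._vols = np.abs(vol)

    def shape_gradients(self) -> np.ndarray:
        """(M, 4, 3) gradients of the P1 shape functions per tetrahedron (1/mm)."""
        if self._grads is None:
            self._compute_grads()
        return self._grads

    def facet_area_normals(self, facets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Areas (mm^2) and unit normals of a facet array; normal orientation is
        arbitrary until fixed by the caller."""
        p = self.vertices[facets]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        area = 0.5 * np.linalg.norm(cr, axis=1)
        n = cr / np.linalg.norm(cr, axis=1)[:, None]
        return area, n

    def contact_area(self, contact_id: str) -> float:
        area, _ = self.facet_area_normals(self.contact_facets[contact_id])
        return float(area.sum())

    def contact_surface_signature(self, contact_id: Optional[str] = None) -> str:
        """Stable hash of a contact's surface discretization (coordinates only,
        independent of node numbering).  Defaults to the active contact."""
        cid = contact_id or self.geometry.variant.active_contact_id
        facets = self.contact_facets[cid]
        pts = np.round(self.vertices[facets], 9)         # (F, 3, 3)
        # canonical order: sort vertices within each facet, then sort facets
        sorted_pts = np.sort(pts, axis=1).reshape(len(pts), -1)
        order = np.lexsort(sorted_pts.T[::-1])
        return hashlib.sha256(sorted_pts[order].tobytes()).hexdigest()

    # -- point location / interpolation --------------------------------------

    def locate(self, points: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
        """Containing tetrahedron and barycentric coordinates for each point.

        Nearest-centroid candidates are tried in growing batches (graded
        anisotropic cells can hide the containing tet from a small candidate
        set), with a brute-force sweep for stragglers.  Points in void regions
        (inside a boundary-represented lead) or outside the domain get -1.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._kdtree is None:
            cent = self.vertices[self.tets].mean(axis=1)
            self._kdtree = cKDTree(cent)
        tet_idx = np.full(len(points), -1, dtype=np.int64)
        bary = np.zeros((len(points), 4))
        pending = np.arange(len(points))
        for k in (24, 256):
            if len(pending) == 0:
                break
            k = min(k, len(self.tets))
            _, cand = self._kdtree.query(points[pending], k=k)
            cand = np.atleast_2d(cand)
            lam = self._bary_batch(points[pending], cand)      # (n, k, 4)
            ok = lam.min(axis=2) >= -tol
            hit = ok.any(axis=1)
            first = np.argmax(ok, axis=1)
            rows = np.nonzero(hit)[0]
            tet_idx[pending[rows]] = cand[rows, first[rows]]
            bary[pending[rows]] = lam[rows, first[rows]]
            pending = pending[~hit]
        for i in pending:  # brute force for anything still unresolved
            lam = self._bary_batch(points[i:i + 1], np.arange(len(self.tets))[None, :])[0]
            best = int(np.argmax(lam.min(axis=1)))
            if lam[best].min() >= -tol:
                tet_idx[i] = best
                bary[i] = lam[best]
        return tet_idx, bary

    def _bary_batch(self, pts: np.ndarray, cand: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of pts (n,3) in candidate tets (n,k) -> (n,k,4)."""
        grads = self.shape_gradients()[cand]               # (n, k, 4, 3)
        v0 = self.vertices[self.tets[cand, 0]]             # (n, k, 3)
        d = pts[:, None, :] - v0
        lam123 = np.einsum("nkij,nkj->nki", grads[:, :, 1:, :], d)
        lam0 = 1.0 - lam123.sum(axis=2, keepdims=True)
        return np.concatenate([lam0, lam123], axis=2)

    def interpolate_nodal(self, nodal: np.ndarray, points: np.ndarray,
                          allow_outside: bool = False) -> np.ndarray:
        """Interpolate a nodal field at arbitrary points (NaN outside if allowed)."""
        tet_idx, bary = self.locate(points)
        out = np.full(len(np.atleast_2d(points)), np.nan)
        ok = tet_idx >= 0
        if not allow_outside and not ok.all():
            bad = np.atleast_2d(points)[~ok][:3]
            raise ValueError(f"points outside the tissue mesh, e.g. {bad.tolist()}")
        vals = nodal[self.tets[tet_idx[ok]]]
        out[ok] = np.einsum("ij,ij->i", vals, bary[ok])
        return out


# ---------------------------------------------------------------------------
# lattice construction helpers


def _geometric_fill(a: float, b: float, h0: float, growth: float) -> np.ndarray:
    """Interior+end points from a to b with spacing starting at ~h0, growing
    geometrically; the sizes are rescaled so the last point lands exactly on b."""
    length = abs(b - a)
    if length <= h0 * 1.0001:
        return np.array([b])
    n = max(1, int(np.ceil(np.log(1.0 + length * (growth - 1.0) / h0) / np.log(growth))))
    sizes = h0 * growth ** np.arange(n)
    sizes *= length / sizes.sum()
    pts = a + np.sign(b - a) * np.cumsum(sizes)
    pts[-1] = b
    return pts


def _uniform_fill(a: float, b: float, h: float, force_even: bool = False) -> np.ndarray:
    n = max(1, int(round(abs(b - a) / h)))
    if force_even and n % 2:
        n += 1
    return np.linspace(a, b, n + 1)[1:]


def _build_zplanes(geo: Geometry, s: MeshSettings) -> np.ndarray:
    lead, dom = geo.lead, geo.domain
    enc = dom.encapsulation_thickness
    ring_end = max(z1 for _, z1, _ in geo.contact_extents.values())
    # near-field breakpoints (every contact band edge, the tip plane, the
    # encapsulation cap below the tip)
    breaks = {0.0, -enc}
    bands = []
    for z0, z1, _ in geo.contact_extents.values():
        breaks.update((z0, z1))
        bands.append((z0, z1))
    lo = -enc - s.near_margin
    hi = ring_end + s.near_margin
    breaks.update((lo, hi))
    bk = sorted(breaks)
    z = [bk[0]]
    for a, b in zip(bk, bk[1:]):
        in_band = any(np.isclose(a, z0) and np.isclose(b, z1) for z0, z1 in bands)
        z.extend(_uniform_fill(a, b, s.axial_size, force_even=in_band))
    # below the near field down to the domain floor
    z = list(_geometric_fill(lo, -dom.brain_radius, s.axial_size * s.axial_growth,
                             s.axial_growth)[::-1]) + z
    # above: to the lead top, the top encapsulation cap, then the domain ceiling
    up = _geometric_fill(hi, lead.shaft_length, s.axial_size * s.axial_growth, s.axial_growth)
    z.extend(up)
    z.append(lead.shaft_length + enc)
    z.extend(_geometric_fill(lead.shaft_length + enc, dom.brain_radius,
                             max(enc, s.axial_size) * s.axial_growth, s.axial_growth))
    z = np.array(z)
    if np.any(np.diff(z) <= 1e-9):
        raise MeshingError("axial plane construction produced non-increasing planes")
    return z


def _build_rings(geo: Geometry, s: MeshSettings) -> np.ndarray:
    lead, dom = geo.lead, geo.domain
    r_in, a, r_enc = geo.inner_radius, lead.lead_radius, geo.encap_radius
    rings = [0.0]
    rings.extend(np.linspace(0.0, r_in, s.inner_rings + 1)[1:])
    rings.append(a)
    rings.extend(np.linspace(a, r_enc, 3)[1:])          # two encapsulation sublayers
    rings.extend(_geometric_fill(r_enc, dom.brain_radius, s.axial_size, s.radial_growth))
    rings = np.array(rings)
    if np.any(np.diff(rings) <= 1e-9):
        raise MeshingError("radial ring construction produced non-increasing radii")
    return rings


def _arc_contains(th0: float, th1: float, theta: np.ndarray) -> np.ndarray:
    """Membership of angles (deg, mod 360) in the arc from th0 to th1 going ccw."""
    t = np.mod(theta - th0, 360.0)
    span = np.mod(th1 - th0, 360.0)
    if span == 0:
        span = 360.0
    return t < span - 1e-9


_PRISM_ROT = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms (P, 6) into tets (3P, 4) with conforming faces.

    Bottom face (0,1,2), top (3,4,5), vertical edges (0,3),(1,4),(2,5).  Quad
    faces are cut by the diagonal through their smallest global vertex; rotating
    the prism so its smallest vertex sits at position 0 leaves one free face
    whose diagonal decides between two three-tet patterns.
    """
    prisms = np.asarray(prisms)
    rot = np.array(_PRISM_ROT)
    which = np.argmin(prisms, axis=1)
    canon = np.take_along_axis(prisms, rot[which], axis=1)
    b1, b2, t1, t2 = canon[:, 1], canon[:, 2], canon[:, 4], canon[:, 5]
    # free quad face (1,2,5,4): diagonal (1,5) iff its smallest vertex is 1 or 5
    m = np.minimum(np.minimum(b1, b2), np.minimum(t1, t2))
    use15 = (m == b1) | (m == t2)
    tets = np.empty((len(prisms), 3, 4), dtype=prisms.dtype)
    c = canon
    tets[use15, 0] = c[use15][:, [0, 1, 2, 5]]
    tets[use15, 1] = c[use15][:, [0, 1, 5, 4]]
    tets[use15, 2] = c[use15][:, [0, 3, 4, 5]]
    v = ~use15
    tets[v, 0] = c[v][:, [0, 1, 2, 4]]
    tets[v, 1] = c[v][:, [0, 2, 4, 5]]
    tets[v, 2] = c[v][:, [0, 3, 4, 5]]
    return tets.reshape(-1, 4)


def _split_quads(quads: np.ndarray) -> np.ndarray:
    """Split quads (Q, 4) with corners in cyclic order into triangles (2Q, 3)
    by the diagonal through the smallest global vertex."""
    quads = np.asarray(quads)
    which = np.argmin(quads, axis=1)
    rolled = np.take_along_axis(
        quads, (which[:, None] + np.arange(4)[None, :]) % 4, axis=1
    )
    tris = np.empty((len(quads), 2, 3), dtype=quads.dtype)
    tris[:, 0] = rolled[:, [0, 1, 2]]
    tris[:, 1] = rolled[:, [0, 2, 3]]
    return tris.reshape(-1, 3)


# ---------------------------------------------------------------------------
# main mesher


def mesh_geometry(geometry: Geometry, settings: Optional[MeshSettings] = None) -> MeshResult:
    """Mesh a variant's geometry into a labeled conforming tetrahedral mesh."""
    s = settings or MeshSettings()
    lead, dom, variant = geometry.lead, geometry.domain, geometry.variant

    dtheta = 360.0 / s.theta_divisions
    for cid, (_, _, arc) in geometry.contact_extents.items():
        if arc is None:
            continue
        for edge in arc:
            if abs(edge / dtheta - round(edge / dtheta)) > 1e-9:
                raise MeshingError(
                    f"theta_divisions={s.theta_divisions} does not resolve the "
                    f"{edge} deg segment edge of contact {cid}"
                )

    zp = _build_zplanes(geometry, s)
    rings = _build_rings(geometry, s)
    nz, nr, nt = len(zp), len(rings), s.theta_divisions
    theta = np.arange(nt) * dtheta

    # ---- nodes: plane-major; per plane one axis node then (nr-1)*nt ring nodes
    stride = 1 + (nr - 1) * nt
    n_nodes = nz * stride
    cos, sin = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    verts = np.empty((n_nodes, 3))
    node_rz = np.empty((n_nodes, 2), dtype=np.int32)
    for iz, z in enumerate(zp):
        base = iz * stride
        verts[base] = (0.0, 0.0, z)
        node_rz[base] = (0, iz)
        for ir in range(1, nr):
            sl = slice(base + 1 + (ir - 1) * nt, base + 1 + ir * nt)
            verts[sl, 0] = rings[ir] * cos
            verts[sl, 1] = rings[ir] * sin
            verts[sl, 2] = z
            node_rz[sl, 0] = ir
            node_rz[sl, 1] = iz

    def nid(iz, ir, it):
        """Global node index (vectorized over any of the arguments)."""
        iz, ir, it = np.broadcast_arrays(np.asarray(iz), np.asarray(ir), np.asarray(it) % nt)
        out = iz * stride + np.where(ir == 0, 0, 1 + (ir - 1) * nt + it)
        return out

    # ---- 2D triangulation of the disc cross-section (shared by every plane)
    it = np.arange(nt)
    axis_tris = np.stack([np.zeros(nt, dtype=np.int64),
                          nid(0, 1, it), nid(0, 1, it + 1)], axis=1)
    quad_list = []
    for ir in range(1, nr - 1):
        quad_list.append(np.stack([nid(0, ir, it), nid(0, ir + 1, it),
                                   nid(0, ir + 1, it + 1), nid(0, ir, it + 1)], axis=1))
    ring_tris = _split_quads(np.concatenate(quad_list, axis=0))
    tris2d = np.concatenate([axis_tris, ring_tris], axis=0)   # node ids within plane 0

    # ---- extrude to prisms and split to tets
    layer_prisms = np.concatenate([tris2d, tris2d + stride], axis=1)  # (P, 6) layer 0
    all_tets = []
    for iz in range(nz - 1):
        all_tets.append(_split_prisms(layer_prisms + iz * stride))
    tets = np.concatenate(all_tets, axis=0)

    # ---- region classification by centroid
    cent = verts[tets].mean(axis=1)
    cr = np.hypot(cent[:, 0], cent[:, 1])
    cz = cent[:, 2]
    cth = np.degrees(np.arctan2(cent[:, 1], cent[:, 0])) % 360.0
    a, r_in, r_enc = lead.lead_radius, geometry.inner_radius, geometry.encap_radius
    enc = dom.encapsulation_thickness
    L = lead.shaft_length

    region = np.full(len(tets), REGION_BRAIN, dtype=np.int32)
    in_lead = (cr < a) & (cz > 0.0) & (cz < L)
    region[in_lead] = REGION_SHAFT
    for k, cid in enumerate(CONTACT_IDS):
        z0, z1, arc = geometry.contact_extents[cid]
        m = in_lead & (cr > r_in) & (cz > z0) & (cz < z1)
        if arc is not None:
            m &= _arc_contains(arc[0], arc[1], cth)
        region[m] = REGION_CONTACT0 + k
    in_encap = (
        ((cr > a) & (cr < r_enc) & (cz > 0.0) & (cz < L))
        | ((cr < r_enc) & (cz > -enc) & (cz < 0.0))
        | ((cr < r_enc) & (cz > L) & (cz < L + enc))
    )
    region[in_encap] = REGION_ENCAPSULATION

    # ---- drop boundary-represented lead components
    keep = np.ones(len(tets), dtype=bool)
    if variant.shaft_rep is Rep.boundary:
        keep &= region != REGION_SHAFT
    for k, cid in enumerate(CONTACT_IDS):
        rep = (variant.active_contact_rep if cid == variant.active_contact_id
               else variant.inactive_contacts_rep)
        if rep is Rep.boundary:
            keep &= region != REGION_CONTACT0 + k
    tets, region = tets[keep], region[keep]

    # ---- contact surface facets: lateral lattice quads at the lead radius
    ir_a = int(np.argmin(np.abs(rings - a)))
    iz_arr = np.arange(nz - 1)
    contact_facets = {}
    for cid in CONTACT_IDS:
        z0, z1, arc = geometry.contact_extents[cid]
        zmid = 0.5 * (zp[:-1] + zp[1:])
        sel_z = iz_arr[(zmid > z0) & (zmid < z1)]
        th_mid = theta + dtheta / 2.0
        sel_t = it[_arc_contains(arc[0], arc[1], th_mid)] if arc is not None else it
        IZ, IT = np.meshgrid(sel_z, sel_t, indexing="ij")
        IZ, IT = IZ.ravel(), IT.ravel()
        quads = np.stack([nid(IZ, ir_a, IT), nid(IZ, ir_a, IT + 1),
                          nid(IZ + 1, ir_a, IT + 1), nid(IZ + 1, ir_a, IT)], axis=1)
        contact_facets[cid] = _split_quads(quads)

    # the tip contact's lower rim is exposed to the encapsulation cap below the
    # tip plane; that annulus (shell inner radius to lead radius at z=0) belongs
    # to its tissue interface in every representation
    iz0 = int(np.argmin(np.abs(zp)))
    ir_in = int(np.argmin(np.abs(rings - r_in)))
    ann = []
    for ir in range(ir_in, ir_a):
        IT = it
        ann.append(np.stack([nid(iz0, ir, IT), nid(iz0, ir + 1, IT),
                             nid(iz0, ir + 1, IT + 1), nid(iz0, ir, IT + 1)], axis=1))
    contact_facets["tip"] = np.concatenate(
        [contact_facets["tip"], _split_quads(np.concatenate(ann, axis=0))], axis=0)

    # ---- outer boundary facets (lateral wall + end discs)
    IZ, IT = np.meshgrid(iz_arr, it, indexing="ij")
    IZ, IT = IZ.ravel(), IT.ravel()
    wall = np.stack([nid(IZ, nr - 1, IT), nid(IZ, nr - 1, IT + 1),
                     nid(IZ + 1, nr - 1, IT + 1), nid(IZ + 1, nr - 1, IT)], axis=1)
    outer = np.concatenate([_split_quads(wall), tris2d, tris2d + (nz - 1) * stride], axis=0)

    # ---- grounded patch: nodes on the bottom disc within the patch radius
    bottom = np.arange(stride)
    ground = bottom[np.hypot(verts[bottom, 0], verts[bottom, 1])
                    <= dom.ground_patch_radius + 1e-9]

    mesh = MeshResult(
        geometry=geometry, settings=s, vertices=verts, tets=tets, region=region,
        contact_facets=contact_facets, ground_nodes=ground, outer_facets=outer,
        node_rz=node_rz, rings=rings, zplanes=zp,
    )
    mesh.tet_volumes()  # validates non-degeneracy
    return mesh


def mesh_lead_model(lead: LeadSpec, domain: DomainSpec, variant: VariantSpec,
                    settings: Optional[MeshSettings] = None) -> MeshResult:
    """Convenience: build_geometry + mesh_geometry."""
    return mesh_geometry(build_geometry(lead, domain, variant), settings)


# ---------------------------------------------------------------------------
# mesh-refinement acceptance


def convergence_check(coarse, fine, probe_points: np.ndarray) -> dict:
    """Relative voltage change between two solutions of the same geometry at
    different mesh resolutions, evaluated on a probe grid.

    Returns max and RMS of |V_f - V_c| / max|V_f| over the probes.  Both
    arguments must expose ``interpolate(points)`` (FieldSolution does) and
    derive from the same lead geometry.
    """
    gc = coarse.mesh.geometry if hasattr(coarse, "mesh") else None
    gf = fine.mesh.geometry if hasattr(fine, "mesh") else None
    if gc is not None and gf is not None and (gc.lead != gf.lead or gc.domain != gf.domain):
        raise ValueError("solutions come from different geometries")
    vc = coarse.interpolate(probe_points)
    vf = fine.interpolate(probe_points)
    scale = np.nanmax(np.abs(vf))
    rel = np.abs(vf - vc) / scale
    return {"max_rel_change": float(np.nanmax(rel)),
            "rms_rel_change": float(np.sqrt(np.nanmean(rel ** 2))),
            "probe_scale_V": float(scale)}
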