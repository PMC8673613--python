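"""Structured meshing: conformity, labeling, determinism, surface matching."""

import numpy as np
import pytest

from dbsfield import (
    DomainSpec,
    LeadSpec,
    MeshSettings,
    SolverSettings,
    VariantSpec,
)
from dbsfield.fixtures import COARSE_MESH, variant_pair
from dbsfield.geometry import (
    GeometryError,
    REGION_BRAIN,
    REGION_CONTACT0,
    REGION_ENCAPSULATION,
    REGION_SHAFT,
    build_geometry,
    convergence_check,
    mesh_geometry,
)


@pytest.fixture(scope="module")
def coarse_pair():
    return variant_pair()


class TestMeshStructure:
    def test_conforming_no_hanging_faces(self, coarse_pair):
        """Every interior face is shared by exactly two tetrahedra (the prism
        subdivision must agree across cell boundaries)."""
        for mesh in coarse_pair:
            faces = np.sort(
                mesh.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3),
                axis=1)
            _, counts = np.unique(faces, axis=0, return_counts=True)
            assert set(counts.tolist()) <= {1, 2}

    def test_positive_volumes_fill_domain(self, coarse_pair, lead, domain):
        m1, m15 = coarse_pair
        vol = m1.tet_volumes()
        assert np.all(vol > 0)
        # the polygonal cross-section underestimates the cylinder area by
        # sin(dtheta)/dtheta; allow 2%
        expected = np.pi * domain.brain_radius ** 2 * (2 * domain.brain_radius)
        assert vol.sum() == pytest.approx(expected, rel=0.02)
        # boundary representation removes exactly the lead interior
        removed = vol.sum() - m15.tet_volumes().sum()
        lead_vol = np.pi * lead.lead_radius ** 2 * lead.shaft_length
        assert removed == pytest.approx(lead_vol, rel=0.03)

    def test_every_tet_has_one_region(self, coarse_pair):
        m1, m15 = coarse_pair
        valid = {REGION_BRAIN, REGION_ENCAPSULATION, REGION_SHAFT} | {
            REGION_CONTACT0 + k for k in range(8)}
        assert set(np.unique(m1.region).tolist()) == valid
        # fully boundary-represented lead leaves only tissue
        assert set(np.unique(m15.region).tolist()) == {REGION_BRAIN, REGION_ENCAPSULATION}

    def test_contact_surfaces_present_in_both_representations(self, coarse_pair):
        m1, m15 = coarse_pair
        for cid in m1.contact_facets:
            assert len(m1.contact_facets[cid]) == len(m15.contact_facets[cid])

    def test_mesh_determinism(self, lead, domain):
        v = VariantSpec.from_model_id(3)
        a = mesh_geometry(build_geometry(lead, domain, v), COARSE_MESH)
        b = mesh_geometry(build_geometry(lead, domain, v), COARSE_MESH)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.region, b.region)


class TestContactSurfaceMatching:
    def test_signature_identical_across_all_variants(self, lead, domain):
        """The active-contact surface discretization is the same for every
        variant of the same lead and mesh settings."""
        sigs = set()
        for mid in range(1, 16):
            m = mesh_geometry(build_geometry(lead, domain,
                                             VariantSpec.from_model_id(mid)),
                              COARSE_MESH)
            sigs.add(m.contact_surface_signature())
        assert len(sigs) == 1

    def test_signature_independent_of_far_field_sizing(self, lead, domain):
        """Coarsening volume growth away from the lead leaves the contact
        surface discretization untouched."""
        v = VariantSpec.from_model_id(1)
        s1 = COARSE_MESH
        s2 = s1.model_copy(update=dict(radial_growth=2.5, axial_growth=2.8))
        m1 = mesh_geometry(build_geometry(lead, domain, v), s1)
        m2 = mesh_geometry(build_geometry(lead, domain, v), s2)
        assert m1.contact_surface_signature() == m2.contact_surface_signature()

    def test_directional_contact_area_within_1pct_of_analytic(self, lead, domain):
        m = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(1)))
        for cid in ("1a", "1b", "2c"):
            assert m.contact_area(cid) == pytest.approx(
                lead.analytic_contact_area(cid), rel=0.01)


class TestGeometryValidation:
    def test_shaft_too_short_for_contacts(self):
        # the four contact bands plus gaps need 7.5 mm of shaft
        with pytest.raises(Exception):
            LeadSpec(shaft_length=7.0)

    def test_domain_cannot_contain_lead(self, lead):
        # passes the far-field ratio check but cannot contain the 20 mm shaft
        small = DomainSpec(brain_radius=20.5)
        with pytest.raises(GeometryError):
            build_geometry(lead, small, VariantSpec.from_model_id(1))

    def test_domain_too_small(self, lead):
        with pytest.raises(Exception):
            DomainSpec(brain_radius=10.0).validate_against(lead)

    def test_theta_divisions_must_resolve_segment_edges(self, lead, domain):
        from dbsfield.geometry import MeshingError

        bad = MeshSettings(theta_divisions=16)  # 22.5 deg cannot hit the 45 deg edge
        with pytest.raises(MeshingError):
            mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(1)), bad)

    def test_explicit_regions_listed(self, lead, domain):
        g1 = build_geometry(lead, domain, VariantSpec.from_model_id(1))
        g15 = build_geometry(lead, domain, VariantSpec.from_model_id(15))
        assert "shaft" in g1.explicit_regions and len(g1.explicit_regions) == 9
        assert g15.explicit_regions == ()


class TestConvergence:
    def test_identical_solutions_give_zero_change(self, lead, domain, cond):
        from dbsfield.solver import solve_variant

        m = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(15)),
                          COARSE_MESH)
        sol = solve_variant(m, cond, -1.0, settings=SolverSettings(method="cg"))
        probes = np.array([[r, 0.0, 2.75] for r in (2.0, 4.0, 6.0)])
        chk = convergence_check(sol, sol, probes)
        assert chk["max_rel_change"] == 0.0

    def test_refinement_study_brackets_working_resolution(self, lead, domain, cond):
        """A deliberately coarse mesh changes the probed voltage by more than
        the 2% working tolerance against the default resolution; refining the
        coarse lattice to default density brings the change under 2%."""
        from dbsfield.solver import solve_variant

        geo = build_geometry(lead, domain, VariantSpec.from_model_id(15))
        cg = SolverSettings(method="cg")
        s_coarse = solve_variant(mesh_geometry(geo, COARSE_MESH), cond, -1.0, settings=cg)
        s_fine = solve_variant(mesh_geometry(geo, COARSE_MESH.refined(0.5)), cond, -1.0,
                               settings=cg)
        s_default = solve_variant(mesh_geometry(geo), cond, -1.0, settings=cg)
        probes = np.array([[r, 0.0, 2.75 + dz]
                           for r in np.geomspace(1.5, 8.0, 10)
                           for dz in (-1.5, 0.0, 1.5)])
        coarse_chk = convergence_check(s_coarse, s_default, probes)
        fine_chk = convergence_check(s_fine, s_default, probes)
        assert coarse_chk["max_rel_change"] > 0.02          # flagged
        assert fine_chk["max_rel_change"] < 0.02            # accepted resolution

    def test_mismatched_geometry_rejected(self, lead, domain, cond):
        from dbsfield.solver import solve_variant

        geo_a = build_geometry(lead, domain, VariantSpec.from_model_id(15))
        lead_b = LeadSpec(ring_contact_length=1.2)
        geo_b = build_geometry(lead_b, domain, VariantSpec.from_model_id(15))
        cg = SolverSettings(method="cg")
        sa = solve_variant(mesh_geometry(geo_a, COARSE_MESH), cond, -1.0, settings=cg)
        sb = solve_variant(mesh_geometry(geo_b, COARSE_MESH), cond, -1.0, settings=cg)
        with pytest.raises(ValueError):
            convergence_check(sa, sb, np.array([[3.0, 0.0, 2.0]]))
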