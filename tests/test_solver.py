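"""Laplace solver: conservation, linearity, boundary conditions, source models."""

import numpy as np
import pytest

from dbsfield import (
    CONTACT_IDS,
    ConductivityMap,
    InvalidVariantError,
    SolverSettings,
    VariantSpec,
)
from dbsfield.fixtures import COARSE_MESH
from dbsfield.geometry import build_geometry, mesh_geometry
from dbsfield.solver import (
    AssemblyError,
    apply_current_density_source,
    apply_point_current_source,
    assemble,
    integrate_contact_current,
    point_source_potential,
    solve,
    solve_electric_potential,
    solve_variant,
    surface_current_density_map,
)

CG = SolverSettings(method="cg")


@pytest.fixture(scope="module")
def coarse15(lead, domain, cond):
    mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(15)),
                         COARSE_MESH)
    return mesh, solve_variant(mesh, cond, -1.0, settings=CG)


class TestConservation:
    @pytest.mark.parametrize("source", ["point_current", "boundary_current",
                                        "current_density", "electric_potential",
                                        "floating_potential"])
    def test_active_contact_delivers_commanded_current(self, source_solutions, source):
        """The surface-integrated normal current over the active contact equals
        the commanded -1 mA for every source implementation."""
        sol = source_solutions[source]
        assert sol.active_current_mA == pytest.approx(-1.0, rel=0.01)

    def test_global_current_balance(self, source_solutions):
        """Kirchhoff: all contact currents plus the ground flux sum to zero."""
        for sol in source_solutions.values():
            total = sum(sol.contact_currents_mA.values()) + sol.ground_current_mA
            assert abs(total) < 1e-6

    def test_inactive_contacts_carry_no_net_current(self, source_solutions):
        for sol in source_solutions.values():
            for cid in CONTACT_IDS:
                if cid == sol.variant.active_contact_id:
                    continue
                assert abs(sol.contact_currents_mA[cid]) < 1e-3

    def test_point_source_closed_surface_capture(self, source_solutions):
        """The point load inside the explicit contact is fully recovered by the
        flux integral over the surface enclosing the contact domain."""
        sol = source_solutions["point_current"]
        cc = integrate_contact_current(sol, "1a")
        assert cc.current_mA == pytest.approx(-1.0, abs=1e-6)


class TestBoundaryConditions:
    def test_ground_patch_is_exactly_zero(self, source_solutions):
        sol = source_solutions["floating_potential"]
        g = sol.node_potentials[sol.mesh.ground_nodes]
        assert np.all(g == 0.0)

    def test_linearity_in_stimulus_current(self, coarse15, cond):
        mesh, sol1 = coarse15
        sol2 = solve_variant(mesh, cond, -2.0, settings=CG)
        ratio = sol2.node_potentials[np.abs(sol1.node_potentials) > 1e-8] / \
            sol1.node_potentials[np.abs(sol1.node_potentials) > 1e-8]
        assert np.allclose(ratio, 2.0, rtol=1e-6)

    def test_floating_contact_is_equipotential(self, coarse15):
        _, sol = coarse15
        mesh = sol.mesh
        for cid in CONTACT_IDS:
            nodes = np.unique(mesh.contact_facets[cid])
            v = sol.node_potentials[nodes]
            assert np.ptp(v) < 1e-12  # merged unknown: constant by construction
            assert v[0] == pytest.approx(sol.floating_values_V[cid], abs=1e-12)

    def test_missing_ground_patch_rejected(self, lead, domain, cond):
        mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(15)),
                             COARSE_MESH)
        mesh.ground_nodes = np.array([], dtype=int)
        with pytest.raises(AssemblyError):
            assemble(mesh, cond, mesh.geometry.variant)

    def test_monotone_far_field_decay(self, source_solutions):
        """|V_e| decreases strictly with distance along rays from the contact
        into the homogeneous brain."""
        sol = source_solutions["floating_potential"]
        for th in (0.0, 120.0, 250.0):
            phi = np.radians(th)
            rr = np.linspace(2.0, 40.0, 25)
            pts = np.stack([rr * np.cos(phi), rr * np.sin(phi),
                            np.full_like(rr, 2.75)], axis=1)
            v = np.abs(sol.interpolate(pts))
            assert np.all(np.diff(v) < 0)


class TestSourceModels:
    def test_point_source_requires_explicit_contact(self, lead, domain, cond):
        mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(15)),
                             COARSE_MESH)
        system = assemble(mesh, cond, mesh.geometry.variant)
        with pytest.raises(InvalidVariantError):
            apply_point_current_source(system, -1.0)

    def test_current_density_requires_boundary_contact(self, lead, domain, cond):
        mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(1)),
                             COARSE_MESH)
        system = assemble(mesh, cond, mesh.geometry.variant)
        with pytest.raises(InvalidVariantError):
            apply_current_density_source(system, -1.0)

    def test_point_load_sums_to_commanded_current(self, lead, domain, cond):
        mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(1)),
                             COARSE_MESH)
        system = assemble(mesh, cond, mesh.geometry.variant)
        apply_point_current_source(system, -1.0)
        assert system.f.sum() == pytest.approx(-1e-3)
        assert np.count_nonzero(system.f) == 1
        assert system.source_info["snap_offset_mm"] < 0.5

    def test_uniform_flux_load_sums_to_commanded_current(self, source_solutions):
        info = source_solutions["current_density"].source_info
        area = info["surface_area_mm2"]
        assert info["flux_mA_per_mm2"] == pytest.approx(-1.0 / area)

    def test_two_solve_scaling_is_pointwise_linear(self, lead, domain, cond):
        """The rescaled Dirichlet solve equals the seed solve scaled by
        I_target / I_1, and a different seed voltage gives the same field."""
        mesh = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(11)),
                             COARSE_MESH)
        sol, info = solve_electric_potential(mesh, cond, mesh.geometry.variant,
                                             current_mA=-1.0, seed_voltage_V=1.0)
        first = info["first_solution"]
        assert np.allclose(sol.node_potentials,
                           first.node_potentials * info["scale"], atol=1e-9)
        assert sol.active_current_mA == pytest.approx(-1.0, rel=0.01)
        sol2, _ = solve_electric_potential(mesh, cond, mesh.geometry.variant,
                                           current_mA=-1.0, seed_voltage_V=2.0)
        assert np.allclose(sol.node_potentials, sol2.node_potentials, atol=1e-9)

    def test_floating_equals_two_solve_dirichlet(self, lead, domain, cond):
        """Floating-potential and scaled-Dirichlet sources both enforce an
        equipotential contact at the commanded total current, so their fields
        agree on a probe grid."""
        m15 = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(15)),
                            COARSE_MESH)
        m11 = mesh_geometry(build_geometry(lead, domain, VariantSpec.from_model_id(11)),
                            COARSE_MESH)
        s_fl = solve_variant(m15, cond, -1.0, settings=CG)
        s_ep = solve_variant(m11, cond, -1.0, settings=CG)
        pts = np.array([[r * np.cos(p), r * np.sin(p), 2.75 + dz]
                        for r in np.geomspace(1.2, 10, 8)
                        for p in np.radians([0, 90, 200])
                        for dz in (-1.0, 0.0, 1.5)])
        va, vb = s_fl.interpolate(pts), s_ep.interpolate(pts)
        rms = np.sqrt(np.mean((va - vb) ** 2)) / np.sqrt(np.mean(vb ** 2))
        assert rms < 0.01


class TestCurrentDensityMaps:
    def test_imposed_neumann_density_is_exactly_uniform(self, source_solutions):
        sol = source_solutions["current_density"]
        sm = surface_current_density_map(sol)
        expected = sol.source_info["flux_mA_per_mm2"]
        assert np.allclose(sm["jn_mA_mm2"], expected, rtol=1e-9)

    @pytest.mark.parametrize("source", ["boundary_current", "current_density",
                                        "electric_potential", "floating_potential"])
    def test_distributed_sources_are_edge_enhanced(self, source_solutions, source):
        sm = surface_current_density_map(source_solutions[source])
        edge, center = _edge_center_means(sm)
        assert edge / center > 1.0

    def test_point_source_center_peak_on_metal_side(self, source_solutions):
        """The weld-point singularity shows as a metal-side density peak at the
        facets nearest the contact center."""
        sm = surface_current_density_map(source_solutions["point_current"])
        c = sm["centroids"]
        th = np.degrees(np.arctan2(c[:, 1], c[:, 0]))
        center_dist = np.hypot((c[:, 2] - 2.75) / 0.75, th / 45.0)
        jm = np.abs(sm["jn_metal_raw"])
        assert jm[np.argmin(center_dist)] > 1.5 * np.nanmedian(jm)

    def test_side_average_understates_the_contact_current(self, source_solutions):
        """Averaging the two sides of the interior boundary instead of taking
        the jump mis-estimates the delivered current."""
        sol = source_solutions["point_current"]
        avg = integrate_contact_current(sol, "1a", method="average").current_mA
        jump = integrate_contact_current(sol, "1a", method="consistent").current_mA
        assert jump == pytest.approx(-1.0, rel=1e-6)
        assert abs(avg - jump) > 0.01


def _edge_center_means(sm):
    c = sm["centroids"]
    th = np.degrees(np.arctan2(c[:, 1], c[:, 0]))
    edge = ((np.abs(c[:, 2] - 2.0) < 0.2) | (np.abs(c[:, 2] - 3.5) < 0.2)
            | (np.abs(th + 45) < 8) | (np.abs(th - 45) < 8))
    center = np.hypot((c[:, 2] - 2.75) / 0.75, th / 45.0) < 0.35
    jm = sm["jmag_mA_mm2"]
    return jm[edge].mean(), jm[center].mean()


class TestAnalyticOracle:
    def test_far_field_matches_monopole(self, oracle_solution):
        """Lead-free control: FEM potential vs I/(4 pi sigma r); the closed
        form gives -0.0796 V at 5 mm for -1 mA in 0.2 S/m."""
        p = oracle_solution.source_point + np.array([5.0, 0.0, 0.0])
        v = oracle_solution.interpolate(p[None])[0]
        assert v == pytest.approx(-0.0796, rel=0.02)
        assert point_source_potential(p[None], oracle_solution.source_point,
                                      -1.0, 0.2)[0] == pytest.approx(-0.07958, rel=1e-3)

    def test_monopole_scaling_linearity(self):
        pts = np.array([[3.0, 1.0, -2.0], [0.5, 0.5, 8.0]])
        src = np.zeros(3)
        v1 = point_source_potential(pts, src, -1.0, 0.2)
        v2 = point_source_potential(pts, src, -3.0, 0.2)
        assert np.allclose(v2, 3 * v1)


class TestDeterminism:
    def test_repeat_solve_is_bitwise_identical(self, lead, domain, cond):
        v = VariantSpec.from_model_id(7)
        a = solve_variant(mesh_geometry(build_geometry(lead, domain, v), COARSE_MESH),
                          cond, -1.0)
        b = solve_variant(mesh_geometry(build_geometry(lead, domain, v), COARSE_MESH),
                          cond, -1.0)
        assert np.array_equal(a.node_potentials, b.node_potentials)
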