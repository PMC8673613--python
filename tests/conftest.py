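"""Shared fixtures: solved reference fields, the analytic-oracle control, and
the reduced-scale variant matrix (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from dbsfield import (
    ConductivityMap,
    DomainSpec,
    GridSpec,
    LeadSpec,
    RunConfig,
    VariantSpec,
)
from dbsfield.fixtures import axon_bundle, lead_free_mesh
from dbsfield.geometry import build_geometry, mesh_geometry
from dbsfield.solver import solve_homogeneous_point_source, solve_variant

#: one representative variant per current-source implementation
SOURCE_REPRESENTATIVES = {
    "point_current": 1,
    "boundary_current": 4,
    "current_density": 7,
    "electric_potential": 11,
    "floating_potential": 15,
}


@pytest.fixture(scope="session")
def lead():
    return LeadSpec()


@pytest.fixture(scope="session")
def domain():
    return DomainSpec()


@pytest.fixture(scope="session")
def cond():
    return ConductivityMap()


@pytest.fixture(scope="session")
def default_meshes(lead, domain):
    """Default-resolution meshes for the representative variants (built lazily)."""
    cache = {}

    def get(mid: int):
        if mid not in cache:
            cache[mid] = mesh_geometry(
                build_geometry(lead, domain, VariantSpec.from_model_id(mid))
            )
        return cache[mid]

    return get


@pytest.fixture(scope="session")
def source_solutions(default_meshes, cond):
    """Solved voltage distributions (default mesh, -1 mA on contact 1a) for one
    representative variant of each of the five current sources."""
    return {name: solve_variant(default_meshes(mid), cond, current_mA=-1.0)
            for name, mid in SOURCE_REPRESENTATIVES.items()}


@pytest.fixture(scope="session")
def oracle_solution():
    """Point source in the lead-free homogeneous domain (absorbing boundary)."""
    mesh = lead_free_mesh()
    return solve_homogeneous_point_source(mesh, current_mA=-1.0, sigma_S_per_m=0.2)


@pytest.fixture(scope="session")
def bundle():
    """Three analytic-field axons for cable-stage tests without FEM."""
    return axon_bundle(seed=1)


@pytest.fixture(scope="session")
def matrix_config():
    """Reduced-scale configuration for the full 15-variant matrix."""
    return RunConfig(grid=GridSpec(r_min=1.5, r_max=8.0, n_radii=8,
                                   axial_offsets=(0.0,), n_azimuths=8))


@pytest.fixture(scope="session")
def matrix_report(matrix_config):
    from dbsfield.comparison import run_matrix

    return run_matrix(matrix_config)
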