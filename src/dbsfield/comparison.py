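"""Side-by-side comparison of the volume-conductor model variants.

Runs geometry -> mesh -> solve -> axon thresholds for each selected variant
with the SAME axon grid and identically discretized active-contact surface,
then reports voltage-difference maps on the perpendicular axon grid, per-axon
threshold errors, and population activation errors relative to the reference
(fully explicit, point-source Model #1).  Build/mesh/solve wall times are
recorded per stage for context; they are hardware-dependent and never part of
any acceptance decision.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, VariantSpec
from .geometry import build_geometry, mesh_geometry
from .population import (
    ActivationSummary,
    AxonGrid,
    ThresholdResult,
    activation_summary,
    attach_grid_field,
    build_grid,
    find_thresholds,
)
from .solver import FieldSolution, solve_variant


class NormalizationError(ValueError):
    """Voltage fields compared at different commanded currents."""


@dataclass
class VariantOutcome:
    """Everything measured for one model variant."""

    model_id: int
    ok: bool
    error: str = ""
    solution: Optional[FieldSolution] = None
    thresholds: Optional[list] = None
    summary: Optional[ActivationSummary] = None
    probe_voltages_V: Optional[np.ndarray] = None
    contact_signature: str = ""
    timing_s: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Matrix results relative to the reference variant."""

    reference_id: int
    active_contact_id: str
    amplitude_mA: float
    outcomes: dict                    # model_id -> VariantOutcome
    grid: AxonGrid
    probe_points: np.ndarray
    voltage_diff: pd.DataFrame        # per variant: min/mean/max difference stats
    threshold_errors: pd.DataFrame    # per (variant, axon): % error
    population_errors: pd.DataFrame   # per variant: % error of counts and volume

    def max_individual_error_pct(self) -> float:
        e = self.threshold_errors
        e = e[e.model_id != self.reference_id]
        return float(np.nanmax(np.abs(e.threshold_error_pct))) if len(e) else np.nan

    def max_population_error_pct(self) -> float:
        e = self.population_errors
        e = e[e.model_id != self.reference_id]
        if not len(e):
            return np.nan
        return float(np.nanmax(np.abs(e[["n_active_error_pct", "volume_error_pct"]]
                                      .to_numpy())))


def voltage_difference_map(ref: FieldSolution, other: FieldSolution,
                           probe_points: np.ndarray,
                           exclusion_radius_mm: float = 0.0) -> dict:
    """Signed voltage difference V_other - V_ref on a probe grid.

    Probes within ``exclusion_radius_mm`` of either solution's point-source
    vertex are dropped (FEM point loads are not pointwise convergent at the
    load).  Raises NormalizationError for fields at different commanded currents.
    """
    if not np.isclose(ref.commanded_current_mA, other.commanded_current_mA):
        raise NormalizationError(
            f"commanded currents differ: {ref.commanded_current_mA} vs "
            f"{other.commanded_current_mA} mA"
        )
    pts = np.atleast_2d(probe_points)
    keep = np.ones(len(pts), dtype=bool)
    for sol in (ref, other):
        node = sol.source_info.get("node")
        if node is not None and exclusion_radius_mm > 0:
            src = sol.mesh.vertices[node]
            keep &= np.linalg.norm(pts - src, axis=1) > exclusion_radius_mm
    pts = pts[keep]
    v_ref = ref.interpolate(pts)
    v_other = other.interpolate(pts)
    diff = v_other - v_ref
    scale = np.max(np.abs(v_ref))
    rel_pct = 100.0 * diff / scale
    return {
        "points": pts, "kept": keep, "difference_V": diff,
        "relative_pct_of_peak": rel_pct,
        "stats": {
            "min_V": float(diff.min()), "mean_V": float(diff.mean()),
            "max_V": float(diff.max()),
            "max_abs_pct": float(np.max(np.abs(rel_pct))),
            "rms_pct": float(np.sqrt(np.mean(rel_pct ** 2))),
        },
    }


def threshold_error(ref_thresholds: Sequence[ThresholdResult],
                    var_thresholds: Sequence[ThresholdResult]) -> pd.DataFrame:
    """Per-axon threshold error 100*(T_v - T_ref)/T_ref for matched axon ids."""
    ref = {t.axon_id: t for t in ref_thresholds}
    rows = []
    for t in var_thresholds:
        if t.axon_id not in ref:
            raise ValueError(f"axon id {t.axon_id} missing from the reference set")
        r = ref[t.axon_id]
        if r.converged and t.converged:
            err = 100.0 * (t.threshold_mA - r.threshold_mA) / r.threshold_mA
            rows.append(dict(axon_id=t.axon_id, threshold_mA=t.threshold_mA,
                             ref_threshold_mA=r.threshold_mA, threshold_error_pct=err))
    return pd.DataFrame(rows)


def run_matrix(config: RunConfig, model_ids: Optional[Sequence[int]] = None,
               point_source_exclusion_mm: float = 0.0) -> ComparisonReport:
    """Execute the variant matrix and assemble the comparison report.

    The axon grid is built once and re-attached to each variant's field; any
    stage failure marks that variant failed and the matrix continues.
    """
    ids = list(model_ids) if model_ids is not None else list(range(1, 16))
    ref_id = ids[0]
    cid = config.variant.active_contact_id
    amplitude = abs(config.source.current_mA)

    grid = build_grid(config.grid, config.lead, config.domain, cid, config.fiber)
    # voltage probes: compartment centers of the facing-azimuth plane
    probe_points = np.concatenate(
        [grid.axons[s.axon_id].coords for s in grid.sites if not s.in_rotated_subset]
        or [grid.axons[s.axon_id].coords for s in grid.sites]
    )

    outcomes: dict[int, VariantOutcome] = {}
    for mid in ids:
        out = VariantOutcome(model_id=mid, ok=False)
        outcomes[mid] = out
        try:
            variant = VariantSpec.from_model_id(mid, cid)
            t0 = time.perf_counter()
            geo = build_geometry(config.lead, config.domain, variant)
            t1 = time.perf_counter()
            mesh = mesh_geometry(geo, config.mesh)
            t2 = time.perf_counter()
            sol = solve_variant(mesh, config.conductivity,
                                current_mA=config.source.current_mA,
                                seed_voltage_V=config.source.dirichlet_seed_V,
                                settings=config.solver)
            t3 = time.perf_counter()
            attach_grid_field(grid, sol, i_ref_mA=config.source.current_mA)
            thresholds = find_thresholds(grid, config.waveform)
            t4 = time.perf_counter()
            out.solution = sol
            out.thresholds = thresholds
            out.summary = activation_summary(thresholds, grid, amplitude)
            out.probe_voltages_V = sol.interpolate(probe_points)
            out.contact_signature = mesh.contact_surface_signature()
            out.timing_s = dict(build=t1 - t0, mesh=t2 - t1, solve=t3 - t2,
                                thresholds=t4 - t3)
            out.ok = True
        except Exception as exc:  # variant failures must not stop the matrix
            out.error = f"{type(exc).__name__}: {exc}"

    ref = outcomes[ref_id]
    if not ref.ok:
        raise RuntimeError(f"reference variant #{ref_id} failed: {ref.error}")

    vrows, trows, prows = [], [], []
    for mid in ids:
        out = outcomes[mid]
        if not out.ok:
            continue
        vd = voltage_difference_map(ref.solution, out.solution, probe_points,
                                    exclusion_radius_mm=point_source_exclusion_mm)
        vrows.append(dict(model_id=mid, **vd["stats"]))
        te = threshold_error(ref.thresholds, out.thresholds)
        te.insert(0, "model_id", mid)
        trows.append(te)
        n_ref, v_ref = ref.summary.n_active, ref.summary.activation_volume_mm3
        prows.append(dict(
            model_id=mid,
            n_active=out.summary.n_active,
            activation_volume_mm3=out.summary.activation_volume_mm3,
            n_active_error_pct=(100.0 * (out.summary.n_active - n_ref) / n_ref
                                if n_ref else np.nan),
            volume_error_pct=(100.0 * (out.summary.activation_volume_mm3 - v_ref) / v_ref
                              if v_ref else np.nan),
        ))

    return ComparisonReport(
        reference_id=ref_id, active_contact_id=cid, amplitude_mA=amplitude,
        outcomes=outcomes, grid=grid, probe_points=probe_points,
        voltage_diff=pd.DataFrame(vrows),
        threshold_errors=(pd.concat(trows, ignore_index=True) if trows
                          else pd.DataFrame()),
        population_errors=pd.DataFrame(prows),
    )
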