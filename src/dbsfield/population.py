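"""Axon population grids, activation thresholds, and spread-of-activation metrics.

A planar grid of straight axons perpendicular to the lead is centered on the
active contact, with radii distributed logarithmically away from the
encapsulation; a subset (all radii at the central axial plane) is rotated
around the lead to capture the angular selectivity of directional contacts.
Per-axon activation thresholds come from bisection on the stimulus amplitude;
population metrics are the number of active axons at a given amplitude and an
activation volume from revolving the per-azimuth activation radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.stats import spearmanr

from .axon import AxonInstance, attach_field, build_axon, simulate, simulate_batch
from .config import DomainSpec, FiberSpec, GridSpec, LeadSpec, StimulusWaveform


@dataclass(frozen=True)
class GridAxon:
    """One axon site: cylindrical position relative to the lead axis."""

    axon_id: int
    radius_mm: float          # distance from the lead axis
    axial_offset_mm: float    # relative to the active contact's axial center
    azimuth_deg: float
    in_rotated_subset: bool


@dataclass
class AxonGrid:
    """Population of perpendicular axons around the active contact."""

    spec: GridSpec
    lead: LeadSpec
    active_contact_id: str
    sites: list                      # list[GridAxon]
    axons: list                      # list[AxonInstance], same order
    contact_center: np.ndarray       # surface center of the active contact (mm)

    def __len__(self) -> int:
        return len(self.sites)

    def distances_to_contact(self) -> np.ndarray:
        centers = np.array([ax.center for ax in self.axons])
        return np.linalg.norm(centers - self.contact_center, axis=1)


def build_grid(spec: GridSpec, lead: LeadSpec, domain: DomainSpec,
               active_contact_id: str, fiber: FiberSpec) -> AxonGrid:
    """Build the perpendicular axon population for one active contact.

    The planar grid lies at the contact's azimuth (radii x axial offsets); the
    rotated subset replicates the central-offset radii at ``n_azimuths`` evenly
    spaced azimuths.  Radii are geometrically (log-)spaced in
    [r_min, r_max] and must clear the encapsulation layer.
    """
    r_inner = lead.lead_radius + domain.encapsulation_thickness
    if spec.r_min <= r_inner:
        raise ValueError(
            f"r_min={spec.r_min} mm must lie outside the encapsulation "
            f"(> {r_inner} mm)"
        )
    cx, cy, cz = lead.contact_center(active_contact_id)
    facing_az = round(float(np.degrees(np.arctan2(cy, cx))) % 360.0, 6) % 360.0
    radii = np.geomspace(spec.r_min, spec.r_max, spec.n_radii)
    rot_az = (np.arange(spec.n_azimuths) * 360.0 / spec.n_azimuths) % 360.0
    mid_dz = spec.axial_offsets[len(spec.axial_offsets) // 2]

    seen = {}
    sites: list[GridAxon] = []
    for dz in spec.axial_offsets:
        for r in radii:
            seen[(round(r, 9), round(dz, 9), round(facing_az, 6))] = False
            sites.append(GridAxon(0, float(r), float(dz), facing_az, False))
    for az in rot_az:
        for r in radii:
            key = (round(r, 9), round(mid_dz, 9), round(float(az), 6))
            if key in seen:
                # the facing-azimuth central row belongs to both sets
                for i, s in enumerate(sites):
                    if (round(s.radius_mm, 9), round(s.axial_offset_mm, 9),
                            round(s.azimuth_deg, 6)) == key:
                        sites[i] = GridAxon(0, s.radius_mm, s.axial_offset_mm,
                                            s.azimuth_deg, True)
                continue
            seen[key] = True
            sites.append(GridAxon(0, float(r), mid_dz, float(az), True))
    sites = [GridAxon(i, s.radius_mm, s.axial_offset_mm, s.azimuth_deg,
                      s.in_rotated_subset) for i, s in enumerate(sites)]

    span = (fiber.n_nodes - 1) * fiber.internode_length * 1e-3
    axons = []
    for s in sites:
        phi = np.radians(s.azimuth_deg)
        center = np.array([s.radius_mm * np.cos(phi), s.radius_mm * np.sin(phi),
                           cz + s.axial_offset_mm])
        direction = np.array([-np.sin(phi), np.cos(phi), 0.0])
        start = center - 0.5 * span * direction
        axons.append(build_axon(fiber, start, direction, span))
    return AxonGrid(spec=spec, lead=lead, active_contact_id=active_contact_id,
                    sites=sites, axons=axons, contact_center=np.array([cx, cy, cz]))


def attach_grid_field(grid: AxonGrid, field_source, i_ref_mA: float = -1.0) -> AxonGrid:
    """Attach a field solution (or callable) to every axon of the grid."""
    grid.axons = [attach_field(ax, field_source, i_ref_mA) for ax in grid.axons]
    return grid


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class ThresholdResult:
    """Bisection outcome for one axon (cathodic amplitude magnitude, mA)."""

    axon_id: int
    threshold_mA: float
    converged: bool
    bracket_mA: tuple[float, float]
    reason: str = ""

    @property
    def bracket_rel_width(self) -> float:
        lo, hi = self.bracket_mA
        mid = 0.5 * (lo + hi)
        return (hi - lo) / mid if mid > 0 else np.inf


class BracketAnomalyError(RuntimeError):
    """Activation at the low end of the search range but not at the high end."""


def find_threshold(axon: AxonInstance, waveform: StimulusWaveform,
                   search_range_mA: tuple[float, float] = (0.05, 10.0),
                   tol: float = 0.01, axon_id: int = 0,
                   dt_ms: float = 0.002) -> ThresholdResult:
    """Bisect the cathodic amplitude magnitude to the activation threshold.

    The returned threshold is the midpoint of the final bracket at relative
    width <= tol.  Out-of-range axons are reported unconverged with a reason
    rather than raising; an inverted response (active at the minimum but not
    the maximum) raises BracketAnomalyError.
    """
    lo, hi = search_range_mA

    def activated(mag: float) -> bool:
        wf = waveform.model_copy(update=dict(amplitude_mA=-abs(mag)))
        return simulate(axon, wf, dt_ms=dt_ms).activated

    act_lo, act_hi = activated(lo), activated(hi)
    if act_lo and not act_hi:
        raise BracketAnomalyError(
            f"axon {axon_id}: activated at {lo} mA but not at {hi} mA"
        )
    if act_lo:
        return ThresholdResult(axon_id, lo, False, (lo, lo),
                               reason="lower bound already activating")
    if not act_hi:
        return ThresholdResult(axon_id, hi, False, (hi, hi),
                               reason="upper bound not activating")
    while (hi - lo) / (0.5 * (hi + lo)) > tol:
        mid = 0.5 * (lo + hi)
        if activated(mid):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(axon_id, 0.5 * (lo + hi), True, (lo, hi))


def find_thresholds(grid_or_axons: Union[AxonGrid, Sequence[AxonInstance]],
                    waveform: StimulusWaveform,
                    search_range_mA: tuple[float, float] = (0.05, 10.0),
                    tol: float = 0.01, dt_ms: float = 0.002) -> list:
    """Population thresholds via batched bisection (all axons advance together).

    Equivalent to per-axon :func:`find_threshold` (same bisection on the same
    activation decisions) but runs the whole population through the vectorized
    cable integrator at each bisection step.  Axons outside the search range --
    including ones already active at the floor yet blocked at the ceiling --
    are reported unconverged with a reason instead of raising.
    """
    axons = grid_or_axons.axons if isinstance(grid_or_axons, AxonGrid) else list(grid_or_axons)
    n = len(axons)
    lo0, hi0 = search_range_mA

    def batch_activated(mags: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        idx = np.nonzero(mask)[0]
        if len(idx):
            out[idx] = simulate_batch([axons[i] for i in idx], waveform,
                                      -np.abs(mags[idx]), dt_ms=dt_ms)
        return out

    every = np.ones(n, dtype=bool)
    act_lo = batch_activated(np.full(n, lo0), every)
    act_hi = batch_activated(np.full(n, hi0), every)
    # axons active at the floor but blocked at the ceiling (conduction block at
    # extreme amplitudes very close to the lead) are classified by their floor
    # response: the threshold lies below the search range
    lo = np.full(n, lo0)
    hi = np.full(n, hi0)
    open_mask = ~act_lo & act_hi
    while True:
        rel = (hi - lo) / (0.5 * (hi + lo))
        todo = open_mask & (rel > tol)
        if not todo.any():
            break
        mid = 0.5 * (lo + hi)
        act = batch_activated(mid, todo)
        hi = np.where(todo & act, mid, hi)
        lo = np.where(todo & ~act, mid, lo)

    results = []
    for i in range(n):
        if act_lo[i]:
            results.append(ThresholdResult(i, lo0, False, (lo0, lo0),
                                           reason="lower bound already activating"))
        elif not act_hi[i]:
            results.append(ThresholdResult(i, hi0, False, (hi0, hi0),
                                           reason="upper bound not activating"))
        else:
            results.append(ThresholdResult(i, 0.5 * (lo[i] + hi[i]), True,
                                           (float(lo[i]), float(hi[i]))))
    return results


# ---------------------------------------------------------------------------
# population metrics


def current_distance_curve(thresholds: Sequence[ThresholdResult], grid: AxonGrid,
                           azimuth_deg: Optional[float] = None) -> dict:
    """(distance, threshold) pairs sorted by distance to the active contact
    center, with a Spearman monotonicity statistic.

    ``azimuth_deg`` restricts the curve to one azimuth (e.g. the facing
    azimuth); default uses every converged axon.
    """
    conv = [t for t in thresholds if t.converged]
    if len(conv) < 2:
        raise ValueError("need at least 2 converged thresholds")
    dist = grid.distances_to_contact()
    rows = []
    for t in conv:
        s = grid.sites[t.axon_id]
        if azimuth_deg is not None and not np.isclose(s.azimuth_deg, azimuth_deg % 360.0):
            continue
        rows.append((dist[t.axon_id], t.threshold_mA))
    if len(rows) < 2:
        raise ValueError("fewer than 2 converged thresholds at the requested azimuth")
    rows.sort()
    d, th = np.array(rows).T
    rho = float(spearmanr(d, th).statistic)
    return {"distance_mm": d, "threshold_mA": th, "spearman_rho": rho}


@dataclass
class ActivationSummary:
    """Spread of activation at one stimulus amplitude."""

    amplitude_mA: float
    n_active: int
    activation_volume_mm3: float
    estimator: str = "sector_revolve"


def activation_summary(thresholds: Sequence[ThresholdResult], grid: AxonGrid,
                       amplitude_mA: float, estimator: str = "sector_revolve"
                       ) -> ActivationSummary:
    """Count active axons and estimate the activation volume at an amplitude.

    ``sector_revolve`` takes, per rotated-subset azimuth, the largest activated
    radius and integrates sector-wise (0.5 * dtheta * r^2 * dz); the
    ``convex_hull`` alternative wraps all activated axon centers.
    """
    mag = abs(amplitude_mA)
    thr = {t.axon_id: t for t in thresholds}
    active_ids = [t.axon_id for t in thresholds
                  if t.converged and t.threshold_mA <= mag]
    # axons activating below the search floor are certainly active at any
    # amplitude at or above the floor
    active_ids += [t.axon_id for t in thresholds
                   if not t.converged and t.reason == "lower bound already activating"
                   and mag >= t.threshold_mA]
    n_active = len(active_ids)

    if estimator == "sector_revolve":
        rot = [grid.sites[i] for i in active_ids if grid.sites[i].in_rotated_subset]
        by_az: dict[float, float] = {}
        for s in rot:
            by_az[s.azimuth_deg] = max(by_az.get(s.azimuth_deg, 0.0), s.radius_mm)
        dtheta = 2.0 * np.pi / grid.spec.n_azimuths
        dz = grid.spec.slab_thickness
        vol = sum(0.5 * dtheta * r * r * dz for r in by_az.values())
    elif estimator == "convex_hull":
        pts = np.array([grid.axons[i].center for i in active_ids])
        vol = 0.0
        if len(pts) >= 4:
            from scipy.spatial import ConvexHull, QhullError
            try:
                vol = float(ConvexHull(pts).volume)
            except QhullError:
                vol = 0.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return ActivationSummary(amplitude_mA=amplitude_mA, n_active=n_active,
                             activation_volume_mm3=float(vol), estimator=estimator)
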