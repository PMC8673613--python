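"""Configuration and specification types for the DBS field-cable pipeline.

Units convention (external API): lengths mm, currents mA, potentials V,
conductivities S/m, times of stimulus pulses in microseconds, membrane
dynamics in ms/mV.  Internally the Laplace solve uses mm / S/mm / A / V so
that assembled conductances multiply node potentials in volts to give amps.
"""

from __future__ import annotations

import enum
import math
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SourceType(str, enum.Enum):
    """How the active contact drives current into the tissue."""

    point_current = "point_current"
    boundary_current = "boundary_current"
    current_density = "current_density"
    electric_potential = "electric_potential"
    floating_potential = "floating_potential"


class Rep(str, enum.Enum):
    """Geometry representation of a lead component: meshed domain or labeled surface."""

    explicit = "explicit"
    boundary = "boundary"


#: The 15 admissible (source, active rep, inactive rep, shaft rep) combinations.
#: Point and boundary current sources need an explicit active-contact domain;
#: the current-density source is only applicable to an exterior (boundary) contact.
VARIANT_TABLE: dict[int, tuple[SourceType, Rep, Rep, Rep]] = {
    1: (SourceType.point_current, Rep.explicit, Rep.explicit, Rep.explicit),
    2: (SourceType.point_current, Rep.explicit, Rep.explicit, Rep.boundary),
    3: (SourceType.point_current, Rep.explicit, Rep.boundary, Rep.boundary),
    4: (SourceType.boundary_current, Rep.explicit, Rep.explicit, Rep.explicit),
    5: (SourceType.boundary_current, Rep.explicit, Rep.explicit, Rep.boundary),
    6: (SourceType.boundary_current, Rep.explicit, Rep.boundary, Rep.boundary),
    7: (SourceType.current_density, Rep.boundary, Rep.boundary, Rep.boundary),
    8: (SourceType.electric_potential, Rep.explicit, Rep.explicit, Rep.explicit),
    9: (SourceType.electric_potential, Rep.explicit, Rep.explicit, Rep.boundary),
    10: (SourceType.electric_potential, Rep.explicit, Rep.boundary, Rep.boundary),
    11: (SourceType.electric_potential, Rep.boundary, Rep.boundary, Rep.boundary),
    12: (SourceType.floating_potential, Rep.explicit, Rep.explicit, Rep.explicit),
    13: (SourceType.floating_potential, Rep.explicit, Rep.explicit, Rep.boundary),
    14: (SourceType.floating_potential, Rep.explicit, Rep.boundary, Rep.boundary),
    15: (SourceType.floating_potential, Rep.boundary, Rep.boundary, Rep.boundary),
}

#: Contact identifiers, tip to shaft: tip contact, two rows of three directional
#: segments (row 1 distal), and the cylindrical ring.
CONTACT_IDS: tuple[str, ...] = ("tip", "1a", "1b", "1c", "2a", "2b", "2c", "ring")

#: CLI shorthand "a".."f" for the six directional segments.
DIRECTIONAL_ALIASES = {
    "a": "1a", "b": "1b", "c": "1c", "d": "2a", "e": "2b", "f": "2c",
    "cylinder": "ring", "tip": "tip", "ring": "ring",
}


class InvalidVariantError(ValueError):
    """Raised for (source, representation) combinations outside the 15 valid rows."""


class LeadSpec(BaseModel):
    """Parametric geometry of the 8-contact directional lead.

    One tip contact, two rows of three 90-degree directional segments, and one
    cylindrical ring contact, on a 1.3 mm-diameter lead body.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    lead_radius: float = 0.65
    tip_contact_length: float = 1.5
    ring_contact_length: float = 1.5
    inter_contact_gap: float = 0.5
    segment_arc: float = 90.0          # degrees per directional segment
    segments_per_row: int = 3
    n_rows: int = 2
    contact_thickness: float = 0.1     # radial depth of explicit contact shells
    shaft_length: float = 20.0

    @model_validator(mode="after")
    def _check(self) -> "LeadSpec":
        lengths = (
            self.lead_radius, self.tip_contact_length, self.ring_contact_length,
            self.inter_contact_gap, self.contact_thickness, self.shaft_length,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lead dimensions must be positive")
        if self.segment_arc * self.segments_per_row >= 360.0:
            raise ValueError("segment arcs must leave nonzero gaps between segments")
        if self.segments_per_row != 3 or self.n_rows != 2:
            raise ValueError("the lead has 3 directional contacts per row and 2 rows")
        if self.contact_thickness >= self.lead_radius:
            raise ValueError("contact shell thicker than the lead radius")
        n_bands = 1 + self.n_rows + 1  # tip + rows + ring
        min_shaft = n_bands * self.tip_contact_length + (n_bands - 1) * self.inter_contact_gap
        if self.shaft_length < min_shaft:
            raise ValueError("shaft too short to carry all contacts")
        return self

    # --- axial extents (z from the tip at the origin, axis = +z) ---

    def contact_extents(self) -> dict[str, tuple[float, float, Optional[tuple[float, float]]]]:
        """Map contact id -> (z0, z1, (theta0, theta1) in degrees or None for full bands)."""
        out: dict[str, tuple[float, float, Optional[tuple[float, float]]]] = {}
        z = 0.0
        out["tip"] = (z, z + self.tip_contact_length, None)
        z += self.tip_contact_length + self.inter_contact_gap
        half = self.segment_arc / 2.0
        pitch = 360.0 / self.segments_per_row
        for row in (1, 2):
            for k, label in enumerate("abc"):
                th0 = (k * pitch - half) % 360.0
                out[f"{row}{label}"] = (z, z + self.ring_contact_length, (th0, (th0 + self.segment_arc) % 360.0))
            z += self.ring_contact_length + self.inter_contact_gap
        out["ring"] = (z, z + self.ring_contact_length, None)
        return out

    def contact_center(self, contact_id: str) -> tuple[float, float, float]:
        """Cartesian center of a contact's outer surface (mm)."""
        z0, z1, arc = self.contact_extents()[contact_id]
        zc = 0.5 * (z0 + z1)
        if arc is None:
            return (self.lead_radius, 0.0, zc)  # reference azimuth for full bands
        th0, th1 = arc
        if th1 < th0:
            th1 += 360.0
        thc = math.radians(0.5 * (th0 + th1))
        return (self.lead_radius * math.cos(thc), self.lead_radius * math.sin(thc), zc)

    def analytic_contact_area(self, contact_id: str) -> float:
        """Lateral cylindrical area of a contact (mm^2)."""
        z0, z1, arc = self.contact_extents()[contact_id]
        frac = 1.0 if arc is None else self.segment_arc / 360.0
        return 2.0 * math.pi * self.lead_radius * frac * (z1 - z0)


class DomainSpec(BaseModel):
    """Simplified homogeneous brain domain bounding the lead.

    A cylinder of radius/half-height ``brain_radius`` stands in for head anatomy;
    the boundary is insulated apart from either a small grounded patch opposite
    the lead tip or an absorbing (infinite-medium) Robin condition.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    encapsulation_thickness: float = 0.5
    brain_radius: float = 50.0
    ground_patch_radius: float = 10.0
    outer_bc: str = "ground_patch"  # "ground_patch" | "absorbing"

    @model_validator(mode="after")
    def _check(self) -> "DomainSpec":
        if self.encapsulation_thickness <= 0:
            raise ValueError("encapsulation_thickness must be positive")
        if self.outer_bc not in ("ground_patch", "absorbing"):
            raise ValueError("outer_bc must be 'ground_patch' or 'absorbing'")
        return self

    def validate_against(self, lead: LeadSpec) -> None:
        if self.brain_radius < 25.0 * lead.lead_radius:
            raise ValueError("brain_radius must be >= 25 x lead_radius (far-field boundary)")


class VariantSpec(BaseModel):
    """One row of the 15-variant model matrix plus the driven contact."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    model_id: int
    source_type: SourceType
    active_contact_rep: Rep
    inactive_contacts_rep: Rep
    shaft_rep: Rep
    active_contact_id: str = "1a"

    @model_validator(mode="after")
    def _check(self) -> "VariantSpec":
        row = VARIANT_TABLE.get(self.model_id)
        if row is None:
            raise InvalidVariantError(f"model_id must be 1..15, got {self.model_id}")
        if row != (self.source_type, self.active_contact_rep,
                   self.inactive_contacts_rep, self.shaft_rep):
            raise InvalidVariantError(
                f"({self.source_type.value}, {self.active_contact_rep.value}, "
                f"{self.inactive_contacts_rep.value}, {self.shaft_rep.value}) is not "
                f"row {self.model_id} of the variant table; e.g. a current-density "
                "source requires a boundary active contact and point/boundary current "
                "sources require an explicit one"
            )
        if self.active_contact_id not in CONTACT_IDS:
            raise ValueError(f"unknown contact id {self.active_contact_id!r}")
        return self

    @classmethod
    def from_model_id(cls, model_id: int, active_contact_id: str = "1a") -> "VariantSpec":
        row = VARIANT_TABLE.get(model_id)
        if row is None:
            raise InvalidVariantError(f"model_id must be 1..15, got {model_id}")
        src, act, inact, shaft = row
        active_contact_id = DIRECTIONAL_ALIASES.get(active_contact_id, active_contact_id)
        return cls(model_id=model_id, source_type=src, active_contact_rep=act,
                   inactive_contacts_rep=inact, shaft_rep=shaft,
                   active_contact_id=active_contact_id)


class ConductivityMap(BaseModel):
    """Per-region isotropic conductivities in S/m."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    brain: float = 0.2
    encapsulation: float = 0.13
    contact: float = 5.3e6   # platinum/iridium
    shaft: float = 1e-16     # insulator

    @model_validator(mode="after")
    def _check(self) -> "ConductivityMap":
        if min(self.brain, self.encapsulation, self.contact, self.shaft) <= 0:
            raise ValueError("conductivities must be positive")
        return self


class SourceSpec(BaseModel):
    """Stimulus drive for the volume-conductor solve (cathodic current is negative)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    current_mA: float = -1.0
    dirichlet_seed_V: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "SourceSpec":
        if self.current_mA == 0:
            raise ValueError("stimulus current must be nonzero")
        return self


class MeshSettings(BaseModel):
    """Structured-mesh sizing.  The lattice (z planes, radial rings, azimuthal
    divisions) is identical for all 15 variants, so the active-contact surface
    discretization matches across the matrix by construction."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    axial_size: float = 0.375      # mm, near the contacts
    theta_divisions: int = 24      # azimuthal divisions (must resolve segment edges)
    radial_growth: float = 1.45    # geometric growth of radial rings into the brain
    axial_growth: float = 1.55     # geometric growth of axial planes away from the lead
    near_margin: float = 1.5       # mm of near-field uniform axial sizing beyond the contacts
    inner_rings: int = 2           # rings inside the contact shell radius (>=1)

    @model_validator(mode="after")
    def _check(self) -> "MeshSettings":
        if self.axial_size <= 0 or self.radial_growth <= 1 or self.axial_growth <= 1:
            raise ValueError("mesh sizes must be positive and growth ratios > 1")
        if self.theta_divisions < 8 or self.theta_divisions % 4:
            raise ValueError("theta_divisions must be a multiple of 4, >= 8")
        if self.inner_rings < 1:
            raise ValueError("inner_rings must be >= 1")
        return self

    def refined(self, factor: float = 0.5) -> "MeshSettings":
        """Scaled copy: factor < 1 refines every characteristic size."""
        n_theta = int(round(self.theta_divisions / factor / 4.0)) * 4
        return self.model_copy(update=dict(
            axial_size=self.axial_size * factor,
            theta_divisions=n_theta,
            radial_growth=1.0 + (self.radial_growth - 1.0) * factor,
            axial_growth=1.0 + (self.axial_growth - 1.0) * factor,
        ))


class FiberSpec(BaseModel):
    """Myelinated axon cable model parameters (MRG-style, 37 C).

    Nodes of Ranvier carry fast Na+, persistent Na+, slow K+ and leak channels;
    internodes are passive, with the myelin sheath and internodal axolemma
    combined in series into a single-cable RC wall.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    fiber_diameter: float = 5.7       # um
    internode_length: float = 500.0   # um, node-to-node spacing
    n_nodes: int = 21
    node_length: float = 1.0          # um
    node_diameter: float = 1.9        # um
    mysa_length: float = 3.0          # um, paranodal attachment segment
    flut_length: float = 35.0         # um, paranodal main segment
    n_stin: int = 6                   # internodal segments between paranodes
    internode_diameter: float = 3.4   # um, axon diameter under the myelin
    n_lamellae: int = 80
    rho_axial: float = 70.0           # Ohm*cm
    c_membrane: float = 2.0           # uF/cm^2 (axolemma)
    c_myelin_lamella: float = 0.1     # uF/cm^2 per lamella membrane
    g_myelin_lamella: float = 1e-3    # S/cm^2 per lamella membrane
    g_internode_passive: float = 1e-4 # S/cm^2, internodal axolemma
    g_naf: float = 3.0                # S/cm^2 (node)
    g_nap: float = 0.01               # S/cm^2 (node)
    g_ks: float = 0.08                # S/cm^2 (node)
    g_leak: float = 0.007             # S/cm^2 (node)
    e_na: float = 50.0                # mV
    e_k: float = -90.0                # mV
    e_leak: float = -90.0             # mV
    v_rest: float = -80.0             # mV
    temperature: float = 37.0         # C

    @model_validator(mode="after")
    def _check(self) -> "FiberSpec":
        if self.n_nodes % 2 == 0 or self.n_nodes < 3:
            raise ValueError("n_nodes must be odd and >= 3 (symmetric about the center)")
        if min(self.g_naf, self.g_nap, self.g_ks, self.g_leak) < 0:
            raise ValueError("conductances must be non-negative")
        interior = (2 * self.mysa_length + 2 * self.flut_length + self.node_length)
        if self.internode_length <= interior:
            raise ValueError("internode_length shorter than its paranodal segments")
        return self

    @classmethod
    def mrg(cls, fiber_diameter: float = 5.7, n_nodes: int = 21, **overrides) -> "FiberSpec":
        """Fiber of a tabulated diameter class with matching morphology."""
        try:
            row = MRG_MORPHOLOGY[fiber_diameter]
        except KeyError:
            raise ValueError(
                f"no morphology tabulated for {fiber_diameter} um; "
                f"available: {sorted(MRG_MORPHOLOGY)}"
            ) from None
        return cls(fiber_diameter=fiber_diameter, n_nodes=n_nodes, **row, **overrides)


#: Node-to-node spacing vs fiber diameter, from the standard myelinated-fiber
#: morphology tables used in DBS field-cable studies.
MRG_MORPHOLOGY: dict[float, dict] = {
    5.7: dict(internode_length=500.0, node_diameter=1.9, internode_diameter=3.4,
              flut_length=35.0, n_lamellae=80),
    7.3: dict(internode_length=750.0, node_diameter=2.4, internode_diameter=4.6,
              flut_length=38.0, n_lamellae=100),
    8.7: dict(internode_length=1000.0, node_diameter=2.8, internode_diameter=5.8,
              flut_length=40.0, n_lamellae=110),
    10.0: dict(internode_length=1150.0, node_diameter=3.3, internode_diameter=6.9,
               flut_length=46.0, n_lamellae=120),
}


class StimulusWaveform(BaseModel):
    """Monophasic rectangular stimulus pulse."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: str = "monophasic_rectangular"
    pulse_width_us: float = 60.0
    amplitude_mA: float = -1.0
    onset_delay_us: float = 100.0
    total_time_ms: float = 3.0

    @model_validator(mode="after")
    def _check(self) -> "StimulusWaveform":
        if self.shape != "monophasic_rectangular":
            raise ValueError("only the monophasic rectangular waveform is modeled")
        if self.pulse_width_us <= 0:
            raise ValueError("pulse_width must be positive")
        return self

    def value(self, t_ms) -> "object":
        """Unit-amplitude waveform sampled at time(s) t (ms); in {0, 1}."""
        import numpy as np

        t = np.asarray(t_ms, dtype=float)
        t0 = self.onset_delay_us * 1e-3
        t1 = t0 + self.pulse_width_us * 1e-3
        return ((t >= t0) & (t < t1)).astype(float)


class GridSpec(BaseModel):
    """Perpendicular axon population around the active contact.

    Radii are log-spaced from the encapsulation outward; a subset (all radii at
    ``axial_offsets[len//2]``) is rotated around the lead at ``n_azimuths``
    evenly spaced azimuths to sample the full 3D spread.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    r_min: float = 1.5
    r_max: float = 8.0
    n_radii: int = 10
    axial_offsets: tuple[float, ...] = (-3.0, -1.5, 0.0, 1.5, 3.0)
    n_azimuths: int = 12
    slab_thickness: float = 1.5  # mm, axial extent attributed to each offset in volume sums

    @model_validator(mode="after")
    def _check(self) -> "GridSpec":
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.n_radii < 2 or self.n_azimuths < 1:
            raise ValueError("need at least 2 radii and 1 azimuth")
        return self


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    rtol: float = 1e-10
    method: str = "direct"  # "direct" | "cg"


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults reproduce the reference setup
    (Model #1, directional contact 1a driven at -1 mA, 60 us pulse)."""

    model_config = ConfigDict(extra="forbid")

    lead: LeadSpec = LeadSpec()
    domain: DomainSpec = DomainSpec()
    conductivity: ConductivityMap = ConductivityMap()
    variant: VariantSpec = VariantSpec.from_model_id(1)
    source: SourceSpec = SourceSpec()
    mesh: MeshSettings = MeshSettings()
    fiber: FiberSpec = FiberSpec.mrg(5.7)
    waveform: StimulusWaveform = StimulusWaveform()
    grid: GridSpec = GridSpec()
    solver: SolverSettings = SolverSettings()
    seed: int = 0
    output_dir: str = "output"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        self.domain.validate_against(self.lead)
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; an empty file yields the full-default RunConfig.

    Unknown keys are rejected by schema validation (``extra='forbid'``).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    if "variant" in data and isinstance(data["variant"], dict) and "model_id" in data["variant"]:
        v = dict(data["variant"])
        if set(v) <= {"model_id", "active_contact_id"}:
            data["variant"] = VariantSpec.from_model_id(
                v["model_id"], v.get("active_contact_id", "1a")
            ).model_dump()
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML (round-trips through load_config)."""
    data = cfg.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
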