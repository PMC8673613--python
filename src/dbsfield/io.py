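"""Standard-format export: VTU (VTK XML) and Gmsh MSH v4.1 meshes, CSV tables,
JSON summaries.

The writers emit plain-text versions of the standard formats (ASCII VTU
UnstructuredGrid, ASCII MSH 4.1) so solved fields and labeled meshes can be
inspected in ParaView/gmsh.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import MeshResult
from .solver import FieldSolution

VTK_TETRA = 10


def write_vtu(path: str | Path, mesh: MeshResult,
              point_data: Optional[dict] = None,
              cell_data: Optional[dict] = None) -> Path:
    """Write the mesh (plus optional nodal/element fields) as ASCII .vtu.

    Region labels are always included as integer cell data.
    """
    path = Path(path)
    pts = mesh.vertices
    tets = mesh.tets
    cdata = {"region": mesh.region.astype(np.int32)}
    if cell_data:
        cdata.update(cell_data)
    pdata = dict(point_data or {})

    def arr_to_text(a, per_line=6):
        flat = np.asarray(a).ravel()
        return "\n".join(
            " ".join(f"{v:.10g}" for v in flat[i:i + per_line])
            for i in range(0, len(flat), per_line)
        )

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="1.0" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{len(pts)}" NumberOfCells="{len(tets)}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr_to_text(pts),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        arr_to_text(tets, per_line=8),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        arr_to_text(np.arange(1, len(tets) + 1) * 4, per_line=12),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        arr_to_text(np.full(len(tets), VTK_TETRA, dtype=np.uint8), per_line=24),
        "        </DataArray>",
        "      </Cells>",
    ]
    if pdata:
        lines.append("      <PointData>")
        for name, a in pdata.items():
            lines += [
                f'        <DataArray type="Float64" Name="{name}" format="ascii">',
                arr_to_text(a),
                "        </DataArray>",
            ]
        lines.append("      </PointData>")
    lines.append("      <CellData>")
    for name, a in cdata.items():
        typ = "Int32" if np.issubdtype(np.asarray(a).dtype, np.integer) else "Float64"
        lines += [
            f'        <DataArray type="{typ}" Name="{name}" format="ascii">',
            arr_to_text(a, per_line=12),
            "        </DataArray>",
        ]
    lines += ["      </CellData>", "    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(lines))
    return path


def write_point_cloud_vtu(path: str | Path, points: np.ndarray,
                          point_data: Optional[dict] = None) -> Path:
    """Write a point set (e.g. activated axon centers or probe-grid difference
    fields) as an ASCII .vtu of vertex cells."""
    path = Path(path)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)

    def txt(a, per_line=6):
        flat = np.asarray(a).ravel()
        return "\n".join(" ".join(f"{v:.10g}" for v in flat[i:i + per_line])
                         for i in range(0, len(flat), per_line))

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="1.0" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{n}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        txt(pts),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        txt(np.arange(n), per_line=12),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        txt(np.arange(1, n + 1), per_line=12),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        txt(np.ones(n, dtype=np.uint8), per_line=24),  # VTK_VERTEX
        "        </DataArray>",
        "      </Cells>",
    ]
    if point_data:
        lines.append("      <PointData>")
        for name, a in point_data.items():
            lines += [
                f'        <DataArray type="Float64" Name="{name}" format="ascii">',
                txt(a),
                "        </DataArray>",
            ]
        lines.append("      </PointData>")
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(lines))
    return path


def write_field_vtu(path: str | Path, sol: FieldSolution) -> Path:
    """Solved field as .vtu: nodal V_e (volts) plus region labels."""
    return write_vtu(path, sol.mesh, point_data={"Ve_V": sol.node_potentials})


def write_msh(path: str | Path, mesh: MeshResult) -> Path:
    """Write the labeled mesh in Gmsh MSH 4.1 ASCII format.

    Each region becomes one discrete volume entity whose tag equals the region
    code, so cell labels survive a round trip through gmsh.
    """
    path = Path(path)
    regions = np.unique(mesh.region)
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    out += ["$Entities", f"0 0 0 {len(regions)}"]
    for r in regions:
        out.append(f"{int(r)} -1e9 -1e9 -1e9 1e9 1e9 1e9 0")
    out.append("$EndEntities")
    n = len(mesh.vertices)
    out += ["$Nodes", f"1 {n} 1 {n}", f"3 {int(regions[0])} 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.vertices]
    out.append("$EndNodes")
    blocks = []
    total = 0
    eid = 1
    for r in regions:
        els = mesh.tets[mesh.region == r]
        blocks.append(f"3 {int(r)} 4 {len(els)}")
        for t in els:
            blocks.append(f"{eid} " + " ".join(str(v + 1) for v in t))
            eid += 1
        total += len(els)
    out += ["$Elements", f"{len(regions)} {total} 1 {total}"] + blocks + ["$EndElements", ""]
    path.write_text("\n".join(out))
    return path


def contact_currents_frame(sol: FieldSolution) -> pd.DataFrame:
    """Per-contact integrated current diagnostics as a DataFrame."""
    rows = [dict(contact_id=cid, current_mA=i,
                 floating_V=sol.floating_values_V.get(cid, np.nan))
            for cid, i in sol.contact_currents_mA.items()]
    rows.append(dict(contact_id="ground", current_mA=sol.ground_current_mA,
                     floating_V=np.nan))
    return pd.DataFrame(rows)


def write_report(report, out_dir: str | Path) -> Path:
    """Write a ComparisonReport as CSV tables plus one JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.voltage_diff.to_csv(out / "voltage_differences.csv", index=False)
    report.threshold_errors.to_csv(out / "threshold_errors.csv", index=False)
    report.population_errors.to_csv(out / "population_errors.csv", index=False)
    timing = pd.DataFrame([
        dict(model_id=mid, ok=o.ok, error=o.error, **o.timing_s)
        for mid, o in report.outcomes.items()
    ])
    timing.to_csv(out / "timing.csv", index=False)
    # probe-grid voltages per variant as a VTU point cloud for visualization
    ref = report.outcomes[report.reference_id]
    data = {"V_ref": ref.probe_voltages_V}
    for mid, o in report.outcomes.items():
        if o.ok and mid != report.reference_id:
            data[f"dV_model{mid:02d}"] = o.probe_voltages_V - ref.probe_voltages_V
    write_point_cloud_vtu(out / "voltage_differences.vtu", report.probe_points, data)
    summary = {
        "reference_id": report.reference_id,
        "active_contact_id": report.active_contact_id,
        "amplitude_mA": report.amplitude_mA,
        "n_axons": len(report.grid),
        "max_individual_threshold_error_pct": report.max_individual_error_pct(),
        "max_population_error_pct": report.max_population_error_pct(),
        "variants": {
            str(mid): {
                "ok": o.ok, "error": o.error,
                "n_active": (o.summary.n_active if o.summary else None),
                "activation_volume_mm3": (o.summary.activation_volume_mm3
                                          if o.summary else None),
                "active_contact_current_mA": (o.solution.active_current_mA
                                              if o.solution else None),
                "timing_s": o.timing_s,
            } for mid, o in report.outcomes.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
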