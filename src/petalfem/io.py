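"""Plain-text exporters: VTU / legacy VTK meshes with fields, CSV tables,
GeoJSON footprints.

The writers emit ASCII files readable by ParaView and by ``vtk``/``meshio``
where available; only triangle cells are needed here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .corolla_geometry import LaminaMesh, MeshQualityReport

VTK_TRIANGLE = 5


def _fmt(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.10g}" for x in row)
                     for row in np.atleast_2d(a))


def write_vtu(path, mesh: LaminaMesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """ASCII XML VTU (VTK unstructured grid) with optional data arrays."""
    cell_data = cell_data or {}
    point_data = point_data or {}
    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(mesh.triangles),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(3 * (i + 1)) for i in range(m)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(VTK_TRIANGLE) for _ in range(m)),
        "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            parts += [
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{nc}" format="ascii">',
                _fmt(arr.reshape(n, -1)),
                "</DataArray>"]
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            parts += [
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{nc}" format="ascii">',
                _fmt(arr.reshape(m, -1)),
                "</DataArray>"]
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(parts))


def write_legacy_vtk(path, mesh: LaminaMesh,
                     cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid."""
    cell_data = cell_data or {}
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "petal lamina", "ASCII", "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double", _fmt(mesh.nodes),
        f"CELLS {m} {4 * m}",
        "\n".join("3 " + " ".join(map(str, t)) for t in mesh.triangles),
        f"CELL_TYPES {m}",
        "\n".join(str(VTK_TRIANGLE) for _ in range(m)),
    ]
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, arr in cell_data.items():
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default",
                      "\n".join(f"{x:.10g}" for x in np.asarray(arr))]
    lines.append("")
    Path(path).write_text("\n".join(lines))


def write_quality_csv(path, report: MeshQualityReport) -> None:
    import pandas as pd

    pd.DataFrame({
        "element_id": np.arange(report.n_elements),
        "quality": report.per_element_quality,
        "skewness": report.per_element_skewness,
    }).to_csv(path, index=False)


def write_network_csv(path, network) -> None:
    network.to_dataframe().to_csv(path, index=False)


def read_network_csv(path):
    """Rebuild a SclereidNetwork from its CSV export."""
    import pandas as pd

    from .sclereid_synth import SclereidCell, SclereidNetwork

    df = pd.read_csv(path)
    cells = []
    for _, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("segment_id")
        cells.append(SclereidCell(
            segments=grp[["x0", "y0", "x1", "y1"]].to_numpy(dtype=float)))
    ties = df.sort_values(["cell_id", "segment_id"])[
        ["tied_node0", "tied_node1"]].to_numpy(dtype=np.int64)
    radius = float(df["radius"].iloc[0]) if len(df) else 0.03
    return SclereidNetwork(cells=cells, section_radius=radius,
                           influence_halfwidth=0.05, node_ties=ties)


def write_network_geojson(path, network) -> None:
    """Footprint polygons (union pieces) for visual QC."""
    import shapely

    from .sclereid_synth import _footprints

    segs = network.all_segments()
    features = []
    if len(segs):
        union = shapely.union_all(
            _footprints(segs, network.influence_halfwidth))
        for part in shapely.get_parts(union):
            features.append({
                "type": "Feature",
                "properties": {},
                "geometry": json.loads(shapely.to_geojson(part)),
            })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
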