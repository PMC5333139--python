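"""Parametric petal-lamina midsurface generation and mesh diagnostics.

The lamina of a *Camellia* petal primordium is modelled as a gently cupped,
ovate thin surface: widest near mid-length, tapering to a rounded apex and a
narrow proximal (pedicel-attachment) base edge.  The surface is triangulated
into flat facets suitable for facet-shell finite elements, and standard
commercial-mesher diagnostics (element quality, normalized equiangular
skewness) are reported.

Coordinates: x across the width, y from base to apex, z out of plane.
All mesh coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LaminaSpec",
    "LaminaMesh",
    "MeshQualityReport",
    "build_lamina",
    "mesh_quality",
]


@dataclass(frozen=True)
class LaminaSpec:
    """Dimensions and meshing parameters of a petal lamina.

    All lengths in millimetres.  ``curvature_depth`` is the apex-to-base
    sagitta of the cupped midsurface (0 gives a flat lamina).  ``seed``
    controls optional interior node jitter (jitter is disabled by default,
    so meshes are deterministic functions of the dimensions alone).
    """

    length: float = 15.0
    width: float = 10.0
    thickness: float = 0.3
    curvature_depth: float = 2.0
    target_edge_length: float = 0.35
    seed: int = 0
    jitter: float = 0.0  # fraction of edge length; 0 disables

    def validate(self) -> None:
        for name in ("length", "width", "thickness", "target_edge_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LaminaSpec.{name} must be positive")
        if self.curvature_depth < 0:
            raise ValueError("curvature_depth must be >= 0")
        if self.target_edge_length >= self.width / 4:
            raise ValueError("target_edge_length must be < width/4")
        if self.thickness >= self.width / 10:
            raise ValueError("thickness must be < width/10 (thin-shell regime)")


@dataclass
class LaminaMesh:
    """Triangulated lamina midsurface.

    nodes      : (n, 3) float array, mm
    triangles  : (m, 3) int array, consistent CCW winding seen from +z
    thickness  : per-element thickness, mm
    base_nodes : node ids on the proximal boundary edge (v = 0)
    surface_param : (n, 2) per-node (u, v); v = 0 at base, 1 at apex
    """

    nodes: np.ndarray
    triangles: np.ndarray
    thickness: np.ndarray
    base_nodes: np.ndarray
    surface_param: np.ndarray
    spec: LaminaSpec | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def plan_areas(self) -> np.ndarray:
        """Element areas projected to the x-y (parameter) plane."""
        p = self.nodes[self.triangles][:, :, :2]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def boundary_nodes(self) -> np.ndarray:
        """Nodes on the free boundary (edges belonging to one triangle)."""
        cached = getattr(self, "_boundary_nodes", None)
        if cached is not None:
            return cached
        t = self.triangles
        edges = np.sort(np.concatenate(
            [t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        out = np.unique(uniq[counts == 1])
        self._boundary_nodes = out
        return out

    def node_normals(self) -> np.ndarray:
        """Area-weighted unit normals at nodes."""
        p = self.nodes[self.triangles]
        fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2A * normal
        nn = np.zeros_like(self.nodes)
        for k in range(3):
            np.add.at(nn, self.triangles[:, k], fn)
        nn /= np.linalg.norm(nn, axis=1, keepdims=True)
        return nn


@dataclass
class MeshQualityReport:
    per_element_quality: np.ndarray
    per_element_skewness: np.ndarray
    quality_mean_sd: tuple[float, float]
    skewness_mean_sd: tuple[float, float]
    n_elements: int
    n_nodes: int

    def to_dict(self) -> dict:
        return {
            "quality_mean": self.quality_mean_sd[0],
            "quality_sd": self.quality_mean_sd[1],
            "skewness_mean": self.skewness_mean_sd[0],
            "skewness_sd": self.skewness_mean_sd[1],
            "n_elements": self.n_elements,
            "n_nodes": self.n_nodes,
        }


def _half_width_profile(v: np.ndarray | float, width: float) -> np.ndarray:
    """Ovate outline half-width at normalized length coordinate v.

    Widest near v ~ 0.45, tapering to a narrow but finite base edge and a
    rounded apex point.
    """
    v = np.asarray(v, dtype=float)
    base = 0.12  # normalized half-width of the attachment edge
    prof = np.sqrt(np.clip((v + base) * (1.0 - v), 0.0, None)) * (1.0 - v) ** 0.15
    # normalize so the maximum equals 1
    vv = np.linspace(0.0, 1.0, 2001)
    pmax = np.max(np.sqrt((vv + base) * (1.0 - vv)) * (1.0 - vv) ** 0.15)
    return (width / 2.0) * prof / pmax


def _cup_height(x: np.ndarray, v: np.ndarray, spec: LaminaSpec) -> np.ndarray:
    """Spherical-cap-like cup: sagitta curvature_depth along the length,
    with a shallower transverse component."""
    d = spec.curvature_depth
    if d == 0.0:
        return np.zeros_like(np.asarray(v, dtype=float))
    longi = 4.0 * v * (1.0 - v)
    trans = 1.0 - 0.3 * (2.0 * x / spec.width) ** 2
    return d * longi * trans


def build_lamina(spec: LaminaSpec) -> LaminaMesh:
    """Generate and triangulate the lamina midsurface.

    The outline is sampled in rows of constant v with in-row spacing close to
    ``target_edge_length``; consecutive rows are stitched by a greedy strip
    triangulation, which guarantees a connected 2-manifold with boundary and
    consistent winding.  Deterministic for a fixed spec.
    """
    spec.validate()
    h = spec.target_edge_length
    n_rows = max(3, int(round(spec.length / h)) + 1)
    vs = np.linspace(0.0, 1.0, n_rows)

    rows: list[np.ndarray] = []  # each (m_i, 2): x, y
    row_v: list[float] = []
    for v in vs:
        hw = float(_half_width_profile(v, spec.width))
        y = v * spec.length
        if hw < 0.51 * h:
            pts = np.array([[0.0, y]])
        else:
            m = max(2, int(round(2 * hw / h)) + 1)
            xs = np.linspace(-hw, hw, m)
            pts = np.column_stack([xs, np.full(m, y)])
        rows.append(pts)
        row_v.append(float(v))

    # node table
    nodes_2d = np.vstack(rows)
    offsets = np.cumsum([0] + [len(r) for r in rows])

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        jit = rng.uniform(-1, 1, size=nodes_2d.shape) * (spec.jitter * h)
        interior = np.ones(len(nodes_2d), dtype=bool)
        for i, r in enumerate(rows):
            interior[offsets[i]] = False
            interior[offsets[i + 1] - 1] = False
            if i == 0 or i == len(rows) - 1:
                interior[offsets[i]:offsets[i + 1]] = False
        nodes_2d = nodes_2d + jit * interior[:, None]

    tris: list[tuple[int, int, int]] = []
    for i in range(len(rows) - 1):
        a = np.arange(offsets[i], offsets[i + 1])
        b = np.arange(offsets[i + 1], offsets[i + 2])
        tris.extend(_stitch_rows(nodes_2d, a, b))
    triangles = np.array(tris, dtype=np.int64)

    if len(triangles) < 50:
        raise ValueError(
            f"target_edge_length={spec.target_edge_length} produces only "
            f"{len(triangles)} elements (< 50): under-resolved shell"
        )

    # parameter coordinates
    vcoord = np.empty(len(nodes_2d))
    ucoord = np.empty(len(nodes_2d))
    for i, v in enumerate(row_v):
        sl = slice(offsets[i], offsets[i + 1])
        vcoord[sl] = v
        hw = float(_half_width_profile(v, spec.width))
        if offsets[i + 1] - offsets[i] == 1 or hw < 1e-12:
            ucoord[sl] = 0.5
        else:
            ucoord[sl] = 0.5 + nodes_2d[sl, 0] / (2 * hw)

    z = _cup_height(nodes_2d[:, 0], vcoord, spec)
    nodes = np.column_stack([nodes_2d, z])

    # enforce CCW winding in plan view
    p = nodes[triangles][:, :, :2]
    ab = p[:, 1] - p[:, 0]
    ac = p[:, 2] - p[:, 0]
    signed = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0]
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    base_nodes = np.arange(offsets[0], offsets[1])
    mesh = LaminaMesh(
        nodes=nodes,
        triangles=triangles,
        thickness=np.full(len(triangles), spec.thickness),
        base_nodes=base_nodes,
        surface_param=np.column_stack([ucoord, vcoord]),
        spec=spec,
    )
    _check_mesh(mesh)
    return mesh


def _stitch_rows(nodes, a, b):
    """Greedy strip triangulation between two ordered node rows."""
    tris = []
    i, j = 0, 0
    while i < len(a) - 1 or j < len(b) - 1:
        adv_a = i < len(a) - 1
        adv_b = j < len(b) - 1
        if adv_a and adv_b:
            # advance the side whose next diagonal is shorter
            da = np.linalg.norm(nodes[a[i + 1]] - nodes[b[j]])
            db = np.linalg.norm(nodes[b[j + 1]] - nodes[a[i]])
            adv_a, adv_b = (da <= db), (da > db)
        if adv_a:
            tris.append((a[i], a[i + 1], b[j]))
            i += 1
        else:
            tris.append((a[i], b[j + 1], b[j]))
            j += 1
    return tris


def _check_mesh(mesh: LaminaMesh) -> None:
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"triangle {bad} has non-positive area")
    # duplicate nodes
    order = np.lexsort(mesh.nodes.T)
    d = np.diff(mesh.nodes[order], axis=0)
    if len(d) and np.any(np.all(np.abs(d) < 1e-9, axis=1)):
        raise ValueError("duplicate node coordinates within 1e-9 mm")
    # connectivity
    import scipy.sparse as sp

    t = mesh.triangles
    i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    g = sp.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise ValueError(f"mesh has {n_comp} connected components")


def mesh_quality(mesh: LaminaMesh) -> MeshQualityReport:
    """Per-triangle quality and normalized equiangular skewness.

    quality  q = 4*sqrt(3) * A / sum(l_i^2)     (1 for equilateral)
    skewness s = max((theta_max - 60)/120, (60 - theta_min)/60)
    """
    p = mesh.nodes[mesh.triangles]
    e0 = p[:, 1] - p[:, 0]
    e1 = p[:, 2] - p[:, 1]
    e2 = p[:, 0] - p[:, 2]
    l2 = (e0 ** 2).sum(1) + (e1 ** 2).sum(1) + (e2 ** 2).sum(1)
    areas = 0.5 * np.linalg.norm(np.cross(e0, -e2), axis=1)
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate (zero-area) triangle: element {bad}")
    q = 4.0 * np.sqrt(3.0) * areas / l2

    def ang(u, v):
        c = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    t0 = ang(e0, -e2)
    t1 = ang(e1, -e0)
    t2 = ang(e2, -e1)
    th = np.column_stack([t0, t1, t2])
    tmax, tmin = th.max(1), th.min(1)
    s = np.maximum((tmax - 60.0) / 120.0, (60.0 - tmin) / 60.0)
    s = np.clip(s, 0.0, 1.0)

    sd = (lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0)
    return MeshQualityReport(
        per_element_quality=q,
        per_element_skewness=s,
        quality_mean_sd=(float(q.mean()), sd(q)),
        skewness_mean_sd=(float(s.mean()), sd(s)),
        n_elements=mesh.n_elements,
        n_nodes=mesh.n_nodes,
    )
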