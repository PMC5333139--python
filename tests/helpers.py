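"""Shared test utilities: synthetic structured meshes and independent
reference solutions (oracles) used to verify the FEM engine."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from petalfem.corolla_geometry import LaminaMesh
from petalfem.fem_core import shell_element_stiffness


def crossed_grid(nx: int, ny: int, Lx: float, Ly: float, zfun=None,
                 thickness: float = 0.3) -> LaminaMesh:
    """Synthetic structured lamina stand-in: crossed-triangle rectangle.

    Coordinates in mm, origin at a corner; v runs along y.  Used where tests
    need a mesh with known symmetry or simple geometry instead of the ovate
    generator output.
    """
    zfun = zfun or (lambda x, y: np.zeros_like(x))
    xs = np.linspace(0, Lx, nx + 1)
    ys = np.linspace(0, Ly, ny + 1)
    idx = {}
    nodes = []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            idx[(i, j)] = len(nodes)
            nodes.append([x, y, float(zfun(x, y))])
    cen = {}
    for j in range(ny):
        for i in range(nx):
            cen[(i, j)] = len(nodes)
            xm, ym = (xs[i] + xs[i + 1]) / 2, (ys[j] + ys[j + 1]) / 2
            nodes.append([xm, ym, float(zfun(xm, ym))])
    tris = []
    for j in range(ny):
        for i in range(nx):
            c = cen[(i, j)]
            v = [idx[(i, j)], idx[(i + 1, j)], idx[(i + 1, j + 1)],
                 idx[(i, j + 1)]]
            tris += [(v[0], v[1], c), (v[1], v[2], c), (v[2], v[3], c),
                     (v[3], v[0], c)]
    nodes = np.array(nodes, dtype=float)
    tris = np.array(tris, dtype=np.int64)
    uv = np.column_stack([nodes[:, 0] / Lx, nodes[:, 1] / Ly])
    base = np.array([idx[(i, 0)] for i in range(nx + 1)], dtype=np.int64)
    return LaminaMesh(nodes=nodes, triangles=tris,
                      thickness=np.full(len(tris), thickness),
                      base_nodes=base, surface_param=uv)


def assemble_shell_dense(mesh: LaminaMesh, thickness_m: float, E: float,
                         nu: float):
    """Independent brute-force dense assembly (triple loop over local DOFs).

    Shares only the element routine with the production path; the gather/
    scatter bookkeeping is written from scratch as an oracle.
    """
    nodes = mesh.nodes * 1e-3
    ndof = 6 * mesh.n_nodes
    K = np.zeros((ndof, ndof))
    for tri in mesh.triangles:
        Ke = shell_element_stiffness(nodes[tri], thickness_m, E, nu)
        for a in range(3):
            for b in range(3):
                for p in range(6):
                    for q in range(6):
                        K[6 * tri[a] + p, 6 * tri[b] + q] += \
                            Ke[6 * a + p, 6 * b + q]
    return K


def navier_ss_plate_center(q: float, a: float, D: float,
                           nmax: int = 39) -> float:
    """Center deflection of a simply supported square plate under uniform
    pressure, by the Navier double sine series."""
    w = 0.0
    for m in range(1, nmax + 1, 2):
        for n in range(1, nmax + 1, 2):
            w += (16 * q / (np.pi ** 6 * D) * np.sin(m * np.pi / 2)
                  * np.sin(n * np.pi / 2) / (m * n * (m ** 2 + n ** 2) ** 2))
    return w


def solve_ss_plate(n: int, a: float, t: float, E: float, nu: float,
                   q: float) -> float:
    """FEM center deflection of the simply supported plate on an n x n
    crossed-triangle mesh (hard simple support; membrane DOFs fixed)."""
    mesh = crossed_grid(n, n, a * 1e3, a * 1e3, thickness=t * 1e3)
    nodes = mesh.nodes * 1e-3
    N = mesh.n_nodes
    ndof = 6 * N
    rows, cols, vals = [], [], []
    f = np.zeros(ndof)
    for tri in mesh.triangles:
        Ke = shell_element_stiffness(nodes[tri], t, E, nu)
        dofs = (6 * tri[:, None] + np.arange(6)).ravel()
        rows.append(np.repeat(dofs, 18))
        cols.append(np.tile(dofs, 18))
        vals.append(Ke.ravel())
        p = nodes[tri]
        A = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        for v in tri:
            f[6 * v + 2] += q * A / 3
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(ndof, ndof)).tocsr()
    fixed = set()
    for k in range(N):
        x, y, _ = nodes[k]
        fixed.update((6 * k, 6 * k + 1, 6 * k + 5))
        on_x = min(y, a - y) < 1e-12  # edges parallel to x
        on_y = min(x, a - x) < 1e-12
        if on_x or on_y:
            fixed.add(6 * k + 2)
        if on_x:
            fixed.add(6 * k + 4)
        if on_y:
            fixed.add(6 * k + 3)
    free = np.setdiff1d(np.arange(ndof), sorted(fixed))
    Kff = K[np.ix_(free, free)].tocsc()
    u = np.zeros(ndof)
    lu = spla.splu(Kff)
    u[free] = lu.solve(f[free])
    for _ in range(2):
        u[free] += lu.solve(f[free] - Kff @ u[free])
    # center node is the grid node at (a/2, a/2)
    d2 = (nodes[:, 0] - a / 2) ** 2 + (nodes[:, 1] - a / 2) ** 2
    return u[6 * int(np.argmin(d2)) + 2]


def point_in_stadium_fraction(seg, halfwidth, lx, ly, n_pts, rng):
    """Monte-Carlo estimate of the stadium-footprint area fraction on an
    lx x ly rectangle: independent cross-check for the polygon-union path."""
    p0 = np.array(seg[:2])
    d = np.array(seg[2:]) - p0
    L2 = d @ d
    pts = rng.uniform((0, 0), (lx, ly), size=(n_pts, 2))
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    closest = p0 + t[:, None] * d
    inside = np.linalg.norm(pts - closest, axis=1) <= halfwidth
    return inside.mean()
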