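"""Linear-elastic shell + space-frame finite element engine.

The petal lamina (soft parenchyma) is discretized with flat triangular facet
shells: a constant-strain membrane superposed with a discrete-Kirchhoff
triangle (DKT) plate-bending field and a small artificial drilling stiffness.
Sclereids are 3-D Euler-Bernoulli space-frame beams (axial + bending +
torsion, 6 DOF/node) sharing nodes with the shell, so they inherit shell
rotations at tied nodes.

The DKT bending stiffness is constructed from the discrete Kirchhoff
constraints themselves: nodal rotations are the gradients of the deflection,
the rotation field is quadratic (6-node interpolation), midside tangential
rotations follow from a cubic deflection along each edge, and midside normal
rotations vary linearly between the corners.  This construction is exact for
constant-curvature states (patch test) by design.

Nodal DOF ordering: (ux, uy, uz, rx, ry, rz) per node, SI units (m, rad, N).
Mesh coordinates arrive in mm and are converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .corolla_geometry import LaminaMesh

__all__ = [
    "MaterialSpec",
    "BeamSection",
    "GlobalSystem",
    "SolutionField",
    "shell_element_stiffness",
    "beam_element_stiffness",
    "assemble",
    "solve_static",
]

MM = 1e-3

# 3-point Gauss rule on the unit triangle, exact for quadratics
_GAUSS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GAUSS_W = np.array([1 / 3, 1 / 3, 1 / 3])

DRILLING_FACTOR = 1e-6


@dataclass(frozen=True)
class MaterialSpec:
    """Linear-elastic constants for the two tissue phases.

    Sclereid defaults follow the reported stone-cell values (E = 0.5 GPa,
    nu = 0.4, bracketed by plant fibers at E = 0.49-1.0 GPa).  The
    parenchyma modulus is not an anatomical constant here; it defaults to
    10 MPa (soft ground tissue, 50x softer than sclereids) and is the free
    parameter of the comparison pipeline's calibration step.

    Poisson ratios >= 0.5 (incompressible limit, singular in plane
    elasticity) are clamped to 0.49 with a warning.
    """

    E_sclereid: float = 0.5e9
    nu_sclereid: float = 0.4
    E_parenchyma: float = 10e6
    nu_parenchyma: float = 0.3

    def __post_init__(self):
        for name in ("E_sclereid", "E_parenchyma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nu_sclereid", "nu_parenchyma"):
            nu = getattr(self, name)
            if nu < 0:
                raise ValueError(f"{name} must be >= 0")
            if nu >= 0.5:
                warnings.warn(
                    f"{name}={nu} is at/beyond the incompressible limit; "
                    "clamping to 0.49", stacklevel=2)
                object.__setattr__(self, name, 0.49)


@dataclass(frozen=True)
class BeamSection:
    """Circular beam cross-section; derived properties are consistent."""

    radius: float  # m

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("beam radius must be positive")

    @property
    def area(self) -> float:
        return np.pi * self.radius ** 2

    @property
    def I(self) -> float:  # noqa: E743 - field-standard symbol
        return np.pi * self.radius ** 4 / 4.0

    @property
    def J(self) -> float:
        return np.pi * self.radius ** 4 / 2.0


def _plane_stress_D(E: float, nu: float) -> np.ndarray:
    c = E / (1.0 - nu ** 2)
    return c * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0],
                         [0.0, 0.0, (1.0 - nu) / 2.0]])


def _local_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal triad (rows of R) and local 2-D coords of a triangle."""
    p1, p2, p3 = coords
    e1 = p2 - p1
    n = np.cross(e1, p3 - p1)
    nn = np.linalg.norm(n)
    if nn <= 0:
        raise ValueError("degenerate triangle (zero area)")
    e1 = e1 / np.linalg.norm(e1)
    e3 = n / nn
    e2 = np.cross(e3, e1)
    R = np.vstack([e1, e2, e3])
    xy = (coords - p1) @ R.T
    return R, xy[:, :2], 0.5 * nn


def _membrane_B(xy: np.ndarray, area: float) -> np.ndarray:
    """CST strain-displacement matrix (3 x 6), dofs (u1,v1,u2,v2,u3,v3)."""
    x, y = xy[:, 0], xy[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    return B / (2.0 * area)


_EDGES = ((1, 2), (2, 0), (0, 1))  # midside nodes 4, 5, 6 of the 6-node triangle


def _dkt_rotation_rows(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hx, Hy (6 x 9): corner + midside rotation values as linear maps of the
    local bending DOFs U = (w1, rx1, ry1, w2, rx2, ry2, w3, rx3, ry3).

    beta = grad(w): corner beta_x = -ry, beta_y = rx.  On each edge, the
    tangential rotation at the midside comes from a cubic deflection
    (discrete Kirchhoff constraint) and the normal rotation is the corner
    average.
    """
    Hx = np.zeros((6, 9))
    Hy = np.zeros((6, 9))
    for c in range(3):
        Hx[c, 3 * c + 2] = -1.0  # beta_x = -ry
        Hy[c, 3 * c + 1] = 1.0   # beta_y =  rx
    for m, (i, j) in enumerate(_EDGES):
        d = xy[j] - xy[i]
        l = np.hypot(d[0], d[1])
        t = d / l
        n = np.array([-t[1], t[0]])
        # beta_s at corners as rows over U
        bs_i = t[0] * Hx[i] + t[1] * Hy[i]
        bs_j = t[0] * Hx[j] + t[1] * Hy[j]
        bn_i = n[0] * Hx[i] + n[1] * Hy[i]
        bn_j = n[0] * Hx[j] + n[1] * Hy[j]
        w_i = np.zeros(9); w_i[3 * i] = 1.0
        w_j = np.zeros(9); w_j[3 * j] = 1.0
        bs_m = 1.5 * (w_j - w_i) / l - 0.25 * (bs_i + bs_j)
        bn_m = 0.5 * (bn_i + bn_j)
        Hx[3 + m] = bs_m * t[0] + bn_m * n[0]
        Hy[3 + m] = bs_m * t[1] + bn_m * n[1]
    return Hx, Hy


def _quad_shape_derivs(xi: float, eta: float) -> np.ndarray:
    """d/d(xi,eta) of the 6-node quadratic shape functions (2 x 6)."""
    lam = 1.0 - xi - eta
    return np.array([
        [1 - 4 * lam, 4 * xi - 1, 0.0, 4 * eta, -4 * eta, 4 * (lam - xi)],
        [1 - 4 * lam, 0.0, 4 * eta - 1, 4 * xi, 4 * (lam - eta), -4 * xi],
    ])


def _dkt_B(xy: np.ndarray, Hx: np.ndarray, Hy: np.ndarray,
           xi: float, eta: float) -> np.ndarray:
    """Curvature-displacement matrix (3 x 9) at a parametric point."""
    Jm = np.array([[xy[1, 0] - xy[0, 0], xy[1, 1] - xy[0, 1]],
                   [xy[2, 0] - xy[0, 0], xy[2, 1] - xy[0, 1]]])
    dN = np.linalg.solve(Jm, _quad_shape_derivs(xi, eta))  # rows: d/dx, d/dy
    bx_x = dN[0] @ Hx
    bx_y = dN[1] @ Hx
    by_x = dN[0] @ Hy
    by_y = dN[1] @ Hy
    return np.vstack([bx_x, by_y, bx_y + by_x])


def shell_element_stiffness(tri_coords: np.ndarray, thickness: float,
                            E: float, nu: float,
                            return_parts: bool = False):
    """18x18 facet-shell stiffness in global coordinates.

    CST membrane + DKT bending + drilling stabilization (a small
    rank-deficient penalty on the three local drilling rotations that
    vanishes for element-wise constant drilling, preserving rigid-body
    rotations).
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    coords = np.asarray(tri_coords, dtype=float)
    R, xy, area = _local_frame(coords)
    D = _plane_stress_D(E, nu)

    Bm = _membrane_B(xy, area)
    Km = thickness * area * Bm.T @ D @ Bm

    Db = (thickness ** 3 / 12.0) * D
    Hx, Hy = _dkt_rotation_rows(xy)
    Kb = np.zeros((9, 9))
    for (xi, eta), w in zip(_GAUSS, _GAUSS_W):
        B = _dkt_B(xy, Hx, Hy, xi, eta)
        Kb += w * area * B.T @ Db @ B

    K = np.zeros((18, 18))
    mi = [0, 1, 6, 7, 12, 13]          # local ux, uy
    bi = [2, 3, 4, 8, 9, 10, 14, 15, 16]  # local w, rx, ry
    di = [5, 11, 17]                   # local rz
    K[np.ix_(mi, mi)] += Km
    K[np.ix_(bi, bi)] += Kb
    # E*t*A is a rotational-stiffness scale (units of moment), so the penalty
    # stays a fixed small fraction of the physical stiffness in any unit
    # system; scaling by the mixed-dimension diagonal max would not
    alpha = DRILLING_FACTOR * E * thickness * area
    P = alpha * np.array([[1.0, -0.5, -0.5], [-0.5, 1.0, -0.5],
                          [-0.5, -0.5, 1.0]])
    K[np.ix_(di, di)] += P

    T = np.kron(np.eye(6, dtype=float), R)
    Kg = T.T @ K @ T
    Kg = 0.5 * (Kg + Kg.T)
    if return_parts:
        return Kg, (R, xy, area, Bm, (Hx, Hy))
    return Kg


def beam_element_stiffness(p0: np.ndarray, p1: np.ndarray,
                           section: BeamSection, E: float, nu: float) -> np.ndarray:
    """12x12 space-frame (Euler-Bernoulli) beam stiffness, global coords."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    L = np.linalg.norm(p1 - p0)
    if L <= 0:
        raise ValueError("zero-length beam segment")
    G = E / (2.0 * (1.0 + nu))
    A, I, J = section.area, section.I, section.J
    a = E * A / L
    tt = G * J / L
    b1 = 12 * E * I / L ** 3
    b2 = 6 * E * I / L ** 2
    b3 = 4 * E * I / L
    b4 = 2 * E * I / L

    K = np.zeros((12, 12))
    K[np.ix_([0, 6], [0, 6])] = a * np.array([[1, -1], [-1, 1]])
    K[np.ix_([3, 9], [3, 9])] = tt * np.array([[1, -1], [-1, 1]])
    # bending in local x-y plane: (v0, rz0, v1, rz1)
    iy = [1, 5, 7, 11]
    K[np.ix_(iy, iy)] = np.array([
        [b1, b2, -b1, b2],
        [b2, b3, -b2, b4],
        [-b1, -b2, b1, -b2],
        [b2, b4, -b2, b3]])
    # bending in local x-z plane: (w0, ry0, w1, ry1)
    iz = [2, 4, 8, 10]
    K[np.ix_(iz, iz)] = np.array([
        [b1, -b2, -b1, -b2],
        [-b2, b3, b2, b4],
        [-b1, b2, b1, b2],
        [-b2, b4, b2, b3]])

    ex = (p1 - p0) / L
    ref = np.array([0.0, 0.0, 1.0]) if abs(ex[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])
    T = np.kron(np.eye(4, dtype=float), R)
    Kg = T.T @ K @ T
    return 0.5 * (Kg + Kg.T)


@dataclass
class GlobalSystem:
    """Assembled sparse system: 6 DOF per node, SI units."""

    stiffness: sp.csr_matrix
    load: np.ndarray
    fixed_dofs: np.ndarray
    mesh: LaminaMesh
    materials: MaterialSpec
    n_beams: int = 0

    @property
    def n_dofs(self) -> int:
        return self.stiffness.shape[0]

    def fix_nodes(self, node_ids) -> None:
        """Clamp all 6 DOFs of the given nodes."""
        dofs = (6 * np.asarray(node_ids, dtype=np.int64)[:, None]
                + np.arange(6)).ravel()
        self.fixed_dofs = np.unique(np.concatenate([self.fixed_dofs, dofs]))


def assemble(mesh: LaminaMesh, network, materials: MaterialSpec,
             section: BeamSection | None = None) -> GlobalSystem:
    """Assemble shell (parenchyma) and optional beam (sclereid) stiffness.

    ``network=None`` yields the sclereid-free system.  Beams connect the
    mesh nodes each sclereid segment is tied to and use the sclereid
    material; ties mapping a segment to one single node are rejected.
    """
    nodes = mesh.nodes * MM  # mm -> m
    ndof = 6 * mesh.n_nodes
    rows, cols, vals = [], [], []

    def add(Ke: np.ndarray, node_ids: np.ndarray) -> None:
        dofs = (6 * node_ids[:, None] + np.arange(6)).ravel()
        r = np.repeat(dofs, len(dofs))
        c = np.tile(dofs, len(dofs))
        rows.append(r)
        cols.append(c)
        vals.append(Ke.ravel())

    for e, tri in enumerate(mesh.triangles):
        Ke = shell_element_stiffness(nodes[tri], mesh.thickness[e] * MM,
                                     materials.E_parenchyma,
                                     materials.nu_parenchyma)
        add(Ke, tri)

    n_beams = 0
    if network is not None and len(network.node_ties):
        sec = section or BeamSection(radius=network.section_radius * MM)
        for (i, j) in network.node_ties:
            if i == j:
                raise ValueError(
                    f"beam tied to coincident nodes (node {i}); "
                    "re-snap endpoints to distinct nodes")
            Ke = beam_element_stiffness(nodes[i], nodes[j], sec,
                                        materials.E_sclereid,
                                        materials.nu_sclereid)
            add(Ke, np.array([i, j]))
            n_beams += 1

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    K = 0.5 * (K + K.T)
    return GlobalSystem(stiffness=K.tocsr(), load=np.zeros(ndof),
                        fixed_dofs=np.array([], dtype=np.int64),
                        mesh=mesh, materials=materials, n_beams=n_beams)


@dataclass
class SolutionField:
    """Static solution: nodal kinematics + per-element strain measures.

    membrane_strain / curvature are per-element (eps_x, eps_y, gamma_xy) /
    (k_x, k_y, 2 k_xy) at the centroid in the element's local frame.  The
    equivalent (von Mises) elastic strain is evaluated at top, mid and
    bottom surfaces and the per-element maximum is reported.
    """

    displacements: np.ndarray  # (n, 3) m
    rotations: np.ndarray      # (n, 3) rad
    membrane_strain: np.ndarray  # (m, 3)
    curvature: np.ndarray        # (m, 3) 1/m
    thickness: np.ndarray        # (m,) m
    nu_eff: np.ndarray           # (m,)
    residual: float
    reactions: np.ndarray
    applied: np.ndarray

    _equiv: np.ndarray | None = field(default=None, repr=False)

    @property
    def equivalent_strain(self) -> np.ndarray:
        if self._equiv is None:
            from .strain_post import equivalent_strain_field

            zs = np.stack([-self.thickness / 2,
                           np.zeros_like(self.thickness),
                           self.thickness / 2])
            fields = [
                equivalent_strain_field(self.membrane_strain - z[:, None]
                                        * self.curvature, self.nu_eff)
                for z in zs
            ]
            self._equiv = np.max(fields, axis=0)
        return self._equiv

    @property
    def max_equivalent_strain(self) -> float:
        return float(self.equivalent_strain.max())

    @property
    def argmax_element(self) -> int:
        return int(np.argmax(self.equivalent_strain))


def solve_static(system: GlobalSystem) -> SolutionField:
    """Direct sparse solve of the constrained static problem.

    Verifies the relative residual (< 1e-8) and global force balance, then
    recovers centroid membrane strains and curvatures element by element.
    """
    K = system.stiffness
    f = system.load
    ndof = K.shape[0]
    fixed = np.asarray(system.fixed_dofs, dtype=np.int64)
    free = np.setdiff1d(np.arange(ndof), fixed)
    Kff = K[np.ix_(free, free)].tocsc()

    u = np.zeros(ndof)
    if np.any(f[free] != 0.0):
        try:
            lu = spla.splu(Kff)
            u[free] = lu.solve(f[free])
        except RuntimeError as err:
            n_modes = _count_zero_modes(Kff)
            raise ValueError(
                f"singular constrained system: {n_modes} unconstrained "
                f"rigid/mechanism mode(s)") from err
        # iterative refinement: the beam/shell stiffness contrast spans many
        # decades, so one LU pass can leave a noticeable residual
        fnorm = np.linalg.norm(f[free])
        for _ in range(3):
            r = f[free] - Kff @ u[free]
            if np.linalg.norm(r) / fnorm <= 1e-12:
                break
            u[free] += lu.solve(r)
        resid = np.linalg.norm(Kff @ u[free] - f[free]) / fnorm
        if resid > 1e-8:
            n_modes = _count_zero_modes(Kff)
            if n_modes > 0:
                raise ValueError(
                    f"singular constrained system: {n_modes} unconstrained "
                    f"rigid/mechanism mode(s)")
            raise ValueError(f"solver residual {resid:.2e} exceeds 1e-8")
    else:
        resid = 0.0

    reactions = np.zeros(ndof)
    reactions[fixed] = (K @ u - f)[fixed]

    mesh = system.mesh
    nodes = mesh.nodes * MM
    m = mesh.n_elements
    eps_m = np.zeros((m, 3))
    kappa = np.zeros((m, 3))
    for e, tri in enumerate(mesh.triangles):
        R, xy, area = _local_frame(nodes[tri])
        dofs = (6 * tri[:, None] + np.arange(6)).ravel()
        T = np.kron(np.eye(6, dtype=float), R)
        ul = T @ u[dofs]
        um = ul[[0, 1, 6, 7, 12, 13]]
        ub = ul[[2, 3, 4, 8, 9, 10, 14, 15, 16]]
        eps_m[e] = _membrane_B(xy, area) @ um
        Hx, Hy = _dkt_rotation_rows(xy)
        kappa[e] = _dkt_B(xy, Hx, Hy, 1 / 3, 1 / 3) @ ub

    return SolutionField(
        displacements=u.reshape(-1, 6)[:, :3],
        rotations=u.reshape(-1, 6)[:, 3:],
        membrane_strain=eps_m,
        curvature=kappa,
        thickness=mesh.thickness * MM,
        nu_eff=np.full(m, system.materials.nu_parenchyma),
        residual=float(resid),
        reactions=reactions,
        applied=f.copy(),
    )


def _count_zero_modes(Kff: sp.spmatrix) -> int:
    n = Kff.shape[0]
    scale = abs(Kff.diagonal()).max()
    if n <= 600:
        w = np.linalg.eigvalsh(Kff.toarray())
        return int(np.sum(np.abs(w) < 1e-10 * scale))
    try:
        w = spla.eigsh(Kff.tocsc(), k=min(12, n - 1), sigma=-1e-8 * scale,
                       return_eigenvectors=False)
        return int(np.sum(np.abs(w) < 1e-10 * scale))
    except Exception:
        return -1
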