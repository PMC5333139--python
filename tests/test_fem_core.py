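"""FEM engine verification against closed forms and brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from helpers import (assemble_shell_dense, crossed_grid,
                     navier_ss_plate_center, solve_ss_plate)
from petalfem.corolla_geometry import LaminaSpec, build_lamina
from petalfem.fem_core import (BeamSection, MaterialSpec, assemble,
                               beam_element_stiffness, shell_element_stiffness,
                               solve_static)
from petalfem.fem_core import _dkt_B, _dkt_rotation_rows, _local_frame
from petalfem.sclereid_synth import SclereidNetwork

TRI = np.array([[0.0, 0.0, 0.0], [0.011, 0.002, 0.001], [0.003, 0.009, 0.002]])


class TestShellElement:
    def test_symmetric_positive_semidefinite(self):
        K = shell_element_stiffness(TRI, 3e-4, 1e7, 0.3)
        assert np.max(np.abs(K - K.T)) == 0.0
        w = np.linalg.eigvalsh(K)
        assert w[0] > -1e-10 * w[-1]

    def test_rigid_body_motions_strain_free(self):
        K = shell_element_stiffness(TRI, 3e-4, 1e7, 0.3)
        modes = []
        for d in np.eye(3):
            u = np.zeros(18)
            u.reshape(3, 6)[:, :3] = d
            modes.append(u)
        for ax in np.eye(3):
            u = np.zeros(18)
            for n in range(3):
                u[6 * n:6 * n + 3] = np.cross(ax, TRI[n])
                u[6 * n + 3:6 * n + 6] = ax
            modes.append(u)
        nK = np.linalg.norm(K)
        for u in modes:
            assert np.linalg.norm(K @ u) < 1e-9 * nK * np.linalg.norm(u)

    def test_constant_curvature_patch(self):
        """Discrete Kirchhoff bending reproduces any constant-curvature
        state exactly at every integration point."""
        _, xy, _ = _local_frame(TRI)
        Hx, Hy = _dkt_rotation_rows(xy)
        kx, ky, kxy = 1.3, -0.7, 0.4
        U = np.zeros(9)
        for n, (x, y) in enumerate(xy):
            U[3 * n] = 0.5 * kx * x ** 2 + 0.5 * ky * y ** 2 + kxy * x * y
            U[3 * n + 1] = ky * y + kxy * x      # rx =  dw/dy
            U[3 * n + 2] = -(kx * x + kxy * y)   # ry = -dw/dx
        for xi, eta in [(1 / 6, 1 / 6), (2 / 3, 1 / 6), (1 / 6, 2 / 3),
                        (1 / 3, 1 / 3)]:
            kap = _dkt_B(xy, Hx, Hy, xi, eta) @ U
            assert kap == pytest.approx([kx, ky, 2 * kxy], abs=1e-12)

    def test_membrane_patch_constant_strain(self):
        """Prescribing a linear in-plane field on the boundary of a 4-element
        patch reproduces the exact constant strain everywhere (CST)."""
        E, nu, t = 5e6, 0.3, 4e-4
        mesh = crossed_grid(1, 1, 2.0, 2.0)   # 4 corner nodes + 1 center
        nodes = mesh.nodes * 1e-3
        exx, eyy, gxy = 1e-3, -4e-4, 6e-4
        exact = lambda p: np.array([exx * p[0] + 0.5 * gxy * p[1],
                                    eyy * p[1] + 0.5 * gxy * p[0]])
        K = assemble_shell_dense(mesh, t, E, nu)
        n = mesh.n_nodes
        fixed, ufix = [], []
        for k in range(n):
            for c in (2, 3, 4, 5):
                fixed.append(6 * k + c); ufix.append(0.0)
        for k in range(n - 1):  # boundary corners
            ub = exact(nodes[k])
            fixed += [6 * k, 6 * k + 1]
            ufix += [ub[0], ub[1]]
        free = np.setdiff1d(np.arange(6 * n), fixed)
        u = np.zeros(6 * n)
        u[fixed] = ufix
        u[free] = np.linalg.solve(K[np.ix_(free, free)],
                                  -K[np.ix_(free, fixed)] @ u[fixed])
        center = n - 1
        assert u[6 * center:6 * center + 2] == pytest.approx(
            exact(nodes[center]), abs=1e-8 * max(abs(exx), abs(gxy)))

    def test_degenerate_triangle_rejected(self):
        bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            shell_element_stiffness(bad, 1e-3, 1e7, 0.3)

    def test_ss_plate_matches_navier_series(self):
        """Center deflection of the simply supported plate converges to the
        independent double-series value (within 2% at 32 x 32 crossed)."""
        a, t, E, nu, q = 1.0, 0.01, 1e9, 0.3, 100.0
        D = E * t ** 3 / 12 / (1 - nu ** 2)
        ref = navier_ss_plate_center(q, a, D)
        wc = solve_ss_plate(32, a, t, E, nu, q)
        assert wc == pytest.approx(ref, rel=0.02)


class TestBeamElement:
    SEC = BeamSection(radius=0.001)

    def test_section_consistency(self):
        r = self.SEC.radius
        assert self.SEC.area == pytest.approx(np.pi * r ** 2)
        assert self.SEC.I == pytest.approx(np.pi * r ** 4 / 4)
        assert self.SEC.J == pytest.approx(np.pi * r ** 4 / 2)

    def test_cantilever_tip_deflection(self):
        E, nu, L, n, P = 2e9, 0.3, 0.1, 10, 1e-3
        ndof = 6 * (n + 1)
        K = np.zeros((ndof, ndof))
        for e in range(n):
            Ke = beam_element_stiffness([e * L / n, 0, 0],
                                        [(e + 1) * L / n, 0, 0],
                                        self.SEC, E, nu)
            idx = np.r_[6 * e:6 * e + 6, 6 * e + 6:6 * e + 12]
            K[np.ix_(idx, idx)] += Ke
        f = np.zeros(ndof)
        f[6 * n + 1] = P
        free = np.arange(6, ndof)
        u = np.linalg.solve(K[np.ix_(free, free)], f[free])
        ref = P * L ** 3 / (3 * E * self.SEC.I)
        assert u[-5] == pytest.approx(ref, rel=1e-3)

    def test_axial_extension_exact(self):
        E, nu, L, P = 2e9, 0.3, 0.1, 1e-3
        Ke = beam_element_stiffness([0, 0, 0], [L, 0, 0], self.SEC, E, nu)
        f = np.zeros(6); f[0] = P
        u = np.linalg.solve(Ke[6:, 6:], f)
        assert u[0] == pytest.approx(P * L / (E * self.SEC.area), rel=1e-12)

    def test_torsion_closed_form(self):
        E, nu, L, T = 2e9, 0.3, 0.1, 1e-4
        G = E / (2 * (1 + nu))
        Ke = beam_element_stiffness([0, 0, 0], [L, 0, 0], self.SEC, E, nu)
        f = np.zeros(6); f[3] = T
        u = np.linalg.solve(Ke[6:, 6:], f)
        assert u[3] == pytest.approx(T * L / (G * self.SEC.J), rel=1e-12)

    def test_frame_indifference(self, rng):
        from scipy.spatial.transform import Rotation

        p0, p1 = rng.uniform(-0.05, 0.05, (2, 3))
        K1 = beam_element_stiffness(p0, p1, self.SEC, 2e9, 0.3)
        for _ in range(5):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            T = np.kron(np.eye(4), R)
            K2 = beam_element_stiffness(R @ p0, R @ p1, self.SEC, 2e9, 0.3)
            assert np.max(np.abs(K2 - T @ K1 @ T.T)) < 1e-9 * np.max(np.abs(K1))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            beam_element_stiffness([1, 2, 3], [1, 2, 3], self.SEC, 2e9, 0.3)


def _toy_network(ties):
    ties = np.asarray(ties, dtype=np.int64)
    return SclereidNetwork(cells=[], section_radius=0.03,
                           influence_halfwidth=0.05, node_ties=ties)


class TestAssembly:
    def test_none_network_equals_pure_shell(self, coarse_mesh):
        mat = MaterialSpec()
        a = assemble(coarse_mesh, None, mat).stiffness
        b = assemble(coarse_mesh, _toy_network(np.zeros((0, 2))), mat).stiffness
        assert (a != b).nnz == 0

    def test_dense_oracle_equivalence(self):
        """Sparse assembly matches an independent dense triple-loop assembly
        on a small mesh, including beam contributions."""
        mesh = crossed_grid(2, 2, 2.0, 2.0)  # 13 nodes
        mat = MaterialSpec()
        ties = [[0, 4], [4, 8], [1, 5]]
        sys_ = assemble(mesh, _toy_network(ties), mat)
        Kd = assemble_shell_dense(mesh, mesh.thickness[0] * 1e-3,
                                  mat.E_parenchyma, mat.nu_parenchyma)
        sec = BeamSection(radius=0.03 * 1e-3)
        nodes = mesh.nodes * 1e-3
        for (i, j) in ties:
            Ke = beam_element_stiffness(nodes[i], nodes[j], sec,
                                        mat.E_sclereid, mat.nu_sclereid)
            dofs = np.r_[6 * i:6 * i + 6, 6 * j:6 * j + 6]
            Kd[np.ix_(dofs, dofs)] += Ke
        Ks = sys_.stiffness.toarray()
        assert np.max(np.abs(Ks - Kd)) < 1e-10 * np.max(np.abs(Kd))

    def test_six_rigid_body_modes(self, coarse_mesh):
        """Unconstrained stiffness of the curved lamina has exactly the six
        rigid-body zero-energy modes."""
        K = assemble(coarse_mesh, None, MaterialSpec()).stiffness.toarray()
        w = np.linalg.eigvalsh(K)
        assert np.sum(w < 1e-14 * w[-1]) == 6
        assert w[6] > 1e-14 * w[-1]

    def test_beams_never_soften(self):
        """Adding a beam (PSD contribution) cannot lower any eigenvalue of
        the constrained system."""
        mesh = crossed_grid(2, 2, 3.0, 3.0)
        mat = MaterialSpec()
        sys0 = assemble(mesh, None, mat)
        sys1 = assemble(mesh, _toy_network([[4, 8], [3, 7]]), mat)
        fixed = (6 * mesh.base_nodes[:, None] + np.arange(6)).ravel()
        free = np.setdiff1d(np.arange(sys0.n_dofs), fixed)
        w0 = np.linalg.eigvalsh(sys0.stiffness.toarray()[np.ix_(free, free)])
        w1 = np.linalg.eigvalsh(sys1.stiffness.toarray()[np.ix_(free, free)])
        assert np.all(w1 >= w0 - 1e-9 * w0[-1])

    def test_coincident_tie_rejected(self, coarse_mesh):
        with pytest.raises(ValueError, match="coincident"):
            assemble(coarse_mesh, _toy_network([[3, 3]]), MaterialSpec())


@pytest.fixture()
def clamped(coarse_mesh):
    sys_ = assemble(coarse_mesh, None, MaterialSpec())
    sys_.fix_nodes(coarse_mesh.base_nodes)
    return sys_


class TestSolve:
    def test_zero_load_zero_displacement(self, clamped):
        sol = solve_static(clamped)
        assert np.all(sol.displacements == 0)
        assert np.all(sol.equivalent_strain == 0)

    def test_linearity_and_residual(self, clamped, coarse_mesh):
        from petalfem.raindrop_load import RaindropSpec, distribute_load

        f = distribute_load(coarse_mesh, RaindropSpec())
        clamped.load = f
        s1 = solve_static(clamped)
        clamped.load = 2 * f
        s2 = solve_static(clamped)
        assert s1.residual < 1e-8
        assert np.allclose(s2.displacements, 2 * s1.displacements,
                           rtol=1e-7, atol=1e-18)

    def test_global_force_balance(self, clamped, coarse_mesh):
        from petalfem.raindrop_load import RaindropSpec, distribute_load

        f = distribute_load(coarse_mesh, RaindropSpec())
        clamped.load = f
        sol = solve_static(clamped)
        resultant = sol.applied.reshape(-1, 6)[:, :3].sum(0)
        reactions = sol.reactions.reshape(-1, 6)[:, :3].sum(0)
        # equilibrium: sum of reactions + sum of applied forces = 0
        assert np.linalg.norm(resultant + reactions) \
            < 1e-6 * np.linalg.norm(resultant)

    def test_energy_consistency(self, clamped, coarse_mesh):
        from petalfem.raindrop_load import RaindropSpec, distribute_load

        f = distribute_load(coarse_mesh, RaindropSpec())
        clamped.load = f
        sol = solve_static(clamped)
        u = np.concatenate([sol.displacements, sol.rotations], axis=1).ravel()
        eK = 0.5 * u @ (clamped.stiffness @ u)
        eF = 0.5 * f @ u
        assert eK == pytest.approx(eF, rel=1e-8)

    def test_unconstrained_system_raises(self, coarse_mesh):
        sys_ = assemble(coarse_mesh, None, MaterialSpec())
        sys_.load = np.ones(sys_.n_dofs)
        with pytest.raises(ValueError, match="singular|unconstrained"):
            solve_static(sys_)


class TestMaterials:
    def test_incompressible_nu_clamped(self):
        with pytest.warns(UserWarning, match="clamping"):
            m = MaterialSpec(nu_sclereid=0.5)
        assert m.nu_sclereid == 0.49

    def test_invalid_modulus(self):
        with pytest.raises(ValueError):
            MaterialSpec(E_parenchyma=0.0)


def test_mesh_convergence_on_refinement():
    """Max deflection of the raindrop-loaded lamina changes < 2% when the
    target edge length is halved from the default."""
    from petalfem.compare_pipeline import _PairedModels, _objects, default_config

    cfg = default_config()
    _, _, mat, rain = _objects(cfg)
    out = {}
    for edge in (0.35, 0.175):
        mesh = build_lamina(LaminaSpec(target_edge_length=edge))
        pair = _PairedModels(mesh, None, mat, rain)
        _, sol = pair.solve_pair(mat.E_parenchyma)
        out[edge] = np.abs(sol.displacements).max()
    assert abs(out[0.175] - out[0.35]) / out[0.175] < 0.02
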