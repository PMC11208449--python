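import numpy as np
import pytest

from pedfem.elements import (
    hex_stiffness,
    tet_b_matrix,
    tet_stiffness,
    truss_stiffness,
    von_mises,
)
from pedfem.materials import MaterialLinear, elasticity_matrix

RNG = np.random.default_rng(42)


def _random_tet():
    while True:
        nodes = RNG.uniform(-1, 1, size=(4, 3))
        vol = np.linalg.det(nodes[1:] - nodes[0]) / 6.0
        if vol > 0.05:
            return nodes


class TestTetStiffness:
    def test_symmetric_with_six_rigid_modes(self):
        D = elasticity_matrix(MaterialLinear(100.0, 0.3))
        K = tet_stiffness(_random_tet(), D)
        assert np.allclose(K, K.T, atol=1e-10)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-8 * np.abs(w).max()) == 6

    def test_rigid_translation_gives_zero_force(self):
        D = elasticity_matrix(MaterialLinear(50.0, 0.25))
        K = tet_stiffness(_random_tet(), D)
        u = np.tile([1.0, -2.0, 0.5], 4)
        assert np.allclose(K @ u, 0.0, atol=1e-9)

    def test_matches_quadrature_oracle(self):
        """K equals the single-point B^T D B V quadrature computed
        independently from finite-differenced shape functions."""
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        D = elasticity_matrix(MaterialLinear(1.0, 0.25))
        K = tet_stiffness(nodes, D)

        # oracle: numeric shape-function gradients via linear solve
        A = np.hstack([np.ones((4, 1)), nodes])
        C = np.linalg.inv(A)             # N_i = C[0,i] + C[1:,i]. x
        grads = C[1:, :].T               # (4, 3)
        B = np.zeros((6, 12))
        for i in range(4):
            gx, gy, gz = grads[i]
            c = 3 * i
            B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
            B[3, c], B[3, c + 1] = gy, gx
            B[4, c + 1], B[4, c + 2] = gz, gy
            B[5, c], B[5, c + 2] = gz, gx
        V = 1.0 / 6.0
        assert np.allclose(K, B.T @ D @ B * V, atol=1e-12)

    def test_degenerate_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            tet_b_matrix(nodes)


class TestTrussStiffness:
    def test_axis_aligned_unit_truss(self):
        K = truss_stiffness(np.array([[0, 0, 0], [1, 0, 0.0]]), 1.0, 1.0)
        assert K[0, 0] == pytest.approx(1.0)
        assert K[0, 3] == pytest.approx(-1.0)
        assert np.allclose(K[1:3, 1:3], 0.0)

    def test_rotation_invariant_energy(self):
        p = np.array([[0, 0, 0], [2, 0, 0.0]])
        u = np.array([0, 0, 0, 0.01, 0, 0.0])
        e0 = u @ truss_stiffness(p, 10.0, 3.0) @ u
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        pr = p @ R.T
        ur = (u.reshape(2, 3) @ R.T).ravel()
        er = ur @ truss_stiffness(pr, 10.0, 3.0) @ ur
        assert er == pytest.approx(e0, rel=1e-12)

    def test_three_truss_net_matches_direct_stiffness_oracle(self):
        """Planar 3-bar truss: solver displacement equals the hand-assembled
        direct stiffness method solution."""
        # nodes: two supports and a loaded apex
        a = np.array([0.0, 0, 0])
        b = np.array([2.0, 0, 0])
        c = np.array([1.0, 1.5, 0])
        E, A = 100.0, 2.0
        bars = [(a, c), (b, c), (a, b)]
        # assemble 9x9 then reduce to the apex's x,y
        K = np.zeros((9, 9))
        coords = {0: a, 1: b, 2: c}
        conn = [(0, 2), (1, 2), (0, 1)]
        for (i, j), (p, q) in zip(conn, bars):
            Ke = truss_stiffness(np.array([p, q]), E, A)
            dof = np.r_[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            K[np.ix_(dof, dof)] += Ke
        f = np.zeros(9)
        f[3 * 2 + 1] = -5.0            # apex pulled down
        free = [6, 7]                  # apex x, y
        u = np.linalg.solve(K[np.ix_(free, free)], f[free])

        # oracle: unit-direction force method for the 2-bar apex
        d1 = (c - a) / np.linalg.norm(c - a)
        d2 = (c - b) / np.linalg.norm(c - b)
        k1 = E * A / np.linalg.norm(c - a)
        k2 = E * A / np.linalg.norm(c - b)
        Kap = k1 * np.outer(d1[:2], d1[:2]) + k2 * np.outer(d2[:2], d2[:2])
        u_oracle = np.linalg.solve(Kap, np.array([0.0, -5.0]))
        assert np.allclose(u, u_oracle, rtol=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            truss_stiffness(np.zeros((2, 3)), 1.0, 1.0)


class TestHex:
    def test_unit_cube_rigid_modes(self):
        nodes = np.array([[x, y, z] for z in (0, 1) for y in (0, 1)
                          for x in (0, 1)], dtype=float)
        # reorder to VTK hex ordering
        nodes = nodes[[0, 1, 3, 2, 4, 5, 7, 6]]
        D = elasticity_matrix(MaterialLinear(10.0, 0.2))
        K = hex_stiffness(nodes, D)
        assert np.allclose(K, K.T, atol=1e-9)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6


class TestVonMises:
    def test_uniaxial(self):
        s = np.diag([123.0, 0, 0])
        assert von_mises(s) == pytest.approx(123.0)

    def test_hydrostatic_zero(self):
        assert von_mises(np.eye(3) * 55.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # sx=100, sy=50, txy=30 -> sqrt(10200)
        s = np.array([100.0, 50.0, 0.0, 30.0, 0.0, 0.0])
        assert von_mises(s) == pytest.approx(np.sqrt(10200.0))

    def test_batch_voigt_matches_tensor(self):
        v = RNG.normal(size=(10, 6))
        T = np.zeros((10, 3, 3))
        T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
        T[:, 0, 1] = T[:, 1, 0] = v[:, 3]
        T[:, 1, 2] = T[:, 2, 1] = v[:, 4]
        T[:, 2, 0] = T[:, 0, 2] = v[:, 5]
        assert np.allclose(von_mises(v), von_mises(T))
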