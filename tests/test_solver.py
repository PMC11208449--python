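"""Solver-level mechanics checks on small assemblies: patch test,
uniaxial bar, penalty contact, tie couplings, energy consistency and
frame invariance."""

import numpy as np
import pytest

from pedfem.contact import ContactPair
from pedfem.elements import tet_b_matrices_batch
from pedfem.fem import (
    FESystem,
    SolverOptions,
    TetGroup,
    TrussSet,
    solve,
)
from pedfem.materials import MaterialLinear, StrainState, strain_energy_linear
from pedfem.mesh import tets_from_voxels


def _fix_all(nodes_idx, values=None):
    fixed, vals = [], []
    for k, n in enumerate(nodes_idx):
        for c in range(3):
            fixed.append(3 * n + c)
            vals.append(0.0 if values is None else values[k][c])
    return np.array(fixed), np.array(vals)


def _ground_tris(x0, x1, y0, y1, n=5, z=0.0):
    xs = np.linspace(x0, x1, n + 1)
    ys = np.linspace(y0, y1, n + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=1)
    tris = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = (i + 1) * (n + 1) + j
            c = (i + 1) * (n + 1) + j + 1
            d = i * (n + 1) + j + 1
            tris += [[a, b, c], [a, c, d]]
    return nodes, np.array(tris)


class TestPatch:
    def test_affine_field_reproduced_to_machine_precision(self):
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 2), bool),
                                          np.zeros(3), 1.0)
        A = np.array([[1e-3, 2e-4, 0], [3e-4, -5e-4, 1e-4],
                      [0, 2e-4, 8e-4]])
        u_exact = nodes @ A.T
        bnd = np.unique(np.nonzero((nodes == 0) | (nodes == 2))[0])
        fixed, vals = _fix_all(bnd, u_exact[bnd])
        sysm = FESystem(nodes=nodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(1000.0, 0.3))],
                        fixed_dofs=fixed, fixed_values=vals)
        res = solve(sysm, np.zeros(sysm.ndof), SolverOptions(increments=1))
        assert res.converged
        assert np.abs(res.displacements - u_exact).max() < 1e-12
        # constant stress field across all elements
        sig = res.group_stress["m"]
        assert np.abs(sig - sig[0]).max() < 1e-9


class TestBar:
    def test_axial_stress_within_one_percent(self):
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 10), bool),
                                          np.zeros(3), 1.0)
        base = np.nonzero(nodes[:, 2] == 0)[0]
        top = np.nonzero(nodes[:, 2] == 10)[0]
        fixed, vals = _fix_all(base)
        F, A = 50.0, 4.0
        f = np.zeros((len(nodes), 3))
        f[top, 2] = F / len(top)
        sysm = FESystem(nodes=nodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(1000.0, 0.0))],
                        fixed_dofs=fixed, fixed_values=vals)
        res = solve(sysm, f.ravel(), SolverOptions(increments=1))
        assert res.converged
        szz = res.group_stress["m"][:, 2]
        assert szz.mean() == pytest.approx(F / A, rel=0.01)

    def test_zero_load_zero_state(self):
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 3), bool),
                                          np.zeros(3), 1.0)
        fixed, vals = _fix_all(np.nonzero(nodes[:, 2] == 0)[0])
        sysm = FESystem(nodes=nodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(100.0, 0.3))],
                        fixed_dofs=fixed, fixed_values=vals)
        res = solve(sysm, np.zeros(sysm.ndof), SolverOptions(increments=1))
        assert np.abs(res.displacements).max() == 0.0
        assert np.abs(res.group_von_mises["m"]).max() == 0.0


class TestEnergyConsistency:
    def test_half_uKu_equals_elementwise_energy(self):
        """1/2 u^T K u equals the sum of per-element strain energies."""
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 2), bool),
                                          np.zeros(3), 1.0)
        mat = MaterialLinear(500.0, 0.3)
        rng = np.random.default_rng(5)
        u = rng.normal(scale=1e-3, size=(len(nodes), 3))
        from pedfem.fem import _tet_group_csr

        g = TetGroup("m", tets, mat)
        B, V = tet_b_matrices_batch(nodes[tets])
        K = _tet_group_csr(nodes, g, B, V)
        quad = 0.5 * u.ravel() @ (K @ u.ravel())
        total = 0.0
        for e in range(len(tets)):
            eps = B[e] @ u[tets[e]].ravel()
            total += strain_energy_linear(StrainState(eps, V[e]), mat)
        assert quad == pytest.approx(total, rel=1e-10)


class TestContact:
    def _block_on_ground(self, mu):
        nodes, tets, _ = tets_from_voxels(np.ones((3, 3, 3), bool),
                                          np.array([0, 0, 0.2]), 2.0)
        gnodes, gtris = _ground_tris(-2, 8, -2, 8)
        off = len(nodes)
        allnodes = np.vstack([nodes, gnodes])
        gtris = gtris + off
        slave = np.nonzero(nodes[:, 2] < 0.3)[0]
        fixed, vals = _fix_all(np.arange(off, len(allnodes)))
        top = np.nonzero(nodes[:, 2] > 6.1)[0]
        extra = np.array([[3 * n, 3 * n + 1] for n in top]).ravel()
        fixed = np.concatenate([fixed, extra])
        vals = np.concatenate([vals, np.zeros(len(extra))])
        F = 60.0
        f = np.zeros((len(allnodes), 3))
        f[top, 2] = -F / len(top)
        pair = ContactPair(slave_nodes=slave, master_tris=gtris,
                           normal_penalty=500.0, mu=mu,
                           regularization=0.02)
        sysm = FESystem(nodes=allnodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(10.0, 0.3))],
                        fixed_dofs=fixed, fixed_values=vals,
                        contacts=[pair])
        res = solve(sysm, f.ravel(),
                    SolverOptions(increments=2, rtol=1e-6))
        return res, pair, F

    @pytest.mark.parametrize("mu", [0.0, 0.6])
    def test_normal_force_balances_load(self, mu):
        res, pair, F = self._block_on_ground(mu)
        assert res.converged
        assert res.vertical_ground_reaction() == pytest.approx(F, rel=1e-3)

    def test_no_deep_penetration_and_nonnegative_forces(self):
        res, pair, F = self._block_on_ground(0.6)
        fn = res.contact_forces[0]
        # penetration = fn / kn stays below the smoothing/penalty tolerance
        assert fn.max() / pair.normal_penalty < 0.1
        # separation carries (at most regularization-level) tension
        assert fn.min() > -0.05

    def test_separation_region_carries_no_compression(self):
        """A block loaded off-center lifts one edge; lifted slaves are
        inactive."""
        res, pair, F = self._block_on_ground(0.6)
        assert pair.state.active.sum() <= len(pair.slave_nodes)


class TestTies:
    def test_tied_nodes_move_identically(self):
        """Two stacked blocks joined by equal-displacement ties behave as
        one bar under load."""
        n1, t1, _ = tets_from_voxels(np.ones((2, 2, 3), bool),
                                     np.zeros(3), 1.0)
        n2, t2, _ = tets_from_voxels(np.ones((2, 2, 3), bool),
                                     np.array([0, 0, 3.0]), 1.0)
        off = len(n1)
        nodes = np.vstack([n1, n2])
        tets = np.vstack([t1, t2 + off])
        top1 = np.nonzero(n1[:, 2] == 3.0)[0]
        bot2 = off + np.nonzero(n2[:, 2] == 3.0)[0]
        # pair coincident nodes
        ties = []
        for s in bot2:
            d = np.linalg.norm(nodes[top1] - nodes[s], axis=1)
            ties.append([s, top1[int(np.argmin(d))]])
        fixed, vals = _fix_all(np.nonzero(nodes[:, 2] == 0)[0])
        top = np.nonzero(nodes[:, 2] == 6.0)[0]
        f = np.zeros((len(nodes), 3))
        f[top, 2] = -10.0 / len(top)
        sysm = FESystem(nodes=nodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(100.0, 0.0))],
                        fixed_dofs=fixed, fixed_values=vals,
                        ties=np.array(ties))
        res = solve(sysm, f.ravel(), SolverOptions(increments=1))
        assert res.converged
        for s, m in ties:
            assert np.allclose(res.displacements[s], res.displacements[m])
        # tip displacement ~ FL/EA of the joined 6mm bar
        expect = -10.0 * 6.0 / (100.0 * 4.0)
        assert res.displacements[top, 2].mean() == pytest.approx(expect,
                                                                 rel=0.1)


class TestFrameInvariance:
    def test_rotation_about_z_rotates_solution(self):
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 4), bool),
                                          np.zeros(3), 1.0)
        fixed_nodes = np.nonzero(nodes[:, 2] == 0)[0]
        top = np.nonzero(nodes[:, 2] == 4)[0]
        f = np.zeros((len(nodes), 3))
        f[top] = [0.5, 0.2, -1.0]

        def run(R):
            nd = nodes @ R.T
            fixed, vals = _fix_all(fixed_nodes)
            fr = (f @ R.T).ravel()
            sysm = FESystem(nodes=nd,
                            tet_groups=[TetGroup("m", tets,
                                                 MaterialLinear(80.0, 0.3))],
                            fixed_dofs=fixed, fixed_values=vals)
            return solve(sysm, fr, SolverOptions(increments=1)).displacements

        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        u0 = run(np.eye(3))
        u1 = run(R)
        assert np.abs(u1 - u0 @ R.T).max() < 1e-8


class TestTensionOnlyTruss:
    def test_compressed_truss_releases(self):
        """A truss bridging a compressed gap carries zero force when
        tension-only is active."""
        nodes, tets, _ = tets_from_voxels(np.ones((2, 2, 3), bool),
                                          np.zeros(3), 1.0)
        fixed, vals = _fix_all(np.nonzero(nodes[:, 2] == 0)[0])
        top = np.nonzero(nodes[:, 2] == 3)[0]
        f = np.zeros((len(nodes), 3))
        f[top, 2] = -5.0 / len(top)     # compression
        tr = TrussSet(conn=np.array([[int(top[0]),
                                      int(np.nonzero(nodes[:, 2] == 0)[0][0])]]),
                      E=np.array([100.0]), A=np.array([2.0]),
                      tension_only=True)
        sysm = FESystem(nodes=nodes,
                        tet_groups=[TetGroup("m", tets,
                                             MaterialLinear(100.0, 0.0))],
                        trusses=tr, fixed_dofs=fixed, fixed_values=vals)
        res = solve(sysm, f.ravel(), SolverOptions(increments=1))
        assert res.truss_force[0] == 0.0
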