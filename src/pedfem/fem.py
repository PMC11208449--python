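"""Quasi-static finite-element core.

A :class:`FESystem` bundles nodes, element groups (linear tets, hyperelastic
tets, hexes), trusses, boundary conditions, tie couplings and contact pairs.
:func:`solve` runs an incremental quasi-Newton iteration: the tangent uses
the small-strain linearization of every material (plus penalty-contact and
active-truss stiffness) and is factorized once per load increment, while the
residual is evaluated with the full nonlinear internal forces (finite-strain
polynomial soft tissue, tension-only trusses, penalty contact with Coulomb
friction).

Boundary conditions for the balanced-standing load case follow the model
contract: tibia and fibula nodes may translate only along Z, the ground base
is fully fixed, the ground reaction equals half body weight, Achilles
tension is half the ground reaction, and the tibia:fibula load split is 6:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contact import ContactPair
from .elements import (
    hex_strain,
    poly_precompute,
    poly_tet_forces,
    tet_b_matrices_batch,
    von_mises,
)
from .materials import (
    MaterialLinear,
    MaterialPolyN2,
    elasticity_matrix,
    poly_small_strain_equivalent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TetGroup",
    "HexGroup",
    "TrussSet",
    "FESystem",
    "SolverOptions",
    "SimulationResult",
    "LoadCase",
    "build_load_case",
    "solve",
    "solve_equilibrium",
]


# ---------------------------------------------------------------------------
# system definition


@dataclass
class TetGroup:
    name: str
    tets: np.ndarray
    material: MaterialLinear | MaterialPolyN2

    @property
    def is_poly(self) -> bool:
        return isinstance(self.material, MaterialPolyN2)


@dataclass
class HexGroup:
    name: str
    hexes: np.ndarray
    material: MaterialLinear


@dataclass
class TrussSet:
    """Two-node axial elements with per-element modulus and area."""

    conn: np.ndarray            # (T, 2) node ids
    E: np.ndarray               # (T,)
    A: np.ndarray               # (T,)
    tension_only: bool = True


@dataclass
class FESystem:
    nodes: np.ndarray
    tet_groups: list[TetGroup] = field(default_factory=list)
    hex_groups: list[HexGroup] = field(default_factory=list)
    trusses: TrussSet | None = None
    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    fixed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    ties: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    contacts: list[ContactPair] = field(default_factory=list)

    @property
    def ndof(self) -> int:
        return 3 * len(self.nodes)


@dataclass
class SolverOptions:
    rtol: float = 1e-6
    max_iter: int = 60
    increments: int = 5
    penalty_scale: float = 1000.0
    tension_only: bool = True
    regularization: float = 0.02     # weak sole-ground spring, N/mm per node
    line_search: bool = True
    step_cap: float = 5.0            # max nodal displacement per Newton step (mm)
    max_refactor: int = 10           # tangent refactorizations per increment


@dataclass
class SimulationResult:
    displacements: np.ndarray
    group_stress: dict[str, np.ndarray]       # per element-group Voigt stress
    group_von_mises: dict[str, np.ndarray]
    truss_force: np.ndarray
    reactions: np.ndarray                     # per fixed DOF
    contact_forces: list[np.ndarray]          # per pair, per-slave normal force
    converged: bool
    iterations: int
    residual_norm: float
    external_norm: float

    def vertical_ground_reaction(self) -> float:
        """Net normal contact force transmitted through all contact pairs."""
        return float(sum(f.sum() for f in self.contact_forces))


# ---------------------------------------------------------------------------
# load case


@dataclass
class LoadCase:
    """Balanced-standing loads: Fr = BW/2, Fa = Fr/2, Ft:Ff = 6:1."""

    Fr: float
    Fa: float
    Ft: float
    Ff: float
    achilles_point: int
    tibia_set: np.ndarray
    fibula_set: np.ndarray


def build_load_case(body_weight: float, model) -> LoadCase:
    """Decompose body weight into the balanced-standing load system.

    ``Fr = body_weight / 2`` (single-leg share of quiet bipedal stance),
    Achilles tension ``Fa = Fr / 2`` applied upward at the insertion node,
    and a total downward leg load ``Ft + Ff = (3/2) Fr`` split 6:1 between
    tibia and fibula, applied as body forces over the bone elements.
    """
    if body_weight < 0:
        raise ValueError("body weight must be non-negative")
    if "achilles_insertion" not in model.landmarks:
        raise KeyError("model lacks the 'achilles_insertion' landmark")
    Fr = body_weight / 2.0
    Fa = Fr / 2.0
    total = 1.5 * Fr
    Ft = total * 6.0 / 7.0
    Ff = total * 1.0 / 7.0
    return LoadCase(
        Fr=Fr,
        Fa=Fa,
        Ft=Ft,
        Ff=Ff,
        achilles_point=int(model.landmarks["achilles_insertion"]),
        tibia_set=np.asarray(model.tet_sets["tibia"]),
        fibula_set=np.asarray(model.tet_sets["fibula"]),
    )


# ---------------------------------------------------------------------------
# assembly helpers


def _tet_group_cache(nodes, group: TetGroup):
    coords = nodes[group.tets]
    B, V = tet_b_matrices_batch(coords)
    return B, V


def _tet_group_csr(nodes, group: TetGroup, B, V, material=None) -> sp.csr_matrix:
    mat = material or group.material
    if isinstance(mat, MaterialPolyN2):
        mat = poly_small_strain_equivalent(mat)
    D = elasticity_matrix(mat)
    Ke = np.einsum("eki,kl,elj,e->eij", B, D, B, V, optimize=True)
    dof = (3 * group.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * len(nodes)
    return sp.csr_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))


def _hex_group_csr(nodes, group: HexGroup) -> sp.csr_matrix:
    from .elements import _HEX_GP, _hex_shape_grads  # quadrature internals

    D = elasticity_matrix(group.material)
    coords = nodes[group.hexes]                          # (e, 8, 3)
    e = len(group.hexes)
    Ke = np.zeros((e, 24, 24))
    for xi in _HEX_GP:
        dN = _hex_shape_grads(xi)                        # (8, 3)
        J = np.einsum("ai,eaj->eij", dN, coords)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("degenerate hexahedron in group " + group.name)
        Jinv = np.linalg.inv(J)
        grads = np.einsum("ai,eji->eaj", dN, Jinv)
        Bm = np.zeros((e, 6, 24))
        gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
        for a in range(8):
            c = 3 * a
            Bm[:, 0, c] = gx[:, a]
            Bm[:, 1, c + 1] = gy[:, a]
            Bm[:, 2, c + 2] = gz[:, a]
            Bm[:, 3, c] = gy[:, a]
            Bm[:, 3, c + 1] = gx[:, a]
            Bm[:, 4, c + 1] = gz[:, a]
            Bm[:, 4, c + 2] = gy[:, a]
            Bm[:, 5, c] = gz[:, a]
            Bm[:, 5, c + 2] = gx[:, a]
        Ke += np.einsum("eki,kl,elj,e->eij", Bm, D, Bm, detJ, optimize=True)
    dof = (3 * group.hexes[:, :, None] + np.arange(3)).reshape(-1, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    n = 3 * len(nodes)
    return sp.csr_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))


def _poly_tangent_csr(nodes, group: TetGroup, u_full: np.ndarray,
                      pre=None, eps: float = 1e-5) -> sp.csr_matrix:
    """Consistent (finite-difference) tangent of a hyperelastic tet group
    at the current displacement state; symmetrized for the factorization."""
    tets = group.tets
    ne = len(tets)
    coords = nodes[tets]
    if pre is None:
        pre = poly_precompute(coords)
    ug = u_full.reshape(-1, 3)[tets]
    f0, _ = poly_tet_forces(coords, ug, group.material, pre=pre)
    f0 = f0.reshape(ne, 12)
    Ke = np.empty((ne, 12, 12))
    for j in range(12):
        du = ug.reshape(ne, 12).copy()
        du[:, j] += eps
        fj, _ = poly_tet_forces(coords, du.reshape(ne, 4, 3), group.material,
                                pre=pre)
        Ke[:, :, j] = (fj.reshape(ne, 12) - f0) / eps
    Ke = 0.5 * (Ke + Ke.transpose(0, 2, 1))
    dof = (3 * tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * len(nodes)
    return sp.csr_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))


def _truss_quantities(system: FESystem, u: np.ndarray):
    """Axial forces (with tension-only clamp) of all trusses under u."""
    tr = system.trusses
    p = system.nodes[tr.conn]                        # (T, 2, 3)
    d = p[:, 1] - p[:, 0]
    L = np.linalg.norm(d, axis=1)
    t = d / L[:, None]
    du = u.reshape(-1, 3)[tr.conn]
    elong = ((du[:, 1] - du[:, 0]) * t).sum(axis=1)
    N = tr.E * tr.A / L * elong
    if tr.tension_only:
        N = np.maximum(N, 0.0)
    return N, t, L


def _truss_csr(system: FESystem, active: np.ndarray) -> sp.csr_matrix:
    tr = system.trusses
    p = system.nodes[tr.conn]
    d = p[:, 1] - p[:, 0]
    L = np.linalg.norm(d, axis=1)
    t = d / L[:, None]
    k = tr.E * tr.A / L * active
    tt = np.einsum("ei,ej->eij", t, t)
    Ke = np.empty((len(L), 6, 6))
    Ke[:, :3, :3] = tt
    Ke[:, 3:, 3:] = tt
    Ke[:, :3, 3:] = -tt
    Ke[:, 3:, :3] = -tt
    Ke *= k[:, None, None]
    dof = (3 * tr.conn[:, :, None] + np.arange(3)).reshape(-1, 6)
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n = system.ndof
    return sp.csr_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))


def _reduction(system: FESystem):
    """Projection of full DOFs onto free reduced DOFs, honouring ties.

    ``system.ties`` is either an (S, 2) array of (slave, master) node
    pairs (equal displacement) or a list of ``(slave, masters, weights)``
    multi-point couplings where the slave node's displacement is the
    weighted combination of several master nodes.  A slave whose masters
    are all fixed is fixed too.
    """
    n = system.ndof
    ties = system.ties
    mpc: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if isinstance(ties, np.ndarray) or (
            len(ties) and not isinstance(ties[0], tuple)):
        for s, m in np.asarray(ties, dtype=np.int64).reshape(-1, 2):
            mpc[int(s)] = (np.array([m], np.int64), np.array([1.0]))
    else:
        for s, masters, weights in ties:
            w = np.asarray(weights, dtype=float)
            mpc[int(s)] = (np.asarray(masters, np.int64), w / w.sum())

    fixed = np.zeros(n, dtype=bool)
    fixed[system.fixed_dofs] = True
    slave = np.zeros(n, dtype=bool)
    for s in mpc:
        slave[3 * s:3 * s + 3] = True
    # a slave dof whose masters are all fixed is effectively prescribed
    g = np.zeros(n)
    g[system.fixed_dofs] = system.fixed_values
    for s, (ms, ws) in mpc.items():
        for c in range(3):
            dofs = 3 * ms + c
            if fixed[dofs].all():
                fixed[3 * s + c] = True
                g[3 * s + c] = float(ws @ g[dofs])
    free = ~(fixed | slave)
    ridx = -np.ones(n, dtype=np.int64)
    ridx[free] = np.arange(free.sum())

    rows, cols, vals = [], [], []
    dof_all = np.nonzero(free)[0]
    rows += dof_all.tolist()
    cols += ridx[dof_all].tolist()
    vals += [1.0] * len(dof_all)
    for s, (ms, ws) in mpc.items():
        for c in range(3):
            if fixed[3 * s + c]:
                continue
            for m, w in zip(ms, ws):
                d = 3 * int(m) + c
                if fixed[d]:
                    g[3 * s + c] += w * g[d]
                elif ridx[d] >= 0:
                    rows.append(3 * s + c)
                    cols.append(int(ridx[d]))
                    vals.append(float(w))
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, free.sum()))
    return P, g, fixed


# ---------------------------------------------------------------------------
# solver


def solve(system: FESystem, f_ext: np.ndarray, options: SolverOptions | None = None
          ) -> SimulationResult:
    """Incremental quasi-Newton solve of the assembled system.

    ``f_ext`` is the full external load vector (3N); prescribed boundary
    values and the external load are ramped together over
    ``options.increments`` steps.
    """
    opt = options or SolverOptions()
    n = system.ndof
    f_ext = np.asarray(f_ext, dtype=float)

    caches = [(_tet_group_cache(system.nodes, g)) for g in system.tet_groups]
    poly_pre = {id(g): poly_precompute(system.nodes[g.tets])
                for g in system.tet_groups if g.is_poly}
    K_lin = sp.csr_matrix((n, n))
    for g, (B, V) in zip(system.tet_groups, caches):
        if not g.is_poly:
            K_lin = K_lin + _tet_group_csr(system.nodes, g, B, V)
    for hg in system.hex_groups:
        K_lin = K_lin + _hex_group_csr(system.nodes, hg)

    if system.trusses is not None:
        system.trusses.tension_only = (
            system.trusses.tension_only and opt.tension_only
        )

    P, g_full, fixed = _reduction(system)
    for c in system.contacts:
        if c.regularization == 0.0:
            c.regularization = opt.regularization

    u = np.zeros(n)

    def internal(uv, update_state, drag_anchors=False):
        f = K_lin @ uv
        for grp, (B, V) in zip(system.tet_groups, caches):
            if grp.is_poly:
                du = uv.reshape(-1, 3)[grp.tets]
                fe, _ = poly_tet_forces(system.nodes[grp.tets], du,
                                        grp.material, pre=poly_pre[id(grp)])
                np.add.at(
                    f.reshape(-1, 3), grp.tets.ravel(), fe.reshape(-1, 3)
                )
        active_tr = None
        if system.trusses is not None and len(system.trusses.conn):
            N, t, L = _truss_quantities(system, uv)
            active_tr = N > 0 if system.trusses.tension_only else np.ones_like(N, bool)
            fv = f.reshape(-1, 3)
            np.add.at(fv, system.trusses.conn[:, 0], -N[:, None] * t)
            np.add.at(fv, system.trusses.conn[:, 1], N[:, None] * t)
        cforces = []
        cactive = []
        for c in system.contacts:
            fc, act, nrm, fn = c.forces(
                system.nodes, uv.reshape(-1, 3), update_state,
                drag_anchors=drag_anchors,
            )
            f -= fc.ravel()
            cforces.append(fn)
            cactive.append(act)
        return f, active_tr, cforces, cactive

    ext_norm = float(np.linalg.norm(P.T @ f_ext))
    ref_norm = max(ext_norm, 1e-8)
    total_it = 0
    converged = True
    rnorm = 0.0

    poly_K_cache: dict = {"u": None, "K": None}

    def tangent_factor(uv, active_tr):
        K_t = K_lin
        has_poly = any(g.is_poly for g in system.tet_groups)
        if has_poly:
            uref = poly_K_cache["u"]
            if uref is None or np.abs(uv - uref).max() > 0.2:
                Kp = sp.csr_matrix((n, n))
                for g in system.tet_groups:
                    if g.is_poly:
                        Kp = Kp + _poly_tangent_csr(
                            system.nodes, g, uv, pre=poly_pre[id(g)])
                poly_K_cache["u"] = uv.copy()
                poly_K_cache["K"] = Kp
            K_t = K_t + poly_K_cache["K"]
        if system.trusses is not None and len(system.trusses.conn):
            act = active_tr if active_tr is not None else \
                np.ones(len(system.trusses.conn), bool)
            K_t = K_t + _truss_csr(system, act.astype(float))
        rows, cols, vals = [], [], []
        for c in system.contacts:
            cr, cc, cv = c.stiffness_entries(system.nodes, uv.reshape(-1, 3))
            rows += cr
            cols += cc
            vals += cv
        if rows:
            K_t = K_t + sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        K_red = (P.T @ K_t @ P).tocsc()
        try:
            return spla.splu(K_red)
        except RuntimeError as exc:
            raise RuntimeError(
                "singular stiffness matrix: a component is unconstrained"
            ) from exc

    def state_signature(active_tr, cactive):
        parts = []
        if active_tr is not None:
            parts.append(active_tr.tobytes())
        for c, a in zip(system.contacts, cactive):
            parts.append(a.tobytes())
            if c.state.sliding is not None:
                parts.append(c.state.sliding.tobytes())
        return b"".join(parts)

    lam_done = 0.0
    step_frac = 1.0 / opt.increments
    halvings = 0
    u_saved = u.copy()
    inc = 0
    while lam_done < 1.0 - 1e-12:
        inc += 1
        lam = min(1.0, lam_done + step_frac)
        u[fixed] = lam * g_full[fixed]
        f_target = lam * f_ext

        f_int, active_tr, _, cactive = internal(u, update_state=True)
        rr = P.T @ (f_target - f_int)
        rnorm = float(np.linalg.norm(rr))

        lu = tangent_factor(u, active_tr)
        sig = state_signature(active_tr, cactive)
        refactors = 0
        prev_norm = rnorm

        inc_ok = False
        for it in range(1, opt.max_iter + 1):
            total_it += 1
            if rnorm <= opt.rtol * ref_norm:
                inc_ok = True
                break
            du_red = lu.solve(rr)
            step = P @ du_red
            # trust-region-style cap on the nodal step size
            smax = float(np.abs(step).max())
            if smax > opt.step_cap:
                step *= opt.step_cap / smax
            alpha = 1.0
            best = (np.inf, 1.0)
            for _ in range(8):
                u_try = u + alpha * step
                f_try, _, _, _ = internal(u_try, update_state=False)
                new_norm = float(np.linalg.norm(P.T @ (f_target - f_try)))
                if new_norm < best[0]:
                    best = (new_norm, alpha)
                if (not opt.line_search) or new_norm < rnorm:
                    break
                alpha *= 0.5
            else:
                alpha = best[1]
            u = u + alpha * step
            f_int, active_tr, _, cactive = internal(u, update_state=True)
            rr = P.T @ (f_target - f_int)
            rnorm = float(np.linalg.norm(rr))
            logger.debug(
                "inc %d it %d |r|=%.3e (alpha=%.3f)", inc, it, rnorm, alpha
            )
            new_sig = state_signature(active_tr, cactive)
            stagnating = rnorm > 0.8 * prev_norm
            if (new_sig != sig or stagnating) and refactors < opt.max_refactor:
                lu = tangent_factor(u, active_tr)
                sig = new_sig
                refactors += 1
            prev_norm = rnorm
        else:
            inc_ok = rnorm <= opt.rtol * ref_norm
        if rnorm <= opt.rtol * ref_norm:
            inc_ok = True
        if not inc_ok:
            if halvings < 4:
                # bisect the load step and retry from the converged state
                halvings += 1
                step_frac *= 0.5
                u = u_saved.copy()
                logger.info(
                    "increment %d not converged (|r|=%.3e); halving the "
                    "load step to %.4f", inc, rnorm, step_frac)
                continue
            converged = False
            logger.warning(
                "increment %d not converged: |r|=%.3e (tol %.3e)",
                inc, rnorm, opt.rtol * ref_norm,
            )
            break
        # accumulate friction slip at the converged increment state
        internal(u, update_state=True, drag_anchors=True)
        lam_done = lam
        u_saved = u.copy()

    # --- recovery ---------------------------------------------------------
    f_int, active_tr, cforces, _ = internal(u, update_state=True)
    group_stress: dict[str, np.ndarray] = {}
    group_vm: dict[str, np.ndarray] = {}
    for grp, (B, V) in zip(system.tet_groups, caches):
        du = u.reshape(-1, 3)[grp.tets]
        if grp.is_poly:
            _, sig = poly_tet_forces(system.nodes[grp.tets], du, grp.material,
                                     pre=poly_pre[id(grp)])
        else:
            D = elasticity_matrix(grp.material)
            eps = np.einsum("eij,ej->ei", B, du.reshape(len(grp.tets), 12))
            sig = eps @ D.T
        group_stress[grp.name] = sig
        group_vm[grp.name] = von_mises(sig)
    for hg in system.hex_groups:
        D = elasticity_matrix(hg.material)
        sig = np.array([
            D @ hex_strain(system.nodes[h], u.reshape(-1, 3)[h])
            for h in hg.hexes
        ])
        group_stress[hg.name] = sig
        group_vm[hg.name] = von_mises(sig)

    truss_force = np.empty(0)
    if system.trusses is not None and len(system.trusses.conn):
        truss_force, _, _ = _truss_quantities(system, u)

    reactions = (f_int - f_ext)[system.fixed_dofs]

    return SimulationResult(
        displacements=u.reshape(-1, 3),
        group_stress=group_stress,
        group_von_mises=group_vm,
        truss_force=truss_force,
        reactions=reactions,
        contact_forces=cforces,
        converged=converged,
        iterations=total_it,
        residual_norm=rnorm,
        external_norm=ext_norm,
    )


# ---------------------------------------------------------------------------
# foot-model front end


def assemble_foot_system(model, materials=None, options: SolverOptions | None = None
                         ) -> FESystem:
    """Build the FE system of a synthetic (or user-supplied) foot model."""
    from .materials import DEFAULT_MATERIALS

    mats = dict(DEFAULT_MATERIALS)
    if materials:
        mats.update(materials)
    opt = options or SolverOptions()

    bone_names = [b for b in model.tet_sets if b not in
                  ("cartilage", "soft_tissue", "released")]
    bone_ids = np.concatenate([model.tet_sets[b] for b in bone_names])
    groups = [TetGroup("bone", model.tets[bone_ids], mats["bone"])]
    if len(model.tet_sets.get("cartilage", [])):
        groups.append(
            TetGroup("cartilage", model.tets[model.tet_sets["cartilage"]],
                     mats["cartilage"])
        )
    groups.append(
        TetGroup("soft_tissue", model.tets[model.tet_sets["soft_tissue"]],
                 mats["soft_tissue"])
    )
    hexes = [HexGroup("ground", model.ground_hexes, mats["ground"])]

    E = np.array([
        mats[cls].E for cls in model.trusses.tissue_class
    ]) if len(model.trusses.conn) else np.empty(0)
    trusses = TrussSet(
        conn=model.trusses.conn,
        E=E,
        A=model.trusses.area,
        tension_only=opt.tension_only,
    )

    # boundary conditions
    leg_nodes = np.unique(model.tets[
        np.concatenate([model.tet_sets["tibia"], model.tet_sets["fibula"]])
    ])
    fixed, values = [], []
    for nid in leg_nodes:                     # only Z translation allowed
        fixed += [3 * nid, 3 * nid + 1]
        values += [0.0, 0.0]
    for nid in model.ground_base_nodes:       # ground base immobilized
        fixed += [3 * nid, 3 * nid + 1, 3 * nid + 2]
        values += [0.0, 0.0, 0.0]
    for nid in model.meta.get("pinned_orphans", []):  # released-tissue nodes
        fixed += [3 * nid, 3 * nid + 1, 3 * nid + 2]
        values += [0.0, 0.0, 0.0]

    soft_small = poly_small_strain_equivalent(mats["soft_tissue"])
    h = model.params.mesh_size
    kn = opt.penalty_scale * soft_small.E * h
    sole = ContactPair(
        slave_nodes=model.meta["sole_nodes"],
        master_tris=model.ground_top_tris,
        normal_penalty=kn,
        mu=0.6,
        regularization=opt.regularization,
        smoothing=0.005 * h,
    )

    ties = model.meta.get("ties", np.empty((0, 2), np.int64))

    return FESystem(
        nodes=model.nodes,
        tet_groups=groups,
        hex_groups=hexes,
        trusses=trusses,
        fixed_dofs=np.asarray(fixed, dtype=np.int64),
        fixed_values=np.asarray(values, dtype=float),
        ties=ties,
        contacts=[sole],
    )


def external_load_vector(model, lc: LoadCase) -> np.ndarray:
    """Assemble the balanced-standing external load vector."""
    f = np.zeros((len(model.nodes), 3))
    f[lc.achilles_point, 2] += lc.Fa
    coords = model.nodes[model.tets]
    from .elements import tet_volumes_batch

    for bone_set, F in ((lc.tibia_set, lc.Ft), (lc.fibula_set, lc.Ff)):
        if F == 0:
            continue
        V = np.abs(tet_volumes_batch(coords[bone_set]))
        w = V / V.sum()
        per_el = (F * w / 4.0)
        for j in range(4):
            np.add.at(f[:, 2], model.tets[bone_set, j], -per_el)
    return f.ravel()


def solve_equilibrium(model, loadcase: LoadCase,
                      options: SolverOptions | None = None,
                      materials=None) -> SimulationResult:
    """Balanced-standing equilibrium of a foot model.

    Returns a :class:`SimulationResult`; ``converged`` must be checked by
    the caller (non-converged solves are excluded from cohort statistics).
    """
    opt = options or SolverOptions()
    system = assemble_foot_system(model, materials=materials, options=opt)
    f_ext = external_load_vector(model, loadcase)
    return solve(system, f_ext, opt)
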