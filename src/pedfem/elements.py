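"""Finite elements: 4-node tetrahedra, 8-node hexahedra, 2-node trusses.

Small-strain kinematics for bones, cartilage, trusses and the ground slab;
finite-strain kinematics (deformation gradient per tet, deviatoric
right-Cauchy-Green invariants) for the hyperelastic soft tissue.

All element routines exist in two forms: a single-element reference form
used by tests and small problems, and a vectorized batch form used by the
assembler.  Voigt ordering is (xx, yy, zz, xy, yz, zx) with engineering
shear strains.
"""

from __future__ import annotations

import numpy as np

from .materials import MaterialLinear, MaterialPolyN2, elasticity_matrix

__all__ = [
    "tet_volume",
    "tet_b_matrix",
    "tet_stiffness",
    "truss_stiffness",
    "hex_stiffness",
    "von_mises",
    "tet_b_matrices_batch",
    "tet_volumes_batch",
    "poly_tet_forces",
]


# ---------------------------------------------------------------------------
# tetrahedra

def tet_volume(nodes: np.ndarray) -> float:
    """Signed volume of a 4-node tet (positive for right-handed ordering)."""
    n = np.asarray(nodes, dtype=float)
    return float(np.linalg.det(n[1:] - n[0]) / 6.0)


def tet_b_matrix(nodes: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant strain-displacement matrix B (6x12) and volume of a tet."""
    n = np.asarray(nodes, dtype=float)
    V = tet_volume(n)
    if V <= 0:
        raise ValueError(f"degenerate or inverted tetrahedron (volume {V:g})")
    # shape-function gradients: rows of the inverse Jacobian construction
    J = n[1:] - n[0]                       # 3x3
    Jinv = np.linalg.inv(J)                # dxi/dx
    grads = np.zeros((4, 3))
    grads[1:] = Jinv.T                     # dN_i/dx for i=1..3
    grads[0] = -grads[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B, V


def tet_stiffness(nodes: np.ndarray, D: np.ndarray) -> np.ndarray:
    """12x12 stiffness ``B^T D B V`` of a linear-elastic constant-strain tet."""
    B, V = tet_b_matrix(nodes)
    return B.T @ np.asarray(D, dtype=float) @ B * V


def tet_volumes_batch(coords: np.ndarray) -> np.ndarray:
    """Signed volumes of tets given as an (n, 4, 3) coordinate array."""
    e = coords[:, 1:, :] - coords[:, :1, :]
    return np.linalg.det(e) / 6.0


def tet_b_matrices_batch(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch B matrices: returns (B (n,6,12), V (n,))."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    J = coords[:, 1:, :] - coords[:, :1, :]
    V = np.linalg.det(J) / 6.0
    if np.any(V <= 0):
        bad = int(np.argmax(V <= 0))
        raise ValueError(f"degenerate or inverted tetrahedron at index {bad}")
    Jinv = np.linalg.inv(J)
    grads = np.zeros((n, 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((n, 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    for i in range(4):
        c = 3 * i
        B[:, 0, c] = gx[:, i]
        B[:, 1, c + 1] = gy[:, i]
        B[:, 2, c + 2] = gz[:, i]
        B[:, 3, c] = gy[:, i]
        B[:, 3, c + 1] = gx[:, i]
        B[:, 4, c + 1] = gz[:, i]
        B[:, 4, c + 2] = gy[:, i]
        B[:, 5, c] = gz[:, i]
        B[:, 5, c + 2] = gx[:, i]
    return B, V


# ---------------------------------------------------------------------------
# trusses

def truss_stiffness(
    endpoints: np.ndarray, E: float, A: float
) -> np.ndarray:
    """6x6 axial stiffness ``(EA/L) t t^T`` pattern of a 2-node truss."""
    p = np.asarray(endpoints, dtype=float)
    d = p[1] - p[0]
    L = float(np.linalg.norm(d))
    if L <= 0:
        raise ValueError("zero-length truss element")
    t = d / L
    k = E * A / L
    tt = np.outer(t, t)
    K = np.empty((6, 6))
    K[:3, :3] = tt
    K[3:, 3:] = tt
    K[:3, 3:] = -tt
    K[3:, :3] = -tt
    return k * K


# ---------------------------------------------------------------------------
# hexahedra (trilinear, 2x2x2 Gauss) — used only for the ground slab

_HEX_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_G = 1.0 / np.sqrt(3.0)
_HEX_GP = np.array(
    [[sx * _G, sy * _G, sz * _G]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)


def _hex_shape_grads(xi: np.ndarray) -> np.ndarray:
    """dN/dxi (8x3) of the trilinear hex at natural coordinates xi."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _HEX_XI[a]
        g[a, 0] = 0.125 * sx * (1 + sy * xi[1]) * (1 + sz * xi[2])
        g[a, 1] = 0.125 * sy * (1 + sx * xi[0]) * (1 + sz * xi[2])
        g[a, 2] = 0.125 * sz * (1 + sx * xi[0]) * (1 + sy * xi[1])
    return g


def hex_stiffness(nodes: np.ndarray, D: np.ndarray) -> np.ndarray:
    """24x24 stiffness of an 8-node hex by 2x2x2 Gauss quadrature."""
    nodes = np.asarray(nodes, dtype=float)
    K = np.zeros((24, 24))
    for xi in _HEX_GP:
        dN = _hex_shape_grads(xi)
        J = dN.T @ nodes
        detJ = np.linalg.det(J)
        if detJ <= 0:
            raise ValueError("degenerate or inverted hexahedron")
        grads = dN @ np.linalg.inv(J).T
        B = np.zeros((6, 24))
        for a in range(8):
            gx, gy, gz = grads[a]
            c = 3 * a
            B[0, c] = gx
            B[1, c + 1] = gy
            B[2, c + 2] = gz
            B[3, c] = gy
            B[3, c + 1] = gx
            B[4, c + 1] = gz
            B[4, c + 2] = gy
            B[5, c] = gz
            B[5, c + 2] = gx
        K += B.T @ D @ B * detJ
    return K


def hex_strain(nodes: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Centroid engineering strain 6-vector of a hex from nodal displacements."""
    dN = _hex_shape_grads(np.zeros(3))
    J = dN.T @ np.asarray(nodes, dtype=float)
    grads = dN @ np.linalg.inv(J).T          # 8x3
    H = np.asarray(u, dtype=float).reshape(8, 3).T @ grads  # du/dx
    return np.array([
        H[0, 0], H[1, 1], H[2, 2],
        H[0, 1] + H[1, 0], H[1, 2] + H[2, 1], H[0, 2] + H[2, 0],
    ])


# ---------------------------------------------------------------------------
# stress invariants

def von_mises(sigma: np.ndarray) -> float | np.ndarray:
    """Von Mises equivalent stress of symmetric stress tensor(s).

    Accepts a single 3x3 tensor, an (n,3,3) stack, or Voigt 6-vectors
    (xx, yy, zz, xy, yz, zx) of shape (6,) or (n,6).
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape[-1] == 3 and s.shape[-2:] == (3, 3):
        sx, sy, sz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        txy, tyz, tzx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    elif s.shape[-1] == 6:
        sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    else:
        raise ValueError(f"unrecognized stress shape {s.shape}")
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2)
    )
    return float(vm) if vm.ndim == 0 else vm


# ---------------------------------------------------------------------------
# hyperelastic tets (finite strain)

def _det3(A: np.ndarray) -> np.ndarray:
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def _inv3(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    inv[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    inv[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    inv[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    inv[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    inv[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    inv[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    inv[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    inv[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return inv / det[..., None, None]


def poly_precompute(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference shape-function gradients and volumes of hyperelastic tets
    (cacheable across force evaluations)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    J0 = coords[:, 1:, :] - coords[:, :1, :]
    V0 = _det3(J0) / 6.0
    Jinv = _inv3(J0, _det3(J0))
    grads = np.zeros((n, 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, V0


def poly_tet_forces(
    coords: np.ndarray,
    u: np.ndarray,
    mat: MaterialPolyN2,
    pre: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Internal nodal forces and Cauchy stresses of hyperelastic tets.

    Parameters
    ----------
    coords : (n, 4, 3) reference coordinates.
    u : (n, 4, 3) nodal displacements.
    mat : polynomial material.

    Returns
    -------
    forces : (n, 4, 3) internal nodal forces (to be subtracted from external).
    sigma : (n, 6) Cauchy stress in Voigt order.

    Deformation gradients near collapse (J < 0.02) are regularized by
    clamping J in the volumetric response, keeping the Newton loop alive
    through transiently bad intermediate states.
    """
    coords = np.asarray(coords, dtype=float)
    u = np.asarray(u, dtype=float)
    n = coords.shape[0]
    grads, V0 = poly_precompute(coords) if pre is None else pre

    # deformation gradient F = I + du/dX
    H = np.einsum("eai,eaj->eij", u, grads)
    F = H + np.eye(3)
    Jdet = _det3(F)
    Jc = np.clip(Jdet, 0.02, None)

    Fbar = F * Jc[:, None, None] ** (-1.0 / 3.0)
    Bbar = np.einsum("eij,ekj->eik", Fbar, Fbar)      # Fbar Fbar^T
    I1 = np.trace(Bbar, axis1=1, axis2=2)
    Bbar2 = np.einsum("eij,ejk->eik", Bbar, Bbar)
    I2 = 0.5 * (I1 ** 2 - np.trace(Bbar2, axis1=1, axis2=2))

    a = I1 - 3.0
    b = I2 - 3.0
    psi1 = mat.C10 + 2.0 * mat.C20 * a + mat.C11 * b
    psi2 = mat.C01 + mat.C11 * a + 2.0 * mat.C02 * b

    # isochoric Cauchy stress: (2/J) dev[(psi1 + I1 psi2) Bbar - psi2 Bbar^2]
    T = (psi1 + I1 * psi2)[:, None, None] * Bbar - psi2[:, None, None] * Bbar2
    trT = np.trace(T, axis1=1, axis2=2)
    dev = T - (trT / 3.0)[:, None, None] * np.eye(3)
    sig = (2.0 / Jc)[:, None, None] * dev

    # volumetric pressure from U_vol = sum (1/Di)(J-1)^(2i)
    dv = Jc - 1.0
    p = np.zeros(n)
    if mat.D1 != 0.0:
        p += (2.0 / mat.D1) * dv
    if mat.D2 != 0.0:
        p += (4.0 / mat.D2) * dv ** 3
    sig += p[:, None, None] * np.eye(3)

    # nodal forces on the current configuration: f_a = V0 J sigma (F^-T dN/dX)
    FinvT = np.transpose(_inv3(F, np.where(Jdet == 0.0, 1e-12, Jdet)),
                         (0, 2, 1))
    grads_x = np.einsum("eij,eaj->eai", FinvT, grads)  # dN/dx
    w = (V0 * Jc)
    forces = np.einsum("e,eij,eaj->eai", w, sig, grads_x)

    voigt = np.stack(
        [sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2],
         sig[:, 0, 1], sig[:, 1, 2], sig[:, 2, 0]], axis=1
    )
    return forces, voigt
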