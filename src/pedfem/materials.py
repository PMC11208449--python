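"""Constitutive models.

Two material classes are used throughout the foot model:

* small-strain isotropic linear elasticity (bones, ligaments, plantar
  fascia, cartilage layers, ground) parameterized by Young's modulus ``E``
  (MPa) and Poisson's ratio ``nu``;
* a reduced polynomial/Mooney-Rivlin-type hyperelastic solid of order
  N = 2 for the bulk soft tissue, with strain-energy density

  ``U = sum_{i+j=1..2} C_ij (I1bar-3)^i (I2bar-3)^j
       + sum_{i=1..2} (1/D_i) (Jel-1)^(2i)``

  written in terms of the deviatoric invariants of the right Cauchy-Green
  tensor and the elastic volume ratio ``Jel``.

Units are mm / N / MPa everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialLinear",
    "MaterialPolyN2",
    "StrainState",
    "DeformationState",
    "elasticity_matrix",
    "strain_energy_linear",
    "poly_energy_density",
    "poly_small_strain_equivalent",
    "DEFAULT_MATERIALS",
]


@dataclass(frozen=True)
class MaterialLinear:
    """Isotropic linear-elastic material: ``E`` in MPa, ``-1 < nu < 0.5``."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(
                f"Poisson's ratio must lie in (-1, 0.5), got {self.nu}"
            )


@dataclass(frozen=True)
class MaterialPolyN2:
    """Order-2 polynomial hyperelastic material.

    ``C10..C02`` are the deviatoric coefficients (MPa), ``D1``/``D2`` the
    compressibility parameters (1/MPa).  ``D_i = 0`` means the corresponding
    volumetric term is absent; a material with *all* D_i zero is fully
    incompressible and is rejected whenever ``Jel != 1``.
    """

    C10: float
    C01: float
    C20: float = 0.0
    C11: float = 0.0
    C02: float = 0.0
    D1: float = 0.0
    D2: float = 0.0


@dataclass(frozen=True)
class StrainState:
    """Engineering strain 6-vector (xx, yy, zz, xy, yz, zx) over a volume V (mm^3)."""

    eps: np.ndarray
    V: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"volume must be positive, got {self.V}")


@dataclass(frozen=True)
class DeformationState:
    """Deviatoric invariants and elastic volume ratio of a deformation."""

    I1bar: float
    I2bar: float
    Jel: float

    def __post_init__(self) -> None:
        if self.Jel <= 0:
            raise ValueError(f"elastic volume ratio must be positive, got {self.Jel}")


def elasticity_matrix(mat: MaterialLinear) -> np.ndarray:
    """6x6 isotropic stiffness matrix D for engineering-strain Voigt ordering.

    Ordering (xx, yy, zz, xy, yz, zx); shear rows use engineering shear
    strain, so the shear diagonal is the shear modulus G.
    """
    E, nu = mat.E, mat.nu
    if nu >= 0.5:
        raise ValueError("nu >= 0.5: incompressible material has no finite D")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    G = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * G
    D[np.arange(3, 6), np.arange(3, 6)] = G
    return D


def strain_energy_linear(state: StrainState, mat: MaterialLinear) -> float:
    """Strain energy ``U = 1/2 eps^T D eps * V`` (N*mm) of a uniform state."""
    eps = np.asarray(state.eps, dtype=float)
    D = elasticity_matrix(mat)
    return float(0.5 * eps @ D @ eps * state.V)


def poly_energy_density(state: DeformationState, mat: MaterialPolyN2) -> float:
    """Strain-energy density (MPa) of the N=2 polynomial material."""
    a = state.I1bar - 3.0
    b = state.I2bar - 3.0
    U = (
        mat.C10 * a
        + mat.C01 * b
        + mat.C20 * a * a
        + mat.C11 * a * b
        + mat.C02 * b * b
    )
    dv = state.Jel - 1.0
    for i, Di in enumerate((mat.D1, mat.D2), start=1):
        if Di == 0.0:
            if dv != 0.0 and i == 1 and mat.D2 == 0.0:
                raise ValueError(
                    "fully incompressible material (D1=D2=0) cannot change volume"
                )
            continue
        U += (1.0 / Di) * dv ** (2 * i)
    return float(U)


def poly_small_strain_equivalent(mat: MaterialPolyN2) -> MaterialLinear:
    """Linearization of the polynomial material about the undeformed state.

    The initial shear modulus is ``mu0 = 2 (C10 + C01)`` and the initial bulk
    modulus ``K0 = 2 / D1``; these give the equivalent (E, nu).
    """
    mu0 = 2.0 * (mat.C10 + mat.C01)
    if mu0 <= 0:
        raise ValueError("non-positive initial shear modulus")
    if mat.D1 <= 0:
        raise ValueError("D1 must be positive to linearize a compressible response")
    K0 = 2.0 / mat.D1
    E = 9.0 * K0 * mu0 / (3.0 * K0 + mu0)
    nu = (3.0 * K0 - 2.0 * mu0) / (6.0 * K0 + 2.0 * mu0)
    return MaterialLinear(E=E, nu=nu)


#: Default material card (config-overridable).  Bone/ligament/fascia/ground
#: follow the antecedent foot-FE literature; soft tissue is the classic
#: second-order polynomial card for plantar soft tissue.
DEFAULT_MATERIALS = {
    "bone": MaterialLinear(E=7300.0, nu=0.3),
    # joint layers are one voxel (~4-7 mm) thick, several times anatomical
    # cartilage thickness; the modulus is scaled up so the joint-layer
    # compliance (thickness / E) matches a 1-2 mm articular layer
    "cartilage": MaterialLinear(E=150.0, nu=0.4),
    "ligament": MaterialLinear(E=260.0, nu=0.4),
    "fascia": MaterialLinear(E=350.0, nu=0.4),
    "ground": MaterialLinear(E=17000.0, nu=0.1),
    "soft_tissue": MaterialPolyN2(
        C10=0.08556, C01=-0.05841, C20=0.03900, C11=-0.02319, C02=0.00851,
        D1=3.65273, D2=0.0,
    ),
}
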