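"""Hyperelastic constitutive law for passive skeletal muscle under compression.

The tissue is modelled as a transversely isotropic, nearly incompressible
hyperelastic solid.  A single fibre family with reference direction ``M``
enters through the structural tensor ``Z = M (x) M`` and the fourth
pseudo-invariant ``I4 = C : Z`` (the squared fibre stretch).  Volume change
and distortion are separated by the Flory split ``F = J^(1/3) F_bar``, so the
isotropic part of the energy depends on the isochoric first invariant
``I1_bar = J^(-2/3) tr C``.

The strain-energy density is

    psi = c1 * g(I4) * f(I1_bar) + K_vol * (J^2 - 1 - 2 ln J)

with the fibre-mode factor ``g(I4) = exp(c2 (I4 - 1))`` and the matrix
response ``f(I1_bar) = exp(c3 (I1_bar - 3)) - 1``.  Because ``g`` is a smooth
multiplicative factor rather than an on/off switch, compressed fibres
(``I4 < 1``) soften the response continuously, stretched fibres
(``I4 > 1``) stiffen it, and fibres held at rest length leave the response
purely isotropic.  ``c1`` (kPa) sets the stress scale, ``c3`` the isotropic
exponential stiffening, ``c2 >= 0`` the strength of the anisotropy.

The bulk penalty coefficient is tied to the model's small-strain shear
modulus ``mu_0 = 2 c1 c3`` (the neo-Hookean identification
``mu / 2 = d psi / d I1_bar`` at the reference state):
``K_vol = kvol_multiplier * mu_0``, with a default multiplier of 5000 giving
nearly incompressible behaviour.

Stresses are first Piola-Kirchhoff (nominal): ``P = 2 F dpsi/dC``, in kPa.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "InvalidDeformationError",
    "FibreDirectionError",
    "MaterialParameters",
    "FibreDirection",
    "Kinematics",
    "Material",
    "PassiveMuscleModel",
    "as_material",
    "structural_tensor",
    "invariants",
    "bulk_modulus",
    "strain_energy",
    "pk1_stress",
    "pk1_fd_oracle",
]


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


class FibreDirectionError(ValueError):
    """Raised when a fibre direction vector is not (normalizable to) a unit vector."""


# --------------------------------------------------------------------------
# parameters and fibre direction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParameters:
    """Parameters of the continuous fibre-mode muscle model.

    Attributes
    ----------
    c1 : float
        Stress-like scale, kPa.  Must be positive.
    c2 : float
        Dimensionless anisotropy exponent, >= 0.  ``c2 = 0`` collapses the
        model to an isotropic exponential law.
    c3 : float
        Dimensionless isotropic exponent, > 0.
    kvol_multiplier : float
        Dimensionless factor relating the bulk penalty ``K_vol`` to the
        small-strain shear modulus ``mu_0 = 2 c1 c3``.  Default 5000.
    """

    c1: float
    c2: float
    c3: float
    kvol_multiplier: float = 5000.0

    def __post_init__(self) -> None:
        if not self.c1 > 0.0:
            raise ValueError(f"c1 must be positive (got {self.c1})")
        if self.c2 < 0.0:
            raise ValueError(f"c2 must be non-negative (got {self.c2})")
        if not self.c3 > 0.0:
            raise ValueError(f"c3 must be positive (got {self.c3})")
        if not self.kvol_multiplier > 0.0:
            raise ValueError("kvol_multiplier must be positive")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus of the isochoric part, mu_0 = 2 c1 c3 (kPa)."""
        return 2.0 * self.c1 * self.c3

    @property
    def vector(self) -> np.ndarray:
        """The identification vector p = (c1, c2, c3)."""
        return np.array([self.c1, self.c2, self.c3])

    def replace(self, **kw) -> "MaterialParameters":
        return replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(
            {
                "c1_kPa": self.c1,
                "c2": self.c2,
                "c3": self.c3,
                "kvol_multiplier": self.kvol_multiplier,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaterialParameters":
        d = json.loads(text)
        return cls(
            c1=d["c1_kPa"],
            c2=d["c2"],
            c3=d["c3"],
            kvol_multiplier=d.get("kvol_multiplier", 5000.0),
        )


def _unit_vector(m, tol: float = 1e-10) -> np.ndarray:
    v = np.asarray(m, dtype=float).reshape(3)
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise FibreDirectionError(
            f"fibre direction must be a unit vector (|M| = {n:.6g}); "
            "use FibreDirection.of() to normalize"
        )
    return v


@dataclass(frozen=True)
class FibreDirection:
    """A unit fibre direction vector in the reference configuration."""

    M: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", _unit_vector(self.M, tol=1e-12))

    @classmethod
    def of(cls, v) -> "FibreDirection":
        """Build a fibre direction from any non-zero vector, normalizing it."""
        v = np.asarray(v, dtype=float).reshape(3)
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise FibreDirectionError("fibre direction vector has (near-)zero length")
        return cls(v / n)

    @classmethod
    def axis(cls, i: int) -> "FibreDirection":
        e = np.zeros(3)
        e[i] = 1.0
        return cls(e)


def _as_direction(m) -> np.ndarray:
    if isinstance(m, FibreDirection):
        return m.M
    return _unit_vector(m)


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _check_F(F) -> tuple[np.ndarray, float]:
    F = np.asarray(F, dtype=float).reshape(3, 3)
    J = float(np.linalg.det(F))
    if not J > 0.0:
        raise InvalidDeformationError(f"det F = {J:.6g} <= 0: inadmissible deformation")
    return F, J


class Kinematics:
    """A deformation gradient with its derived invariants.

    Derived quantities (``J``, ``C``, ``I1_bar``, and ``I4`` for a given
    fibre direction) are computed on demand.
    """

    def __init__(self, F) -> None:
        self.F, self.J = _check_F(F)

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor C = F^T F."""
        return self.F.T @ self.F

    @property
    def F_bar(self) -> np.ndarray:
        """Isochoric part of F (unit determinant)."""
        return self.J ** (-1.0 / 3.0) * self.F

    @property
    def i1_bar(self) -> float:
        """Isochoric first invariant, tr(J^(-2/3) C) >= 3."""
        return self.J ** (-2.0 / 3.0) * float(np.trace(self.C))

    def i4(self, m) -> float:
        """Squared fibre stretch C : (M (x) M) for fibre direction ``m``."""
        FM = self.F @ _as_direction(m)
        return float(FM @ FM)

    def fibre_stretch(self, m) -> float:
        return math.sqrt(self.i4(m))


def structural_tensor(m) -> np.ndarray:
    """Structural tensor Z = M (x) M of a unit fibre direction.

    Symmetric, idempotent, trace one.  Raises ``FibreDirectionError`` for a
    non-unit input.
    """
    M = _as_direction(m)
    return np.outer(M, M)


def invariants(F, m) -> tuple[float, float, float]:
    """Return (J, I1_bar, I4) of a deformation gradient and fibre direction."""
    kin = Kinematics(F)
    return kin.J, kin.i1_bar, kin.i4(m)


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

class Material:
    """Base class for invariant-based transversely isotropic materials.

    Subclasses provide the isochoric energy through :meth:`energy_terms`;
    the volumetric penalty ``K_vol (J^2 - 1 - 2 ln J)`` with
    ``K_vol = kvol_multiplier * mu_0`` is shared.
    """

    kvol_multiplier: float

    @property
    def reference_shear_modulus(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def bulk_modulus(self) -> float:
        """Penalty bulk modulus K_vol (kPa)."""
        return self.kvol_multiplier * self.reference_shear_modulus

    def energy_terms(self, i1_bar: float, i4: float) -> tuple[float, float, float]:
        """Isochoric energy and its derivatives.

        Returns ``(psi_iso, dpsi/dI1_bar, dpsi/dI4)`` at the given invariants.
        """
        raise NotImplementedError

    # ---- generic tensor-level evaluation -------------------------------

    def energy(self, F, m) -> float:
        """Strain-energy density psi(F) in kPa (per unit reference volume)."""
        J, i1b, i4 = invariants(F, m)
        psi_iso, _, _ = self.energy_terms(i1b, i4)
        return psi_iso + self.bulk_modulus * (J * J - 1.0 - 2.0 * math.log(J))

    def pk1(self, F, m) -> np.ndarray:
        """Analytic first Piola-Kirchhoff stress P = 2 F dpsi/dC (kPa).

        The fibre term is the rank-one tensor ``2 psi_4 (F M) (x) M``
        (equivalently ``2 psi_4 F Z``), consistent with
        ``dI4/dC = M (x) M``.
        """
        F, J = _check_F(F)
        M = _as_direction(m)
        C = F.T @ F
        i1 = float(np.trace(C))
        Jm23 = J ** (-2.0 / 3.0)
        FM = F @ M
        i4 = float(FM @ FM)
        _, p1b, p4 = self.energy_terms(Jm23 * i1, i4)
        pJ = self.bulk_modulus * (2.0 * J - 2.0 / J)
        Finv_T = np.linalg.inv(F).T
        P = (
            2.0 * p4 * np.outer(FM, M)
            + 2.0 * p1b * Jm23 * (F - (i1 / 3.0) * Finv_T)
            + pJ * J * Finv_T
        )
        return P


class PassiveMuscleModel(Material):
    """The continuous fibre-mode model psi = c1 g(I4) f(I1_bar) + volumetric penalty."""

    def __init__(self, params: MaterialParameters) -> None:
        self.params = params
        self.kvol_multiplier = params.kvol_multiplier

    @property
    def reference_shear_modulus(self) -> float:
        return self.params.shear_modulus

    def energy_terms(self, i1_bar: float, i4: float) -> tuple[float, float, float]:
        c1, c2, c3 = self.params.c1, self.params.c2, self.params.c3
        g = math.exp(c2 * (i4 - 1.0))
        e3 = math.exp(c3 * (i1_bar - 3.0))
        f = e3 - 1.0
        psi = c1 * g * f
        dpsi_di1b = c1 * g * c3 * e3
        dpsi_di4 = c1 * c2 * g * f
        return psi, dpsi_di1b, dpsi_di4

    def __repr__(self) -> str:
        p = self.params
        return (
            f"PassiveMuscleModel(c1={p.c1:g} kPa, c2={p.c2:g}, c3={p.c3:g}, "
            f"kvol_multiplier={p.kvol_multiplier:g})"
        )


def as_material(obj) -> Material:
    """Coerce ``MaterialParameters`` (or pass through a ``Material``)."""
    if isinstance(obj, Material):
        return obj
    if isinstance(obj, MaterialParameters):
        return PassiveMuscleModel(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a material")


# --------------------------------------------------------------------------
# module-level convenience operations
# --------------------------------------------------------------------------

def bulk_modulus(params: MaterialParameters) -> float:
    """Penalty bulk modulus K_vol = kvol_multiplier * 2 c1 c3 (kPa)."""
    return params.kvol_multiplier * params.shear_modulus


def strain_energy(F, m, params) -> float:
    """Strain-energy density of the muscle model at deformation ``F`` (kPa)."""
    return as_material(params).energy(F, m)


def pk1_stress(F, m, params) -> np.ndarray:
    """Analytic nominal (first Piola-Kirchhoff) stress tensor (kPa)."""
    return as_material(params).pk1(F, m)


def pk1_fd_oracle(F, m, params, h: float | None = None) -> np.ndarray:
    """Numerical-derivative stress oracle, P_ij ~ dpsi/dF_ij by central differences.

    Intended for verification only: independent of the analytic stress path.
    The step ``h`` is scaled to the magnitude of ``F`` unless given.
    """
    material = as_material(params)
    F, _ = _check_F(F)
    if h is None:
        h = 1e-6 * max(1.0, float(np.linalg.norm(F)))
    if h < 1e-12:
        raise ValueError("finite-difference step underflow")
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp = F.copy()
            Fm = F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (material.energy(Fp, m) - material.energy(Fm, m)) / (2.0 * h)
    return P
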