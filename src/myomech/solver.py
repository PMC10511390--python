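"""Homogeneous compression boundary-value problems for the six test protocols.

Because the platens are lubricated (friction neglected) and the specimen is a
small cube, each protocol is treated as a single homogeneous deformation: the
loading stretch is prescribed and the remaining kinematic degrees of freedom
are found from traction-free equilibrium of the free faces.  This mirrors a
single-element inverse-FEM forward run with 50 equal load steps to 40%
nominal compression.

Frame convention (fixed, right-handed Cartesian): loading along axis 3,
lateral confinement (when present) along axis 2, free lateral axis 1.

Protocols
---------
axial 0/45/90
    Unconfined compression; both lateral stretches free.  The fibre makes
    the stated angle with the loading direction (45 deg in the 1-3 plane,
    with one simple-shear degree of freedom ``F13`` so the fibre can shear
    between the parallel platens).
semi-confined modes I/II/III
    Displacement blocked along axis 2; a single free lateral stretch.  The
    fibre lies along the loading axis (mode I, fibre compressed), the free
    axis (mode II, fibre stretched), or the confined axis (mode III, fibre
    length constant).

Equilibrium at each step is found by a damped Newton iteration on the free
nominal-traction components (which are exactly the gradients of the strain
energy with respect to the free degrees of freedom), warm-started from the
previous step; a multi-start simplex energy minimization is the fallback for
the non-convex energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .constitutive import (
    InvalidDeformationError,
    Material,
    MaterialParameters,
    as_material,
)
from .curves import StressStrainCurve

__all__ = [
    "SolverError",
    "LoadProtocol",
    "axial",
    "semiconfined",
    "standard_protocols",
    "admissible_deformation",
    "equilibrium_solve",
    "simulate_protocol",
    "closed_form_semiconfined",
]

_SQ2 = math.sqrt(0.5)

# per-configuration kinematic layout:
#   ndof: number of free dofs; shear: whether dof list ends with gamma = F13
#   fibre: reference fibre direction; case: key for scalar I4 formulas
_CONFIGS: dict[tuple[str, str], dict] = {
    ("axial", "0"): dict(ndof=2, shear=False, case="e3", M=(0.0, 0.0, 1.0)),
    ("axial", "45"): dict(ndof=3, shear=True, case="f45", M=(_SQ2, 0.0, _SQ2)),
    ("axial", "90"): dict(ndof=2, shear=False, case="e1", M=(1.0, 0.0, 0.0)),
    ("semiconfined", "I"): dict(ndof=1, shear=False, case="e3", M=(0.0, 0.0, 1.0)),
    ("semiconfined", "II"): dict(ndof=1, shear=False, case="e1", M=(1.0, 0.0, 0.0)),
    ("semiconfined", "III"): dict(ndof=1, shear=False, case="e2", M=(0.0, 1.0, 0.0)),
}


class SolverError(RuntimeError):
    """Equilibrium iteration failed to converge."""


@dataclass(frozen=True)
class LoadProtocol:
    """One of the six homogeneous compression configurations.

    ``family`` is ``"axial"`` (unconfined) or ``"semiconfined"``;
    ``configuration`` is the fibre angle (``"0"``, ``"45"``, ``"90"``) or the
    semi-confined mode (``"I"``, ``"II"``, ``"III"``).
    """

    family: str
    configuration: str
    max_nominal_strain: float = 0.40
    n_steps: int = 50

    def __post_init__(self) -> None:
        if (self.family, self.configuration) not in _CONFIGS:
            raise ValueError(
                f"unknown protocol {self.family}/{self.configuration}; "
                f"valid: {sorted(_CONFIGS)}"
            )
        if not (0.0 <= self.max_nominal_strain < 1.0):
            raise ValueError("max_nominal_strain must lie in [0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.family}_{self.configuration}"

    @property
    def fibre(self) -> np.ndarray:
        """Reference fibre direction implied by the configuration."""
        return np.asarray(_CONFIGS[(self.family, self.configuration)]["M"])

    @property
    def n_free(self) -> int:
        return _CONFIGS[(self.family, self.configuration)]["ndof"]

    @property
    def reference_dofs(self) -> np.ndarray:
        cfg = _CONFIGS[(self.family, self.configuration)]
        d = np.ones(cfg["ndof"])
        if cfg["shear"]:
            d[-1] = 0.0
        return d

    def strain_grid(self) -> np.ndarray:
        """The load-step grid: eps = 0 plus n_steps equal increments."""
        if self.max_nominal_strain == 0.0:
            return np.zeros(1)
        return np.linspace(0.0, self.max_nominal_strain, self.n_steps + 1)

    def replace(self, **kw) -> "LoadProtocol":
        return replace(self, **kw)


def axial(angle: int | str, **kw) -> LoadProtocol:
    """Unconfined axial compression with fibre at 0, 45 or 90 degrees."""
    return LoadProtocol("axial", str(angle), **kw)


def semiconfined(mode: str, **kw) -> LoadProtocol:
    """Semi-confined compression, mode I, II or III."""
    return LoadProtocol("semiconfined", mode.upper(), **kw)


def standard_protocols(max_nominal_strain: float = 0.40, n_steps: int = 50):
    """The six protocols of the experimental campaign, in canonical order."""
    return [
        axial(a, max_nominal_strain=max_nominal_strain, n_steps=n_steps)
        for a in ("0", "45", "90")
    ] + [
        semiconfined(m, max_nominal_strain=max_nominal_strain, n_steps=n_steps)
        for m in ("I", "II", "III")
    ]


# --------------------------------------------------------------------------
# kinematics of the admissible deformations
# --------------------------------------------------------------------------

def _state(protocol: LoadProtocol, eps: float, dofs) -> tuple[float, float, float, float]:
    """Unpack free dofs into (l1, l2, l3, gamma)."""
    cfg = _CONFIGS[(protocol.family, protocol.configuration)]
    dofs = np.asarray(dofs, dtype=float).ravel()
    if dofs.size != cfg["ndof"]:
        raise ValueError(
            f"{protocol.name} expects {cfg['ndof']} free dof(s), got {dofs.size}"
        )
    l3 = 1.0 - eps
    if protocol.family == "semiconfined":
        return float(dofs[0]), 1.0, l3, 0.0
    if cfg["shear"]:
        return float(dofs[0]), float(dofs[1]), l3, float(dofs[2])
    return float(dofs[0]), float(dofs[1]), l3, 0.0


def admissible_deformation(protocol: LoadProtocol, eps: float, free_dofs) -> np.ndarray:
    """Deformation gradient for a protocol at nominal strain ``eps``.

    The loading stretch ``F33 = 1 - eps`` is prescribed; the free entries
    are the lateral stretches (and, for the 45 deg protocol, the simple
    shear ``F13`` in the fibre-loading plane).
    """
    if not (0.0 <= eps < 1.0):
        raise ValueError("nominal strain must lie in [0, 1)")
    l1, l2, l3, g = _state(protocol, eps, free_dofs)
    F = np.diag([l1, l2, l3])
    F[0, 2] = g
    if l1 * l2 * l3 <= 0.0:
        raise InvalidDeformationError("free dofs produce det F <= 0")
    return F


def _i4_and_derivs(case: str, l1: float, l2: float, l3: float, g: float):
    """I4 and its derivatives w.r.t. (l1, l2, l3, g) for each fibre layout."""
    if case == "e1":
        return l1 * l1, (2.0 * l1, 0.0, 0.0, 0.0)
    if case == "e2":
        return l2 * l2, (0.0, 2.0 * l2, 0.0, 0.0)
    if case == "e3":
        return g * g + l3 * l3, (0.0, 0.0, 2.0 * l3, 2.0 * g)
    if case == "f45":
        a = l1 + g
        return 0.5 * (a * a + l3 * l3), (a, 0.0, l3, a)
    raise KeyError(case)


def _gradients(
    material: Material,
    protocol: LoadProtocol,
    eps: float,
    dofs,
    want_p33: bool = False,
):
    """Energy gradients w.r.t. free dofs (= free nominal tractions), scalar path.

    For the homogeneous deformations used here the gradient of psi with
    respect to a free stretch (or the shear) is exactly the conjugate
    nominal-stress component (P11, P22 or P13), so the zero-gradient point
    is the traction-free equilibrium.  Returns the residual vector, and the
    loading-direction nominal stress P33 = dpsi/dl3 when requested.
    """
    cfg = _CONFIGS[(protocol.family, protocol.configuration)]
    l1, l2, l3, g = _state(protocol, eps, dofs)
    J = l1 * l2 * l3
    if J <= 0.0:
        raise InvalidDeformationError("det F <= 0 during equilibrium iteration")
    i1 = l1 * l1 + l2 * l2 + l3 * l3 + g * g
    Jm23 = J ** (-2.0 / 3.0)
    i1b = Jm23 * i1
    i4, di4 = _i4_and_derivs(cfg["case"], l1, l2, l3, g)
    _, p1b, p4 = material.energy_terms(i1b, i4)
    pJ = material.bulk_modulus * (2.0 * J - 2.0 / J)
    # dI1 and dJ w.r.t. (l1, l2, l3, g)
    di1 = (2.0 * l1, 2.0 * l2, 2.0 * l3, 2.0 * g)
    dJ = (l2 * l3, l1 * l3, l1 * l2, 0.0)
    c_vol = (2.0 / 3.0) * Jm23 / J * i1

    def grad(k: int) -> float:
        return p1b * (Jm23 * di1[k] - c_vol * dJ[k]) + p4 * di4[k] + pJ * dJ[k]

    if protocol.family == "semiconfined":
        res = np.array([grad(0)])
    elif cfg["shear"]:
        res = np.array([grad(0), grad(1), grad(3)])
    else:
        res = np.array([grad(0), grad(1)])
    if want_p33:
        return res, grad(2)
    return res


def _path_energy(material: Material, protocol: LoadProtocol, eps: float, dofs) -> float:
    l1, l2, l3, g = _state(protocol, eps, dofs)
    J = l1 * l2 * l3
    if J <= 0.0:
        return np.inf
    i1 = l1 * l1 + l2 * l2 + l3 * l3 + g * g
    i1b = J ** (-2.0 / 3.0) * i1
    i4, _ = _i4_and_derivs(
        _CONFIGS[(protocol.family, protocol.configuration)]["case"], l1, l2, l3, g
    )
    psi_iso, _, _ = material.energy_terms(i1b, i4)
    return psi_iso + material.bulk_modulus * (J * J - 1.0 - 2.0 * math.log(J))


# --------------------------------------------------------------------------
# equilibrium
# --------------------------------------------------------------------------

_MIN_STRETCH = 0.05
_MAX_NEWTON_STEP = 0.25


def _newton(material, protocol, eps, x0, tol, max_iter=80):
    """Damped Newton on the traction residual; returns (dofs, ok)."""
    cfg = _CONFIGS[(protocol.family, protocol.configuration)]
    n = cfg["ndof"]
    shear = cfg["shear"]
    x = np.array(x0, dtype=float)
    r = _gradients(material, protocol, eps, x)
    rn = float(np.max(np.abs(r)))
    for _ in range(max_iter):
        if rn < tol:
            return x, True
        # finite-difference Jacobian of the residual
        Jac = np.empty((n, n))
        for i in range(n):
            h = 1e-7 * max(1.0, abs(x[i]))
            xp = x.copy()
            xp[i] += h
            Jac[:, i] = (_gradients(material, protocol, eps, xp) - r) / h
        try:
            dx = np.linalg.solve(Jac, -r)
        except np.linalg.LinAlgError:
            return x, False
        cap = float(np.max(np.abs(dx)))
        if cap > _MAX_NEWTON_STEP:
            dx *= _MAX_NEWTON_STEP / cap
        # backtracking on the residual norm
        step = 1.0
        for _bt in range(10):
            xn = x + step * dx
            n_stretch = n - 1 if shear else n
            if np.any(xn[:n_stretch] < _MIN_STRETCH):
                step *= 0.5
                continue
            try:
                r_new = _gradients(material, protocol, eps, xn)
            except InvalidDeformationError:
                step *= 0.5
                continue
            rn_new = float(np.max(np.abs(r_new)))
            if rn_new < rn or rn_new < tol:
                x, r, rn = xn, r_new, rn_new
                break
            step *= 0.5
        else:
            return x, False
    return x, rn < tol


def _multistart(material, protocol, eps, tol):
    """Fallback: simplex energy minimization from a coarse grid of starts."""
    cfg = _CONFIGS[(protocol.family, protocol.configuration)]
    n, shear = cfg["ndof"], cfg["shear"]
    n_stretch = n - 1 if shear else n
    stretch_starts = (0.8, 1.0, 1.3)
    shear_starts = (-0.2, 0.0, 0.2) if shear else ((0.0,),)

    def energy(x):
        if np.any(np.asarray(x)[:n_stretch] < _MIN_STRETCH):
            return np.inf
        try:
            return _path_energy(material, protocol, eps, x)
        except InvalidDeformationError:
            return np.inf

    best_x, best_e = None, np.inf
    grids = np.meshgrid(*([stretch_starts] * n_stretch), indexing="ij")
    for idx in np.ndindex(*[len(stretch_starts)] * n_stretch):
        base = [grids[k][idx] for k in range(n_stretch)]
        for gs in shear_starts if shear else [()]:
            x0 = np.array(base + ([gs] if shear else []), dtype=float).ravel()[:n]
            res = optimize.minimize(
                energy,
                x0,
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-14, maxiter=2000),
            )
            if res.fun < best_e:
                best_x, best_e = res.x, res.fun
    x, ok = _newton(material, protocol, eps, best_x, tol)
    return x, ok


def _solve_dofs(material, protocol, eps, warm_start=None):
    if eps == 0.0:
        return protocol.reference_dofs
    tol = 1e-9 * max(1.0, material.bulk_modulus / 5000.0)
    x0 = protocol.reference_dofs if warm_start is None else np.asarray(warm_start, float)
    x, ok = _newton(material, protocol, eps, x0, tol)
    if not ok:
        x, ok = _multistart(material, protocol, eps, tol)
    if not ok:
        r = _gradients(material, protocol, eps, x)
        raise SolverError(
            f"equilibrium failed: protocol={protocol.name} eps={eps:.4f} "
            f"material={material!r} residual={np.max(np.abs(r)):.3e}"
        )
    return x


def equilibrium_solve(protocol, eps, material, warm_start=None):
    """Traction-free equilibrium at one load step.

    Returns ``(free_dofs, F, P)``: the converged free degrees of freedom, the
    deformation gradient, and the full nominal stress tensor (kPa).  Free-face
    components of ``P`` vanish to solver tolerance.
    """
    material = as_material(material)
    x = _solve_dofs(material, protocol, eps, warm_start)
    F = admissible_deformation(protocol, eps, x)
    P = material.pk1(F, protocol.fibre)
    return x, F, P


def simulate_protocol(protocol, material, fibre=None) -> StressStrainCurve:
    """Simulate one protocol: sweep the load steps with warm-started solves.

    Returns the nominal loading-direction stress curve (negative in
    compression).  The curve's ``extras`` attribute records the converged
    volume ratios (``"J"``) and free dofs per step for diagnostics (not
    serialized with the curve).
    """
    material = as_material(material)
    if fibre is not None:
        raise NotImplementedError(
            "fibre override is not supported; the direction is implied by the protocol"
        )
    grid = protocol.strain_grid()
    stresses = np.zeros(grid.size)
    Js = np.ones(grid.size)
    dofs_hist = np.tile(protocol.reference_dofs, (grid.size, 1))
    warm = None
    for k, eps in enumerate(grid):
        if eps == 0.0:
            continue
        x = _solve_dofs(material, protocol, float(eps), warm)
        warm = x
        _, p33 = _gradients(material, protocol, float(eps), x, want_p33=True)
        l1, l2, l3, _ = _state(protocol, float(eps), x)
        stresses[k] = p33
        Js[k] = l1 * l2 * l3
        dofs_hist[k] = x
    curve = StressStrainCurve(
        strain=grid,
        stress=stresses,
        protocol=protocol.name,
        meta={"material": repr(material)},
    )
    curve.extras = {"J": Js, "free_dofs": dofs_hist}
    return curve


# --------------------------------------------------------------------------
# incompressible closed form (verification oracle for the semi-confined modes)
# --------------------------------------------------------------------------

def closed_form_semiconfined(mode: str, lam, params: MaterialParameters):
    """Ideal-incompressibility loading stress for semi-confined compression.

    With exact incompressibility the kinematics are fully determined:
    ``F = diag(1/lam, 1, lam)`` (free, confined, loading axes), so the
    nominal loading stress is the total derivative ``d psi_iso / d lam``
    along that one-parameter path.  Serves as the limit of the penalty
    formulation as the bulk multiplier grows.

    ``lam`` is the loading stretch (scalar or array), ``mode`` one of
    ``"I"``, ``"II"``, ``"III"``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0) or np.any(lam > 1.0 + 1e-12):
        raise ValueError("loading stretch must lie in (0, 1]")
    c1, c2, c3 = params.c1, params.c2, params.c3
    i1 = lam**2 + 1.0 + lam**-2
    E = np.exp(c3 * (i1 - 3.0))
    f = E - 1.0
    di1 = 2.0 * lam - 2.0 * lam**-3
    mode = mode.upper()
    if mode == "I":  # fibre along loading: I4 = lam^2
        g = np.exp(c2 * (lam**2 - 1.0))
        out = c1 * g * (2.0 * c2 * lam * f + c3 * E * di1)
    elif mode == "II":  # fibre along free axis: I4 = 1/lam^2
        g = np.exp(c2 * (lam**-2 - 1.0))
        out = c1 * g * (-2.0 * c2 * lam**-3 * f + c3 * E * di1)
    elif mode == "III":  # fibre along confined axis: I4 = 1
        out = c1 * c3 * E * di1
    else:
        raise ValueError(f"unknown semi-confined mode {mode!r}")
    return out if out.ndim else float(out)
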