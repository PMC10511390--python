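"""Inverse parameter identification from compression stress-strain curves.

The forward model (one homogeneous simulation per protocol) is coupled to a
Nelder-Mead simplex search over the parameter vector ``p = (c1, c2, c3)``.
Agreement between simulated and measured curves is scored by the combined
relative square error

    O(p) = sum_i sum_j  1/(m n_i) * sqrt( (P_sim_ij - P_exp_ij)^2 / |P_exp_ij| )

where ``m`` is the number of experiments (protocols) included and ``n_i`` the
number of retained stress samples of experiment ``i``.  Two conventions are
made explicit:

* the denominator uses ``|P_exp|`` — stresses are negative in compression and
  a "relative" error requires a positive normalizer;
* samples with ``|P_exp|`` below a small floor (default 1e-3 kPa, which always
  removes the zero-stress reference point) are excluded and ``n_i`` adjusted,
  since they carry no information and would otherwise blow up the quotient.

Experimental replicates are first linearly resampled onto the simulation's
strain grid; when several replicates of a protocol are supplied, their mean
curve (pointwise arithmetic mean, sample SD) is fitted, matching how the
experimental campaign is summarised.

Positivity of ``c1`` and ``c3`` is enforced by searching in log-space; ``c2``
is searched linearly with reflection at zero so that exactly ``c2 = 0``
(an isotropic optimum) is reachable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .constitutive import MaterialParameters, PassiveMuscleModel
from .curves import StressStrainCurve
from .solver import LoadProtocol, simulate_protocol, standard_protocols

__all__ = [
    "FitConfig",
    "FitResult",
    "ExperimentSet",
    "resample_linear",
    "mean_curve",
    "objective",
    "objective_hessian",
    "fit_parameters",
    "load_campaign",
]

STRESS_FLOOR_KPA = 1e-3


# --------------------------------------------------------------------------
# curve resampling and averaging
# --------------------------------------------------------------------------

def resample_linear(curve: StressStrainCurve, grid) -> np.ndarray:
    """Piecewise-linear stress interpolation at the given strain grid.

    Exact at original sample points; extrapolation outside the curve's strain
    range is refused.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = curve.strain[0], curve.strain[-1]
    eps = 1e-12 * max(1.0, abs(hi))
    if np.any(grid < lo - eps) or np.any(grid > hi + eps):
        raise ValueError(
            f"resampling grid [{grid.min():g}, {grid.max():g}] exceeds curve "
            f"strain range [{lo:g}, {hi:g}]"
        )
    return np.interp(np.clip(grid, lo, hi), curve.strain, curve.stress)


def mean_curve(curves, grid) -> StressStrainCurve:
    """Pointwise mean of replicate curves on a shared grid.

    Each curve is resampled linearly, then the arithmetic mean and the
    sample (n-1) standard deviation are taken per grid point.  The SD is
    returned in ``extras["sd"]`` (zero for a single curve).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("mean_curve requires at least one curve")
    grid = np.asarray(grid, dtype=float)
    stack = np.vstack([resample_linear(c, grid) for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    out = StressStrainCurve(
        strain=grid,
        stress=mean,
        protocol=curves[0].protocol,
        meta={"n_replicates": len(curves)},
    )
    out.extras["sd"] = sd
    return out


# --------------------------------------------------------------------------
# experiment sets
# --------------------------------------------------------------------------

@dataclass
class ExperimentSet:
    """Replicate curves grouped by protocol, with derived mean curves."""

    curves: dict[str, list[StressStrainCurve]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, group in self.curves.items():
            if not group:
                raise ValueError(f"protocol {name!r} has no curves")

    @property
    def protocols(self) -> list[str]:
        return list(self.curves)

    def n_curves(self, protocol: str | None = None) -> int:
        if protocol is not None:
            return len(self.curves[protocol])
        return sum(len(g) for g in self.curves.values())

    def mean(self, protocol: str, grid) -> StressStrainCurve:
        return mean_curve(self.curves[protocol], grid)

    def subset(self, protocols) -> "ExperimentSet":
        names = [p.name if isinstance(p, LoadProtocol) else p for p in protocols]
        missing = [n for n in names if n not in self.curves]
        if missing:
            raise KeyError(f"experiment set lacks protocol(s) {missing}")
        return ExperimentSet(
            curves={n: self.curves[n] for n in names}, meta=dict(self.meta)
        )


def load_campaign(directory) -> ExperimentSet:
    """Read a campaign directory (curve CSVs + ``manifest.json``)."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    curves: dict[str, list[StressStrainCurve]] = {}
    for name, files in manifest["protocols"].items():
        curves[name] = [
            StressStrainCurve.from_csv(directory / f, protocol=name) for f in files
        ]
    meta = {k: v for k, v in manifest.items() if k != "protocols"}
    return ExperimentSet(curves=curves, meta=meta)


# --------------------------------------------------------------------------
# objective function
# --------------------------------------------------------------------------

def _prepare_targets(experiments: ExperimentSet, protocols, stress_floor: float):
    """Resample each protocol's mean experimental curve onto the sim grid."""
    targets = []
    for proto in protocols:
        grid = proto.strain_grid()
        mean = experiments.mean(proto.name, grid)
        keep = np.abs(mean.stress) >= stress_floor
        if not np.any(keep):
            raise ValueError(
                f"{proto.name}: all experimental stresses below the "
                f"{stress_floor} kPa floor — degenerate data"
            )
        targets.append((proto, keep, mean.stress))
    return targets


def objective(
    params: MaterialParameters,
    experiments: ExperimentSet,
    protocols=None,
    stress_floor: float = STRESS_FLOOR_KPA,
    _targets=None,
) -> float:
    """Combined relative square error O(p) over the included protocols."""
    if protocols is None:
        protocols = [p for p in standard_protocols() if p.name in experiments.curves]
    if _targets is None:
        _targets = _prepare_targets(experiments, protocols, stress_floor)
    m = len(_targets)
    total = 0.0
    for proto, keep, p_exp in _targets:
        sim = simulate_protocol(proto, params)
        n = int(keep.sum())
        resid = np.abs(sim.stress[keep] - p_exp[keep]) / np.sqrt(np.abs(p_exp[keep]))
        total += float(resid.sum()) / (m * n)
    return total


def objective_hessian(
    params: MaterialParameters,
    experiments: ExperimentSet,
    protocols=None,
    rel_step: float = 1e-2,
    abs_step: float = 1e-3,
) -> np.ndarray:
    """Central finite-difference Hessian of the objective in (c1, c2, c3).

    Used to probe identifiability: flat or nearly flat directions (e.g. the
    anisotropy exponent when only mode III is fitted) show up as small
    eigenvalues / large condition numbers.
    """
    if protocols is None:
        protocols = [p for p in standard_protocols() if p.name in experiments.curves]
    targets = _prepare_targets(experiments, protocols, STRESS_FLOOR_KPA)
    p0 = params.vector
    steps = np.maximum(rel_step * np.abs(p0), abs_step)

    def f(v):
        pars = params.replace(c1=max(v[0], 1e-8), c2=max(v[1], 0.0), c3=max(v[2], 1e-8))
        return objective(pars, experiments, protocols, _targets=targets)

    H = np.empty((3, 3))
    f0 = f(p0)
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3)
            ej = np.zeros(3)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(p0 + ei) - 2.0 * f0 + f(p0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(p0 + ei + ej) - f(p0 + ei - ej) - f(p0 - ei + ej) + f(p0 - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
    return H


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Configuration of one identification run.

    ``protocols`` selects the experiments entering the objective (m = 1, 3
    or 6 in the campaign's combination schemes); ``p0`` is the initial
    ``(c1, c2, c3)``; the simplex stops when the objective changes by less
    than ``fatol`` (and the simplex spread in search space falls below
    ``xatol``) or after ``max_iter`` iterations.
    """

    protocols: tuple = ()
    p0: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fatol: float = 1e-6
    xatol: float = 1e-4
    max_iter: int = 2000
    max_restarts: int = 3
    kvol_multiplier: float = 5000.0
    stress_floor: float = STRESS_FLOOR_KPA

    def __post_init__(self) -> None:
        if self.fatol <= 0 or self.xatol <= 0:
            raise ValueError("tolerances must be positive")
        if self.p0[0] <= 0 or self.p0[2] <= 0:
            raise ValueError("p0 must be strictly positive in c1 and c3")
        if self.p0[1] < 0:
            raise ValueError("p0 must have c2 >= 0")


@dataclass
class FitResult:
    """Outcome of a Nelder-Mead identification run."""

    params: MaterialParameters
    objective: float
    n_iter: int
    n_fev: int
    converged: bool
    m: int
    per_protocol: dict[str, float]
    flat_directions: list[str]
    p0: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "params": {
                "c1_kPa": self.params.c1,
                "c2": self.params.c2,
                "c3": self.params.c3,
                "kvol_multiplier": self.params.kvol_multiplier,
            },
            "objective": self.objective,
            "n_iter": self.n_iter,
            "n_fev": self.n_fev,
            "converged": self.converged,
            "m": self.m,
            "per_protocol": self.per_protocol,
            "flat_directions": self.flat_directions,
            "p0": list(self.p0),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, **kw)

    def report(self) -> str:
        lines = [
            f"fitted parameters: c1 = {self.params.c1:.4g} kPa, "
            f"c2 = {self.params.c2:.4g}, c3 = {self.params.c3:.4g}",
            f"objective O = {self.objective:.6g}  (m = {self.m}, "
            f"{'converged' if self.converged else 'NOT converged'}, "
            f"{self.n_iter} iterations)",
        ]
        for name, val in self.per_protocol.items():
            lines.append(f"  {name:>18s}: per-protocol residual {val:.6g}")
        if self.flat_directions:
            lines.append(
                "  warning: objective is flat in " + ", ".join(self.flat_directions)
            )
        return "\n".join(lines)


def _encode(p) -> np.ndarray:
    return np.array([math.log(p[0]), p[1], math.log(p[2])])


def _decode(x, kvol_multiplier) -> MaterialParameters:
    # reflection at zero keeps c2 >= 0 while leaving c2 = 0 reachable
    return MaterialParameters(
        c1=math.exp(min(x[0], 50.0)),
        c2=abs(x[1]),
        c3=math.exp(min(x[2], 50.0)),
        kvol_multiplier=kvol_multiplier,
    )


def fit_parameters(experiments: ExperimentSet, config: FitConfig) -> FitResult:
    """Identify (c1, c2, c3) by Nelder-Mead on the relative square error.

    Deterministic given the experiment set and configuration.  If the
    iteration cap is reached the best point so far is returned with
    ``converged=False``.
    """
    protocols = list(config.protocols) or [
        p for p in standard_protocols() if p.name in experiments.curves
    ]
    protocols = [
        p if isinstance(p, LoadProtocol) else _protocol_by_name(p) for p in protocols
    ]
    targets = _prepare_targets(experiments, protocols, config.stress_floor)
    m = len(targets)

    def fun(x):
        pars = _decode(x, config.kvol_multiplier)
        try:
            return objective(pars, experiments, protocols, _targets=targets)
        except Exception:
            return 1e12

    # Nelder-Mead with restarts: the simplex is re-initialized at the
    # incumbent until it stops improving by more than fatol, a standard
    # safeguard against premature collapse of the simplex.
    options = dict(
        fatol=config.fatol,
        xatol=config.xatol,
        maxiter=config.max_iter,
        maxfev=10 * config.max_iter,
    )
    x0 = _encode(config.p0)
    n_iter = n_fev = 0
    res = optimize.minimize(fun, x0, method="Nelder-Mead", options=options)
    n_iter += int(res.nit)
    n_fev += int(res.nfev)
    for _ in range(config.max_restarts):
        prev = float(res.fun)
        res2 = optimize.minimize(fun, res.x, method="Nelder-Mead", options=options)
        n_iter += int(res2.nit)
        n_fev += int(res2.nfev)
        if res2.fun < res.fun:
            res = res2
        if prev - float(res.fun) <= config.fatol:
            break
    best = _decode(res.x, config.kvol_multiplier)
    o_best = float(res.fun)

    per_protocol = {}
    for proto, keep, p_exp in targets:
        sim = simulate_protocol(proto, best)
        n = int(keep.sum())
        resid = np.abs(sim.stress[keep] - p_exp[keep]) / np.sqrt(np.abs(p_exp[keep]))
        per_protocol[proto.name] = float(resid.sum()) / n

    # flag directions in which the objective does not respond (identifiability)
    flat = []
    for name in ("c1", "c2", "c3"):
        v = getattr(best, name)
        step = max(0.05 * abs(v), 0.05)
        for sign in (+1.0, -1.0):
            trial = v + sign * step
            if name != "c2" and trial <= 0:
                continue
            if name == "c2" and trial < 0:
                continue
            pars = best.replace(**{name: trial})
            if abs(objective(pars, experiments, protocols, _targets=targets) - o_best) > (
                1e-10 + 1e-6 * o_best
            ):
                break
        else:
            flat.append(name)

    return FitResult(
        params=best,
        objective=o_best,
        n_iter=n_iter,
        n_fev=n_fev,
        converged=bool(res.success),
        m=m,
        per_protocol=per_protocol,
        flat_directions=flat,
        p0=tuple(config.p0),
    )


def _protocol_by_name(name: str) -> LoadProtocol:
    for p in standard_protocols():
        if p.name == name:
            return p
    raise KeyError(f"unknown protocol name {name!r}")
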