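# Methods

## Constitutive model

The tissue is treated as a homogeneous, transversely isotropic, nearly
incompressible hyperelastic solid with one perfectly aligned fibre family.
With deformation gradient `F`, volume ratio `J = det F`, right Cauchy–Green
tensor `C = FᵀF`, Flory split `F = J^(1/3) F̄`, isochoric first invariant
`Ī1 = J^(−2/3) tr C` and squared fibre stretch `I4 = C : (M ⊗ M)`, the
strain-energy density is

```
psi = c1 · g(I4) · f(Ī1) + K_vol (J² − 1 − 2 ln J)
g(I4) = exp[c2 (I4 − 1)]
f(Ī1) = exp[c3 (Ī1 − 3)] − 1
```

`f ≥ 0` vanishes only when the shape is undistorted, which makes the
reference state stress-free for any `c2`; `g` is a smooth mode factor that
is < 1 for shortened fibres, 1 at rest length and > 1 for stretched fibres.
This is the model's central design point: the fibre contribution never
switches off, so configurations that compress the fibres and configurations
that hold them at rest length produce genuinely different stresses, unlike
Heaviside-switch formulations.

The nominal stress is the analytic derivative `P = 2 F ∂psi/∂C`, assembled
from the invariant derivatives (`∂I4/∂C = M ⊗ M`, so the fibre term is the
rank-one tensor `2 ψ4 (F M) ⊗ M`). An independent central-difference oracle
(`pk1_fd_oracle`) verifies it in the tests to better than 1e-5 relative over
random admissible deformations.

The energy is intentionally simple and is *not* convex in general for
shortened fibres; the solvers therefore never assume convexity.

### Parameters

| parameter | units | meaning | default |
|---|---|---|---|
| `c1` | kPa | stress scale of the isochoric term | 0.39 |
| `c2` | – | anisotropy exponent (0 = isotropic) | 0.53 |
| `c3` | – | isotropic exponential stiffening | 1.27 |
| `kvol_multiplier` | – | `K_vol` / small-strain shear modulus | 5000 |

The defaults are the combined six-experiment identification result for
rabbit soleus tissue; they put simulated stresses at 40% compression in the
physiological range of a few to a few tens of kPa.

The bulk penalty is referred to the model's own small-strain shear modulus.
Linearizing the isochoric term at the reference state gives
`μ0 = 2 ∂psi/∂Ī1 |_ref = 2 c1 c3` (the fibre factor contributes no
reference-state stiffness because `f = 0` there), so `K_vol =
kvol_multiplier · 2 c1 c3`. Because `μ0` depends on the parameters, `K_vol`
is recomputed for every parameter iterate during identification. This
convention is a design choice of this package: it is the unique small-strain
modulus derivable from the energy itself.

## Compression protocols and equilibrium solver

All six protocols are homogeneous single-element boundary-value problems:
lubricated platens make friction negligible, the loading stretch
`λ3 = 1 − ε` is prescribed, and the remaining kinematic degrees of freedom
are set by traction-free equilibrium of the free faces. The frame is fixed:
loading along axis 3, confinement (when present) along axis 2, free lateral
axis 1.

| protocol | free dofs | fibre |
|---|---|---|
| axial 0° | λ1, λ2 | loading axis |
| axial 45° | λ1, λ2, γ = F13 | (e1 + e3)/√2 |
| axial 90° | λ1, λ2 | free axis 1 |
| semi-confined I | λ1 | loading axis (fibre compressed) |
| semi-confined II | λ1 | free axis (fibre stretched) |
| semi-confined III | λ1 | confined axis (fibre length constant) |

For the 45° specimen the deformation is assumed homogeneous with a single
simple-shear component in the fibre–loading plane (`F13`); rigid frictionless
platens stay parallel, so no `F31` tilt is admitted. This is this package's
modelling choice for a configuration whose experimental kinematics are not
fully constrained by the test description.

For these deformations the energy gradient with respect to each free dof is
exactly the conjugate nominal-traction component (`P11`, `P22`, `P13`), so
equilibrium is found as the zero of the analytic gradient: a damped Newton
iteration with finite-difference Jacobian, warm-started from the previous
load step, with step capping and residual backtracking. Because the energy
is non-convex, a multi-start Nelder–Mead energy minimization over a coarse
grid of lateral stretches (and shears) is the fallback whenever Newton
stalls; in practice the warm-started Newton converges in a handful of
iterations at every one of the 50 equal load steps to 40% strain. The
residual tolerance (1e-9 kPa, scaled with the bulk penalty) keeps free-face
tractions below 1e-6 of the peak stress. Doubling the number of load steps
changes endpoint stresses only at the 1e-10 relative level, since each step's
equilibrium is independent of the loading history for an elastic model.

An exact-incompressibility closed form for the three semi-confined modes
(`closed_form_semiconfined`, obtained by differentiating the energy along
the fully determined path `F = diag(1/λ, 1, λ)`) serves as an independent
oracle: the penalty solution approaches it monotonically as the bulk
multiplier grows, with a gap ≈ 0.1% or less at multiplier 50000.

### Known limitation: volume tolerance in mode II

At the default multiplier 5000 the volume deviation `|J − 1|` stays below
1e-3 in five of the six protocols, but reaches ≈ 1.23e-3 at 40% strain in
semi-confined mode II. This is a direct consequence of the penalty scaling:
mode II develops hydrostatic pressures of roughly 25 × μ0, so
`|J − 1| ≈ p / (4 K_vol)` slightly exceeds 1e-3 there. A larger multiplier
removes it (at multiplier 50000 the deviation is ≈ 1.2e-4) at the price of a
stiffer Newton system; the default follows the 5000 × μ0 convention rather
than chasing a uniform volume tolerance.

## Objective function and identification

The misfit between simulation and experiment is the combined relative square
error

```
O(p) = Σ_{i=1..m} Σ_{j=1..n_i} 1/(m n_i) √[(P_sim_ij − P_exp_ij)² / |P_exp_ij|]
```

per deformation increment `j` and experiment `i`. Conventions, made explicit
because the expression is ambiguous as usually typeset:

- the normalizer uses `|P_exp|`: compressive stresses are negative and a
  relative error needs a positive denominator;
- the square root is applied per point;
- `n_i` counts the *retained* samples of curve `i`: points with
  `|P_exp| < 1e-3 kPa` (always including the zero-stress reference point)
  are dropped, since they carry no information and would divide by ≈ 0;
- replicates are reduced to a mean curve per protocol first (linear
  interpolation onto the 50-step simulation grid, pointwise arithmetic mean,
  sample (n−1) SD — appropriate at the campaign's replicate counts of 12–16).

With these conventions `O` is non-negative and zero exactly when every
retained sample matches. Duplicating an experiment leaves `O` unchanged
(1/(m n) normalization).

Identification minimizes `O` over `p = (c1, c2, c3)` with Nelder–Mead.
`c1` and `c3` are searched in log-space (positivity built in); `c2` is
searched linearly with reflection at zero, so an exactly isotropic optimum
`c2 = 0` is reachable. Termination: objective change < 1e-6 and simplex
spread < 1e-4 in search space, capped at 2000 iterations. Because a simplex
can collapse prematurely on these objectives, the search is restarted from
the incumbent (fresh simplex) until an extra restart improves the objective
by less than the tolerance, up to 3 restarts — a standard Nelder–Mead
safeguard that is decisive on noisy campaigns. Given identical inputs and
configuration the whole procedure is deterministic.

`FitResult` flags directions in which the objective does not respond to a
5% parameter perturbation. The canonical example is `c2` when only
fibre-neutral (mode III) data are fitted: that path has `I4 ≡ 1`, so the
anisotropy exponent is structurally unidentifiable. Fits restricted to the
fibre-stretched mode II are locally worse conditioned than six-protocol
fits (larger objective-Hessian condition number), mirroring the scatter
that individual mode II fits show in practice.

## Synthetic campaigns

The generator emulates the design of the experimental campaign the model
was built for: six protocols with replicate counts 12/16/14 (axial 0/45/90)
and 14/15/15 (semi-confined I/II/III), 86 tests in total, 40% maximum
nominal strain in 50 steps. Each replicate is a forward simulation at the
true parameters with two noise components:

- a per-specimen stiffness factor multiplying `c1`, drawn mean-one lognormal
  (`exp(σZ − σ²/2)`, default σ = 0.2) — since the energy is proportional to
  `c1`, this scales the whole curve exactly, mimicking animal-to-animal
  stiffness spread;
- pointwise multiplicative Gaussian noise whose SD ramps linearly from 0 at
  zero strain to a fraction (default 0.25) of the local mean at maximum
  strain, reproducing the observation that scatter is largest at peak
  compression; the reference point is forced to exactly zero stress.

With 15 replicates these defaults give endpoint SD/mean ratios of roughly
25–40%, inside the ≤ 44% band reported for the real tissue. The generator
does **not** model specimen geometry variability, friction artefacts,
preconditioning, rate dependence, or within-curve noise correlation; passing
recovery tests therefore demonstrate the identifiability machinery under the
stated noise model, not robustness to every artefact of real experiments.
Because both noise components are mean-one, large campaigns average to the
noiseless curve at the generator's own √n standard-error rate — the test
suite checks the n = 200 mean against a 3.5 × SE envelope derived a priori
from the noise parameters.

All randomness flows through a single seeded generator; campaigns are
bitwise reproducible from their seed.

## Fibre-switch baseline

For the contrast study a conventional on/off model is provided:
`psi = a (e^{b(Ī1−3)} − 1) + H(I4 − 1) · k (e^{q(I4−1)²} − 1) + volumetric`,
with the unit step `H`. The squared fibre strain in the exponent makes the
energy C¹ across the switch. The specific functional form is this package's
choice — the on/off *family* is what matters, not any particular published
member. Defaults match the continuous model's matrix magnitudes
(a = 0.39 kPa, b = 1.27). Because semi-confined modes I and III both keep
`I4 ≤ 1` and share identical isotropic kinematics, the baseline produces
bitwise-identical curves for them, while the continuous model separates them
by the factor `g(I4)` — the separation at 40% strain is about 5.4 kPa at the
default parameters.

## Problem sizes and numerical choices

Default simulations use 50 load steps (51 samples including the reference
point). Acceptance-level verification sweeps use 100 random deformations
for stress/objectivity checks, 10 campaign seeds for noisy recovery, and
the full 86-curve campaign per seed; a complete acceptance run is dominated
by the 11 Nelder–Mead identifications and takes a few minutes on one CPU.
Degenerate inputs are rejected early: `det F ≤ 0`, non-unit fibre
directions, empty curve sets, all-below-floor experimental curves, and
free dofs that invert the deformation all raise specific exceptions.
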