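# Methods

## Model

The epithelium is a closed axisymmetric surface of revolution, elastic with
respect to area changes and fluid with respect to in-plane shear, carrying a
bending rigidity and internal (active) tensions and bending moments. In
dimensionless units (`κ = R0 = η = 1`, tensions in `κ/R0²`, moments in
`κ/R0`, times in `τ_a = ηR0²/κ`) the constitutive laws are

    t_ij  = (2K u + ζ + (η_b − η) v_kk) g_ij + 2η v_ij + ζ_n Q_ij
    m̄_ij = (2κ C_kk + ζ_c + η_cb DC_kk/Dt) g_ij + ζ_cn Q_ij

with the transverse tension given by the torque balance,
`t_ns = ∂_s m̄_ss + (cosψ/x)(m̄_ss − m̄_φφ)`, and the tangential/normal force
balances

    ∂_s t_ss + (cosψ/x)(t_ss − t_φφ) + C_ss t_ns = 0
    ∂_s t_ns + (cosψ/x) t_ns − C_ss t_ss − C_φφ t_φφ + P = 0.

Signs and index conventions are fixed by four analytic gates the solver
must reproduce: the Laplace law on a uniform-tension sphere, the spontaneous
curvature `C_kk = −ζ_c/(2κ)` of the isotropic moment, the anisotropic
curvature relation `C_ss − C_φφ = q ζ_cn/(2κ)` (hence the tube radius
`R_c = −2κ/ζ_cn`), and the two-sphere ideal-neck condition for budding.
Chiral terms, curvature-tensor couplings in the constitutive laws, active
effects on nematic ordering, and post-self-intersection physics are outside
the model.

The nematic amplitude `q` (with `Q_φφ = q = −Q_ss`) relaxes
quasi-statically to the Euler–Lagrange equation of a one-constant
Landau–de Gennes/Frank functional; on a closed axisymmetric surface it has
two +1 defects at the poles where `q` vanishes quadratically over the
nematic length `l_c = √(k/a)`. The text of the underlying free energy fixes
only `l_c`; the axisymmetric reduction used here,
`F ∝ ∫ dS [ k((∂_s q)² + 4(cosψ/x)² q²) − (a/2)q² + (a/4)q⁴ ]`, reduces on
the unit sphere to the amplitude equation solved by `solve_nematic`, and
its `(cosψ/x · q)²` term is what melts order in necks and junction
shoulders.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `K` | area modulus (κ/R0²) | 1000 | thin-shell relation `K = 12(R0/h)²` with `h/R0 ≈ 0.1` |
| `η, η_b` | shear / bulk viscosity | 1 | time unit definition |
| `η_cb` | bulk bending viscosity | 1e-2 | `∼ (h/R0)²`; damps short-wavelength bending |
| `η_V` | volume viscosity (free mode) | 1e-4 | fast volume relaxation, pressure small vs activity |
| `l_c` | nematic length (R0) | 0.1 | defect core small vs shell |
| `l_a` | active patch size (R0) | π (whole shell) | control of the patterning |
| `σ_s` | smooth-profile width | 0.02·L0 | dynamics profile; value not fixed by the theory |
| `μ_t, σ_t` | time switch-on | 0.01, 0.002 | target intensity reached at t ≈ 0.02 |

## Steady states

Equilibria solve a nonlinear two-point BVP with state
`(x, ψ, m̄_ss, t_ss, t_ns, s0, V [, q, ∂_s q])` and the meridian length `L`
(plus `P` for conserved volume, plus the control activity in
pseudo-arclength mode) as unknown parameters. Writing the system in
`m̄_ss` rather than `C_ss` keeps every state variable continuous across
activity steps (the curvature jump is algebraic); the area strain is
algebraic at equilibrium, `u = (t_ss − ζ + ζ_n q)/(2K)`, and the material
coordinate integrates `ds0/ds = x/(sin s0 (1+u))`.

Pole singularities: the domain is truncated at `ε = 10⁻³ R0` from each pole
and closed with series-expansion boundary conditions
(`x ≈ ε − C²ε³/6`, `ψ ≈ Cε`, `t_ns ≈ ε(C t_ss − P/2)`, `q ≈ (ε/2)∂_s q`,
`s0 ≈ ε/√(1+u)`). The transverse-tension regularity condition at the north
pole is implied by global axial force balance on a closed surface and is
omitted; keeping it would overdetermine the BVP. The collocation solver is
scipy's `solve_bvp` (adaptive fourth-order), warm-started along branches.

Activity steps: steady computations use the sharp-step patch convention.
Numerically the step is realised as a sigmoid of width
`min(0.001·L0, 0.01·min(l_a, L0−l_a))`; the constriction point of budding
branches converges as this width shrinks (68.8 at width `0.01·l_a` for
`l_a/L0 = 0.04`, vs 67.7 analytic), so the width is chosen well below both
patch dimensions. Observables that depend on the realisation (notably
where a neck sits relative to the patch edge) are sensitive to this width;
the smooth-profile (`σ_s = 0.02 L0`) branches constrict markedly later.

Branch continuation: natural stepping in the control activity (initial step
1% of the target range, halved on failure, grown on success), switching to
pseudo-arclength stepping in the (control, V) plane when natural steps fail
repeatedly or `|dV/dcontrol|` steepens; the arclength constraint enters the
BVP as one extra unknown parameter plus one boundary condition, which is
how branches are followed around folds. Termination: target reached, neck
radius below `10⁻³ R0`, meridian self-intersection (segment test plus
pole-contact), or step underflow. Stability is not classified; post-fold
segments are presumably unstable.

## Dynamics

The instantaneous velocity field solves a linear two-point BVP on the
frozen shape, fourth order in `v_n` (bending viscosity) and second order in
`v_s`, with the full viscous bending moment `m̄_ss` as one of the unknowns
so that `∂_s²v_n` stays algebraic. The pressure is an unknown parameter
(`∮ v_n dS = 0` when volume is conserved; `P = −η_V dV/dt` for a permeable
shell). The balance determines `v` only up to a rigid axial translation;
the gauge `v_n(south) = v_n(north)` removes it. Both pole regularity
conditions for `t_ns` are imposed and the system is made square with a
bordering unknown (a uniform axial force density) that vanishes at the
solution by global force balance — its computed value, ~10⁻¹¹, is an
online consistency check.

The production path discretises this linear BVP with an implicit-midpoint
(box) scheme on 1200 uniform nodes and solves one sparse LU per step;
the adaptive collocation route is retained and the two agree to ~3·10⁻⁴
relative, which a test enforces.

Time stepping is explicit Euler on the material points
(`X ← X + dt·v`, `ψ ← ψ + dt(−∂_s v_n + v_s C_ss)`), followed by arc length
reparametrisation (cubic-spline transport of `s0` and `q`), strain recovery
from the stretches (`u = f_φ f_s − 1`; the local rate law
`Du/Dt = (1+u)v_kk` is kept as a cross-check, not the primary update), and
a quasi-static warm-started nematic re-solve. The step size is capped by a
displacement bound (5·10⁻⁴ R0 by default), a 1% curvature-change bound and
the explicit-Euler stability bound of the stiff area-elastic mode,
`dt < η_b/K`, which is the binding constraint at `K = 1000`. Runs start
from the unit sphere with the sigmoidal switch-on and stop on steady state
(`max|v|` below tolerance), neck constriction, self-intersection or
`t_max`. The model is deterministic; the `seed` field in `SimConfig` exists
only for interface stability.

## Measurements

Necks are interior local minima of `x` (spline-refined); tubes are measured
as `L_c = s(s0 = l_a)` with radius `1/C_φφ` at the tube midpoint, flagged
non-tubular unless `C_φφ` is uniform over the middle half *and*
`|C_ss| ≪ C_φφ`; disc half-thickness is half the pole-to-pole axial
distance. All observables are reparametrisation-invariant.

## Problem sizes used in the test-suite

Budding branches run at `l_a/L0 ∈ {0.03, 0.04, 0.05}` to neck `10⁻³ R0`;
tube branches to `ζ_cn = −20` (homogeneous) and `δζ_cn = −40` (patterned,
`l_a/L0 ∈ {0.3, 0.7}`); the flattening scaling uses `K ∈ {250, 1000, 4000}`
along the ray `ζ_n = −K`, i.e. at equal relative area compression for each
modulus, which is where the `h ∼ K^{−1/3}` asymptote is probed; the
dynamics–statics consistency case is `l_a/L0 = 0.1`, `δζ_c = 25`, free
volume, on a 400-point grid — below that patch size's budding transition
(the two-sphere construction puts full constriction at `δζ_c ≈ 29.6`), so a
dynamically stable deformed equilibrium exists; driving the same patch at
`δζ_c = 40`, beyond the transition, is checked to produce the division-like
constriction pathway instead (neck radius vanishing in time). Near the
transition the neck equilibria found by continuation are dynamically
unstable in this realisation: trajectories escape to constriction under
every loading protocol tried, which is why the consistency case sits
clearly below the transition.

## Known limitations

- Equilibrium balance residuals are measured on the returned collocation
  interpolant, normalised by the local tension scale; pole caps
  (`|s| < 2% L`) are excluded where `1/x` limits amplify interpolation
  error. Homogeneous-state identities (e.g. the anisotropic curvature
  relation) are checked away from the pole caps for the same reason: the
  suppressed `1/x²` homogeneous mode turns ~10⁻¹⁰ boundary-condition
  residuals into ~10⁻⁴ pointwise values at `x = ε`.
- The patterned-tube length follows the area-conservation prediction only
  up to a finite-`l_c` correction: a fixed amount of active area sits in
  the junction shoulder between shell and tube, where the nematic melts.
  The relative deficit is ~2% at `l_a/L0 = 0.7` but ~9% at `l_a/L0 = 0.3`,
  and does not shrink with larger `|δζ_cn|`.
- The smooth and sharp activity profiles are different physical problems
  near shape transitions: constriction thresholds can differ by tens of
  percent between them (see the step-width discussion above).
- The strain-rate cross-check (`Du/Dt` from the material map versus
  `(1+u) v_kk`) agrees at the 10⁻²-RMS level on the production grid; it is
  limited by cubic-spline transport of the material coordinate across
  reparametrisations, whose differentiation noise grows under grid
  refinement at fixed step size. The strain bookkeeping itself satisfies
  `u = f_φ f_s − 1` to machine precision by construction.
- No stability analysis: dynamic simulation is the only stability probe.
- Self-intersection ends a run; fusion and topology change are out of
  scope.
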