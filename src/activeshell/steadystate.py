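"""Mechanical-equilibrium shapes of the active shell and branch continuation.

At steady state all velocities vanish, so the viscous terms drop out of the
constitutive laws and the equilibrium is governed by a nonlinear two-point
boundary-value problem along the meridian.  The state vector is

    y = (x, psi, mbar_ss, t_ss, t_ns, s0, V [, q, dq])

with the meridian length ``L`` (and, for conserved volume, the pressure
``P``) as unknown parameters.  The area strain is algebraic at equilibrium,
``u = (t_ss - zeta + zeta_n q) / (2K)``, and the total curvature follows
from the moment variable, ``C_kk = (mbar_ss - zeta_c + zeta_cn q)/(2 kappa)``
-- writing the system in terms of ``mbar_ss`` (continuous across activity
steps) instead of ``C_ss`` (which jumps there) keeps the collocation
well-behaved.

The geometric pole singularities are handled by truncating the domain at a
small cutoff ``eps`` from each pole and imposing series-expansion boundary
conditions there; the transverse-tension condition at the north pole is
implied by global axial force balance and is omitted (the system would
otherwise be overdetermined by one condition).

Solution branches versus a control activity are continued by natural
stepping in the control, switching to pseudo-arclength stepping in the
(control, V) plane near folds, which allows following branches into regions
where the equilibrium is non-unique in the control parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_simpson, solve_bvp

from .activity import ActivityPattern, evaluate_profiles
from .geometry import (
    AxisymShape,
    MaterialMap,
    L0,
    cphiphi_from,
    material_map_from_s0,
    self_intersects,
    surface_measures,
)
from .mechanics import Parameters, TensionMomentField
from .nematic import NematicField, solve_nematic

__all__ = [
    "ShellEquilibrium",
    "SolutionBranch",
    "EquilibriumError",
    "solve_equilibrium",
    "continue_branch",
    "ideal_neck_line",
]

_EPS = 1e-3  # pole cutoff, units of R0
V0_SPHERE = 4.0 * np.pi / 3.0


class EquilibriumError(RuntimeError):
    """BVP solver failure, carrying residual diagnostics."""


def steady_profile_width(pattern: ActivityPattern) -> float | None:
    """Numerical width of the activity step used by the steady solver.

    A sharp step makes the collocation right-hand side discontinuous; the
    solver replaces it by a narrow sigmoid whose width is small compared to
    both the active and the passive region.  Smooth-mode patterns keep their
    own width.  Returns None for a fully homogeneous pattern.
    """
    if pattern.mode == "smooth":
        return pattern.sigma_s
    la = pattern.la
    if la >= L0 - 1e-12:
        return None
    return min(0.001 * L0, 0.01 * min(la, L0 - la))


@dataclass
class ShellEquilibrium:
    """One converged steady state of the shell."""

    shape: AxisymShape
    nematic: NematicField | None
    mmap: MaterialMap
    fields: TensionMomentField
    P: float
    V: float
    pattern: ActivityPattern
    params: Parameters
    volume_mode: str
    control: tuple[str, float] | None = None
    residuals: tuple[float, float] = (np.nan, np.nan)
    _warm: dict = field(default_factory=dict, repr=False)

    @property
    def area(self) -> float:
        return surface_measures(self.shape)[0]


@dataclass
class SolutionBranch:
    """Ordered family of equilibria along a control parameter."""

    control_name: str
    equilibria: list[ShellEquilibrium]
    termination: str = "max-control"
    fold_indices: list[int] = field(default_factory=list)

    @property
    def control_values(self) -> np.ndarray:
        return np.array([eq.control[1] for eq in self.equilibria])

    def observables(self):
        import pandas as pd

        from .diagnostics import measure_neck

        rows = []
        for eq in self.equilibria:
            neck = measure_neck(eq.shape)
            rows.append(
                {
                    "control": eq.control[1],
                    "V": eq.V,
                    "P": eq.P,
                    "L": eq.shape.L,
                    "neck_radius": neck["radius"] if neck["found"] else np.nan,
                    "ckk_south": eq.shape.ckk()[0],
                    "ckk_north": eq.shape.ckk()[-1],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BVP assembly
# ---------------------------------------------------------------------------

class _System:
    """Closure bundle for the steady-state BVP in solve_bvp form.

    Index map: 0 x, 1 psi, 2 mbar_ss, 3 t_ss, 4 t_ns, 5 s0, 6 V
    and, when the nematic is active, 7 q, 8 dq.
    Parameter vector: [L] (+[P] if conserved) (+[control] if arclength).
    """

    def __init__(self, pattern, params, volume_mode, with_nematic,
                 control_name=None, arclength=None, V0=V0_SPHERE):
        self.pattern = pattern
        self.params = params
        self.volume_mode = volume_mode
        self.with_nematic = with_nematic
        self.control_name = control_name
        self.arclength = arclength  # dict(tc, tV, c_ref, V_ref, ds, c_scale)
        self.V0 = V0
        self.sigma = steady_profile_width(pattern)
        self.n = 9 if with_nematic else 7
        self.conserved = volume_mode == "conserved"

    # parameter vector layout ------------------------------------------------
    def unpack_params(self, p):
        L = p[0]
        i = 1
        if self.conserved:
            P = p[i]
            i += 1
        else:
            P = 0.0
        ctrl = p[i] if self.arclength is not None else None
        return L, P, ctrl

    def pattern_at(self, ctrl):
        if ctrl is None or self.control_name is None:
            return self.pattern
        return self.pattern.with_control(self.control_name, float(ctrl))

    def profiles(self, s0, ctrl):
        return evaluate_profiles(self.pattern_at(ctrl), s0,
                                 t=None, sigma_override=self.sigma)

    # ODE right-hand side ----------------------------------------------------
    def rhs(self, tau, y, p):
        prm = self.params
        L, P, ctrl = self.unpack_params(p)
        span = L - 2.0 * _EPS
        x = np.clip(y[0], 1e-10, None)
        psi = y[1]
        mss, tss, tns = y[2], y[3], y[4]
        s0 = np.clip(y[5], 1e-10, np.pi - 1e-10)
        if self.with_nematic:
            q, dq = y[7], y[8]
        else:
            q = dq = np.zeros_like(x)
        prof = self.profiles(s0, ctrl)
        zn_q = prof["zeta_n"] * q
        u = (tss - prof["zeta"] + zn_q) / (2.0 * prm.K)
        tphi = tss + 2.0 * zn_q
        sinpsi, cospsi = np.sin(psi), np.cos(psi)
        cphi = sinpsi / x
        ckk = (mss - prof["zeta_c"] + prof["zeta_cn"] * q) / (2.0 * prm.kappa)
        css = ckk - cphi
        c = cospsi / x

        d = np.empty((self.n, x.size))
        d[0] = cospsi
        d[1] = css
        d[2] = tns + 2.0 * c * prof["zeta_cn"] * q
        d[3] = 2.0 * c * zn_q - css * tns
        d[4] = -c * tns + css * tss + cphi * tphi - P
        d[5] = x / (np.sin(s0) * (1.0 + u))
        d[6] = np.pi * x * x * sinpsi
        if self.with_nematic:
            lc2 = prm.lc * prm.lc
            d[7] = dq
            d[8] = q * (q * q - 1.0) / (2.0 * lc2) + c * (4.0 * c * q - dq)
        return span * d

    # boundary conditions ----------------------------------------------------
    def bc(self, ya, yb, p):
        prm = self.params
        L, P, ctrl = self.unpack_params(p)
        e = _EPS
        qa = ya[7] if self.with_nematic else 0.0
        qb = yb[7] if self.with_nematic else 0.0
        prof_a = self.profiles(np.atleast_1d(np.clip(ya[5], 0.0, np.pi)), ctrl)
        prof_b = self.profiles(np.atleast_1d(np.clip(yb[5], 0.0, np.pi)), ctrl)
        za, zca, zna, zcna = (prof_a[k][0] for k in ("zeta", "zeta_c", "zeta_n", "zeta_cn"))
        zb, zcb, znb, zcnb = (prof_b[k][0] for k in ("zeta", "zeta_c", "zeta_n", "zeta_cn"))

        css_a = (ya[2] - zca + zcna * qa) / (4.0 * prm.kappa)
        css_b = (yb[2] - zcb + zcnb * qb) / (4.0 * prm.kappa)
        ua = max((ya[3] - za + zna * qa) / (2.0 * prm.K), -0.95)
        ub = max((yb[3] - zb + znb * qb) / (2.0 * prm.K), -0.95)

        res = [
            ya[0] - (e - css_a**2 * e**3 / 6.0),
            ya[1] - css_a * e,
            ya[4] - e * (css_a * (ya[3] + zna * qa) - 0.5 * P),
            ya[5] - e / np.sqrt(1.0 + ua),
            ya[6],
            yb[0] - (e - css_b**2 * e**3 / 6.0),
            yb[1] - (np.pi - css_b * e),
            yb[5] - (np.pi - e / np.sqrt(1.0 + ub)),
        ]
        if self.with_nematic:
            res.append(ya[7] - 0.5 * e * ya[8])
            res.append(yb[7] + 0.5 * e * yb[8])
        if self.conserved:
            res.append(yb[6] - self.V0)
        if self.arclength is not None:
            al = self.arclength
            res.append(
                (ctrl - al["c_ref"]) / al["c_scale"] * al["tc"]
                + (yb[6] - al["V_ref"]) / al["V_scale"] * al["tV"]
                - al["ds"]
            )
        return np.array(res)


def _sphere_guess(system: _System, params: Parameters, n: int = 151):
    """Initial mesh and state for the undeformed unit sphere."""
    tau = np.linspace(0.0, 1.0, n)
    L = np.pi
    s = _EPS + tau * (L - 2 * _EPS)
    y = np.zeros((system.n, n))
    y[0] = np.sin(s)
    y[1] = s
    y[2] = 4.0 * params.kappa
    y[5] = s
    y[6] = cumulative_simpson(np.pi * np.sin(s) ** 2 * np.sin(s), x=s, initial=0.0)
    if system.with_nematic:
        sphere = AxisymShape.sphere(n=401)
        fld = solve_nematic(sphere, params.lc)
        y[7] = np.interp(s, sphere.s, fld.q)
        y[8] = np.interp(s, sphere.s, fld.dq)
    p = [L]
    if system.conserved:
        p.append(0.0)
    return tau, y, np.array(p)


def _coarsen(tau, y, max_keep=1600):
    if tau.size <= max_keep:
        return tau, y
    idx = np.unique(np.linspace(0, tau.size - 1, max_keep).astype(int))
    return tau[idx], y[:, idx]


def solve_equilibrium(
    pattern: ActivityPattern,
    params: Parameters,
    volume_mode: str = "free",
    guess: ShellEquilibrium | None = None,
    with_nematic: bool | None = None,
    control: tuple[str, float] | None = None,
    arclength: dict | None = None,
    V0: float = V0_SPHERE,
    tol: float = 1e-8,
    max_nodes: int = 12000,
) -> ShellEquilibrium:
    """Solve the equilibrium BVP for a given activity pattern.

    ``guess`` warm-starts from a previous equilibrium (branch continuation);
    otherwise the undeformed sphere is used, which is the exact solution at
    zero activity.  ``control`` records which activity increment is being
    scanned; in ``arclength`` mode that increment becomes an unknown of the
    BVP constrained by a pseudo-arclength condition.
    """
    if volume_mode not in ("free", "conserved"):
        raise ValueError("volume_mode must be 'free' or 'conserved'")
    if with_nematic is None:
        with_nematic = pattern.uses_nematic() or (
            control is not None and control[0] in ("dzeta_n", "dzeta_cn")
        )
    control_name = control[0] if control is not None else None
    if control is not None and arclength is None:
        pattern = pattern.with_control(*control)

    system = _System(
        pattern, params, volume_mode, with_nematic,
        control_name=control_name, arclength=arclength, V0=V0,
    )

    if guess is not None and guess._warm:
        tau, y = _coarsen(guess._warm["tau"], guess._warm["y"])
        p = list(guess._warm["p"][:1])
        if system.conserved:
            p.append(guess.P if np.isfinite(guess.P) else 0.0)
        if arclength is not None:
            p.append(arclength["c_start"])
        p = np.array(p)
    else:
        tau, y, p = _sphere_guess(system, params)
        if arclength is not None:
            p = np.append(p, arclength["c_start"])

    sol = solve_bvp(system.rhs, system.bc, tau, y, p=p, tol=tol,
                    max_nodes=max_nodes, verbose=0)
    if not sol.success:
        raise EquilibriumError(
            f"equilibrium solver failed: {sol.message} "
            f"(max rms residual {np.max(sol.rms_residuals):.2e}, "
            f"{sol.x.size} nodes)"
        )
    return _assemble(system, sol, control_name)


def _assemble(system: _System, sol, control_name) -> ShellEquilibrium:
    prm = system.params
    L, P, ctrl = system.unpack_params(sol.p)
    pattern = system.pattern_at(ctrl)
    tau = sol.x
    y = sol.y
    s_in = _EPS + tau * (L - 2 * _EPS)

    # extend to the poles with the series values
    s = np.concatenate([[0.0], s_in, [L]])

    def ext(row, left, right):
        return np.concatenate([[left], row, [right]])

    if system.with_nematic:
        q_in, dq_in = y[7], y[8]
    else:
        q_in = dq_in = np.zeros_like(s_in)

    prof_in = system.profiles(np.clip(y[5], 0, np.pi), ctrl)
    css_a = (y[2][0] - prof_in["zeta_c"][0] + prof_in["zeta_cn"][0] * q_in[0]) / (4 * prm.kappa)
    css_b = (y[2][-1] - prof_in["zeta_c"][-1] + prof_in["zeta_cn"][-1] * q_in[-1]) / (4 * prm.kappa)

    x = ext(y[0], 0.0, 0.0)
    psi = ext(y[1], 0.0, np.pi)
    mss = ext(y[2], y[2][0], y[2][-1])
    tss = ext(y[3], y[3][0], y[3][-1])
    tns = ext(y[4], 0.0, 0.0)
    s0 = ext(y[5], 0.0, np.pi)
    q = ext(q_in, 0.0, 0.0)
    dq = ext(dq_in, 0.0, 0.0)

    prof = system.profiles(s0, ctrl)
    ckk = (mss - prof["zeta_c"] + prof["zeta_cn"] * q) / (2.0 * prm.kappa)
    cphiphi = cphiphi_from(psi, x, 0.5 * ckk)
    css = ckk - cphiphi
    css[0], cphiphi[0] = css_a, css_a
    css[-1], cphiphi[-1] = css_b, css_b

    z = cumulative_simpson(np.sin(psi), x=s, initial=0.0) - 1.0
    shape = AxisymShape(s=s, x=x, z=z, psi=psi, css=css, cphiphi=cphiphi, L=L)

    mmap = material_map_from_s0(shape, s0)
    # at equilibrium u is algebraic in t_ss; prefer the mechanical value
    u_mech = (tss - prof["zeta"] + prof["zeta_n"] * q) / (2.0 * prm.K)
    mmap.u = u_mech
    tphiphi = tss + 2.0 * prof["zeta_n"] * q
    mphiphi = mss + 2.0 * prof["zeta_cn"] * q
    fields = TensionMomentField(tss=tss, tphiphi=tphiphi, tns=tns,
                                mss=mss, mphiphi=mphiphi)

    nem = None
    if system.with_nematic:
        nem = NematicField(q=q, dq=dq, lc=prm.lc,
                           trivial=bool(np.max(np.abs(q)) < 1e-3))

    V = float(y[6][-1])
    ctrl_val = None
    if control_name is not None:
        ctrl_val = getattr(pattern, control_name)

    eq = ShellEquilibrium(
        shape=shape, nematic=nem, mmap=mmap, fields=fields,
        P=float(P), V=V, pattern=pattern, params=prm,
        volume_mode=system.volume_mode,
        control=(control_name, float(ctrl_val)) if control_name else None,
        residuals=_dense_residuals(system, sol),
        # keep only what a warm restart needs; the dense solver object is
        # large for long meshes and branches hold many equilibria
        _warm={"tau": tau, "y": y, "p": sol.p},
    )
    return eq


def _dense_residuals(system: _System, sol, n_probe: int = 2000):
    """Force-balance residuals of the returned interpolant.

    Evaluates d/ds of the collocation solution minus the balance right-hand
    sides on a fine grid (poles excluded), normalised by the local tension
    scale.  Rows 3 and 4 of the system are exactly the tangential and normal
    force balances.
    """
    L = sol.p[0]
    tau = np.linspace(0.005, 0.995, n_probe)
    y = sol.sol(tau)
    dy = sol.sol(tau, 1)
    f = system.rhs(tau, y, sol.p)
    scale = np.maximum(1.0, np.abs(y[3]))
    span = L - 2 * _EPS
    r_tan = np.max(np.abs(dy[3] - f[3]) / scale) / span
    r_norm = np.max(np.abs(dy[4] - f[4]) / scale) / span
    return float(r_tan), float(r_norm)


# ---------------------------------------------------------------------------
# Branch continuation
# ---------------------------------------------------------------------------

def continue_branch(
    pattern: ActivityPattern,
    params: Parameters,
    control: str,
    target: float,
    volume_mode: str = "free",
    step0: float | None = None,
    max_step: float | None = None,
    min_step_frac: float = 1e-5,
    neck_threshold: float = 1e-3,
    max_steps: int = 400,
    tol: float = 1e-8,
    max_nodes: int = 12000,
    fold_slope: float = 40.0,
    store_every: int = 1,
    callback: Callable | None = None,
) -> SolutionBranch:
    """Follow the branch of equilibria from zero control towards ``target``.

    Natural stepping in the control parameter, halving the step on solver
    failure; after repeated failures, or when ``|dV/dcontrol|`` steepens
    beyond ``fold_slope`` (scaled units), the stepper switches to
    pseudo-arclength in the (control, V) plane and can round folds.
    Terminates on: reaching the target, neck radius below
    ``neck_threshold`` R0, meridian self-intersection, or step underflow.
    """
    from .diagnostics import measure_neck

    if target == 0:
        raise ValueError("target control must be nonzero")
    sgn = np.sign(target)
    c_scale = abs(target)
    step0 = abs(step0) if step0 else 0.01 * c_scale
    max_step = abs(max_step) if max_step else 0.05 * c_scale
    min_step = min_step_frac * c_scale

    with_nem = control in ("dzeta_n", "dzeta_cn") or pattern.uses_nematic()
    eqs: list[ShellEquilibrium] = []
    folds: list[int] = []
    termination = "max-steps"

    eq = solve_equilibrium(pattern, params, volume_mode,
                           control=(control, 0.0), with_nematic=with_nem,
                           tol=tol, max_nodes=max_nodes)
    eqs.append(eq)

    mode = "natural"
    dc = sgn * step0
    fails = 0
    ds_arc = None
    V_scale = max(abs(eq.V), 1.0)

    for it in range(max_steps):
        prev = eqs[-1]
        c_prev = prev.control[1]
        try:
            if mode == "natural":
                c_new = c_prev + dc
                if sgn * (c_new - target) > 0:
                    c_new = target
                eq = solve_equilibrium(pattern, params, volume_mode,
                                       guess=prev, control=(control, c_new),
                                       with_nematic=with_nem, tol=tol,
                                       max_nodes=max_nodes)
            else:
                tc, tV = _branch_tangent(eqs, c_scale, V_scale)
                arc = {
                    "tc": tc, "tV": tV,
                    "c_ref": c_prev, "V_ref": prev.V,
                    "c_scale": c_scale, "V_scale": V_scale,
                    "ds": ds_arc, "c_start": c_prev + tc * ds_arc * c_scale,
                }
                eq = solve_equilibrium(pattern, params, volume_mode,
                                       guess=prev, control=(control, c_prev),
                                       arclength=arc, with_nematic=with_nem,
                                       tol=tol, max_nodes=max_nodes)
        except EquilibriumError:
            fails += 1
            if mode == "natural":
                dc *= 0.5
                if abs(dc) < min_step or fails >= 2:
                    if len(eqs) >= 2:
                        mode = "arclength"
                        ds_arc = max(4 * min_step / c_scale,
                                     0.25 * _last_ds(eqs, c_scale, V_scale))
                        fails = 0
                        continue
                if abs(dc) < min_step:
                    termination = "step-underflow"
                    break
            else:
                ds_arc *= 0.5
                if ds_arc < min_step / c_scale:
                    termination = "step-underflow"
                    break
            continue

        fails = 0
        eqs.append(eq)
        if len(eqs) >= 3:
            eqs[-3]._warm = {}  # bound branch memory; restarts use the tail
        if callback is not None:
            callback(eq)

        # fold bookkeeping: control reversal along the branch
        if len(eqs) >= 3:
            d1 = eqs[-1].control[1] - eqs[-2].control[1]
            d2 = eqs[-2].control[1] - eqs[-3].control[1]
            if d1 * d2 < 0 and not (folds and folds[-1] >= len(eqs) - 3):
                folds.append(len(eqs) - 2)

        neck = measure_neck(eq.shape)
        if neck["found"] and neck["radius"] < neck_threshold:
            termination = "neck-constriction"
            break
        if self_intersects(eq.shape):
            termination = "self-intersection"
            break
        if mode == "natural" and eq.control[1] == target:
            termination = "max-control"
            break
        if mode == "arclength" and sgn * (eq.control[1] - target) >= 0:
            # land exactly on the requested control value
            try:
                eq_t = solve_equilibrium(pattern, params, volume_mode,
                                         guess=eq, control=(control, target),
                                         with_nematic=with_nem, tol=tol,
                                         max_nodes=max_nodes)
                eqs.append(eq_t)
            except EquilibriumError:
                pass
            termination = "max-control"
            break

        # step adaptation and mode switching
        if mode == "natural":
            if len(eqs) >= 2:
                dV = abs(eqs[-1].V - eqs[-2].V) / V_scale
                dC = abs(eqs[-1].control[1] - eqs[-2].control[1]) / c_scale
                if dC > 0 and dV / dC > fold_slope:
                    mode = "arclength"
                    ds_arc = _last_ds(eqs, c_scale, V_scale)
                    continue
            dc = sgn * min(abs(dc) * 1.4, max_step)
        else:
            ds_arc = min(ds_arc * 1.3, max_step / c_scale * 4)

    else:
        termination = "max-steps"

    if store_every > 1:
        kept = eqs[::store_every]
        if kept[-1] is not eqs[-1]:
            kept.append(eqs[-1])
        eqs = kept
    return SolutionBranch(control_name=control, equilibria=eqs,
                          termination=termination, fold_indices=folds)


def _last_ds(eqs, c_scale, V_scale):
    dc = (eqs[-1].control[1] - eqs[-2].control[1]) / c_scale
    dV = (eqs[-1].V - eqs[-2].V) / V_scale
    return float(np.hypot(dc, dV))


def _branch_tangent(eqs, c_scale, V_scale):
    dc = (eqs[-1].control[1] - eqs[-2].control[1]) / c_scale
    dV = (eqs[-1].V - eqs[-2].V) / V_scale
    h = np.hypot(dc, dV)
    if h == 0:
        return 1.0, 0.0
    return dc / h, dV / h


# ---------------------------------------------------------------------------
# Ideal neck line (two-sphere construction)
# ---------------------------------------------------------------------------

def ideal_neck_line(
    la_over_L0: np.ndarray | float,
    kappa: float = 1.0,
    regime: str | None = None,
):
    """Bending-moment difference for budding into two unstrained spheres.

    With free volume and vanishing strain the two compartments inherit their
    areas from the initial sphere: the active cap of meridional size ``la``
    has area ``2 pi (1 - cos la)``, giving radii ``Ra = sin(la/2)`` and
    ``Rp = cos(la/2)``.  Matching the meridional bending moment across the
    infinitesimal neck (the meridional tension changes sign there and
    carries no condition) gives

        inward bud  (small active cap):  dzeta_c = 4 kappa (1/Ra + 1/Rp)
        outward bud (small passive cap): dzeta_c = 4 kappa (1/Rp - 1/Ra)

    the sign difference arising because the inward bud is a sphere of
    negative mean curvature.
    """
    frac = np.atleast_1d(np.asarray(la_over_L0, dtype=float))
    if np.any((frac <= 0) | (frac >= 1)):
        raise ValueError("la/L0 must lie strictly between 0 and 1")
    la = frac * np.pi
    Ra = np.sin(la / 2.0)
    Rp = np.cos(la / 2.0)
    if regime is None:
        inward = frac <= 0.5
    else:
        inward = np.full_like(frac, regime == "inward", dtype=bool)
    dzc = np.where(inward, 4.0 * kappa * (1.0 / Ra + 1.0 / Rp),
                   4.0 * kappa * (1.0 / Rp - 1.0 / Ra))
    out = {"la_over_L0": frac, "dzeta_c": dzc, "Ra": Ra, "Rp": Rp,
           "inward": inward}
    if np.isscalar(la_over_L0) or np.asarray(la_over_L0).ndim == 0:
        return {k: (v.item() if hasattr(v, "item") else v) for k, v in out.items()}
    return out
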