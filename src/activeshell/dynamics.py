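"""Time evolution of the active shell.

Each step solves the *instantaneous* force/torque balance for the velocity
field on the frozen current shape: with the viscous constitutive terms the
balance is a linear two-point BVP in ``(v_s, v_n)``, fourth order in the
normal velocity (through the bending viscosity) and second order in the
tangential one.  The state vector used is

    y = (v_s, ds v_s, v_n, ds v_n, mbar_ss, t_ns, Iv)

where ``mbar_ss`` is the full (viscous-inclusive) meridional bending moment
and ``Iv = int 2 pi x v_n ds`` accumulates the volume rate.  The pressure
``P`` is an unknown parameter: for conserved volume it is the Lagrange
multiplier enforcing ``Iv(L) = 0``; for a permeable shell it follows the
volume-viscosity law ``P = -eta_V dV/dt``.  The balance determines the
velocity only up to a rigid translation along the axis; the gauge
``v_n(south) + v_n(north) = 0`` removes it without affecting the shape
evolution.

Material points are then advected with the full velocity (explicit Euler),
the surface is reparametrised to arc length, the material map and activity
profiles are advected, the area strain is recomputed from the stretches,
and the nematic order parameter is re-solved quasi-statically on the new
shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.interpolate import CubicSpline

from .activity import ActivityPattern, evaluate_profiles
from .geometry import (
    AxisymShape,
    MaterialMap,
    ShapeError,
    material_map_from_s0,
    reparametrise,
    self_intersects,
    surface_measures,
)
from .mechanics import FlowField, Parameters, flow_kinematics
from .nematic import NematicField, solve_nematic

__all__ = ["ShellState", "SimConfig", "FlowError", "instantaneous_flow",
           "advance", "run_simulation", "initial_state"]

# pole cutoff for the flow problem: boundary-condition truncation excites the
# shell's softest mode (amplified near incipient necks), so the cutoff is
# kept an order of magnitude below the steady solver's; the clustered flow
# grid resolves the 1/x terms there
_EPS = 1e-4


class FlowError(RuntimeError):
    pass


@dataclass
class ShellState:
    """Complete dynamical state at one instant (arc length parametrised)."""

    t: float
    shape: AxisymShape
    mmap: MaterialMap
    pattern: ActivityPattern
    params: Parameters
    volume_mode: str
    nematic: NematicField | None = None
    flow: FlowField | None = None
    P: float = 0.0
    V: float = 0.0

    @property
    def q(self) -> np.ndarray:
        if self.nematic is None:
            return np.zeros_like(self.shape.s)
        return self.nematic.q


@dataclass
class SimConfig:
    """Time-stepping controls (all in dimensionless units).

    The step is capped by a displacement bound (``disp_cap`` per step), a
    relative curvature-change bound, and an explicit-Euler stability bound
    for the stiff area-elastic mode, ``dt < eta_b / K``.
    """

    dt0: float = 1e-5
    dt_max: float = 1e-3
    disp_cap: float = 5e-4
    curv_frac: float = 0.01
    t_max: float = 1.0
    steady_vtol: float = 1e-3
    neck_threshold: float = 1e-3
    n_grid: int = 400
    output_every: int = 20
    seed: int = 0  # unused: the model is deterministic; kept for interface stability


def initial_state(pattern: ActivityPattern, params: Parameters,
                  volume_mode: str = "free", n: int = 400) -> ShellState:
    """Undeformed unit sphere at t=0 with the activity still switched off."""
    shape = AxisymShape.sphere(n=n)
    mmap = MaterialMap.identity(shape)
    nem = solve_nematic(shape, params.lc) if pattern.uses_nematic() else None
    _, V = surface_measures(shape)
    return ShellState(t=0.0, shape=shape, mmap=mmap, pattern=pattern,
                      params=params, volume_mode=volume_mode, nematic=nem, V=V)


# ---------------------------------------------------------------------------
# instantaneous flow BVP
# ---------------------------------------------------------------------------

class _FlowSystem:
    def __init__(self, state: ShellState, params: Parameters):
        sh = state.shape
        s = sh.s
        self.L = sh.L
        self.prm = params
        self.conserved = state.volume_mode == "conserved"
        prof = evaluate_profiles(state.pattern, state.mmap.s0, t=state.t)
        q = state.q
        u = state.mmap.u

        self.x_s = CubicSpline(s, sh.x)
        self.psi_s = CubicSpline(s, sh.psi)
        self.css_s = CubicSpline(s, sh.css)
        self.cphi_s = CubicSpline(s, sh.cphiphi)
        self.dcss_s = self.css_s.derivative()
        self.dcphi_s = self.cphi_s.derivative()
        es = 2.0 * params.K * u + prof["zeta"] - prof["zeta_n"] * q
        self.es_s = CubicSpline(s, es)
        self.des_s = self.es_s.derivative()
        ms = 2.0 * params.kappa * sh.ckk() + prof["zeta_c"] - prof["zeta_cn"] * q
        self.ms_s = CubicSpline(s, ms)
        self.znq_s = CubicSpline(s, prof["zeta_n"] * q)
        self.zcnq_s = CubicSpline(s, prof["zeta_cn"] * q)

    def geo(self, s):
        x = np.clip(self.x_s(s), 1e-10, None)
        psi = self.psi_s(s)
        css = self.css_s(s)
        cphi = self.cphi_s(s)
        c = np.cos(psi) / x
        dc = -np.sin(psi) * css / x - np.cos(psi) ** 2 / (x * x)
        return x, psi, css, cphi, c, dc

    def rhs(self, tau, y, p):
        prm = self.prm
        P, lam = p[0], p[1]
        span = self.L - 2 * _EPS
        s = _EPS + tau * span
        x, psi, css, cphi, c, dc = self.geo(s)
        dcss, dcphi = self.dcss_s(s), self.dcphi_s(s)
        dckk = dcss + dcphi
        es, des = self.es_s(s), self.des_s(s)
        ms = self.ms_s(s)
        znq = self.znq_s(s)
        zcnq = self.zcnq_s(s)

        vs, dvs, vn, dvn, mss, tns, _ = y
        eb, e = prm.eta_b, prm.eta
        vss = dvs + css * vn
        vphi = c * vs + cphi * vn
        tss = es + (eb + e) * vss + (eb - e) * vphi
        tphi = (es + 2.0 * znq) + (eb + e) * vphi + (eb - e) * vss
        ddtckk = (mss - ms) / prm.eta_cb

        # lam is a bordering unknown: a uniform axial external force density
        # lam * z_hat whose amplitude must vanish by global force balance.
        # It makes the BVP square while both pole regularity conditions for
        # t_ns and the rigid-translation gauge are imposed.
        sinpsi = np.sin(psi)
        d = np.empty_like(y)
        d[0] = dvs
        d[1] = (
            -c * (tss - tphi)
            - css * tns
            - lam * sinpsi
            - des
            - (eb + e) * (css * dvn + vn * dcss)
            - (eb - e) * (vs * dc + c * dvs + cphi * dvn + vn * dcphi)
        ) / (eb + e)
        d[2] = dvn
        d[3] = -ddtckk - c * dvn - vn * (css**2 + cphi**2) + vs * dckk
        d[4] = tns + 2.0 * c * zcnq
        d[5] = -c * tns + css * tss + cphi * tphi - P + lam * np.cos(psi)
        d[6] = 2.0 * np.pi * x * vn
        return span * d

    def _pole_data(self, sa: float):
        x, psi, css, cphi, c, dc = self.geo(np.atleast_1d(sa))
        return css[0], cphi[0]

    def bc(self, ya, yb, p):
        prm = self.prm
        P = p[0]
        e = _EPS
        sa, sb = e, self.L - e
        css_a, cphi_a = self._pole_data(sa)
        css_b, cphi_b = self._pole_data(sb)
        ms_a, ms_b = float(self.ms_s(sa)), float(self.ms_s(sb))
        es_a, es_b = float(self.es_s(sa)), float(self.es_s(sb))
        dckk_a = float(self.dcss_s(sa) + self.dcphi_s(sa))
        dckk_b = float(self.dcss_s(sb) + self.dcphi_s(sb))

        # regular part of the dvn equation (the 1/s term excluded)
        g_a = (-(ya[4] - ms_a) / prm.eta_cb
               - ya[2] * (css_a**2 + cphi_a**2) + ya[0] * dckk_a)
        g_b = (-(yb[4] - ms_b) / prm.eta_cb
               - yb[2] * (css_b**2 + cphi_b**2) + yb[0] * dckk_b)
        # at a pole v_ss = v_phiphi, so t_ss = E_s + 2 eta_b (dvs + Css vn)
        tss_a = es_a + 2.0 * prm.eta_b * (ya[1] + css_a * ya[2])
        tss_b = es_b + 2.0 * prm.eta_b * (yb[1] + css_b * yb[2])

        res = [
            ya[0] - e * ya[1],
            ya[3] - 0.5 * e * g_a,
            ya[5] - e * (css_a * tss_a - 0.5 * P),
            ya[6],
            yb[0] + e * yb[1],
            yb[3] + 0.5 * e * g_b,
            yb[5] + e * (css_b * tss_b - 0.5 * P),
            ya[2] - yb[2],  # rigid-translation gauge (vn is -V/+V at the poles)
        ]
        if self.conserved:
            res.append(yb[6])
        else:
            res.append(P + prm.eta_V * yb[6])
        return np.array(res)


def _linear_coefficients(sys_: "_FlowSystem", s: np.ndarray):
    """Matrix form of the flow ODEs: dy/ds = A(s) y + Cp(s) [P, lam] + b(s)."""
    prm = sys_.prm
    x, psi, css, cphi, c, dc = sys_.geo(s)
    dcss, dcphi = sys_.dcss_s(s), sys_.dcphi_s(s)
    dckk = dcss + dcphi
    es, des = sys_.es_s(s), sys_.des_s(s)
    ms = sys_.ms_s(s)
    znq = sys_.znq_s(s)
    zcnq = sys_.zcnq_s(s)
    eb, e = prm.eta_b, prm.eta
    m = s.size
    A = np.zeros((m, 7, 7))
    b = np.zeros((m, 7))
    Cp = np.zeros((m, 7, 2))
    sinpsi, cospsi = np.sin(psi), np.cos(psi)

    A[:, 0, 1] = 1.0
    den = eb + e
    A[:, 1, 0] = (2 * e * c * c - (eb - e) * dc) / den
    A[:, 1, 1] = (-2 * e * c - (eb - e) * c) / den
    A[:, 1, 2] = (-2 * e * c * (css - cphi) - den * dcss - (eb - e) * dcphi) / den
    A[:, 1, 3] = (-den * css - (eb - e) * cphi) / den
    A[:, 1, 5] = -css / den
    b[:, 1] = (2 * c * znq - des) / den
    Cp[:, 1, 1] = -sinpsi / den

    A[:, 2, 3] = 1.0
    A[:, 3, 0] = dckk
    A[:, 3, 2] = -(css**2 + cphi**2)
    A[:, 3, 3] = -c
    A[:, 3, 4] = -1.0 / prm.eta_cb
    b[:, 3] = ms / prm.eta_cb

    A[:, 4, 5] = 1.0
    b[:, 4] = 2.0 * c * zcnq

    A[:, 5, 0] = css * (eb - e) * c + cphi * den * c
    A[:, 5, 1] = css * den + cphi * (eb - e)
    A[:, 5, 2] = css * (den * css + (eb - e) * cphi) + cphi * (den * cphi + (eb - e) * css)
    A[:, 5, 5] = -c
    b[:, 5] = (css + cphi) * es + cphi * 2.0 * znq
    Cp[:, 5, 0] = -1.0
    Cp[:, 5, 1] = cospsi

    A[:, 6, 2] = 2.0 * np.pi * x
    return A, b, Cp


def _solve_flow_direct(sys_: "_FlowSystem", m: int = 1200):
    """Direct sparse solve of the linear flow BVP (implicit midpoint).

    Unknowns: 7 fields at m nodes plus (P, lam).  Second-order accurate;
    one sparse LU factorisation, no iteration — the per-step workhorse of
    the time stepper.  Cross-validated against the collocation route.
    """
    from scipy.sparse import coo_matrix, csc_matrix
    from scipy.sparse.linalg import spsolve

    prm = sys_.prm
    e = _EPS
    # cosine-clustered nodes: the 1/x pole terms (~1/eps at the cutoffs)
    # need locally fine spacing that a uniform grid cannot afford
    tau = np.linspace(0.0, 1.0, m)
    s = e + (sys_.L - 2 * e) * 0.5 * (1.0 - np.cos(np.pi * tau))
    h = np.diff(s)
    smid = 0.5 * (s[:-1] + s[1:])
    A, bvec, Cp = _linear_coefficients(sys_, smid)

    n_unk = 7 * m + 2
    rhs = np.zeros(n_unk)
    eye = np.eye(7)
    mi = m - 1
    J = -0.5 * h[:, None, None] * A  # (mi, 7, 7)
    blk_l = (J - eye).ravel()
    blk_r = (J + eye).ravel()
    i_idx = np.arange(mi)
    rows_blk = (7 * i_idx[:, None, None] + np.arange(7)[None, :, None]
                + np.zeros(7, dtype=int)[None, None, :]).ravel()
    cols_l = (7 * i_idx[:, None, None] + np.zeros(7, dtype=int)[None, :, None]
              + np.arange(7)[None, None, :]).ravel()
    cols_r = cols_l + 7
    rows_p = (7 * i_idx[:, None, None] + np.arange(7)[None, :, None]
              + np.zeros(2, dtype=int)[None, None, :]).ravel()
    cols_p = (7 * m + np.arange(2)[None, None, :]
              + np.zeros((mi, 7, 1), dtype=int)).ravel()
    data = np.concatenate([blk_l, blk_r, (-h[:, None, None] * Cp).ravel()])
    rows_all = [np.concatenate([rows_blk, rows_blk, rows_p])]
    cols_all = [np.concatenate([cols_l, cols_r, cols_p])]
    data_all = [data]
    rhs[:7 * mi] = (h[:, None] * bvec).ravel()
    row = 7 * mi

    bc_rows, bc_cols, bc_data = [], [], []

    class _M:  # tiny adapter so the boundary-row helper below stays readable
        @staticmethod
        def add(r, c, v):
            bc_rows.append(r)
            bc_cols.append(c)
            bc_data.append(v)

    M = _M

    # boundary rows -------------------------------------------------------
    sa, sb = s[0], s[-1]
    css_a, cphi_a = sys_._pole_data(sa)
    css_b, cphi_b = sys_._pole_data(sb)
    ms_a, ms_b = float(sys_.ms_s(sa)), float(sys_.ms_s(sb))
    es_a, es_b = float(sys_.es_s(sa)), float(sys_.es_s(sb))
    dckk_a = float(sys_.dcss_s(sa) + sys_.dcphi_s(sa))
    dckk_b = float(sys_.dcss_s(sb) + sys_.dcphi_s(sb))
    ia = 0
    ib = 7 * (m - 1)
    iP, il = 7 * m, 7 * m + 1

    def bcrow(cols_vals, rhs_val=0.0):
        nonlocal row
        for col, val in cols_vals:
            M.add(row, col, val)
        rhs[row] = rhs_val
        row += 1

    # vs regularity at both poles
    bcrow([(ia + 0, 1.0), (ia + 1, -e)])
    bcrow([(ib + 0, 1.0), (ib + 1, e)])
    # dvn regularity: dvn -+ (e/2) * g = 0 with
    # g = -(mss - Ms)/eta_cb - vn (Css^2+Cphi^2) + vs dCkk
    ga = [(ia + 4, 1.0 / prm.eta_cb), (ia + 2, css_a**2 + cphi_a**2), (ia + 0, -dckk_a)]
    bcrow([(ia + 3, 1.0)] + [(c_, 0.5 * e * v) for c_, v in ga], -0.5 * e * ms_a / prm.eta_cb)
    gb = [(ib + 4, 1.0 / prm.eta_cb), (ib + 2, css_b**2 + cphi_b**2), (ib + 0, -dckk_b)]
    bcrow([(ib + 3, 1.0)] + [(c_, -0.5 * e * v) for c_, v in gb], 0.5 * e * ms_b / prm.eta_cb)
    # tns regularity at both poles: tns = +- e (Css tss - P/2),
    # tss = Es + 2 eta_b (dvs + Css vn) at a pole
    bcrow([(ia + 5, 1.0),
           (ia + 1, -e * css_a * 2 * prm.eta_b),
           (ia + 2, -e * css_a * 2 * prm.eta_b * css_a),
           (iP, 0.5 * e)], e * css_a * es_a)
    bcrow([(ib + 5, 1.0),
           (ib + 1, e * css_b * 2 * prm.eta_b),
           (ib + 2, e * css_b * 2 * prm.eta_b * css_b),
           (iP, -0.5 * e)], -e * css_b * es_b)
    # volume integral starts at zero; translation gauge
    bcrow([(ia + 6, 1.0)])
    bcrow([(ia + 2, 1.0), (ib + 2, -1.0)])
    if sys_.conserved:
        bcrow([(ib + 6, 1.0)])
    else:
        bcrow([(iP, 1.0), (ib + 6, prm.eta_V)])

    rows_all.append(np.asarray(bc_rows))
    cols_all.append(np.asarray(bc_cols))
    data_all.append(np.asarray(bc_data, dtype=float))
    Mat = csc_matrix(
        coo_matrix(
            (np.concatenate(data_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(n_unk, n_unk),
        )
    )
    sol = spsolve(Mat, rhs)
    y = sol[:7 * m].reshape(m, 7).T
    return s, y, float(sol[iP]), float(sol[il])


def instantaneous_flow(state: ShellState, params: Parameters | None = None,
                       tol: float = 1e-6, max_nodes: int = 24000,
                       method: str = "direct", m: int = 1200):
    """Solve the linear flow problem on the current shape.

    ``method="direct"`` (default) assembles the linear two-point BVP as one
    sparse system on ``m`` uniform nodes and solves it with a single LU
    factorisation; ``method="collocation"`` uses the adaptive collocation
    solver instead (slower; used as an independent numerical route in
    validation tests).  Returns ``(vs, vn, P)`` sampled on the state grid
    (poles included, with ``vs = 0`` there) plus the raw solver output.
    """
    params = params or state.params
    sys_ = _FlowSystem(state, params)
    s_grid = state.shape.s

    if method == "direct":
        s_fd, y, P, lam = _solve_flow_direct(sys_, m=m)
        vs = np.interp(s_grid, s_fd, y[0])
        vn = np.interp(s_grid, s_fd, y[2])
        vs[0] = vs[-1] = 0.0
        return vs, vn, P, (s_fd, y, lam)

    from scipy.integrate import solve_bvp

    warm = getattr(state, "_flow_warm", None)
    if warm is not None:
        tau0, y0, p0 = warm
    else:
        tau0 = np.linspace(0.0, 1.0, 201)
        y0 = np.zeros((7, tau0.size))
        p0 = np.array([0.0, 0.0])
    sol = solve_bvp(sys_.rhs, sys_.bc, tau0, y0, p=p0, tol=tol,
                    max_nodes=max_nodes, verbose=0)
    if not sol.success:
        raise FlowError(f"flow solver failed: {sol.message} "
                        f"(max rms residual {np.max(sol.rms_residuals):.2e})")
    P = float(sol.p[0])
    L = state.shape.L
    tau = np.clip((s_grid - _EPS) / (L - 2 * _EPS), 0.0, 1.0)
    ys = sol.sol(tau)
    vs, vn = ys[0], ys[2]
    vs[0] = vs[-1] = 0.0
    state._flow_warm = (sol.x, sol.y, sol.p)  # type: ignore[attr-defined]
    return vs, vn, P, sol


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def _choose_dt(state: ShellState, cfg: SimConfig, vs, vn) -> float:
    prm = state.params
    vmax = max(float(np.max(np.hypot(vs, vn))), 1e-14)
    flow = flow_kinematics(state.shape, vs, vn)
    ckk_rate = max(float(np.max(np.abs(flow.dtckk))), 1e-14)
    ckk_scale = max(float(np.max(np.abs(state.shape.ckk()))), 1.0)
    dt_stiff = 0.8 * prm.eta_b / prm.K  # explicit-Euler bound for the area mode
    return float(min(cfg.dt_max, dt_stiff, cfg.disp_cap / vmax,
                     cfg.curv_frac * ckk_scale / ckk_rate))


def advance(state: ShellState, cfg: SimConfig, dt: float | None = None) -> ShellState:
    """One explicit Euler step of the Lagrangian surface evolution."""
    sh = state.shape
    vs, vn, P, _ = instantaneous_flow(state)
    if dt is None:
        dt = _choose_dt(state, cfg, vs, vn)

    sinp, cosp = np.sin(sh.psi), np.cos(sh.psi)
    dvn = CubicSpline(sh.s, vn).derivative()(sh.s)
    x_new = sh.x + dt * (vs * cosp + vn * sinp)
    z_new = sh.z + dt * (vs * sinp - vn * cosp)
    psi_new = sh.psi + dt * (-dvn + vs * sh.css)
    x_new[0] = x_new[-1] = 0.0
    if np.any(x_new[1:-1] <= 0):
        raise ShapeError("meridian crossed the axis during the step")

    moved = AxisymShape(s=sh.s, x=x_new, z=z_new, psi=psi_new,
                        css=sh.css, cphiphi=sh.cphiphi, L=sh.L)
    carried = {"s0": state.mmap.s0}
    if state.nematic is not None:
        carried["q"] = state.nematic.q
    new_shape, fields = reparametrise(moved, carried, n=cfg.n_grid)
    # rebuild the tangent angle from the moved curve itself: evolving psi
    # independently accumulates drift against (x, z), which feeds noisy
    # curvature into the next flow solve and can tangle the mesh at folds
    dx = new_shape.spline("x").derivative()(new_shape.s)
    dz = new_shape.spline("z").derivative()(new_shape.s)
    psi_curve = np.unwrap(np.arctan2(dz, dx))
    psi_curve += np.round((new_shape.psi[0] - psi_curve[0]) / (2 * np.pi)) * 2 * np.pi
    new_shape.psi = psi_curve
    new_shape._spl.pop("psi", None)
    # axis regularity is exact; interpolation drift at the poles is O(dt * h^2)
    new_shape.psi[0], new_shape.psi[-1] = 0.0, np.pi
    psi_spl = CubicSpline(new_shape.s, new_shape.psi)
    new_shape.css = psi_spl.derivative()(new_shape.s)
    from .geometry import cphiphi_from

    new_shape.cphiphi = cphiphi_from(new_shape.psi, new_shape.x, new_shape.css)
    mmap = material_map_from_s0(new_shape, np.clip(fields["s0"], 0.0, np.pi))
    mmap.s0[0], mmap.s0[-1] = 0.0, np.pi

    nem = None
    if state.nematic is not None:
        warm = NematicField(q=fields["q"],
                            dq=CubicSpline(new_shape.s, fields["q"]).derivative()(new_shape.s),
                            lc=state.params.lc, trivial=state.nematic.trivial)
        nem = solve_nematic(new_shape, state.params.lc,
                            guess=None if warm.trivial else warm, tol=1e-8)

    _, V = surface_measures(new_shape)
    flow = flow_kinematics(sh, vs, vn)
    return ShellState(t=state.t + dt, shape=new_shape, mmap=mmap,
                      pattern=state.pattern, params=state.params,
                      volume_mode=state.volume_mode, nematic=nem,
                      flow=flow, P=P, V=V)


@dataclass
class Trajectory:
    frames: list[ShellState]
    summary: list[dict]
    termination: str

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(self.summary)


def run_simulation(cfg: SimConfig, pattern: ActivityPattern, params: Parameters,
                   volume_mode: str = "free",
                   state: ShellState | None = None) -> Trajectory:
    """Evolve from the unit sphere with sigmoidal activity switch-on.

    Stops on steady state (``max |v| < steady_vtol`` after the switch-on has
    completed), neck constriction, self-intersection, or ``t_max``.
    """
    from .diagnostics import measure_neck

    if pattern.mode != "smooth":
        pattern = replace(pattern, mode="smooth")
    if state is None:
        state = initial_state(pattern, params, volume_mode, n=cfg.n_grid)
    frames = [state]
    summary = []
    termination = "t-max"
    switch_done = state.pattern.mu_t + 5 * state.pattern.sigma_t
    step = 0
    while state.t < cfg.t_max:
        try:
            state = advance(state, cfg)
        except (ShapeError, FlowError) as err:
            termination = f"aborted: {err}"
            break
        step += 1
        vmax = float(np.max(np.hypot(state.flow.vs, state.flow.vn)))
        neck = measure_neck(state.shape)
        if step % cfg.output_every == 0:
            frames.append(state)
        summary.append({
            "t": state.t, "V": state.V, "P": state.P, "vmax": vmax,
            "neck_radius": neck["radius"] if neck["found"] else np.nan,
            "ckk_south": float(state.shape.ckk()[0]),
            "ckk_north": float(state.shape.ckk()[-1]),
        })
        if state.t > switch_done and vmax < cfg.steady_vtol:
            termination = "steady-state"
            break
        if neck["found"] and neck["radius"] < cfg.neck_threshold:
            termination = "neck-constriction"
            break
        if self_intersects(state.shape):
            termination = "self-intersection"
            break
    if frames[-1] is not state:
        frames.append(state)
    return Trajectory(frames=frames, summary=summary, termination=termination)
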