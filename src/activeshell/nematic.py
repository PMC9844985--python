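"""Quasi-static nematic order on an axisymmetric closed surface.

With axial symmetry the tangent nematic tensor has the single independent
component ``q = Q_phiphi = -Q_ss``.  The Poincare--Hopf theorem forces two +1
defects at the poles, where ``q = 0``; order melts there over the nematic
length ``lc = sqrt(k/a)`` (Frank constant ``k``, Landau coefficient ``a``).
The amplitude satisfies the Euler--Lagrange equation

    d2q/ds2 = q (q^2 - 1) / (2 lc^2)
              + (cos psi / x) * (4 (cos psi / x) q - dq/ds),

solved as a boundary-value problem with ``q = 0`` at both poles.  Near a pole
the regular solution vanishes quadratically, ``q ~ c s^2``, which supplies the
boundary conditions on the truncated domain ``[eps, L-eps]``.

In the bulk of a large sphere ``q -> +-1``; the positive branch (``q > 0``,
circumferential alignment) is the reference convention.  On surfaces smaller
than or comparable to ``lc`` only the isotropic solution ``q = 0`` exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson, solve_bvp
from scipy.interpolate import CubicSpline

from .geometry import AxisymShape

__all__ = ["NematicField", "NematicError", "solve_nematic", "defect_census", "free_energy"]


class NematicError(RuntimeError):
    pass


@dataclass
class NematicField:
    """Scalar order parameter amplitude on the shape grid."""

    q: np.ndarray
    dq: np.ndarray  # d q / d s
    lc: float
    trivial: bool = False  # True when only the isotropic solution q=0 exists
    residual: float = 0.0

    def spline(self, s: np.ndarray) -> CubicSpline:
        return CubicSpline(s, self.q)


def _cot_term(shape: AxisymShape, s: np.ndarray) -> np.ndarray:
    """cos(psi)/x evaluated by splines; safe on the truncated domain."""
    x = np.clip(shape.spline("x")(s), 1e-12, None)
    return np.cos(shape.spline("psi")(s)) / x


def solve_nematic(
    shape: AxisymShape,
    lc: float,
    branch_sign: int = +1,
    guess: NematicField | None = None,
    eps: float = 1e-4,
    tol: float = 1e-10,
    max_nodes: int = 40000,
) -> NematicField:
    """Solve the amplitude equation on a given closed shape.

    ``branch_sign`` selects the bulk sign of the ordered solution.  If the
    solver only reaches the trivial solution (max |q| below 1e-3) the field is
    returned flagged ``trivial=True``, which is the physical outcome for
    shapes smaller than or comparable to ``lc``.
    """
    if lc <= 0:
        raise ValueError("nematic length lc must be positive")
    L = shape.L
    eps = min(eps, 1e-3 * L)
    a, b = eps, L - eps

    def rhs(s, y):
        q, dq = y
        c = _cot_term(shape, s)
        return np.vstack([dq, q * (q * q - 1.0) / (2.0 * lc * lc) + c * (4.0 * c * q - dq)])

    def bc(ya, yb):
        # q ~ c s^2 at each pole: q(eps) = (eps/2) dq(eps) (mirror at north)
        return np.array([ya[0] - 0.5 * eps * ya[1], yb[0] + 0.5 * eps * yb[1]])

    if guess is not None and guess.q.size >= 8 and not guess.trivial:
        s_init = np.linspace(a, b, max(64, guess.q.size))
        frac = (s_init - a) / (b - a)
        old = np.linspace(0.0, 1.0, guess.q.size)
        q0 = np.interp(frac, old, guess.q)
        dq0 = np.interp(frac, old, guess.dq)
        y0 = np.vstack([q0, dq0])
    else:
        s_init = np.linspace(a, b, 201)
        w = max(2.0 * lc, 4.0 * eps)
        bump = (1.0 - np.exp(-((s_init - 0.0) / w) ** 2)) * (
            1.0 - np.exp(-((L - s_init) / w) ** 2)
        )
        q0 = branch_sign * bump
        dq0 = np.gradient(q0, s_init)
        y0 = np.vstack([q0, dq0])

    sol = solve_bvp(rhs, bc, s_init, y0, tol=tol, max_nodes=max_nodes)
    if not sol.success:
        raise NematicError(f"nematic solver failed: {sol.message} "
                           f"(max residual {np.max(sol.rms_residuals):.2e})")

    s_out = shape.s
    q = np.zeros_like(s_out)
    dq = np.zeros_like(s_out)
    inner = (s_out >= a) & (s_out <= b)
    q[inner], dq[inner] = sol.sol(s_out[inner])
    # quadratic pole caps
    south = s_out < a
    north = s_out > b
    c_s = sol.sol(a)[0] / (a * a)
    c_n = sol.sol(b)[0] / (eps * eps)
    q[south] = c_s * s_out[south] ** 2
    dq[south] = 2.0 * c_s * s_out[south]
    q[north] = c_n * (L - s_out[north]) ** 2
    dq[north] = -2.0 * c_n * (L - s_out[north])

    fld = NematicField(q=q, dq=dq, lc=lc, residual=float(np.max(sol.rms_residuals)))
    if np.max(np.abs(q)) < 1e-3:
        fld.trivial = True
        fld.q[:] = 0.0
        fld.dq[:] = 0.0
    elif np.sign(q[np.argmax(np.abs(q))]) != np.sign(branch_sign):
        raise NematicError("solver converged to the wrong branch")
    return fld


def defect_census(field: NematicField, shape: AxisymShape, threshold: float = 0.5):
    """Count defect cores and estimate their size.

    A core is a maximal region with ``|q| < threshold`` contiguous to a pole;
    its size is the arc distance from the pole to the first threshold
    crossing.  Undefined for a disordered field.
    """
    if field.trivial or np.max(np.abs(field.q)) <= threshold:
        return {"count": None, "core_sizes": None, "disordered": True}
    absq = np.abs(field.q)
    above = absq >= threshold
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    count = int(first > 0) + int(last < len(above) - 1)
    s = shape.s

    def crossing(i_lo, i_hi):
        # linear interpolation of the threshold crossing between grid nodes
        f = (threshold - absq[i_lo]) / (absq[i_hi] - absq[i_lo])
        return s[i_lo] + f * (s[i_hi] - s[i_lo])

    sizes = []
    if first > 0:
        sizes.append(crossing(first - 1, first) - s[0])
    if last < len(above) - 1:
        sizes.append(s[-1] - crossing(last + 1, last))
    return {"count": count, "core_sizes": sizes, "disordered": False}


def free_energy(shape: AxisymShape, q: np.ndarray, lc: float, a_coef: float = 1.0) -> float:
    """Discretised Landau-de Gennes + Frank functional on the surface.

    With ``Q_phiphi = q = -Q_ss`` the gradient term reduces to
    ``k [ (dq/ds)^2 + 4 (cos psi/x)^2 q^2 ]`` and the bulk part to
    ``-(a/2) q^2 + (a/4) q^4`` (so that ``Q_ij Q_ij = 2 q^2 = 2`` minimises
    the bulk part for ``a > 0``).  ``k = a lc^2``.
    """
    k = a_coef * lc * lc
    dq = CubicSpline(shape.s, q).derivative()(shape.s)
    c = np.empty_like(shape.s)
    interior = shape.x > 1e-9
    c[interior] = np.cos(shape.psi[interior]) / shape.x[interior]
    # at the poles cos(psi)/x ~ 1/s diverges, but q ~ s^2 keeps c*q finite;
    # the integrand with weight x -> 0 vanishes there, so clamp is harmless
    c[~interior] = 0.0
    cq2 = np.where(interior, (c * q) ** 2, 0.0)
    dens = k * (dq**2 + 4.0 * cq2) - 0.5 * a_coef * q**2 + 0.25 * a_coef * q**4
    return float(simpson(2.0 * np.pi * shape.x * dens, x=shape.s))
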