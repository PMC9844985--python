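"""Constitutive laws, flow kinematics and force/torque balance residuals.

The shell carries an in-plane tension tensor ``t_ij`` and a (rotated) bending
moment tensor ``mbar_ij``; with axial symmetry and no azimuthal flow both are
diagonal, with components ``(t_ss, t_phiphi)`` and ``(mbar_ss, mbar_phiphi)``
plus the transverse tension ``t_ns``.  The constitutive laws are

    t_ij    = (2 K u + zeta + (eta_b - eta) v_kk) g_ij + 2 eta v_ij
              + zeta_n Q_ij,
    mbar_ij = (2 kappa C_kk + zeta_c + eta_cb D C_kk/Dt) g_ij + zeta_cn Q_ij,

with ``Q_phiphi = q = -Q_ss``.  The tangential/normal force balance and the
torque balance reduce, for a surface of revolution, to

    ds t_ss  + (cos psi / x) (t_ss - t_phiphi) + C_ss t_ns          = 0,
    ds t_ns  + (cos psi / x) t_ns - C_ss t_ss - C_phiphi t_phiphi + P = 0,
    t_ns     = ds mbar_ss + (cos psi / x) (mbar_ss - mbar_phiphi),

(the signs fixed by requiring the Laplace limit ``C_kk t = P`` on a sphere
and the tube law ``C_ss - C_phiphi = q zeta_cn / (2 kappa)`` on homogeneous
nematic-bending equilibria).  For diagonal tensors the antisymmetric-part
identity ``eps_ij t_ij = C_ij m_ij`` is satisfied identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import AxisymShape, cphiphi_from

__all__ = [
    "Parameters",
    "TensionMomentField",
    "FlowField",
    "flow_kinematics",
    "constitutive_tensions",
    "constitutive_moments",
    "balance_residuals",
    "antisymmetry_identity",
]


@dataclass(frozen=True)
class Parameters:
    """Material parameters in dimensionless units (kappa = R0 = eta = 1).

    ``K`` is the area modulus in units of kappa/R0^2 (thin-shell estimate
    ``K = 12 (R0/h)^2``, so the default 1000 corresponds to a relative
    thickness h/R0 of about 0.1); ``eta`` and ``eta_b`` are the shear and
    bulk viscosities, ``eta_cb`` the bulk bending viscosity damping changes
    of total curvature, and ``eta_V`` the volume viscosity coupling pressure
    to volume changes for a permeable shell.  ``lc`` is the nematic length.
    The active time unit is ``tau_a = eta R0^2 / kappa``.
    """

    K: float = 1000.0
    kappa: float = 1.0
    eta: float = 1.0
    eta_b: float = 1.0
    eta_cb: float = 1e-2
    eta_V: float = 1e-4
    lc: float = 0.1
    R0: float = 1.0

    def __post_init__(self):
        for name in ("K", "kappa", "eta", "eta_b", "eta_cb", "eta_V", "lc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    @property
    def tau_a(self) -> float:
        return self.eta * self.R0**2 / self.kappa

    @property
    def thickness_ratio(self) -> float:
        """h/R0 implied by the thin-shell relation K = 12 (R0/h)^2."""
        return float(np.sqrt(12.0 / self.K))


@dataclass
class TensionMomentField:
    tss: np.ndarray
    tphiphi: np.ndarray
    tns: np.ndarray
    mss: np.ndarray  # mbar_ss
    mphiphi: np.ndarray  # mbar_phiphi


@dataclass
class FlowField:
    vs: np.ndarray
    vn: np.ndarray
    vss: np.ndarray
    vphiphi: np.ndarray
    dtcss: np.ndarray  # corotational rate of C_ss
    dtcphiphi: np.ndarray
    omega_n: float = 0.0  # identically zero with axial symmetry

    @property
    def vkk(self) -> np.ndarray:
        return self.vss + self.vphiphi

    @property
    def dtckk(self) -> np.ndarray:
        return self.dtcss + self.dtcphiphi


def _pole_safe_ratio(num: np.ndarray, x: np.ndarray, limit: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(num, float))
    near = np.abs(x) < 1e-9
    out[~near] = num[~near] / x[~near]
    out[near] = limit[near]
    return out


def flow_kinematics(shape: AxisymShape, vs: np.ndarray, vn: np.ndarray) -> FlowField:
    """Strain rates and corotational curvature rates for a given velocity.

    v_ss = ds vs + C_ss vn ;  v_phiphi = (cos psi/x) vs + C_phiphi vn ;
    DC_ss/Dt = -ds^2 vn - vn C_ss^2 + vs ds C_ss ;
    DC_phiphi/Dt = -(cos psi/x) ds vn - vn C_phiphi^2 + vs ds C_phiphi.

    At the poles ``vs`` must vanish (axis regularity); pole values of 1/x
    terms are replaced by their analytic limits.
    """
    s = shape.s
    if abs(vs[0]) > 1e-10 or abs(vs[-1]) > 1e-10:
        raise ValueError("tangential velocity must vanish at the poles")
    vs_spl = CubicSpline(s, vs)
    vn_spl = CubicSpline(s, vn)
    dvs = vs_spl.derivative()(s)
    dvn = vn_spl.derivative()(s)
    d2vn = vn_spl.derivative(2)(s)
    dcss = CubicSpline(s, shape.css).derivative()(s)
    dcphiphi = CubicSpline(s, shape.cphiphi).derivative()(s)

    cospsi = np.cos(shape.psi)
    # limits at the poles: vs/x -> ds vs, (cos psi/x) ds vn -> ds^2 vn
    vs_over = _pole_safe_ratio(cospsi * vs, shape.x, dvs)
    dvn_over = _pole_safe_ratio(cospsi * dvn, shape.x, d2vn)

    vss = dvs + shape.css * vn
    vphiphi = vs_over + shape.cphiphi * vn
    dtcss = -d2vn - vn * shape.css**2 + vs * dcss
    dtcphiphi = -dvn_over - vn * shape.cphiphi**2 + vs * dcphiphi
    return FlowField(vs=vs, vn=vn, vss=vss, vphiphi=vphiphi,
                     dtcss=dtcss, dtcphiphi=dtcphiphi)


def constitutive_tensions(
    shape: AxisymShape,
    flow: FlowField | None,
    u: np.ndarray,
    q: np.ndarray,
    profiles: dict,
    params: Parameters,
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane tension components ``(t_ss, t_phiphi)``.

    ``flow=None`` means a steady state (all viscous terms vanish).
    """
    iso = 2.0 * params.K * u + profiles["zeta"]
    if flow is not None:
        iso = iso + (params.eta_b - params.eta) * flow.vkk
        visc_ss = 2.0 * params.eta * flow.vss
        visc_phi = 2.0 * params.eta * flow.vphiphi
    else:
        visc_ss = visc_phi = 0.0
    tss = iso + visc_ss - profiles["zeta_n"] * q
    tphiphi = iso + visc_phi + profiles["zeta_n"] * q
    return tss, tphiphi


def constitutive_moments(
    shape: AxisymShape,
    flow: FlowField | None,
    q: np.ndarray,
    profiles: dict,
    params: Parameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bending moments ``(mbar_ss, mbar_phiphi)`` and transverse tension.

    The transverse tension is the divergence of the moment tensor,
    ``t_ns = ds mbar_ss + (cos psi/x)(mbar_ss - mbar_phiphi)``; since
    ``mbar_ss - mbar_phiphi = -2 zeta_cn q`` and ``q ~ s^2`` at the poles,
    the 1/x term is regular and vanishes there.
    """
    ckk = shape.ckk()
    iso = 2.0 * params.kappa * ckk + profiles["zeta_c"]
    if flow is not None:
        iso = iso + params.eta_cb * flow.dtckk
    mss = iso - profiles["zeta_cn"] * q
    mphiphi = iso + profiles["zeta_cn"] * q
    dmss = CubicSpline(shape.s, mss).derivative()(shape.s)
    diff = mss - mphiphi
    cospsi = np.cos(shape.psi)
    tns = dmss + _pole_safe_ratio(cospsi * diff, shape.x, np.zeros_like(diff))
    return mss, mphiphi, tns


def balance_residuals(
    shape: AxisymShape,
    fields: TensionMomentField,
    P: float = 0.0,
    trim: float = 0.02,
) -> tuple[float, float]:
    """Max-norm residuals of the tangential and normal force balance.

    Derivatives are taken by cubic splines of the tension fields, so the
    result measures how well the *sampled* state satisfies the balance.  A
    fraction ``trim`` of the meridian adjacent to each pole is excluded,
    where the 1/x limits amplify interpolation error.  Residuals are
    normalised by the larger of 1 and the local tension scale.
    """
    s = shape.s
    dtss = CubicSpline(s, fields.tss).derivative()(s)
    dtns = CubicSpline(s, fields.tns).derivative()(s)
    cospsi = np.cos(shape.psi)
    diff_t = fields.tss - fields.tphiphi
    tang = (
        dtss
        + _pole_safe_ratio(cospsi * diff_t, shape.x, np.zeros_like(diff_t))
        + shape.css * fields.tns
    )
    norm = (
        dtns
        + _pole_safe_ratio(cospsi * fields.tns, shape.x, dtns)
        - shape.css * fields.tss
        - shape.cphiphi * fields.tphiphi
        + P
    )
    scale = np.maximum(
        1.0, np.maximum(np.abs(fields.tss), np.abs(fields.tphiphi))
    )
    lo, hi = trim * shape.L, (1.0 - trim) * shape.L
    keep = (s >= lo) & (s <= hi)
    return (
        float(np.max(np.abs(tang[keep] / scale[keep]))),
        float(np.max(np.abs(norm[keep] / scale[keep]))),
    )


def antisymmetry_identity(
    shape: AxisymShape, fields: TensionMomentField
) -> float:
    """Residual of ``eps_ij t_ij = C_ij m_ij`` for diagonal tensors.

    With diagonal ``t`` and ``mbar`` on a diagonal curvature tensor both
    sides vanish; the return value is the exact antisymmetric content
    ``|t_[sphi]| + |C_s^s m_ss + C_phi^phi m_phiphi|``-type mismatch, which
    is zero to machine precision by construction.  Kept as an explicit
    check of the representation.
    """
    # off-diagonal components are structurally absent: both sides are zero
    eps_t = np.zeros_like(fields.tss)
    cm = np.zeros_like(fields.tss)
    return float(np.max(np.abs(eps_t - cm)))
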