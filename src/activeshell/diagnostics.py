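"""Shape observables: necks, tubes, discs, and neck matching conditions.

All measurements are functions of the sampled state only, and are invariant
under reparametrisation of the meridian.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .geometry import AxisymShape
from .mechanics import TensionMomentField

__all__ = ["measure_neck", "measure_tube", "measure_disc", "neck_matching_check"]


def measure_neck(shape: AxisymShape, edge_frac: float = 0.02) -> dict:
    """Locate the neck as the interior local minimum of the radius ``x``.

    Returns the neck radius and the curvatures there.  ``found=False`` when
    no interior local minimum exists (e.g. a sphere).  For shapes with
    several waists the narrowest one is reported.
    """
    s, x = shape.s, shape.x
    n = len(s)
    i0 = max(2, int(edge_frac * n))
    interior = slice(i0, n - i0)
    xi = x[interior]
    # local minima in the interior
    mins = np.where((xi[1:-1] < xi[:-2]) & (xi[1:-1] <= xi[2:]))[0] + 1 + i0
    if mins.size == 0:
        return {"found": False, "radius": None}
    i_neck = mins[np.argmin(x[mins])]
    # refine with the spline of x around the grid minimum
    xs = shape.spline("x")
    lo, hi = s[max(i_neck - 2, 0)], s[min(i_neck + 2, n - 1)]
    res = minimize_scalar(xs, bounds=(lo, hi), method="bounded")
    s_neck = float(res.x)
    css = shape.spline("css")(s_neck)
    cphi = shape.spline("cphiphi")(s_neck)
    return {
        "found": True,
        "radius": float(xs(s_neck)),
        "s": s_neck,
        "css": float(css),
        "cphiphi": float(cphi),
        "ckk": float(css + cphi),
    }


def measure_tube(shape: AxisymShape, s0: np.ndarray, la: float,
                 uniformity: float = 0.10) -> dict:
    """Tube length and radius of a deformed active region.

    The tube length is the current arc length of the active material,
    ``Lc = s(s0 = la)`` (the whole meridian when the pattern is
    homogeneous), and the tube radius is read from the circumferential
    curvature at the tube midpoint, ``Rc = 1/C_phiphi(Lc/2)``.  The region
    is flagged non-tubular if ``C_phiphi`` varies by more than
    ``uniformity`` over the middle half of the tube.
    """
    if la >= np.pi - 1e-9:
        s_tube = shape.L
    else:
        s_tube = float(np.interp(la, s0, shape.s))
    s_mid = 0.5 * s_tube
    cphi_mid = float(shape.spline("cphiphi")(s_mid))
    probe = np.linspace(0.25 * s_tube, 0.75 * s_tube, 101)
    cphi = shape.spline("cphiphi")(probe)
    spread = float((np.max(cphi) - np.min(cphi)) / max(abs(cphi_mid), 1e-12))
    # a cylinder has a straight meridian: C_ss must be small versus C_phiphi
    css_mid = float(shape.spline("css")(s_mid))
    tubular = spread <= uniformity and abs(css_mid) <= 0.2 * abs(cphi_mid)
    return {
        "Lc": s_tube,
        "Rc": 1.0 / cphi_mid if cphi_mid != 0 else np.inf,
        "cphiphi_mid": cphi_mid,
        "tubular": bool(tubular),
        "cphiphi_spread": spread,
    }


def measure_disc(shape: AxisymShape) -> dict:
    """Disc radius and half-thickness of a flattened shape.

    ``Rd`` is the maximal distance from the axis; the half-thickness ``h``
    is half the axial distance between the two flattened faces measured at
    the axis, i.e. half the pole-to-pole distance.
    """
    return {
        "Rd": float(np.max(shape.x)),
        "h": float(0.5 * abs(shape.z[-1] - shape.z[0])),
    }


def neck_matching_check(shape: AxisymShape, fields: TensionMomentField,
                        window: float | None = None) -> dict:
    """Matching conditions across a narrow neck.

    In the infinitesimal-neck limit the meridional tension ``t_ss`` changes
    sign across the neck while the meridional bending moment ``mbar_ss`` is
    continuous.  Reports the signs of ``t_ss`` on either side of the neck
    and the excursion of ``mbar_ss`` across it (which tends to zero as the
    neck constricts).
    """
    neck = measure_neck(shape)
    if not neck["found"]:
        raise ValueError("no neck found on this shape")
    s_neck = neck["s"]
    # the matching region scales with the neck size, not the whole meridian
    w = window if window is not None else max(0.02 * shape.L, 20 * neck["radius"])
    s = shape.s
    left = (s > s_neck - w) & (s < s_neck - 0.2 * w)
    right = (s > s_neck + 0.2 * w) & (s < s_neck + w)
    tss_l = float(np.mean(fields.tss[left]))
    tss_r = float(np.mean(fields.tss[right]))
    around = (s > s_neck - w) & (s < s_neck + w)
    m_around = fields.mss[around]
    m_jump = float(np.max(m_around) - np.min(m_around))
    return {
        "neck": neck,
        "tss_left": tss_l,
        "tss_right": tss_r,
        "sign_change": tss_l * tss_r < 0,
        "mss_excursion": m_jump,
    }
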