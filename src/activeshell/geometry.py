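"""Axisymmetric midsurface geometry and the Lagrangian material map.

A closed surface of revolution is described by its meridian curve
``(x(s), z(s))`` parametrised by arc length ``s`` on ``[0, L]``, with tangent
angle ``psi`` satisfying ``dx/ds = cos(psi)``, ``dz/ds = sin(psi)``.  The two
principal curvatures are the meridional curvature ``C_ss = d(psi)/ds`` and the
circumferential curvature ``C_phiphi = sin(psi)/x``; at the poles regularity
forces ``C_phiphi -> C_ss``.

Conventions: ``s`` runs from the south pole (``s=0``, ``psi=0``) to the north
pole (``s=L``, ``psi=pi``); the normal ``n = (sin psi, -cos psi)`` points
outward, so the unit sphere has ``C_ss = C_phiphi = +1``.

The material map links the current shape to the undeformed unit sphere: a
material point now at ``s`` sat at arc length ``s0(s)`` on the sphere.  The
meridional and circumferential stretches are ``fs = ds/ds0`` and
``fphi = x/sin(s0)``, and the area strain is ``u = fphi*fs - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import cumulative_simpson, simpson, solve_ivp
from scipy.interpolate import CubicSpline

__all__ = [
    "AxisymShape",
    "MaterialMap",
    "ShapeError",
    "integrate_shape",
    "surface_measures",
    "reparametrise",
    "update_material_map",
    "material_map_from_s0",
    "cphiphi_from",
    "shape_distance",
    "self_intersects",
]

R0 = 1.0
L0 = np.pi * R0  # meridian length of the undeformed unit sphere

#: below this axial distance the 1/x pole singularity is replaced by limits
_POLE_XTOL = 1e-9


class ShapeError(ValueError):
    """Raised for geometrically invalid shapes (open, tangled, non-monotone)."""


def cphiphi_from(psi: np.ndarray, x: np.ndarray, css: np.ndarray) -> np.ndarray:
    """Circumferential curvature ``sin(psi)/x`` with the pole limit ``C_ss``."""
    psi, x, css = np.broadcast_arrays(psi, x, css)
    out = np.empty_like(np.asarray(x, dtype=float))
    near = np.abs(x) < _POLE_XTOL
    out[~near] = np.sin(psi[~near]) / x[~near]
    out[near] = css[near]
    return out


@dataclass
class AxisymShape:
    """Meridian curve and curvatures of an axisymmetric midsurface.

    All arrays live on a common (usually uniform) arc length grid ``s``.
    """

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    css: np.ndarray
    cphiphi: np.ndarray
    L: float
    outward_normal: bool = True
    closure_error: float = 0.0

    # cached splines (not part of equality/serialisation)
    _spl: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def sphere(cls, radius: float = 1.0, n: int = 401) -> "AxisymShape":
        """Exact sphere of given radius, south pole at ``z=-radius``."""
        L = np.pi * radius
        s = np.linspace(0.0, L, n)
        th = s / radius
        return cls(
            s=s,
            x=radius * np.sin(th),
            z=-radius * np.cos(th),
            psi=th.copy(),
            css=np.full(n, 1.0 / radius),
            cphiphi=np.full(n, 1.0 / radius),
            L=L,
        )

    # -- cached interpolants ------------------------------------------------
    def spline(self, name: str) -> CubicSpline:
        if name not in self._spl:
            self._spl[name] = CubicSpline(self.s, getattr(self, name))
        return self._spl[name]

    def ckk(self) -> np.ndarray:
        return self.css + self.cphiphi

    def is_closed(self, tol: float = 1e-6) -> bool:
        return (
            abs(self.x[0]) < tol
            and abs(self.x[-1]) < tol
            and abs(self.psi[0]) < tol
            and abs(self.psi[-1] - np.pi) < tol
        )

    def check_invariants(self, tol: float = 1e-4) -> None:
        """Verify the arc length relations and curvature definitions."""
        dx = self.spline("x").derivative()(self.s)
        dz = self.spline("z").derivative()(self.s)
        if np.max(np.abs(dx - np.cos(self.psi))) > tol:
            raise ShapeError("metric violation: dx/ds != cos(psi)")
        if np.max(np.abs(dz - np.sin(self.psi))) > tol:
            raise ShapeError("metric violation: dz/ds != sin(psi)")


@dataclass
class MaterialMap:
    """Lagrangian map between the undeformed sphere and the current shape."""

    s0: np.ndarray  # arc position on the initial sphere of the point now at s
    u: np.ndarray  # area strain fphi*fs - 1
    fs: np.ndarray  # meridional stretch ds/ds0
    fphi: np.ndarray  # circumferential stretch x/x0

    @classmethod
    def identity(cls, shape: AxisymShape) -> "MaterialMap":
        n = len(shape.s)
        return cls(
            s0=shape.s.copy(),
            u=np.zeros(n),
            fs=np.ones(n),
            fphi=np.ones(n),
        )


def integrate_shape(
    css_profile: Callable[[np.ndarray], np.ndarray],
    L: float,
    n: int = 801,
    psi_start: float = 0.0,
    x_start: float = 0.0,
    closure_tol: float = 1e-6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> AxisymShape:
    """Reconstruct a surface of revolution from its meridional curvature.

    Integrates ``x' = cos psi``, ``z' = sin psi``, ``psi' = C_ss(s)`` from the
    south pole.  The returned shape carries the closure error ``|x(L)|``; a
    shape failing ``closure_tol`` is returned with ``closure_error`` set but
    not raised, so callers can decide.
    """
    s_grid = np.linspace(0.0, L, n)
    probe = np.asarray(css_profile(s_grid), dtype=float)
    if not np.all(np.isfinite(probe)):
        raise ShapeError("curvature profile is not finite on [0, L]")

    def rhs(s, y):
        return [np.cos(y[2]), np.sin(y[2]), float(css_profile(np.asarray(s)))]

    sol = solve_ivp(
        rhs,
        (0.0, L),
        [x_start, -1.0, psi_start],
        t_eval=s_grid,
        rtol=rtol,
        atol=atol,
        method="DOP853",
        dense_output=False,
    )
    if not sol.success:
        raise ShapeError(f"curvature integration failed: {sol.message}")
    x, z, psi = sol.y
    css = probe
    cphiphi = cphiphi_from(psi, x, css)
    err = abs(x[-1] - x_start) if abs(x_start) > 0 else abs(x[-1])
    return AxisymShape(
        s=s_grid, x=x, z=z, psi=psi, css=css, cphiphi=cphiphi, L=L,
        closure_error=err if err > closure_tol else 0.0,
    )


def surface_measures(shape: AxisymShape) -> tuple[float, float]:
    """Total area and enclosed volume of a closed surface of revolution.

    ``A = int 2 pi x ds`` and, by the divergence theorem applied to the axial
    field, ``V = int pi x^2 sin(psi) ds``.
    """
    if not shape.is_closed(tol=1e-4):
        raise ShapeError("surface_measures requires a closed shape")
    area = simpson(2.0 * np.pi * shape.x, x=shape.s)
    vol = simpson(np.pi * shape.x**2 * np.sin(shape.psi), x=shape.s)
    return float(area), float(vol)


def enclosed_volume_profile(shape: AxisymShape) -> np.ndarray:
    """Cumulative enclosed volume from the south pole (same quadrature as above)."""
    integrand = np.pi * shape.x**2 * np.sin(shape.psi)
    return cumulative_simpson(integrand, x=shape.s, initial=0.0)


def reparametrise(
    shape: AxisymShape,
    fields: Mapping[str, np.ndarray] | None = None,
    n: int | None = None,
) -> tuple[AxisymShape, dict[str, np.ndarray]]:
    """Restore the arc length parametrisation ``g_ss = 1``.

    The input meridian may be given on any monotone parameter (e.g. the
    pre-step arc length after an explicit Euler displacement).  The new arc
    length is computed from the curve, the grid is made uniform, and every
    carried field is resampled by cubic splines at fixed material points.
    """
    t = shape.s
    xs = CubicSpline(t, shape.x)
    zs = CubicSpline(t, shape.z)
    speed_nodes = np.hypot(xs.derivative()(t), zs.derivative()(t))
    if np.any(speed_nodes <= 0):
        raise ShapeError("degenerate parametrisation (zero speed)")
    # cumulative arc length via the antiderivative of a spline of the speed
    arc = CubicSpline(t, speed_nodes).antiderivative()(t)
    arc -= arc[0]
    if np.any(np.diff(arc) <= 0):
        raise ShapeError("non-monotone parametrisation")
    Lnew = float(arc[-1])
    m = n if n is not None else len(t)
    s_new = np.linspace(0.0, Lnew, m)
    t_of_s = CubicSpline(arc, t)(s_new)
    t_of_s[0], t_of_s[-1] = t[0], t[-1]

    x_new = xs(t_of_s)
    z_new = zs(t_of_s)
    psi_new = CubicSpline(t, shape.psi)(t_of_s)
    x_new[0] = x_new[-1] = 0.0  # poles stay on the axis
    psi_spl = CubicSpline(s_new, psi_new)
    css_new = psi_spl.derivative()(s_new)
    cphiphi_new = cphiphi_from(psi_new, x_new, css_new)

    out_fields: dict[str, np.ndarray] = {}
    if fields:
        for key, vals in fields.items():
            out_fields[key] = CubicSpline(t, np.asarray(vals))(t_of_s)

    new_shape = AxisymShape(
        s=s_new, x=x_new, z=z_new, psi=psi_new,
        css=css_new, cphiphi=cphiphi_new, L=Lnew,
        closure_error=shape.closure_error,
    )
    return new_shape, out_fields


def material_map_from_s0(shape: AxisymShape, s0: np.ndarray) -> MaterialMap:
    """Rebuild stretches and area strain from the advected ``s0`` samples.

    ``fs = ds/ds0`` comes from a spline of ``s0(s)``; ``fphi = x/sin(s0)``
    with the regular limit ``fs`` at the poles (both stretches coincide
    there by axisymmetry).
    """
    s0 = np.asarray(s0, dtype=float)
    ds0 = np.diff(s0)
    if np.any(ds0 <= 0):
        raise ShapeError("material map lost monotonicity (mesh tangling)")
    ds0_ds = CubicSpline(shape.s, s0).derivative()(shape.s)
    ds0_ds = np.clip(ds0_ds, 1e-12, None)
    fs = 1.0 / ds0_ds
    x0 = np.sin(s0)
    fphi = np.empty_like(fs)
    interior = x0 > _POLE_XTOL
    fphi[interior] = shape.x[interior] / x0[interior]
    fphi[~interior] = fs[~interior]
    u = fphi * fs - 1.0
    return MaterialMap(s0=s0, u=u, fs=fs, fphi=fphi)


def update_material_map(
    mmap: MaterialMap,
    shape: AxisymShape,
    vs: np.ndarray | None = None,
    dt: float = 0.0,
) -> MaterialMap:
    """Advect the material map through one Lagrangian step.

    Grid nodes are material points, so the ``s0`` value carried by each node
    is constant in time; after the node positions have moved (and before or
    after reparametrisation) the strain is recomputed from the stretches on
    the new shape.  ``vs`` and ``dt`` are accepted for interface parity with
    Eulerian schemes but are not needed in the Lagrangian update.
    """
    del vs, dt
    return material_map_from_s0(shape, mmap.s0)


def self_intersects(shape: AxisymShape) -> bool:
    """Check the meridian polyline for self-intersection or pole contact."""
    if shape.z[-1] <= shape.z[0]:
        return True
    try:
        from shapely.geometry import LineString
    except ImportError:  # pragma: no cover
        return False
    pts = np.column_stack([shape.x, shape.z])
    return not LineString(pts).is_simple


def _volume_centroid_z(shape: AxisymShape) -> float:
    w = np.pi * shape.x**2 * np.sin(shape.psi)
    vol = simpson(w, x=shape.s)
    return float(simpson(w * shape.z, x=shape.s) / vol)


def shape_distance(a: AxisymShape, b: AxisymShape, n: int = 400) -> float:
    """Max meridian-point distance after aligning the volume centroids.

    Both meridians are sampled at equal fractions of arc length; the distance
    is the maximum Euclidean separation of corresponding points in the
    ``(x, z)`` half-plane.  Translation along the axis is quotiented out.
    """
    frac = np.linspace(0.0, 1.0, n)
    za = a.spline("z")(frac * a.L) - _volume_centroid_z(a)
    zb = b.spline("z")(frac * b.L) - _volume_centroid_z(b)
    xa = a.spline("x")(frac * a.L)
    xb = b.spline("x")(frac * b.L)
    return float(np.max(np.hypot(xa - xb, za - zb)))
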