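"""Analytic test shapes with exactly known geometry.

These are synthetic states used by the test-suite and the ``fixtures`` CLI
subcommand: a unit sphere, a two-lobed dumbbell, a capped cylinder and a
flattened (oblate) disc.  They are geometric fixtures only — their material
map is the trivial proportional one and no nematic field is attached.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .activity import ActivityPattern
from .dynamics import ShellState
from .geometry import AxisymShape, material_map_from_s0, reparametrise, surface_measures
from .mechanics import Parameters

__all__ = ["generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("sphere", "dumbbell", "cylinder-capped", "flattened-disc")


def _from_parametric(x, z, n=801):
    """Build an arc length shape from a parametric meridian (pole to pole)."""
    t = np.linspace(0.0, 1.0, len(x))
    psi = np.unwrap(np.arctan2(np.gradient(z, t), np.gradient(x, t)))
    raw = AxisymShape(s=t, x=x, z=z, psi=psi,
                      css=np.gradient(psi, t), cphiphi=np.zeros_like(t),
                      L=t[-1])
    shape, _ = reparametrise(raw, n=n)
    # pin the analytic pole angles (finite-difference psi is O(dt) off there)
    shape.psi[0], shape.psi[-1] = 0.0, np.pi
    return shape


def _dumbbell(n=801, waist=0.55):
    t = np.linspace(0.0, np.pi, 2001)
    x = np.sin(t) * (1.0 - waist * np.sin(t) ** 2)
    z = -np.cos(t) * (0.8 + 0.2 * np.sin(t) ** 2)
    return _from_parametric(x, z, n)


def _capped_cylinder(n=801, r=0.5, length=1.2):
    s1 = np.pi * r / 2.0
    s = np.linspace(0.0, 2 * s1 + length, n)
    x = np.empty_like(s)
    z = np.empty_like(s)
    psi = np.empty_like(s)
    css = np.empty_like(s)
    south = s <= s1
    tube = (s > s1) & (s < s1 + length)
    north = s >= s1 + length
    th = s[south] / r
    x[south], z[south], psi[south], css[south] = r * np.sin(th), -r * np.cos(th), th, 1 / r
    x[tube], z[tube], psi[tube], css[tube] = r, s[tube] - s1, np.pi / 2, 0.0
    th = (s[north] - s1 - length) / r + np.pi / 2
    x[north], z[north] = r * np.sin(th), length + r * np.sin(th - np.pi / 2)
    psi[north], css[north] = th, 1 / r
    from .geometry import cphiphi_from

    return AxisymShape(s=s, x=x, z=z, psi=psi, css=css,
                       cphiphi=cphiphi_from(psi, x, css), L=float(s[-1]))


def _oblate(n=801, a=1.3, c=0.45):
    t = np.linspace(0.0, np.pi, 2001)
    return _from_parametric(a * np.sin(t), -c * np.cos(t), n)


def generate_fixture(name: str, params: Parameters | None = None) -> ShellState:
    params = params or Parameters()
    builders = {
        "sphere": lambda: AxisymShape.sphere(n=801),
        "dumbbell": _dumbbell,
        "cylinder-capped": _capped_cylinder,
        "flattened-disc": _oblate,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    shape = builders[name]()
    s0 = np.pi * shape.s / shape.L
    mmap = material_map_from_s0(shape, s0)
    _, V = surface_measures(shape)
    return ShellState(t=0.0, shape=shape, mmap=mmap,
                      pattern=ActivityPattern(), params=params,
                      volume_mode="free", V=V)
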