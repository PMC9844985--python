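"""Patterned active tensions and bending moments on material coordinates.

Four activity coefficients drive the shell: the isotropic tension ``zeta``,
the nematic tension ``zeta_n`` (contractile > 0, extensile < 0), the isotropic
bending moment ``zeta_c`` (preferred total curvature ``-zeta_c/(2 kappa)``)
and the nematic bending moment ``zeta_cn``.  Each is prescribed on the
*initial* sphere as a circular patch of meridional size ``la`` around the
south pole and advected with the material: profiles are functions of the
material coordinate ``s0``, so the patch edge stays glued to the same cells
while the surface deforms.

Spatial shape: a step (steady-state convention) or a smooth sigmoid of width
``sigma_s``.  In dynamic runs the amplitude is switched on by a sigmoid in
time, reaching ~99% of target by t ~ mu_t + 5 sigma_t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import L0

__all__ = ["ActivityPattern", "sigmoid", "sigmoid_slope", "evaluate_profiles"]

FOUR = ("zeta", "zeta_c", "zeta_n", "zeta_cn")


def sigmoid(x, mu, sigma):
    """Decreasing sigmoid ``f = 1 - 1/(1 + exp(-(x - mu)/sigma))``.

    ``f(mu) = 1/2``; ``f -> 1`` for ``x << mu`` and ``f -> 0`` for
    ``x >> mu``.  In the limit ``sigma -> 0`` it reproduces the sharp step.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    # numerically stable two-sided evaluation
    out = np.where(z > 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(np.clip(z, None, 50))))
    return out if out.ndim else float(out)


def sigmoid_slope(x, mu, sigma):
    """d f / d x of :func:`sigmoid` (negative)."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    sech2 = 1.0 / np.cosh(np.clip(z / 2.0, -30, 30)) ** 2
    out = -sech2 / (4.0 * sigma)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ActivityPattern:
    """Baselines, increments and geometry of the active patch.

    Tensions are in units of ``kappa/R0^2`` and bending moments in
    ``kappa/R0``; ``la`` is in units of ``R0`` with the whole sphere at
    ``la = L0 = pi``.  ``mode`` selects the spatial profile: ``"step"``
    (sharp, used for steady states) or ``"smooth"`` (sigmoid of width
    ``sigma_s``, used for dynamics).
    """

    zeta0: float = 0.0
    zeta_c0: float = 0.0
    zeta_n0: float = 0.0
    zeta_cn0: float = 0.0
    dzeta: float = 0.0
    dzeta_c: float = 0.0
    dzeta_n: float = 0.0
    dzeta_cn: float = 0.0
    la: float = L0
    sigma_s: float = 0.02 * L0
    mu_t: float = 0.01
    sigma_t: float = 0.002
    mode: str = "smooth"

    def __post_init__(self):
        if not 0.0 < self.la <= L0 + 1e-12:
            raise ValueError("active region size must satisfy 0 < la <= pi R0")
        if self.mode not in ("step", "smooth"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        if self.mode == "smooth" and (self.sigma_s <= 0 or self.sigma_t <= 0):
            raise ValueError("smooth mode needs positive sigma_s, sigma_t")

    def with_control(self, name: str, value: float) -> "ActivityPattern":
        if name not in ("dzeta", "dzeta_c", "dzeta_n", "dzeta_cn"):
            raise ValueError(f"unknown control parameter {name!r}")
        return replace(self, **{name: value})

    def uses_nematic(self) -> bool:
        return any(
            abs(v) > 0
            for v in (self.zeta_n0, self.zeta_cn0, self.dzeta_n, self.dzeta_cn)
        )

    def increments(self) -> dict[str, float]:
        return {
            "zeta": self.dzeta,
            "zeta_c": self.dzeta_c,
            "zeta_n": self.dzeta_n,
            "zeta_cn": self.dzeta_cn,
        }

    def baselines(self) -> dict[str, float]:
        return {
            "zeta": self.zeta0,
            "zeta_c": self.zeta_c0,
            "zeta_n": self.zeta_n0,
            "zeta_cn": self.zeta_cn0,
        }

    # -- evaluation ---------------------------------------------------------
    def spatial_factor(self, s0, sigma_override: float | None = None):
        """Profile shape in the material coordinate, in [0, 1]."""
        s0 = np.asarray(s0, dtype=float)
        if self.mode == "step" and sigma_override is None:
            return (s0 <= self.la).astype(float)
        sigma = self.sigma_s if sigma_override is None else sigma_override
        return sigmoid(s0, self.la, sigma)

    def spatial_factor_derivative(self, s0, sigma_override: float | None = None):
        """d/d s0 of the spatial factor (zero in sharp-step mode away from the edge)."""
        s0 = np.asarray(s0, dtype=float)
        if self.mode == "step" and sigma_override is None:
            return np.zeros_like(s0)
        sigma = self.sigma_s if sigma_override is None else sigma_override
        return sigmoid_slope(s0, self.la, sigma)

    def time_factor(self, t: float | None) -> float:
        """Switch-on amplitude ``1 - f(t, mu_t, sigma_t)``; 1 at steady state."""
        if t is None:
            return 1.0
        return 1.0 - float(sigmoid(t, self.mu_t, self.sigma_t))


def evaluate_profiles(
    pattern: ActivityPattern,
    s0,
    t: float | None = None,
    sigma_override: float | None = None,
) -> dict[str, np.ndarray]:
    """The four activity profiles at material positions ``s0`` and time ``t``.

    ``t=None`` means the steady-state (fully switched-on) pattern.  An
    optional ``sigma_override`` lets steady-state solvers use a narrow sigmoid
    as the numerical realisation of the sharp step.
    """
    s0 = np.asarray(s0, dtype=float)
    g = pattern.spatial_factor(s0, sigma_override)
    amp = pattern.time_factor(t)
    base = pattern.baselines()
    inc = pattern.increments()
    return {name: amp * (base[name] + inc[name] * g) for name in FOUR}
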