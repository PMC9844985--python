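"""Geometry: shape reconstruction, measures, reparametrisation, material map."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from activeshell.geometry import (
    AxisymShape,
    MaterialMap,
    ShapeError,
    integrate_shape,
    material_map_from_s0,
    reparametrise,
    shape_distance,
    surface_measures,
    update_material_map,
)


class TestIntegrateShape:
    def test_constant_curvature_gives_sphere(self):
        R = 1.0
        sh = integrate_shape(lambda s: np.full_like(s, 1.0 / R), np.pi * R)
        assert np.allclose(sh.x, np.sin(sh.s), atol=1e-9)
        assert np.allclose(sh.psi, sh.s, atol=1e-9)
        assert np.allclose(sh.cphiphi, 1.0, atol=1e-7)
        assert sh.closure_error == 0.0

    def test_zero_curvature_open_cylinder(self):
        # psi = pi/2 throughout: x stays constant, z grows linearly
        sh = integrate_shape(lambda s: np.zeros_like(s), 2.0,
                             psi_start=np.pi / 2, x_start=0.7)
        assert np.allclose(sh.x, 0.7, atol=1e-10)
        dz = np.diff(sh.z)
        assert np.allclose(dz, dz[0], atol=1e-10)

    def test_perturbed_profile_matches_fine_integrator(self):
        css = lambda s: 1.0 + 0.1 * np.sin(s)
        sh = integrate_shape(css, np.pi)

        def rhs(s, y):
            return [np.cos(y[2]), np.sin(y[2]), css(s)]

        ref = solve_ivp(rhs, (0, np.pi), [0.0, -1.0, 0.0], t_eval=sh.s,
                        rtol=1e-12, atol=1e-13, method="DOP853")
        assert np.max(np.abs(sh.x - ref.y[0])) < 1e-8
        assert np.max(np.abs(sh.psi - ref.y[2])) < 1e-8

    def test_nonfinite_curvature_rejected(self):
        with pytest.raises(ShapeError):
            integrate_shape(lambda s: np.where(s > 1, np.inf, 1.0), np.pi)

    def test_roundtrip_from_own_curvature(self, unit_sphere):
        sh = integrate_shape(lambda s: np.interp(s, unit_sphere.s, unit_sphere.css),
                             unit_sphere.L)
        assert np.max(np.abs(sh.x - unit_sphere.x)) < 1e-8


class TestSurfaceMeasures:
    @pytest.mark.parametrize("R", [1.0, 2.0])
    def test_sphere(self, R):
        sh = AxisymShape.sphere(radius=R, n=2001)
        area, vol = surface_measures(sh)
        assert area == pytest.approx(4 * np.pi * R**2, rel=1e-8)
        assert vol == pytest.approx(4 * np.pi * R**3 / 3, rel=1e-8)

    def test_capped_cylinder_against_closed_form(self):
        from activeshell.fixtures import generate_fixture

        st = generate_fixture("cylinder-capped")
        r, length = 0.5, 1.2
        area, vol = surface_measures(st.shape)
        assert area == pytest.approx(4 * np.pi * r**2 + 2 * np.pi * r * length, rel=1e-6)
        assert vol == pytest.approx(4 * np.pi * r**3 / 3 + np.pi * r**2 * length, rel=1e-6)

    def test_open_shape_rejected(self):
        sh = integrate_shape(lambda s: np.zeros_like(s), 2.0,
                             psi_start=np.pi / 2, x_start=0.7)
        with pytest.raises(ShapeError):
            surface_measures(sh)


class TestReparametrise:
    def test_identity_on_arclength_shape(self, unit_sphere):
        new, fields = reparametrise(unit_sphere, {"u": np.cos(unit_sphere.s)})
        assert abs(new.L - np.pi) < 1e-10
        assert np.max(np.abs(new.x - unit_sphere.x)) < 1e-10
        assert np.max(np.abs(fields["u"] - np.cos(new.s))) < 1e-9

    def test_uniform_stretch_recovers_half_parameter(self):
        # parametrised with sigma = s/2: speed 2, so L doubles the parameter span
        sig = np.linspace(0, np.pi / 2, 401)
        s_true = 2 * sig
        raw = AxisymShape(s=sig, x=np.sin(s_true), z=-np.cos(s_true),
                          psi=s_true, css=np.ones_like(sig),
                          cphiphi=np.ones_like(sig), L=np.pi / 2)
        new, _ = reparametrise(raw)
        assert new.L == pytest.approx(np.pi, abs=1e-8)
        assert np.max(np.abs(new.x - np.sin(new.s))) < 1e-7

    def test_idempotent(self, unit_sphere):
        once, _ = reparametrise(unit_sphere)
        twice, _ = reparametrise(once)
        assert np.max(np.abs(once.x - twice.x)) < 1e-11

    def test_restores_metric_after_perturbation(self):
        # a perturbed parametrisation of the sphere meridian
        t = np.linspace(0, np.pi, 801)
        warp = t + 0.05 * np.sin(2 * t)
        raw = AxisymShape(s=t, x=np.sin(warp), z=-np.cos(warp), psi=warp,
                          css=np.ones_like(t), cphiphi=np.ones_like(t), L=np.pi)
        new, fields = reparametrise(raw, {"s0": warp})
        new.check_invariants(tol=1e-6)
        # fields ride with material points: s0 equals the true angle
        assert np.max(np.abs(fields["s0"] - new.s)) < 1e-6


class TestMaterialMap:
    def test_identity_on_sphere(self, unit_sphere):
        mmap = material_map_from_s0(unit_sphere, unit_sphere.s)
        assert np.max(np.abs(mmap.u)) < 1e-9
        assert np.max(np.abs(mmap.fs - 1)) < 1e-9

    def test_uniform_inflation(self):
        R = 1.3
        sh = AxisymShape.sphere(radius=R, n=801)
        mmap = material_map_from_s0(sh, sh.s / R)
        assert np.allclose(mmap.u, R**2 - 1, atol=1e-7)

    def test_consistency_u_equals_product_of_stretches(self, unit_sphere):
        s0 = unit_sphere.s + 0.03 * np.sin(2 * unit_sphere.s)
        mmap = material_map_from_s0(unit_sphere, s0)
        assert np.max(np.abs(mmap.u - (mmap.fphi * mmap.fs - 1))) < 1e-12

    def test_zero_velocity_leaves_map_unchanged(self, unit_sphere):
        mmap = MaterialMap.identity(unit_sphere)
        out = update_material_map(mmap, unit_sphere, None, 0.1)
        assert np.allclose(out.s0, mmap.s0)
        assert np.max(np.abs(out.u)) < 1e-9

    def test_tangled_map_rejected(self, unit_sphere):
        bad = unit_sphere.s.copy()
        bad[10], bad[11] = bad[11], bad[10]
        with pytest.raises(ShapeError):
            material_map_from_s0(unit_sphere, bad)


def test_shape_distance_translation_invariant(unit_sphere):
    moved = AxisymShape(s=unit_sphere.s, x=unit_sphere.x, z=unit_sphere.z + 0.7,
                        psi=unit_sphere.psi, css=unit_sphere.css,
                        cphiphi=unit_sphere.cphiphi, L=unit_sphere.L)
    assert shape_distance(unit_sphere, moved) < 1e-9


def test_pole_curvature_regularity(unit_sphere):
    # C_phiphi -> C_ss at both poles for any closed shape
    from activeshell.fixtures import generate_fixture

    for name in ("sphere", "dumbbell", "flattened-disc"):
        sh = generate_fixture(name).shape
        assert abs(sh.cphiphi[0] - sh.css[0]) < 5e-2
        assert abs(sh.cphiphi[-1] - sh.css[-1]) < 5e-2
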