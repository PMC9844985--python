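"""Equilibrium solver: analytic limits, sphericity, ideal neck construction."""

import numpy as np
import pytest

from activeshell import (
    ActivityPattern,
    Parameters,
    ideal_neck_line,
    solve_equilibrium,
)


class TestAnalyticEquilibria:
    def test_zero_activity_gives_unit_sphere(self, zero_pattern, params):
        eq = solve_equilibrium(zero_pattern, params, "free")
        assert eq.shape.L == pytest.approx(np.pi, abs=1e-8)
        assert eq.V == pytest.approx(4 * np.pi / 3, rel=1e-8)
        assert eq.P == 0.0
        assert np.max(np.abs(eq.mmap.u)) < 1e-10
        assert max(eq.residuals) < 1e-6

    def test_uniform_isotropic_tension_contracts_sphere(self, params):
        # free volume: t_ss = 0 at P=0 forces u = -zeta/(2K), R = sqrt(1+u)
        zeta = 10.0
        eq = solve_equilibrium(ActivityPattern(dzeta=zeta, mode="step"), params, "free")
        u_pred = -zeta / (2 * params.K)
        assert np.allclose(eq.mmap.u, u_pred, atol=1e-9)
        assert eq.shape.L == pytest.approx(np.pi * np.sqrt(1 + u_pred), rel=1e-8)

    def test_step_isotropic_tension_stays_spherical(self, params):
        # a positive tension step rescales regions but cannot deform the
        # shell away from a sphere (no shear elasticity)
        pat = ActivityPattern(dzeta=10.0, la=0.3 * np.pi, mode="step")
        eq = solve_equilibrium(pat, params, "free")
        aniso = np.abs(eq.shape.css - eq.shape.cphiphi)
        assert np.max(aniso[5:-5]) < 1e-4
        assert eq.P == 0.0

    def test_conserved_volume_contract(self, zero_pattern, params):
        eq = solve_equilibrium(zero_pattern, params, "conserved")
        assert abs(eq.V - 4 * np.pi / 3) / (4 * np.pi / 3) < 1e-6
        assert abs(eq.P) < 1e-6

    def test_smooth_quadratic_volume_response_to_bending_step(self, params):
        # small isotropic bending increments at intermediate la: V decreases
        # smoothly, with the leading response quadratic in the increment
        # (the linear term vanishes for the volume observable)
        pat = ActivityPattern(mode="step", la=0.4 * np.pi)
        cs = (0.0, 0.5, 1.0, 2.0)
        Vs = [solve_equilibrium(pat.with_control("dzeta_c", c), params, "free").V
              for c in cs]
        drops = np.diff(Vs)
        assert np.all(drops < 0)
        a = (Vs[0] - Vs[1]) / 0.25  # quadratic coefficient from c = 0.5
        assert Vs[0] - Vs[3] == pytest.approx(a * 4.0, rel=0.15)


class TestBranch:
    def test_budding_branch_reaches_constriction(self, budding_branch):
        frac, branch = budding_branch
        assert branch.termination == "neck-constriction"

    def test_branch_continuity(self, budding_branch):
        from activeshell import shape_distance

        _, branch = budding_branch
        eqs = branch.equilibria
        dists = [shape_distance(a.shape, b.shape)
                 for a, b in zip(eqs[:-1], eqs[1:])]
        assert max(dists) < 0.35

    def test_all_equilibria_balanced(self, budding_branch):
        _, branch = budding_branch
        worst = max(max(eq.residuals) for eq in branch.equilibria)
        assert worst < 1e-6

    def test_neck_curvatures_diverge_oppositely(self, budding_branch):
        from activeshell import measure_neck

        _, branch = budding_branch
        neck = measure_neck(branch.equilibria[-1].shape)
        assert neck["css"] > 100 and neck["cphiphi"] < -100
        assert abs(neck["ckk"]) < 0.1 * abs(neck["css"])

    def test_neck_matching_conditions(self, budding_branch):
        from activeshell import neck_matching_check

        _, branch = budding_branch
        eq = branch.equilibria[-1]
        report = neck_matching_check(eq.shape, eq.fields)
        assert report["sign_change"]
        # mbar_ss stays continuous: excursion small versus its own scale
        assert report["mss_excursion"] < 0.05 * np.max(np.abs(eq.fields.mss))

    def test_mss_excursion_decreases_while_constriction(self, budding_branch):
        from activeshell import measure_neck, neck_matching_check

        _, branch = budding_branch
        picks = [eq for eq in branch.equilibria
                 if measure_neck(eq.shape)["found"]]
        exc = [neck_matching_check(eq.shape, eq.fields)["mss_excursion"]
               for eq in picks[::4]] + [neck_matching_check(
                   picks[-1].shape, picks[-1].fields)["mss_excursion"]]
        assert exc[-1] < exc[0]


class TestIdealNeckLine:
    def test_small_cap_limit_diverges(self):
        near = ideal_neck_line(1e-3)
        far = ideal_neck_line(0.1)
        assert near["dzeta_c"] > far["dzeta_c"] > 0
        assert near["Ra"] == pytest.approx(np.sin(1e-3 * np.pi / 2), rel=1e-12)

    def test_symmetric_case_outward_branch_vanishes(self):
        res = ideal_neck_line(0.5, regime="outward")
        assert res["dzeta_c"] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ideal_neck_line(0.0)
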