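"""1:1 equilibrium, complexation diffusion model, sizing and Ka fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from hgdiff.binding import (
    BindingSystem,
    combine_complex_diffusivity,
    equilibrium_jacobian,
    fit_association_constant,
    predict_dik_1to1,
    solve_equilibrium,
    stokes_einstein_radius,
    transport_ratio_summary,
)
from hgdiff.core import DiffusionMatrix, TernaryComposition, dik_rows, load_fixture
from hgdiff.synthetic import generate_dik_table


def _bisection_complex(Ka, C1, C2):
    """Independent speciation oracle: root of the mass-action residual."""
    if Ka == 0 or C1 == 0 or C2 == 0:
        return 0.0
    f = lambda x: Ka * (C1 - x) * (C2 - x) - x
    return brentq(f, 0.0, min(C1, C2), xtol=1e-18, rtol=1e-15)


class TestEquilibrium:
    def test_against_bisection_oracle(self, bcd_binding):
        eq = solve_equilibrium(bcd_binding, TernaryComposition(0.005, 0.005))
        oracle = _bisection_complex(80.0, 0.005, 0.005)
        assert eq.C_complex == pytest.approx(oracle, rel=1e-12)
        assert eq.C_complex == pytest.approx(1.17e-3, rel=5e-3)

    def test_trivial_limits(self, bcd_binding):
        none = BindingSystem(Ka=0.0, D_guest=0.918, D_host=0.436, D_complex=0.421)
        assert solve_equilibrium(none, TernaryComposition(0.01, 0.01)).C_complex == 0.0
        eq = solve_equilibrium(bcd_binding, TernaryComposition(0.01, 0.0))
        assert eq.C_complex == 0.0
        assert eq.C_guest_free == pytest.approx(0.01)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 0.05), st.floats(0.0, 0.05))
    @settings(max_examples=300, deadline=None)
    def test_mass_balance_and_action_invariants(self, Ka, C1, C2):
        system = BindingSystem(Ka=Ka, D_guest=1.0, D_host=0.5, D_complex=0.4)
        eq = solve_equilibrium(system, TernaryComposition(C1, C2))
        scale = max(C1, C2, 1e-30)
        assert eq.C_guest_free + eq.C_complex == pytest.approx(C1, abs=1e-12 * scale)
        assert eq.C_host_free + eq.C_complex == pytest.approx(C2, abs=1e-12 * scale)
        resid = eq.C_complex - Ka * eq.C_guest_free * eq.C_host_free
        assert abs(resid) <= 1e-12 * scale
        assert 0.0 <= eq.C_complex <= min(C1, C2)


class TestJacobian:
    def test_matches_finite_differences(self, bcd_binding):
        comp = TernaryComposition(0.0075, 0.0025)
        dx1, dx2 = equilibrium_jacobian(bcd_binding, comp)
        h = 1e-7
        fd1 = (_bisection_complex(80, comp.C1 + h, comp.C2)
               - _bisection_complex(80, comp.C1 - h, comp.C2)) / (2 * h)
        fd2 = (_bisection_complex(80, comp.C1, comp.C2 + h)
               - _bisection_complex(80, comp.C1, comp.C2 - h)) / (2 * h)
        assert dx1 == pytest.approx(fd1, rel=1e-6)
        assert dx2 == pytest.approx(fd2, rel=1e-6)

    def test_symmetry_and_range(self, bcd_binding):
        a = equilibrium_jacobian(bcd_binding, TernaryComposition(0.007, 0.003))
        b = equilibrium_jacobian(bcd_binding, TernaryComposition(0.003, 0.007))
        assert a[0] == pytest.approx(b[1], rel=1e-12)
        assert all(0.0 <= v < 1.0 for v in a)

    def test_no_host_no_sensitivity(self, bcd_binding):
        dx1, _ = equilibrium_jacobian(bcd_binding, TernaryComposition(0.01, 0.0))
        assert dx1 == 0.0


class TestPredictDik:
    def test_no_host_limit(self, bcd_binding):
        m = predict_dik_1to1(bcd_binding, TernaryComposition(0.01, 0.0))
        assert m.D11 == pytest.approx(0.918)
        assert m.D21 == pytest.approx(0.0, abs=1e-15)
        dx2 = 80 * 0.01 / (1 + 80 * 0.01)
        assert m.D12 == pytest.approx((0.421 - 0.918) * dx2, rel=1e-12)
        assert m.D22 == pytest.approx(0.436 + (0.421 - 0.436) * dx2, rel=1e-12)

    def test_dilute_host_cross_coefficient(self, bcd_binding):
        """C2 -> 0 at C1 = 0.01: D12 -> (D_GH - D_G)*KaC1/(1+KaC1) ~ -0.221."""
        m = predict_dik_1to1(bcd_binding, TernaryComposition(0.01, 1e-12))
        assert m.D12 == pytest.approx((0.421 - 0.918) * 0.8 / 1.8, rel=1e-6)
        assert m.D12 == pytest.approx(-0.221, abs=1e-3)

    def test_counter_current_sign(self, bcd_binding):
        """A complex slower than the free guest drives negative D12."""
        m = predict_dik_1to1(bcd_binding, TernaryComposition(0.005, 0.005))
        assert m.D12 < 0

    def test_no_binding_is_diagonal(self):
        system = BindingSystem(Ka=0.0, D_guest=0.9, D_host=0.4, D_complex=0.35)
        m = predict_dik_1to1(system, TernaryComposition(0.005, 0.005))
        assert m.as_array() == pytest.approx(np.diag([0.9, 0.4]))


class TestSizingRules:
    def test_stokes_einstein_value_and_round_trip(self):
        r = stokes_einstein_radius(0.436e-9, 298.15, 0.89e-3)
        assert r == pytest.approx(0.563e-9, abs=1e-12)
        from hgdiff.core import CONSTANTS
        back = CONSTANTS.kB * 298.15 / (6 * np.pi * 0.89e-3 * r)
        assert back == pytest.approx(0.436e-9, rel=1e-14)
        assert stokes_einstein_radius(0.872e-9) == pytest.approx(r / 2, rel=1e-14)

    def test_combined_complex_diffusivity(self):
        assert combine_complex_diffusivity(0.918, 0.436) == pytest.approx(
            0.421, abs=5e-4)
        d = combine_complex_diffusivity(0.7, 0.7)
        assert d == pytest.approx(0.7 * 2 ** (-1 / 3), rel=1e-14)

    @given(st.floats(0.1, 3.0), st.floats(0.1, 3.0), st.floats(1.001, 1.5))
    @settings(max_examples=100, deadline=None)
    def test_combination_bounds_and_monotonicity(self, dg, dh, f):
        d = combine_complex_diffusivity(dg, dh)
        assert d < min(dg, dh)
        assert combine_complex_diffusivity(dg * f, dh) > d
        assert combine_complex_diffusivity(dg, dh * f) > d


class TestKaFit:
    def test_noiseless_round_trip(self, bcd_binding):
        truth = BindingSystem(Ka=100.0, D_guest=0.918, D_host=0.436,
                              D_complex=0.421)
        comps = [TernaryComposition(x * 0.01, (1 - x) * 0.01)
                 for x in (0.2, 0.4, 0.5, 0.6, 0.8)]
        rows, _ = generate_dik_table(truth, comps, sigma_rel=0.0)
        fit = fit_association_constant(rows, 0.918, 0.436, 0.421)
        assert fit.Ka == pytest.approx(100.0, rel=0.01)

    def test_zero_binding_hits_boundary(self):
        truth = BindingSystem(Ka=0.0, D_guest=0.9, D_host=0.45, D_complex=0.4)
        comps = [TernaryComposition(x * 0.01, (1 - x) * 0.01)
                 for x in (0.3, 0.5, 0.7)]
        rows, _ = generate_dik_table(truth, comps)
        fit = fit_association_constant(rows, 0.9, 0.45, 0.4, subset=("D12", "D21"))
        assert fit.Ka == pytest.approx(0.0, abs=1e-2) or fit.at_boundary

    def test_unidentifiable_table(self):
        rows = [(TernaryComposition(0.01, 0.0),
                 DiffusionMatrix(D11=0.9, D12=0.0, D21=0.0, D22=0.45)),
                (TernaryComposition(0.0, 0.01),
                 DiffusionMatrix(D11=0.9, D12=0.0, D21=0.0, D22=0.45))]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_association_constant(rows, 0.9, 0.45, 0.4)

    def test_measured_table_gives_large_Ka_with_report(self):
        """The β-CD table's D12 magnitudes need Ka well above the published 80."""
        rows = dik_rows(load_fixture("table2"))
        fit = fit_association_constant(rows, 0.918, 0.436, 0.421)
        assert 10.0 <= fit.Ka <= 1e3
        assert len(fit.residuals) == 5
        assert np.isfinite(fit.Ka_sd)

    def test_recovery_under_noise(self):
        """Median recovered Ka within 10% of truth at 1% relative noise."""
        comps = [TernaryComposition(x * 0.01, (1 - x) * 0.01)
                 for x in (0.2, 0.4, 0.5, 0.6, 0.8)]
        for Ka in (10.0, 80.0, 500.0):
            truth = BindingSystem(Ka=Ka, D_guest=0.918, D_host=0.436,
                                  D_complex=0.421)
            errs = []
            for rep in range(20):
                rows, _ = generate_dik_table(truth, comps, sigma_rel=0.01,
                                             seed=1000 + rep)
                fit = fit_association_constant(rows, 0.918, 0.436, 0.421)
                errs.append(abs(fit.Ka - Ka) / Ka)
            assert np.median(errs) <= 0.10


class TestTransportRatios:
    def test_na4etra_table_maxima(self):
        summary = transport_ratio_summary(dik_rows(load_fixture("table1")))
        assert summary["max_abs_D12_over_D22"] == pytest.approx(2.4, abs=0.05)
        assert summary["sign_D12_at_max"] == 1
        assert summary["X1_at_max_D12_over_D22"] == pytest.approx(1.0)
        assert summary["max_abs_D21_over_D11"] == pytest.approx(0.10, abs=0.005)

    def test_bcd_table_maxima(self):
        summary = transport_ratio_summary(dik_rows(load_fixture("table2")))
        assert summary["max_abs_D12_over_D22"] == pytest.approx(0.50, abs=0.005)
        assert summary["sign_D12_at_max"] == -1

    def test_diagonal_and_empty(self):
        rows = [(TernaryComposition(0.005, 0.005),
                 DiffusionMatrix(D11=1.0, D12=0.0, D21=0.0, D22=0.5))]
        summary = transport_ratio_summary(rows)
        assert summary["max_abs_D12_over_D22"] == 0.0
        assert summary["max_abs_D21_over_D11"] == 0.0
        with pytest.raises(ValueError):
            transport_ratio_summary([])
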