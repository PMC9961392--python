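"""Dispersion peak model, eigenmode map, fitting and matrix inversion."""

import numpy as np
import pytest
from scipy.integrate import quad

from hgdiff.core import DiffusionMatrix
from hgdiff.synthetic import generate_peak_dataset
from hgdiff.taylor import (
    DispersionPeak,
    InjectionProfile,
    PeakFitResult,
    TaylorInstrument,
    fit_peak,
    invert_dik,
    modes_from_matrix,
    taylor_signal,
)


def _fitresult(**kw):
    defaults = dict(V0=0.0, V1=0.0, Vmax=1.0, tR=3504.0,
                    D1=1.0e-9, D2=0.5e-9, W1=0.6)
    defaults.update(kw)
    return PeakFitResult(**defaults)


class TestSignal:
    def test_apex_value(self, instrument):
        fit = _fitresult()
        v = taylor_signal(fit, instrument, np.array([fit.tR]))
        assert v[0] == pytest.approx(fit.Vmax, rel=1e-14)

    def test_single_mode_reduction(self, instrument):
        t = np.linspace(3000.0, 4000.0, 200)
        one = taylor_signal(_fitresult(W1=1.0, D2=0.3e-9), instrument, t)
        ref = taylor_signal(_fitresult(W1=1.0, D2=1.0e-9, D1=1.0e-9), instrument, t)
        # with W1=1 the second mode is inert
        assert one == pytest.approx(ref, rel=1e-14)

    def test_positive_time_required(self, instrument):
        with pytest.raises(ValueError):
            taylor_signal(_fitresult(), instrument, np.array([-1.0, 10.0]))

    def test_moments_match_quadrature(self, instrument):
        """Discrete moments of a dense noiseless peak agree with quadrature."""
        fit = _fitresult(V1=0.0)
        lo, hi = 2500.0, 4700.0

        def f(t):
            return float(taylor_signal(fit, instrument, np.array([t]))[0])

        t = np.linspace(lo, hi, 20001)
        v = taylor_signal(fit, instrument, t)
        m0_grid = np.trapezoid(v, t)
        m0_quad, _ = quad(f, lo, hi, limit=200)
        assert m0_grid == pytest.approx(m0_quad, rel=1e-6)
        mu_grid = np.trapezoid(v * t, t) / m0_grid
        mu_quad = quad(lambda t: f(t) * t, lo, hi, limit=200)[0] / m0_quad
        m2_grid = np.trapezoid(v * (t - mu_grid) ** 2, t) / m0_grid
        m2_quad = quad(lambda t: f(t) * (t - mu_quad) ** 2, lo, hi,
                       limit=200)[0] / m0_quad
        assert m2_grid == pytest.approx(m2_quad, rel=1e-6)


class TestModes:
    def test_diagonal_decoupled(self):
        D = DiffusionMatrix(D11=1.0, D12=0.0, D21=0.0, D22=0.5)
        d1, d2, w1 = modes_from_matrix(D, InjectionProfile(1e-3, 0.0))
        assert (d1, d2) == pytest.approx((1.0, 0.5))
        assert w1 == pytest.approx(1.0)

    def test_eigenvalues_match_characteristic_polynomial(self):
        """Brute-force quadratic roots of det(D-λI) as an independent oracle."""
        D = DiffusionMatrix(D11=1.034, D12=0.076, D21=0.055, D22=0.660)
        tr, det = D.D11 + D.D22, D.D11 * D.D22 - D.D12 * D.D21
        roots = np.roots([1.0, -tr, det])
        d1, d2, _ = modes_from_matrix(D, InjectionProfile(1e-3, 1e-3))
        assert sorted([d1, d2]) == pytest.approx(sorted(roots.real), rel=1e-12)

    def test_weights_normalized_for_random_inputs(self):
        rng = np.random.default_rng(7)
        from conftest import random_valid_matrix
        for _ in range(50):
            D = random_valid_matrix(rng)
            inj = InjectionProfile(rng.normal(), rng.normal())
            sens = (rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0))
            _, _, w1 = modes_from_matrix(D, inj, sens)
            assert np.isfinite(w1)   # W2 = 1 - W1 by construction

    def test_complex_eigenvalue_error(self):
        D = DiffusionMatrix(D11=1.0, D12=-1.0, D21=1.0, D22=1.0)
        with pytest.raises(ValueError, match="complex"):
            modes_from_matrix(D, InjectionProfile(1e-3, 0.0))


class TestFitPeak:
    def test_binary_round_trip(self, instrument):
        truth = DiffusionMatrix(D11=1.096, D12=0.0, D21=0.0, D22=1.096)
        peaks, _ = generate_peak_dataset(truth, instrument,
                                         [InjectionProfile(1e-3, 0.0)], sigma=0.0)
        fit = fit_peak(peaks[0], mode_count=1)
        assert fit.converged
        assert fit.D1 * 1e9 == pytest.approx(1.096, rel=1e-3)

    def test_ternary_round_trip(self, instrument):
        truth = DiffusionMatrix(D11=1.009, D12=-0.220, D21=0.050, D22=0.446)
        inj = InjectionProfile(1e-3, 0.0)
        peaks, _ = generate_peak_dataset(truth, instrument, [inj], sigma=0.0)
        d1, d2, w1 = modes_from_matrix(truth, inj)
        fit = fit_peak(peaks[0])
        assert fit.D1 * 1e9 == pytest.approx(d1, rel=5e-3)
        assert fit.D2 * 1e9 == pytest.approx(d2, rel=5e-3)
        assert fit.W1 == pytest.approx(w1, rel=5e-3)

    def test_equal_modes_flags_weight_unidentifiable(self, instrument):
        truth = DiffusionMatrix(D11=0.8, D12=0.0, D21=0.0, D22=0.8)
        peaks, _ = generate_peak_dataset(truth, instrument,
                                         [InjectionProfile(1e-3, 1e-3)], sigma=0.0)
        fit = fit_peak(peaks[0], mode_count=2)
        assert not fit.w1_identifiable
        assert np.isnan(fit.W1)
        assert fit.D1 * 1e9 == pytest.approx(0.8, rel=1e-3)

    def test_baseline_invariance(self, instrument):
        truth = DiffusionMatrix(D11=1.0, D12=0.1, D21=0.05, D22=0.5)
        peaks, _ = generate_peak_dataset(truth, instrument,
                                         [InjectionProfile(1e-3, 0.0)], sigma=0.0)
        p = peaks[0]
        ref = fit_peak(p)
        shifted = DispersionPeak(t=p.t, V=p.V + 0.25 + 3e-6 * p.t,
                                 instrument=instrument)
        fit = fit_peak(shifted)
        assert fit.V0 == pytest.approx(ref.V0 + 0.25, abs=1e-4)
        assert fit.V1 == pytest.approx(ref.V1 + 3e-6, rel=1e-3)
        assert fit.D1 == pytest.approx(ref.D1, rel=1e-4)
        assert fit.D2 == pytest.approx(ref.D2, rel=1e-4)

    def test_flat_trace_unfittable(self, instrument):
        t = np.arange(100.0, 1100.0, 5.0)
        flat = DispersionPeak(t=t, V=np.full_like(t, 0.3), instrument=instrument)
        with pytest.raises(ValueError, match="unfittable"):
            fit_peak(flat)


class TestInvert:
    def test_diagonal_exact_recovery(self):
        truth = DiffusionMatrix(D11=1.0, D12=0.0, D21=0.0, D22=0.5)
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]
        fits = [_modes_as_fit(truth, inj) for inj in injs]
        rec = invert_dik(fits, injs)
        assert rec.as_array() == pytest.approx(truth.as_array(), abs=1e-8)

    def test_collinear_injections_rejected(self):
        truth = DiffusionMatrix(D11=1.0, D12=0.1, D21=0.05, D22=0.5)
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(2e-3, 0.0)]
        fits = [_modes_as_fit(truth, inj) for inj in injs]
        with pytest.raises(ValueError, match="collinear"):
            invert_dik(fits, injs)

    def test_inconsistent_eigenvalues_rejected(self):
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]
        fits = [_fitresult(D1=1.0e-9, D2=0.5e-9, W1=0.8),
                _fitresult(D1=1.4e-9, D2=0.5e-9, W1=0.3)]
        with pytest.raises(ValueError, match="inconsistent"):
            invert_dik(fits, injs)

    def test_forward_backward_identity_random_matrices(self):
        rng = np.random.default_rng(11)
        from conftest import random_valid_matrix
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]
        for _ in range(20):
            truth = random_valid_matrix(rng)
            fits = [_modes_as_fit(truth, inj) for inj in injs]
            rec = invert_dik(fits, injs)
            assert rec.as_array() == pytest.approx(truth.as_array(),
                                                   rel=1e-8, abs=1e-8)

    def test_joint_refinement_beats_two_stage(self, instrument):
        """refine_dik recovers a strongly coupled matrix from noisy traces."""
        from hgdiff.taylor import refine_dik
        truth = DiffusionMatrix(D11=1.067, D12=0.410, D21=0.044, D22=0.599)
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]
        peaks, _ = generate_peak_dataset(truth, instrument, injs,
                                         sigma=1e-6, seed=21)
        rec = refine_dik(peaks, injs)
        scale = np.abs(truth.as_array()).max()
        assert np.abs(rec.as_array() - truth.as_array()).max() <= 0.01 * scale

    def test_simulated_table_row_recovery(self, instrument):
        """Full simulate->fit->invert chain on a measured-table matrix."""
        truth = DiffusionMatrix(D11=1.009, D12=-0.220, D21=0.050, D22=0.446)
        injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]
        peaks, _ = generate_peak_dataset(truth, instrument, injs, sigma=0.0)
        fits = [fit_peak(p) for p in peaks]
        rec = invert_dik(fits, injs)
        assert rec.as_array() == pytest.approx(truth.as_array(), rel=0.01,
                                               abs=0.002)


def _modes_as_fit(D, inj, sens=(1.0, 1.0)):
    d1, d2, w1 = modes_from_matrix(D, inj, sens)
    return PeakFitResult(V0=0.0, V1=0.0, Vmax=1.0, tR=3504.0,
                         D1=d1 * 1e-9, D2=d2 * 1e-9, W1=w1)
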