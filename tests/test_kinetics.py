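"""Unit and property tests for the one-tissue kinetic core."""

import math

import numpy as np
import pytest
from scipy import integrate

import h2opet as h
from h2opet.errors import DegenerateInputError, DomainError, ParameterError


# ---------------------------------------------------------------------------
# convolve_exponential
# ---------------------------------------------------------------------------

class TestConvolveExponential:
    def test_zero_input_gives_zeros(self):
        out = h.convolve_exponential(h.InputFunction.zero(), 0.5, [10, 60, 120])
        assert np.all(out == 0)

    @pytest.mark.parametrize("beta", [0.1, 0.4, 2.0])
    def test_constant_input_closed_form(self, beta):
        c = 10.0
        t = np.array([15.0, 60.0, 150.0])
        out = h.convolve_exponential(h.InputFunction.constant(c), beta, t)
        exact = (c / beta) * (1.0 - np.exp(-beta * t / 60.0))
        assert np.allclose(out, exact, rtol=1e-4)

    def test_beta_zero_is_running_integral(self):
        c = 4.0
        t = np.array([30.0, 90.0])
        out = h.convolve_exponential(h.InputFunction.constant(c), 0.0, t)
        assert np.allclose(out, c * t / 60.0, rtol=1e-9)

    def test_gamma_input_matches_adaptive_quadrature(self, input_fn):
        """Fine-grid quadrature vs scipy adaptive integration, 0.1 % tolerance."""
        beta = 0.4
        for t in (60.0, 120.0):
            oracle, _ = integrate.quad(
                lambda s: input_fn(s) * math.exp(-beta * (t - s) / 60.0), 0.0, t,
                limit=200)
            oracle /= 60.0
            got = h.convolve_exponential(input_fn, beta, t)[0]
            assert got == pytest.approx(oracle, rel=1e-3)

    def test_negative_beta_rejected(self, input_fn):
        with pytest.raises(ParameterError):
            h.convolve_exponential(input_fn, -0.1, [10.0])

    def test_eval_outside_sampled_support_rejected(self):
        fn = h.InputFunction.from_samples([0, 10, 20], [0, 5, 1])
        with pytest.raises(DomainError):
            h.convolve_exponential(fn, 0.5, [30.0])


# ---------------------------------------------------------------------------
# forward_model
# ---------------------------------------------------------------------------

class TestForwardModel:
    def test_no_tissue_exchange_is_frame_averaged_vascular(self, schedule, input_fn):
        p = h.OneTissueParams(K1=0.0, k2=0.3, V0=0.1)
        tac = h.forward_model(p, input_fn, schedule)
        grid = schedule.fine_grid()
        expected = 0.1 * schedule.frame_average(grid, input_fn(grid))
        assert np.allclose(tac.activity, expected, rtol=1e-12)

    def test_irreversible_trapping_is_running_integral(self, schedule, input_fn):
        p = h.OneTissueParams(K1=0.6, k2=0.0, V0=0.0)
        tac = h.forward_model(p, input_fn, schedule)
        grid = schedule.fine_grid()
        integral = 0.6 * h.convolve_exponential(input_fn, 0.0, grid)
        assert np.allclose(tac.activity, schedule.frame_average(grid, integral),
                           rtol=1e-6)

    def test_constant_input_closed_form(self, schedule):
        K1, k2, V0, c = 0.8, 0.4, 0.05, 10.0
        tac = h.forward_model(h.OneTissueParams(K1, k2, V0),
                              h.InputFunction.constant(c), schedule)
        grid = schedule.fine_grid()
        exact = (K1 * c / k2) * (1 - np.exp(-k2 * grid / 60.0)) + V0 * c
        assert np.allclose(tac.activity, schedule.frame_average(grid, exact),
                           rtol=2e-4)

    def test_superposition_in_k1(self, schedule, input_fn):
        """Tissue term is linear in K1 for shared k2, V0."""
        kw = dict(k2=0.5, V0=0.0)
        a = h.forward_model(h.OneTissueParams(K1=0.3, **kw), input_fn, schedule)
        b = h.forward_model(h.OneTissueParams(K1=0.9, **kw), input_fn, schedule)
        ab = h.forward_model(h.OneTissueParams(K1=1.2, **kw), input_fn, schedule)
        assert np.allclose(a.activity + b.activity, ab.activity, rtol=1e-12)

    def test_quadrature_grid_refinement_stable(self, schedule, input_fn, default_params):
        coarse = h.forward_model(default_params, input_fn, schedule, dt=0.5)
        fine = h.forward_model(default_params, input_fn, schedule, dt=0.25)
        rel = np.abs(fine.activity - coarse.activity) / fine.activity.max()
        assert rel.max() < 1e-3

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            h.OneTissueParams(K1=-0.1, k2=0.4)
        with pytest.raises(ParameterError):
            h.OneTissueParams(K1=0.5, k2=0.4, V0=1.5)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ParameterError):
            h.FrameSchedule(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# spectral_fit / perfusion_from_spectrum
# ---------------------------------------------------------------------------

def _brute_force_nnls(A, m, n_grid=81, n_refine=7):
    """Exhaustive grid search of min ||A a - m|| over the non-negative quadrant
    of a 2-parameter problem, with iterative window refinement."""
    lo = np.zeros(2)
    hi = np.full(2, 2.0 * max(1.0, np.abs(m).max() / max(np.abs(A).max(), 1e-12)))
    best = None
    for _ in range(n_refine):
        g0 = np.linspace(lo[0], hi[0], n_grid)
        g1 = np.linspace(lo[1], hi[1], n_grid)
        a0, a1 = np.meshgrid(g0, g1, indexing="ij")
        resid = ((A[:, 0, None, None] * a0 + A[:, 1, None, None] * a1
                  - m[:, None, None]) ** 2).sum(axis=0)
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        best = np.array([g0[i], g1[j]])
        w0 = (hi[0] - lo[0]) / (n_grid - 1)
        w1 = (hi[1] - lo[1]) / (n_grid - 1)
        lo = np.maximum(best - 2 * np.array([w0, w1]), 0.0)
        hi = best + 2 * np.array([w0, w1])
    return best


class TestSpectralFit:
    def test_zero_tac_gives_zero_spectrum(self, schedule, input_fn, basis):
        tac = h.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        res = h.spectral_fit(tac, input_fn, basis)
        assert np.all(res.alpha == 0) and res.v0 == 0
        assert res.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_on_grid_rate_recovery(self, schedule, input_fn, basis):
        """Noise-free curve with k2 on the basis grid and V0 = 0: the recovered
        total weight matches K1 within 1 %."""
        k2 = float(basis.rates[30])
        tac = h.forward_model(h.OneTissueParams(K1=0.8, k2=k2, V0=0.0),
                              input_fn, schedule)
        res = h.spectral_fit(tac, input_fn, basis)
        assert res.perfusion_sum == pytest.approx(0.8, rel=1e-2)
        active = res.basis.rates[res.alpha > 1e-3 * res.alpha.max()]
        assert np.any(np.abs(active - k2) < 1e-9)

    def test_matches_brute_force_oracle_on_toy_problem(self):
        """3-frame / 2-rate toy problem: NNLS equals an exhaustive grid search
        over the non-negative quadrant to 1e-6."""
        sched = h.FrameSchedule.from_durations([10.0, 10.0, 10.0])
        fn = h.InputFunction.from_samples([0, 5, 30], [0, 12, 2])
        toy_basis = h.SpectralBasis(np.array([0.0, 1.0]))
        tac = h.TimeActivityCurve(sched, np.array([0.9, 1.8, 2.1]))
        res = h.spectral_fit(tac, fn, toy_basis, fit_blood_volume=False)
        from h2opet.kinetics import _design_matrix
        A = _design_matrix(fn, sched, toy_basis)
        oracle = _brute_force_nnls(A, tac.activity)
        assert np.allclose(res.alpha, oracle, atol=1e-6)

    def test_nested_basis_residual_monotone(self, schedule, input_fn, default_params):
        """Adding basis rates can only reduce the NNLS residual."""
        tac = h.forward_model(default_params, input_fn, schedule)
        rng = np.random.default_rng(3)
        noisy = h.TimeActivityCurve(
            schedule, tac.activity + rng.normal(0, 0.5, schedule.n_frames))
        rates_small = np.array([0.0, 0.1, 0.5, 1.0])
        rates_big = np.array([0.0, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0])
        r_small = h.spectral_fit(noisy, input_fn, h.SpectralBasis(rates_small),
                                 fit_blood_volume=False).residual_norm
        r_big = h.spectral_fit(noisy, input_fn, h.SpectralBasis(rates_big),
                               fit_blood_volume=False).residual_norm
        assert r_big <= r_small + 1e-12

    def test_zero_input_is_degenerate(self, schedule, basis):
        tac = h.TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        with pytest.raises(DegenerateInputError):
            h.spectral_fit(tac, h.InputFunction.zero(), basis)

    def test_perfusion_conventions(self, schedule, input_fn, basis):
        """Sum over all weights splits exactly into tissue and vascular parts."""
        tac = h.forward_model(h.OneTissueParams(K1=0.8, k2=0.4, V0=0.05),
                              input_fn, schedule)
        res = h.spectral_fit(tac, input_fn, basis)
        out = h.perfusion_from_spectrum(res)
        assert out["perfusion"] == pytest.approx(
            out["perfusion_tissue"] + out["vascular_weight"], abs=1e-12)
        assert out["perfusion_tissue"] == pytest.approx(0.8, rel=0.05)
        assert out["blood_volume_fraction"] == pytest.approx(0.05, abs=0.02)

    def test_spectral_and_nonlinear_agree_on_grid(self, schedule, input_fn, basis):
        k2 = float(basis.rates[28])
        tac = h.forward_model(h.OneTissueParams(K1=1.1, k2=k2, V0=0.04),
                              input_fn, schedule)
        sp = h.spectral_fit(tac, input_fn, basis)
        nl = h.nonlinear_fit(tac, input_fn)
        assert sp.perfusion_tissue == pytest.approx(nl.params.K1, rel=1e-2)


# ---------------------------------------------------------------------------
# nonlinear_fit
# ---------------------------------------------------------------------------

class TestNonlinearFit:
    def test_noise_free_recovery(self, schedule, input_fn):
        truth = h.OneTissueParams(K1=1.2, k2=0.55, V0=0.08)
        tac = h.forward_model(truth, input_fn, schedule)
        fit = h.nonlinear_fit(tac, input_fn)
        assert fit.converged
        assert fit.params.K1 == pytest.approx(truth.K1, rel=5e-3)
        assert fit.params.k2 == pytest.approx(truth.k2, rel=5e-3)
        assert fit.params.V0 == pytest.approx(truth.V0, rel=5e-3)

    def test_pure_vascular_signal(self, schedule, input_fn):
        tac = h.forward_model(h.OneTissueParams(K1=0.0, k2=0.3, V0=0.12),
                              input_fn, schedule)
        fit = h.nonlinear_fit(tac, input_fn)
        assert fit.params.K1 == pytest.approx(0.0, abs=1e-4)
        assert fit.params.V0 == pytest.approx(0.12, abs=1e-3)

    def test_noisy_recovery_within_band(self, schedule, input_fn):
        """At the default phantom noise level (peak-frame SNR ~ 10) the typical
        (median over seeded replicates) K1 error stays within 15 %."""
        truth = h.OneTissueParams(K1=0.8, k2=0.4, V0=0.05)
        errors = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            tac = h.simulate_tac(truth, input_fn, schedule,
                                 sigma0=h.DEFAULT_SIGMA0, rng=rng)
            fit = h.nonlinear_fit(tac, input_fn)
            errors.append(abs(fit.params.K1 - truth.K1) / truth.K1)
        assert np.median(errors) < 0.15


# ---------------------------------------------------------------------------
# estimate_delay
# ---------------------------------------------------------------------------

class TestEstimateDelay:
    def test_zero_delay(self, schedule, input_fn, default_params):
        tac = h.forward_model(default_params, input_fn, schedule)
        est = h.estimate_delay(tac, input_fn)
        assert est.delay == 0.0 and not est.low_confidence

    def test_ten_second_delay_on_two_second_grid(self, schedule, input_fn):
        p = h.OneTissueParams(K1=0.8, k2=0.4, V0=0.05, delay=10.0)
        tac = h.forward_model(p, input_fn, schedule)
        est = h.estimate_delay(tac, input_fn)
        assert est.delay == 10.0

    def test_pure_noise_flagged_low_confidence(self, schedule, input_fn):
        rng = np.random.default_rng(11)
        tac = h.TimeActivityCurve(schedule, rng.normal(0.0, 0.5, schedule.n_frames))
        est = h.estimate_delay(tac, input_fn)
        assert np.isfinite(est.delay)
        assert est.low_confidence

    def test_empty_grid_rejected(self, schedule, input_fn, default_params):
        tac = h.forward_model(default_params, input_fn, schedule)
        with pytest.raises(ParameterError):
            h.estimate_delay(tac, input_fn, search_grid=[])


# ---------------------------------------------------------------------------
# decay correction and percent change
# ---------------------------------------------------------------------------

class TestDecayAndChange:
    def test_infinite_half_life_is_identity(self, schedule):
        tac = h.TimeActivityCurve(schedule, np.linspace(1, 10, schedule.n_frames),
                                  decay_corrected=False)
        out = h.decay_correct(tac, half_life=np.inf)
        assert np.allclose(out.activity, tac.activity)
        assert out.decay_corrected

    def test_one_half_life_doubles(self):
        sched = h.FrameSchedule(np.array([h.O15_HALF_LIFE_S - 5.0]), np.array([10.0]))
        tac = h.TimeActivityCurve(sched, np.array([3.0]), decay_corrected=False)
        out = h.decay_correct(tac)
        assert out.activity[0] == pytest.approx(6.0, rel=1e-12)

    def test_round_trip(self, schedule):
        tac = h.TimeActivityCurve(schedule, np.linspace(0.5, 8, schedule.n_frames),
                                  decay_corrected=False)
        back = h.decay_uncorrect(h.decay_correct(tac))
        assert np.allclose(back.activity, tac.activity, rtol=1e-12)

    def test_double_correction_rejected(self, schedule):
        tac = h.TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        with pytest.raises(ParameterError):
            h.decay_correct(tac)

    @pytest.mark.parametrize("baseline,followup,expected", [
        (1.0, 1.0, 0.0),
        (2.0, 3.0, 50.0),
        (0.81, 0.1215, -85.0),  # printed baseline and change invert consistently
    ])
    def test_percent_change(self, baseline, followup, expected):
        assert h.percent_change(baseline, followup) == pytest.approx(expected)

    def test_percent_change_nonpositive_baseline(self):
        with pytest.raises(ParameterError):
            h.percent_change(0.0, 1.0)
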