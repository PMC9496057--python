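"""Tests for the 5PL Gauss-Newton fitter and SDM Ct caller.

The independent oracles here are (a) central finite differences of the model
value for the analytic derivatives, (b) the closed-form second-derivative
maximum of the symmetric logistic, ct = x0 - k*ln(2 + sqrt(3)), and (c)
brute-force dense grids over the analytic curve.
"""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from ampcurve import ctcall, simgen
from ampcurve.ctcall import (
    CtUndefinedError,
    FitFailureError,
    FivePLParams,
    NotAmplifyingError,
    UncallableError,
    call_ct,
    ct_from_fit,
    d1,
    d2,
    gauss_newton_fit,
    init_guess,
    model_eval,
)
from ampcurve.simgen import FluorescenceCurve

SDM_OFFSET = np.log(2 + np.sqrt(3))  # symmetric-logistic d2-max offset in k units


def _curve_from_params(p, n=40, noise=0.0, seed=0):
    x = np.arange(1, n + 1, dtype=float)
    y = model_eval(p, x)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, size=n)
    return FluorescenceCurve.from_rfu(np.clip(y, 0, None))


params_strategy = st.builds(
    FivePLParams,
    f_b=st.floats(0.0, 0.3),
    f_max=st.floats(0.5, 2.0),
    x0=st.floats(10.0, 32.0),
    k=st.floats(0.5, 3.0),
    s=st.floats(0.4, 2.5),
)


class TestModelEval:
    def test_midpoint_value_symmetric(self):
        p = FivePLParams(0.1, 0.9, 25.0, 1.3, 1.0)
        assert model_eval(p, 25.0) == pytest.approx(0.5, abs=1e-12)

    def test_asymptotes(self):
        p = FivePLParams(0.1, 0.9, 25.0, 1.3, 0.8)
        assert model_eval(p, -1e3) == pytest.approx(0.1, abs=1e-9)
        assert model_eval(p, 1e3) == pytest.approx(0.9, abs=1e-9)
        assert d2(p, -1e3) == pytest.approx(0.0, abs=1e-12)
        assert d2(p, 1e3) == pytest.approx(0.0, abs=1e-12)

    @given(params_strategy, st.floats(5.0, 38.0))
    @settings(max_examples=50, deadline=None)
    def test_derivatives_match_finite_differences(self, p, x):
        h = 1e-5
        fd1 = (model_eval(p, x + h) - model_eval(p, x - h)) / (2 * h)
        # wider step for the second difference: h=1e-5 would be roundoff-bound
        h2 = 1e-4
        fd2 = (model_eval(p, x + h2) - 2 * model_eval(p, x) + model_eval(p, x - h2)) / h2**2
        scale1 = max(abs(fd1), 1e-3)
        scale2 = max(abs(fd2), 1e-3)
        assert abs(d1(p, x) - fd1) / scale1 < 1e-5
        assert abs(d2(p, x) - fd2) / scale2 < 1e-4

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FivePLParams(0, 1, 25, -1, 1)
        with pytest.raises(ValueError):
            FivePLParams(0, 1, 25, 1, 0)


class TestInitGuess:
    def test_x0_guess_close_to_truth(self):
        truth = FivePLParams(0.05, 0.9, 26.0, 1.2, 1.0)
        guess = init_guess(_curve_from_params(truth))
        assert abs(guess.x0 - truth.x0) < 2.0

    def test_flat_curve_raises(self):
        with pytest.raises(NotAmplifyingError):
            init_guess(FluorescenceCurve.from_rfu(np.full(40, 0.05)))

    def test_noisy_flat_curve_raises(self):
        c = simgen.simulate_curve(simgen.CurveClass.C, simgen.SimConfig(seed=1))
        with pytest.raises(NotAmplifyingError):
            init_guess(c)

    def test_ramp_produces_guess(self):
        cfg = replace(simgen.SimConfig(), noise_sd=0.0)
        c = simgen.simulate_curve(simgen.CurveClass.F, cfg)
        guess = init_guess(c)
        assert guess.k > 0 and guess.s > 0


class TestGaussNewtonFit:
    def test_noiseless_parameter_recovery(self):
        truth = FivePLParams(0.08, 0.95, 23.0, 1.4, 0.8)
        curve = _curve_from_params(truth)
        fit = gauss_newton_fit(curve, init_guess(curve))
        assert fit.converged
        for name in ("f_b", "f_max", "x0", "k", "s"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert abs(got - want) / abs(want) < 1e-4, name
        energy = float(np.sum(curve.rfu**2))
        assert fit.residual_norm < 1e-12 * energy

    def test_fixed_point_converges_fast(self):
        truth = FivePLParams(0.05, 1.0, 25.0, 1.0, 1.0)
        curve = _curve_from_params(truth)
        fit = gauss_newton_fit(curve, truth)
        assert fit.converged
        assert fit.iterations <= 2
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-20)

    def test_noisy_x0_recovery_median(self):
        truth = FivePLParams(0.05, 1.05, 25.0, 1.0, 1.0)
        x = np.arange(1, 41, dtype=float)
        clean = model_eval(truth, x)
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(100):
            noisy = np.clip(clean + rng.normal(0, 0.005, 40), 0, None)
            curve = FluorescenceCurve.from_rfu(noisy)
            fit = gauss_newton_fit(curve, init_guess(curve))
            errors.append(abs(fit.params.x0 - truth.x0))
        assert np.median(errors) < 0.1

    def test_ssr_never_worse_than_init(self):
        truth = FivePLParams(0.05, 0.9, 27.0, 1.1, 1.2)
        curve = _curve_from_params(truth, noise=0.01, seed=3)
        init = init_guess(curve)
        x = curve.cycles.astype(float)
        init_ssr = float(np.sum((curve.rfu - model_eval(init, x)) ** 2))
        fit = gauss_newton_fit(curve, init)
        assert fit.residual_norm <= init_ssr

    def test_affine_rescaling_invariance(self):
        truth = FivePLParams(0.05, 0.95, 24.0, 1.2, 0.9)
        curve = _curve_from_params(truth)
        ct_ref = call_ct(curve).ct
        scaled = FluorescenceCurve.from_rfu(1234.5 * curve.rfu + 67.8)
        ct_scaled = call_ct(scaled).ct
        assert abs(ct_ref - ct_scaled) < 1e-6


class TestCtFromFit:
    def test_closed_form_symmetric_logistic(self):
        truth = FivePLParams(0.05, 1.0, 25.0, 1.0, 1.0)
        fit = gauss_newton_fit(_curve_from_params(truth), truth)
        res = ct_from_fit(fit)
        assert res.ct == pytest.approx(25.0 - SDM_OFFSET, abs=1e-3)
        assert res.method == "SDM"

    @pytest.mark.parametrize("s", [0.5, 0.7, 1.0])
    def test_ct_precedes_midpoint(self, s):
        p = FivePLParams(0.05, 1.0, 25.0, 1.0, s)
        fit = gauss_newton_fit(_curve_from_params(p), p)
        assert ct_from_fit(fit).ct < p.x0

    def test_translation_equivariance(self):
        for delta in (0.0, 2.5, 5.0):
            p = FivePLParams(0.05, 1.0, 22.0 + delta, 1.0, 1.0)
            fit = gauss_newton_fit(_curve_from_params(p), p)
            ct = ct_from_fit(fit).ct
            assert ct == pytest.approx(22.0 - SDM_OFFSET + delta, abs=1e-6)

    def test_agrees_with_dense_grid_oracle(self):
        p = FivePLParams(0.07, 0.9, 26.0, 1.3, 0.8)
        fit = gauss_newton_fit(_curve_from_params(p), p)
        ct = ct_from_fit(fit).ct
        # independent oracle: brute-force FD second derivative of model_eval
        grid = np.arange(1.0, 40.0, 1e-3)
        h = 1e-4
        fd2 = (
            model_eval(fit.params, grid + h)
            - 2 * model_eval(fit.params, grid)
            + model_eval(fit.params, grid - h)
        ) / h**2
        assert abs(ct - grid[np.argmax(fd2)]) < 1e-3

    def test_boundary_argmax_rejected(self):
        # midpoint far beyond the domain: d2 max sits on the right edge
        p = FivePLParams(0.05, 1.0, 60.0, 1.0, 1.0)
        fit = ctcall.FitResult(params=p, residual_norm=0.0, iterations=1, converged=True)
        with pytest.raises(CtUndefinedError, match="boundary"):
            ct_from_fit(fit)

    def test_unconverged_fit_rejected(self):
        p = FivePLParams(0.05, 1.0, 25.0, 1.0, 1.0)
        fit = ctcall.FitResult(params=p, residual_norm=1.0, iterations=200, converged=False)
        with pytest.raises(CtUndefinedError, match="converge"):
            ct_from_fit(fit)


class TestCallCt:
    def test_known_sigmoid_ct(self):
        truth = FivePLParams(0.05, 1.0, 25.0, 1.0, 1.0)
        res = call_ct(_curve_from_params(truth))
        assert round(res.ct, 2) == pytest.approx(23.68, abs=0.01)

    def test_flat_curve_uncallable(self):
        with pytest.raises(UncallableError):
            call_ct(FluorescenceCurve.from_rfu(np.full(40, 0.05)))

    def test_ct_within_domain(self, noiseless_config):
        for label in (simgen.CurveClass.A, simgen.CurveClass.B):
            for i in range(5):
                c = simgen.simulate_curve(label, noiseless_config, index=i)
                res = call_ct(c)
                assert 1.0 <= res.ct <= 40.0

    @given(st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_generated_positive_curves_callable(self, index):
        c = simgen.simulate_curve(simgen.CurveClass.A, simgen.SimConfig(seed=1), index=index)
        res = call_ct(c)
        assert 1.0 <= res.ct <= 40.0
        assert res.fit.converged
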