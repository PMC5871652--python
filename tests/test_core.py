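"""Forward signal model and segmented-fit estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivim3b import (
    BRAIN,
    KIDNEY,
    LIVER,
    AcquisitionScheme,
    SignalCurve,
    TissueModel,
    ivim_signal,
    segmented_fit,
    two_point_fit,
)
from ivim3b.core import fit_signal_matrix

ALL_MODELS = [BRAIN, KIDNEY, LIVER]
ALL_B_LOWS = [200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0]


class TestTissueModel:
    def test_canonical_ratios(self):
        assert BRAIN.ratio == pytest.approx(10.0)
        assert KIDNEY.ratio == pytest.approx(20.0)
        assert LIVER.ratio == pytest.approx(70.0)

    @pytest.mark.parametrize("D,Ds", [(-1e-3, 7e-3), (0.0, 7e-3), (7e-4, 7e-4), (7e-4, 1e-4)])
    def test_rejects_unphysical_parameters(self, D, Ds):
        with pytest.raises(ValueError):
            TissueModel("bad", D=D, D_star=Ds)


class TestAcquisitionScheme:
    def test_two_point_protocol_has_three_acquisitions(self):
        s = AcquisitionScheme.two_point(300.0)
        assert s.b_values == (0.0, 300.0, 1000.0)
        assert s.fit_pair == (300.0, 1000.0)
        assert s.name == "[300,1000]"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(b_values=(300.0, 1000.0), fit_bvalues=(300.0, 1000.0)),  # no b=0
            dict(b_values=(0.0, 300.0, 1000.0), fit_bvalues=(300.0,)),  # one point
            dict(b_values=(0.0, 1000.0), fit_bvalues=(300.0, 1000.0)),  # not acquired
            dict(b_values=(0.0, 300.0, 1000.0), fit_bvalues=(300.0, 300.0)),
        ],
    )
    def test_invalid_schemes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionScheme(**kwargs)


class TestIvimSignal:
    def test_normalisation_at_b0(self):
        for m in ALL_MODELS:
            assert ivim_signal(m, 0.23, 0.0) == pytest.approx(1.0)

    def test_mono_exponential_limit_f0(self):
        b = np.array([0.0, 250.0, 990.0])
        assert ivim_signal(BRAIN, 0.0, b) == pytest.approx(np.exp(-b * BRAIN.D))

    def test_brain_reference_value(self):
        # direct evaluation of the bi-exponential at f=0.1, b=1000
        assert ivim_signal(BRAIN, 0.1, 1000.0) == pytest.approx(0.44702, abs=5e-6)

    def test_liver_high_f_value(self):
        expected = 0.3 * math.exp(-49.0) + 0.7 * math.exp(-0.7)
        assert ivim_signal(LIVER, 0.3, 1000.0) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ivim_signal(BRAIN, -0.1, 100.0)
        with pytest.raises(ValueError):
            ivim_signal(BRAIN, 1.2, 100.0)
        with pytest.raises(ValueError):
            ivim_signal(BRAIN, 0.1, -5.0)

    def test_strictly_decreasing_in_b(self):
        b = np.linspace(0, 1000, 50)
        s = ivim_signal(BRAIN, 0.15, b)
        assert np.all(np.diff(s) < 0)


def _noise_free_curve(model, f, b_values):
    b = np.asarray(b_values, dtype=float)
    return SignalCurve(b, ivim_signal(model, f, b), truth=(model, f))


class TestSegmentedFit:
    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.name)
    @pytest.mark.parametrize("b_low", ALL_B_LOWS)
    def test_exact_recovery_when_f_zero(self, model, b_low):
        """With no perfusion compartment the mono-exponential fit is exact."""
        scheme = AcquisitionScheme.two_point(b_low)
        res = segmented_fit(_noise_free_curve(model, 0.0, scheme.b_values), scheme)
        assert res.valid
        assert res.D_est == pytest.approx(model.D, rel=1e-12)
        assert res.f_est == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "b_low,exp_D,exp_f",
        [(300.0, 7.235e-4, 0.07842), (500.0, 7.0909e-4, 0.09159)],
    )
    def test_noise_free_brain_intrinsic_bias(self, oracle, b_low, exp_D, exp_f):
        """Residual perfusion signal at b_low biases f down and D up."""
        scheme = AcquisitionScheme.two_point(b_low)
        res = segmented_fit(_noise_free_curve(BRAIN, 0.1, scheme.b_values), scheme)
        assert res.f_est == pytest.approx(exp_f, abs=5e-5)
        assert res.D_est == pytest.approx(exp_D, rel=1e-3)
        D_o, f_o = oracle(BRAIN, 0.1, b_low)
        assert res.D_est == pytest.approx(D_o, rel=1e-12)
        assert res.f_est == pytest.approx(f_o, rel=1e-12)

    @pytest.mark.parametrize("f", [0.06, 0.2, 0.3])
    def test_liver_perfusion_negligible_at_high_b(self, f):
        """At b=800 the liver perfusion term is < e^-39: fit is unbiased."""
        scheme = AcquisitionScheme.two_point(800.0)
        res = segmented_fit(_noise_free_curve(LIVER, f, scheme.b_values), scheme)
        assert res.D_est == pytest.approx(LIVER.D, rel=1e-3)
        assert res.f_est == pytest.approx(f, abs=1e-3)

    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.name)
    def test_intrinsic_bias_signs(self, model):
        """Noise-free f_est <= f and D_est >= D for every scheme."""
        for b_low in ALL_B_LOWS:
            scheme = AcquisitionScheme.two_point(b_low)
            for f in (0.06, 0.18, 0.30):
                res = segmented_fit(_noise_free_curve(model, f, scheme.b_values), scheme)
                assert res.f_est <= f + 1e-12
                assert res.D_est >= model.D - 1e-15

    def test_bias_vanishes_monotonically_with_b_low(self):
        """|f_est - f| shrinks as b_low * D* grows (brain, b_low 200..900)."""
        errs = []
        for b_low in ALL_B_LOWS:
            scheme = AcquisitionScheme.two_point(b_low)
            res = segmented_fit(_noise_free_curve(BRAIN, 0.1, scheme.b_values), scheme)
            errs.append(abs(res.f_est - 0.1))
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < errs[0] / 10

    def test_f_est_uses_measured_s0(self):
        """A perturbed b=0 measurement must shift f_est through Eq. 3."""
        scheme = AcquisitionScheme.two_point(500.0)
        curve = _noise_free_curve(BRAIN, 0.1, scheme.b_values)
        bumped = SignalCurve(curve.b_values, curve.signals.copy())
        bumped.signals[0] *= 1.05
        res0 = segmented_fit(curve, scheme)
        res1 = segmented_fit(bumped, scheme)
        assert res1.D_est == res0.D_est
        assert res1.f_est == pytest.approx(1.0 - (1.0 - res0.f_est) / 1.05)

    def test_negative_slope_returned_unclamped(self):
        scheme = AcquisitionScheme.two_point(500.0)
        curve = SignalCurve(np.array([0.0, 500.0, 1000.0]),
                            np.array([1.0, 0.5, 0.6]))  # rising high-b signal
        res = segmented_fit(curve, scheme)
        assert res.valid
        assert res.D_est < 0

    def test_nonpositive_signal_flagged_invalid(self):
        scheme = AcquisitionScheme.two_point(500.0)
        curve = SignalCurve(np.array([0.0, 500.0, 1000.0]),
                            np.array([1.0, 0.5, -0.01]))
        res = segmented_fit(curve, scheme)
        assert not res.valid
        assert math.isnan(res.D_est) and math.isnan(res.f_est)


class TestFitterEquivalence:
    @given(
        s0=st.floats(0.5, 1.5),
        s_low=st.floats(0.2, 1.0),
        s_high=st.floats(0.05, 0.8),
        b_low=st.floats(150.0, 900.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_two_point_closed_form_equals_least_squares(self, s0, s_low, s_high, b_low):
        """The closed-form pair solution and the OLS path agree to machine
        precision on arbitrary positive two-point data."""
        res_cf = two_point_fit(s0, s_low, s_high, b_low, 1000.0)
        D, f, S_int, ok = fit_signal_matrix(
            np.array([s0]), np.array([[s_low, s_high]]),
            np.array([b_low, 1000.0]))
        assert ok[0] and res_cf.valid
        # abs floors cover round-off when the slope is numerically zero;
        # 1e-13 is ~10 orders below any physical D in mm^2/s
        assert D[0] == pytest.approx(res_cf.D_est, rel=1e-12, abs=1e-13)
        assert f[0] == pytest.approx(res_cf.f_est, rel=1e-12, abs=1e-13)
        assert S_int[0] == pytest.approx(res_cf.S_int, rel=1e-12)

    def test_multipoint_fit_matches_polyfit(self):
        """>=3 fit points: OLS of ln S on b agrees with numpy's polyfit."""
        rng = np.random.default_rng(7)
        b_fit = np.array([300.0, 500.0, 800.0, 1000.0])
        scheme = AcquisitionScheme(b_values=(0.0, *b_fit), fit_bvalues=tuple(b_fit))
        signals = ivim_signal(BRAIN, 0.12, np.array([0.0, *b_fit]))
        signals = signals * (1 + rng.normal(0, 0.01, signals.shape))
        curve = SignalCurve(np.array([0.0, *b_fit]), signals)
        res = segmented_fit(curve, scheme)
        slope, intercept = np.polyfit(b_fit, np.log(signals[1:]), 1)
        assert res.D_est == pytest.approx(-slope, rel=1e-10)
        assert res.f_est == pytest.approx(1 - np.exp(intercept) / signals[0], rel=1e-10)
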