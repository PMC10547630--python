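"""Disposition impulse response and the four candidate concentration models."""

import numpy as np
import pytest
from scipy import integrate
from scipy.linalg import expm

from oralpk import (
    AbsorptionInput,
    BatemanParams,
    Disposition3C,
    GammaParams,
    IG1CParams,
    IGInput,
    bateman_auc,
    conc_2ig3c,
    conc_bateman,
    conc_gamma,
    conc_ig1c,
    gamma_auc,
    impulse_response,
)
from oralpk.models import ig1c_auc


def _rate_matrix(disp):
    k10 = disp.CL / disp.V1
    k12 = disp.CLd2 / disp.V1
    k21 = disp.CLd2 / disp.V2
    k13 = disp.CLd3 / disp.V1
    k31 = disp.CLd3 / disp.V3
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )


class TestImpulseResponse:
    def test_integral_is_inverse_clearance(self, disposition):
        h = impulse_response(disposition)
        assert h.auc == pytest.approx(1.0 / disposition.CL, abs=1e-9)
        num, _ = integrate.quad(h, 0, np.inf, limit=200)
        assert num == pytest.approx(1.0 / disposition.CL, abs=1e-8)

    def test_coefficients_sum_to_inverse_volume(self, disposition):
        h = impulse_response(disposition)
        assert h.coeffs.sum() == pytest.approx(1.0 / disposition.V1, rel=1e-12)
        assert np.all(h.rates > 0)

    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0])
    def test_matches_matrix_exponential(self, disposition, t):
        h = impulse_response(disposition)
        A = _rate_matrix(disposition)
        oracle = (expm(A * t) @ np.array([1.0, 0.0, 0.0]))[0] / disposition.V1
        assert h(t) == pytest.approx(oracle, rel=1e-9)

    def test_one_compartment_collapse(self):
        disp = Disposition3C(V1=50, CL=10, CLd2=1e-8, V2=1e-4, CLd3=1e-9, V3=1e-4)
        h = impulse_response(disp)
        t = np.linspace(0.1, 20, 30)
        ref = np.exp(-(10 / 50) * t) / 50
        np.testing.assert_allclose(h(t), ref, rtol=1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Disposition3C(V1=-1, CL=10, CLd2=20, V2=100, CLd3=5, V3=200)

    def test_mdrt_is_vss_over_cl(self, disposition):
        assert disposition.mdrt == pytest.approx((50 + 100 + 200) / 10)


class TestConc2IG3C:
    def test_zero_at_origin(self, absorption, disposition):
        assert conc_2ig3c(0.0, absorption, disposition) == 0.0

    def test_matches_adaptive_quadrature(self, absorption, disposition):
        h = impulse_response(disposition)
        for t in (0.5, 3.0, 10.0, 40.0):
            oracle, _ = integrate.quad(
                lambda tau: absorption.D
                * absorption.F
                * absorption.mixture_density(tau)
                * h(t - tau),
                0,
                t,
                limit=300,
            )
            assert conc_2ig3c(t, absorption, disposition) == pytest.approx(
                oracle, rel=1e-8
            )

    def test_linear_in_dose(self, absorption, disposition):
        t = np.linspace(0.5, 60, 20)
        doubled = AbsorptionInput(
            D=2 * absorption.D,
            F=absorption.F,
            p=absorption.p,
            ig1=absorption.ig1,
            ig2=absorption.ig2,
        )
        np.testing.assert_allclose(
            conc_2ig3c(t, doubled, disposition),
            2 * conc_2ig3c(t, absorption, disposition),
            rtol=1e-12,
        )

    def test_delta_input_limit_is_bolus_response(self, disposition):
        ig = IGInput(MT=0.01, RD2=0.1)
        ab = AbsorptionInput(D=10, F=0.5, p=0.5, ig1=ig, ig2=ig)
        h = impulse_response(disposition)
        t = np.array([2.0, 10.0, 30.0])
        np.testing.assert_allclose(
            conc_2ig3c(t, ab, disposition), 5.0 * h(t), rtol=1e-2
        )

    def test_one_compartment_single_ig_equals_ig1c(self):
        disp = Disposition3C(V1=50, CL=10, CLd2=1e-8, V2=1e-4, CLd3=1e-9, V3=1e-4)
        ig = IGInput(MT=8, RD2=0.5)
        ab = AbsorptionInput(D=30, F=0.5, p=0.5, ig1=ig, ig2=ig)
        params = IG1CParams(scale=30 * 0.5 / 50, MT=8, RD2=0.5, ke=10 / 50)
        t = np.linspace(0.5, 60, 25)
        np.testing.assert_allclose(
            conc_2ig3c(t, ab, disp), conc_ig1c(t, params), rtol=1e-5
        )


class TestBateman:
    def test_zero_at_origin(self):
        assert conc_bateman(0.0, BatemanParams(A=1, ka=1, ke=0.1)) == 0.0

    def test_closed_form_auc(self):
        p = BatemanParams(A=1, ka=1, ke=0.1)
        assert bateman_auc(p) == pytest.approx(9.0)
        num, _ = integrate.quad(lambda t: conc_bateman(t, p), 0, np.inf, limit=200)
        assert num == pytest.approx(bateman_auc(p), abs=1e-8)

    def test_peak_time(self):
        p = BatemanParams(A=1, ka=1, ke=0.1)
        assert p.t_max == pytest.approx(np.log(10) / 0.9)
        t = np.linspace(0.01, 30, 5000)
        assert t[np.argmax(conc_bateman(t, p))] == pytest.approx(p.t_max, abs=0.02)

    def test_equal_rate_constants_rejected(self):
        with pytest.raises(ValueError):
            BatemanParams(A=1, ka=0.5, ke=0.5)

    def test_log_concave(self):
        # log C has non-positive second differences everywhere (the regime a
        # one-compartment fit can represent)
        p = BatemanParams(A=1, ka=0.5, ke=0.05)
        t = np.linspace(0.5, 60, 200)
        d2 = np.diff(np.log(conc_bateman(t, p)), 2)
        assert np.all(d2 <= 1e-12)


class TestIG1C:
    def test_zero_at_origin(self):
        assert conc_ig1c(0.0, IG1CParams(scale=1, MT=8, RD2=0.5, ke=0.2)) == 0.0

    def test_numeric_auc_is_scale_over_ke(self):
        p = IG1CParams(scale=0.3, MT=8, RD2=0.5, ke=0.2)
        num, _ = integrate.quad(lambda t: conc_ig1c(t, p), 0, 400, limit=400)
        assert num == pytest.approx(ig1c_auc(p), rel=1e-3)

    def test_delta_input_limit(self):
        p = IG1CParams(scale=1.0, MT=0.01, RD2=0.1, ke=0.2)
        t = np.array([2.0, 10.0, 25.0])
        np.testing.assert_allclose(conc_ig1c(t, p), np.exp(-0.2 * t), rtol=1e-2)

    def test_not_log_concave_unlike_bateman(self):
        # when elimination is fast relative to the IG input tail the curve
        # becomes input-rate limited and its log develops a convex tail —
        # a shape no Bateman function (log-concave everywhere) can take
        p = IG1CParams(scale=1.0, MT=8, RD2=0.5, ke=2.0)
        t = np.linspace(2, 60, 300)
        d2 = np.diff(np.log(conc_ig1c(t, p)), 2)
        assert np.any(d2 > 1e-8) and np.any(d2 < -1e-8)


class TestGammaCurve:
    def test_closed_form_auc(self):
        assert gamma_auc(GammaParams(A=1, a=2, b=1)) == pytest.approx(1.0)
        p = GammaParams(A=0.3, a=2.5, b=0.2)
        num, _ = integrate.quad(lambda t: conc_gamma(t, p), 0, np.inf, limit=200)
        assert num == pytest.approx(gamma_auc(p), abs=1e-8)

    def test_mode_location(self):
        p = GammaParams(A=1, a=3, b=0.5)
        assert p.t_max == pytest.approx(4.0)
        t = np.linspace(0.01, 40, 8000)
        assert t[np.argmax(conc_gamma(t, p))] == pytest.approx(4.0, abs=0.01)

    def test_shape_constraint(self):
        with pytest.raises(ValueError):
            GammaParams(A=1, a=1.0, b=0.5)

    def test_zero_at_origin(self):
        assert conc_gamma(0.0, GammaParams(A=1, a=2, b=1)) == 0.0
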