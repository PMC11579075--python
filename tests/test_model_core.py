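"""Structural-model functions: surge secretion, Hill curves, binding, absorption."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from hpaxis import StructuralParams
from hpaxis.model_core import (apply_covariates, bound_from_unbound,
                               cortisol_production_rate, feedback_factor,
                               mtt_for_dose, pulsatile_secretion, surge_rate,
                               transit_input_rate, unbound_from_total)
from hpaxis.params import HC_NMOL_PER_MG


class TestSurge:
    def test_peak_equals_amplitude(self, theta):
        v = surge_rate(theta.Pt1, theta.SA1, theta.SW1, theta.Pt1, theta.n_surge)
        assert v == pytest.approx(1300.0, abs=0.05)  # adjacent-day tails < 0.02

    def test_half_width_identity(self, theta):
        # one width away from the peak the single-day term is SA/2
        v = surge_rate(theta.Pt1 + theta.SW1, theta.SA1, theta.SW1,
                       theta.Pt1, theta.n_surge)
        assert v == pytest.approx(650.0, abs=0.05)

    def test_twelve_hour_tail(self, theta):
        # polynomial tail 12 h from the morning peak: direct evaluation of a
        # single surge term is ~0.0085 pmol/h; the periodic function sees
        # day-images at +-12 h (and a negligible one at 36 h)
        single = theta.SA1 / ((12.0 / theta.SW1) ** 4 + 1.0)
        assert single == pytest.approx(0.008455, rel=1e-3)
        v = surge_rate(theta.Pt1 + 12.0, theta.SA1, theta.SW1,
                       theta.Pt1, theta.n_surge)
        expected = sum(theta.SA1 / (((12.0 + 24.0 * d) / theta.SW1) ** 4 + 1.0)
                       for d in (-1, 0, 1))
        assert v == pytest.approx(expected, rel=1e-9)

    def test_midday_surge_tail_sets_nocturnal_floor(self, theta):
        # the wide midday surge still contributes ~0.2 pmol/h at 21:00, which
        # keeps the nocturnal ACTH floor above Base (see the simulate tests)
        tail = surge_rate(21.0, theta.SA2, theta.SW2, theta.Pt2, 4)
        expected = sum(theta.SA2 /
                       (((21.0 + 24.0 * d - theta.Pt2) / theta.SW2) ** 4 + 1.0)
                       for d in (-1, 0, 1))
        assert tail == pytest.approx(expected, rel=1e-9)
        assert 0.15 < tail < 0.35

    def test_periodicity(self, theta):
        t = np.linspace(0, 24, 97)
        a = surge_rate(t, theta.SA1, theta.SW1, theta.Pt1, 4)
        b = surge_rate(t + 48.0, theta.SA1, theta.SW1, theta.Pt1, 4)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    @pytest.mark.parametrize("bad", [{"SW": 0.0}, {"SW": -1.0}, {"n": 3}, {"n": 0}])
    def test_domain_errors(self, bad):
        kw = dict(SA=100.0, SW=1.0, Pt=6.0, n=4)
        kw.update(bad)
        with pytest.raises(ValueError):
            surge_rate(6.0, kw["SA"], kw["SW"], kw["Pt"], kw["n"])

    def test_zero_amplitudes(self, theta):
        p = theta.replace(SA1=0.0, SA2=0.0)
        t = np.linspace(0, 24, 49)
        assert np.all(pulsatile_secretion(t, p) == 0.0)

    def test_two_surge_sum_at_midday_peak(self, theta):
        # at the midday peak: SA2 plus its own tiny day-images plus the
        # morning-surge tail
        v = pulsatile_secretion(theta.Pt2, theta)
        tail1 = surge_rate(theta.Pt2, theta.SA1, theta.SW1, theta.Pt1, 4)
        assert v - tail1 == pytest.approx(50.0, abs=0.01)
        assert v > 50.0


class TestHillCurves:
    def test_feedback_limits(self, theta):
        assert feedback_factor(0.0, theta) == 1.0
        assert feedback_factor(theta.IC50, theta) == pytest.approx(0.5005)
        assert feedback_factor(1e9, theta) == pytest.approx(0.001, rel=1e-3)

    def test_feedback_monotone_decreasing(self, theta):
        cu = np.linspace(0, 50, 400)
        f = feedback_factor(cu, theta)
        assert np.all(np.diff(f) <= 0)

    def test_production_half_max(self, theta):
        assert cortisol_production_rate(theta.EC50, theta) == pytest.approx(2700.0)

    def test_production_zero_activity(self, theta):
        p = theta.replace(activity=0.0)
        a = np.linspace(0, 100, 50)
        assert np.all(cortisol_production_rate(a, p) == 0.0)

    def test_production_inverts_to_2200(self, theta):
        # independent oracle: root-solve the Hill curve for 2200 nmol/h
        a_star = brentq(lambda a: cortisol_production_rate(a, theta) - 2200.0,
                        0.1, theta.EC50)
        assert a_star == pytest.approx(5.84, abs=0.01)
        assert cortisol_production_rate(5.84, theta) == pytest.approx(2200.0, rel=2e-3)

    def test_production_monotone_increasing(self, theta):
        a = np.linspace(0, 60, 400)
        v = cortisol_production_rate(a, theta)
        assert np.all(np.diff(v) >= 0)

    def test_negative_inputs_rejected(self, theta):
        with pytest.raises(ValueError):
            feedback_factor(-0.1, theta)
        with pytest.raises(ValueError):
            cortisol_production_rate(-1.0, theta)


class TestBinding:
    def test_zero(self, theta):
        assert bound_from_unbound(0.0, theta) == 0.0
        assert unbound_from_total(0.0, theta) == 0.0

    def test_ic50_maps_to_160_total(self, theta):
        assert bound_from_unbound(4.60, theta) == pytest.approx(160.0, abs=0.5)
        assert unbound_from_total(160.0, theta) == pytest.approx(4.60, abs=0.01)

    def test_saturation_asymptote(self, theta):
        cu = 1e5  # far above Kd
        expected = (1 + theta.NS) * cu + theta.Bmax
        assert bound_from_unbound(cu, theta) == pytest.approx(expected, rel=1e-4)

    def test_strictly_increasing(self, theta):
        cu = np.logspace(-6, 4, 300)
        ct = bound_from_unbound(cu, theta)
        assert np.all(np.diff(ct) > 0)

    @settings(derandomize=True, max_examples=200)
    @given(ct=st.floats(min_value=1e-6, max_value=1e4))
    def test_round_trip(self, ct):
        theta = StructuralParams()
        cu = unbound_from_total(ct, theta)
        back = bound_from_unbound(cu, theta)
        assert abs(back - ct) <= 1e-8 * max(ct, 1.0)

    def test_negative_rejected(self, theta):
        with pytest.raises(ValueError):
            unbound_from_total(-1.0, theta)


class TestAbsorption:
    def test_mtt_reference_and_extremes(self, theta):
        assert mtt_for_dose(5.0, theta) == pytest.approx(0.868)
        assert round(mtt_for_dose(0.5, theta), 2) == 0.57
        assert round(mtt_for_dose(20.0, theta), 2) == 1.11

    def test_mtt_rejects_nonpositive_dose(self, theta):
        with pytest.raises(ValueError):
            mtt_for_dose(0.0, theta)

    def test_ktr_formula(self):
        # Ktr = (Ntr+1)/MTT at the reference dose
        ktr = (2.12 + 1.0) / 0.868
        assert ktr == pytest.approx(3.594, abs=0.002)

    def test_mass_conservation(self, theta):
        dose_nmol = 5.0 * HC_NMOL_PER_MG
        mtt, ntr, f = 0.868, 2.12, 0.344
        total, _ = quad(transit_input_rate, 0, 30 * mtt,
                        args=(dose_nmol, mtt, ntr, f), limit=200)
        assert total == pytest.approx(f * dose_nmol, rel=1e-3)

    def test_ntr_zero_is_first_order(self):
        t = np.linspace(0.0, 5.0, 50)
        ktr = 1.0 / 0.8
        expected = 0.5 * 100.0 * ktr * np.exp(-ktr * t)
        got = transit_input_rate(t, 100.0, 0.8, 0.0, 0.5)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_matches_discrete_transit_chain(self):
        # independent oracle at integer Ntr: explicit transit-compartment ODE
        ntr, mtt, f, dose = 2, 0.9, 0.4, 1000.0
        ktr = (ntr + 1) / mtt

        def chain_rhs(t, y):
            dy = np.empty(ntr + 1)
            dy[0] = -ktr * y[0]
            for i in range(1, ntr + 1):
                dy[i] = ktr * (y[i - 1] - y[i])
            return dy

        y0 = np.zeros(ntr + 1)
        y0[0] = f * dose
        t = np.linspace(1e-3, 6.0, 120)
        sol = solve_ivp(chain_rhs, (0, 6.0), y0, t_eval=t, rtol=1e-10, atol=1e-12)
        chain_input = ktr * sol.y[ntr]
        analytic = transit_input_rate(t, dose, mtt, ntr, f)
        ref = np.max(chain_input)
        np.testing.assert_allclose(analytic, chain_input, atol=1e-3 * ref)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            transit_input_rate(1.0, 100.0, 0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            transit_input_rate(1.0, 100.0, 1.0, -1.0, 0.5)


class TestCovariates:
    def test_reference_subject_unchanged(self, theta):
        p = apply_covariates(theta, 70.0)
        assert p.SA1 == pytest.approx(1300.0)
        assert p.CL == pytest.approx(106.0)
        assert p.Vc == pytest.approx(2.15)

    def test_90kg_surge_amplitude(self, theta):
        p = apply_covariates(theta, 90.0)
        assert abs(round(p.SA1) - 6708) <= 1

    def test_allometric_clearance(self, theta):
        p = apply_covariates(theta, 140.0)
        assert p.CL == pytest.approx(106.0 * 2 ** 0.75, rel=1e-9)
        assert p.Vc == pytest.approx(2.15 * 2.0, rel=1e-9)

    def test_dose_specific_mtt(self, theta):
        p = apply_covariates(theta, 70.0, dose_mg=20.0)
        assert p.MTT_ref == pytest.approx(mtt_for_dose(20.0, theta))

    def test_nonpositive_bw_rejected(self, theta):
        with pytest.raises(ValueError):
            apply_covariates(theta, 0.0)


class TestParams:
    def test_defaults_validate(self):
        StructuralParams()

    @pytest.mark.parametrize("kw", [{"SW1": -1.0}, {"F": 1.5}, {"n_surge": 5},
                                    {"Ntr": -0.1}, {"Pt1": 25.0}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            StructuralParams(**kw)

    def test_unbound_elimination_rate(self, theta):
        assert theta.CL / theta.Vc == pytest.approx(49.3, abs=0.1)
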