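import numpy as np
import pytest
from scipy.integrate import solve_ivp

from telprop.inversion import default_contour_b, invert_2d, protein_marginal
from telprop.model_b import (NearPoleError, autoreg_gf_b, char_exact_b,
                             char_expansion_u, coeffs_from_ics_b, eval_gf_b,
                             gf_total_b, inverse_u0, inverse_u0_exact,
                             leading_closed_form_b)
from telprop.params import (ChiSpec, InvalidParameterError, ModelBParams,
                            RegulationB)
from telprop.closed_forms import binomial_decay


def flow_characteristic(u0, v0, s, gamma, mu):
    def rhs(ss, y):
        u, v = y[0] + 1j * y[1], y[2] + 1j * y[3]
        du = gamma * (u - mu * v * (u + 1))
        return [du.real, du.imag, v.real, v.imag]
    sol = solve_ivp(rhs, (0, s), [u0.real, u0.imag, v0.real, v0.imag],
                    rtol=1e-12, atol=1e-14, method="DOP853")
    return sol.y[0, -1] + 1j * sol.y[1, -1], sol.y[2, -1] + 1j * sol.y[3, -1]


class TestExactCharacteristic:
    def test_identity_at_zero_time(self):
        u, v = char_exact_b(0.2 - 0.3j, -0.1 + 0.2j, 0.0, 10.0, 1.0)
        assert u == pytest.approx(0.2 - 0.3j)
        assert v == pytest.approx(-0.1 + 0.2j)

    def test_decoupled_exponential_when_v0_zero(self):
        u, v = char_exact_b(0.4 + 0.1j, 0.0, 1.5, 3.0, 1.0)
        assert u == pytest.approx((0.4 + 0.1j) * np.exp(3.0 * 1.5))
        assert v == 0

    def test_agrees_with_ode_integration(self, rng):
        for _ in range(5):
            u0 = complex(rng.uniform(-.5, .5), rng.uniform(-.5, .5))
            v0 = complex(rng.uniform(-.4, .4), rng.uniform(-.4, .4))
            s = rng.uniform(0.1, 2.0)
            ue, ve = char_exact_b(u0, v0, s, 7.3, 0.8)
            un, vn = flow_characteristic(u0, v0, s, 7.3, 0.8)
            assert abs(ue - un) / max(1, abs(un)) < 1e-8
            assert abs(ve - vn) < 1e-10

    def test_round_trip_with_exact_inverse(self):
        u0, v0 = 0.2 - 0.3j, -0.1 + 0.2j
        u, v = char_exact_b(u0, v0, 1.2, 10.0, 1.0)
        assert abs(inverse_u0_exact(u, v, 1.2, 10.0, 1.0) - u0) < 1e-10


class TestFastExpansion:
    def test_initial_values(self):
        uh = char_expansion_u(0.3 - 0.1j, 0.2j, 0.0, 0.05, 1.0, order=1)
        assert uh[0] == pytest.approx(0.3 - 0.1j)
        assert uh[1] == pytest.approx(0.0)

    def test_critical_manifold_is_stationary_at_leading_order(self):
        v0 = -0.2 + 0.1j
        u0 = 1.0 * v0 / (1 - 1.0 * v0)
        for sig in (0.5, 2.0, 5.0):
            uh = char_expansion_u(u0, v0, sig, 0.05, 1.0, order=0)
            assert abs(uh[0] - u0) < 1e-13

    def test_two_term_sum_converges_at_second_order(self, rng):
        # against the exact flow at fixed fast time
        sig = 1.5
        errs = []
        for eps in (0.1, 0.05, 0.025):
            per = []
            for _ in range(6):
                u0 = complex(rng.uniform(-.4, .4), rng.uniform(-.4, .4))
                v0 = complex(rng.uniform(-.3, .3), rng.uniform(-.3, .3))
                uh = char_expansion_u(u0, v0, sig, eps, 1.0, order=1)
                ue, _ = flow_characteristic(u0, v0, eps * sig, 1 / eps, 1.0)
                per.append(abs(uh[0] + eps * uh[1] - ue))
            errs.append(np.median(per))
        slope = np.polyfit(np.log([0.1, 0.05, 0.025]), np.log(errs), 1)[0]
        assert slope > 1.6

    def test_near_pole_rejected(self):
        with pytest.raises(NearPoleError):
            char_expansion_u(0.1, 1.0 + 0j, 1.0, 0.05, 1.0)


class TestInverseTransform:
    def test_identity_at_zero_time(self):
        u, v = 0.3 - 0.2j, -0.4 + 0.1j
        assert abs(inverse_u0(u, v, 0.0, 0.05, 1.0, order=1) - u) < 1e-13

    def test_pure_contraction_when_v_zero(self):
        u = 0.3 - 0.2j
        t, eps = 0.2, 0.05
        got = inverse_u0(u, 0.0, t, eps, 1.0, order=1)
        assert got == pytest.approx(u * np.exp(-t / eps))

    def test_round_trip_residual_second_order(self, rng):
        sig = 2.0
        meds = []
        for eps in (0.1, 0.05, 0.025):
            res = []
            t = sig * eps
            for _ in range(12):
                u = complex(rng.uniform(-.5, .5), rng.uniform(-.5, .5))
                v = complex(rng.uniform(-.4, .4), rng.uniform(-.4, .4))
                u0 = inverse_u0(u, v, t, eps, 1.0, order=1)
                uh = char_expansion_u(u0, v * np.exp(-t), sig, eps, 1.0, 1)
                res.append(abs(uh[0] + eps * uh[1] - u))
            meds.append(np.median(res))
        slope = np.polyfit(np.log([0.1, 0.05, 0.025]), np.log(meds), 1)[0]
        assert slope > 1.6


class TestInitialCoefficients:
    def test_trivial_state(self, telegraph_b):
        co = coeffs_from_ics_b(1.0, telegraph_b, 0, 0, 0j, 0j)
        assert co.f0 == 1 and co.f1 == 0 and co.f2 == 0
        assert co.g1 == pytest.approx(-telegraph_b.kappa_0)
        assert co.g2 == 0

    def test_on_component_initial_value(self, telegraph_b, rng):
        chi0, m0, n0 = 0.35, 2, 3
        u0 = 0.2 - 0.1j
        v0 = -0.15 + 0.25j
        co = coeffs_from_ics_b(chi0, telegraph_b, m0, n0, u0, v0)
        Pi = (1 + u0) ** m0 * (1 + v0) ** n0
        F1_0 = (co.f0 * telegraph_b.kappa_0 + co.g1) / telegraph_b.kappa_1
        assert F1_0 == pytest.approx((1 - chi0) * Pi)
        assert co.f1 == 0

    def test_vanishing_on_switch_rate_rejected(self):
        p = ModelBParams(1.0, 0.0, 2.0, 1.0, 0.1)
        with pytest.raises(InvalidParameterError):
            coeffs_from_ics_b(0.5, p, 0, 0, 0j, 0j)


class TestAssembledGF:
    def test_order_zero_equals_closed_form(self, telegraph_b, rng):
        chi = ChiSpec(mode="fixed", value=0.4)
        worst = 0.0
        for _ in range(100):
            w = np.exp(2j * np.pi * rng.random())
            z = 0.9 * np.exp(2j * np.pi * rng.random())
            t = rng.uniform(0, 2)
            ev = eval_gf_b(telegraph_b, chi, 2, 3, w, z, t, eps_order=0)
            F0c, F1c = leading_closed_form_b(telegraph_b, 0.4, 2, 3, w, z, t)
            worst = max(worst, abs(ev.total_F0 - F0c), abs(ev.total_F1 - F1c))
        assert worst < 1e-12

    def test_initial_condition_split(self, telegraph_b):
        chi = ChiSpec(mode="fixed", value=0.4)
        w, z = 0.3 + 0.4j, -0.2 + 0.6j
        ev = eval_gf_b(telegraph_b, chi, 2, 3, w, z, 0.0, eps_order=2)
        assert abs(ev.total_F0 - 0.4 * w ** 2 * z ** 3) < 1e-13
        assert abs(ev.total_F1 - 0.6 * w ** 2 * z ** 3) < 1e-13

    def test_leading_normalisation_at_unit_arguments(self, telegraph_b):
        chi = ChiSpec(mode="fixed", value=0.3)
        ev = eval_gf_b(telegraph_b, chi, 2, 3, 1.0, 1.0, 0.7, eps_order=0)
        assert abs(ev.total_F0 + ev.total_F1 - 1) < 1e-14

    def test_pure_death_marginal_with_no_mrna(self, telegraph_b):
        chi = ChiSpec(mode="markov")
        t, n0 = 0.7, 6
        gf = gf_total_b(telegraph_b, chi, 0, n0, t, eps_order=0)
        tab = protein_marginal(lambda w, z: gf(w, z), 10,
                               default_contour_b(telegraph_b.mu), t=t)
        assert np.max(np.abs(tab.P - binomial_decay(n0, t, 10))) < 1e-12

    def test_propagator_accuracy_improves_with_eps(self, chi_markov_spec):
        from telprop.fsp import FSPConfig, fsp_propagate
        from telprop.params import chi_markov
        m0, n0, sig = 2, 3, 2.0
        cfg = FSPConfig(m_trunc=16, n_trunc=31)
        errs = []
        for eps in (0.1, 0.05):
            t = sig * eps
            p = ModelBParams(1.0, 1.0, 2.0, 1.0, eps)
            fsp = fsp_propagate("B", p, (m0, n0), chi_markov(p, m0, n0), t, cfg)
            gf = gf_total_b(p, chi_markov_spec, m0, n0, t, eps_order=2)
            tab = invert_2d(gf, 15, 30, default_contour_b(1.0), t=t)
            errs.append(np.max(np.abs(tab.P - fsp.P[:16, :31])))
        assert errs[1] < 0.6 * errs[0]
        assert errs[1] < 2.5e-3

    def test_unsupported_order(self, telegraph_b, chi_markov_spec):
        with pytest.raises(InvalidParameterError):
            eval_gf_b(telegraph_b, chi_markov_spec, 0, 0, 1.0, 1.0, 0.1,
                      eps_order=3)

    def test_long_time_warns_outside_validity(self, telegraph_b,
                                              chi_markov_spec):
        with pytest.warns(RuntimeWarning):
            eval_gf_b(telegraph_b, chi_markov_spec, 1, 1, 0.5, -0.5, 5.0,
                      eps_order=2)


@pytest.fixture(params=[RegulationB.MRNA_ACT, RegulationB.MRNA_REP,
                        RegulationB.PROT_ACT, RegulationB.PROT_REP])
def regulated_b(request):
    return ModelBParams(1.0, 1.0, 2.0, 1.0, 0.05, request.param,
                        delta=0.05, reg_coeff=1.0)


class TestAutoregulation:
    def test_zero_feedback_reduces_to_unregulated(self, telegraph_b,
                                                  chi_markov_spec):
        w, z, t = 0.4 + 0.3j, 0.2 - 0.6j, 0.1
        ev0 = eval_gf_b(telegraph_b, chi_markov_spec, 2, 3, w, z, t,
                        eps_order=1)
        ev1 = autoreg_gf_b(telegraph_b, chi_markov_spec, 2, 3, w, z, t,
                           delta_order=1, eps_order=1)
        assert ev1.total_F0 == pytest.approx(ev0.total_F0, rel=1e-13)
        assert ev1.total_F1 == pytest.approx(ev0.total_F1, rel=1e-13)

    def test_short_time_split_uses_chi_series(self, regulated_b,
                                              chi_markov_spec):
        from telprop.params import chi_series
        w, z = 0.7 + 0.2j, 0.5 - 0.4j
        m0, n0 = 3, 2
        chis = chi_series(chi_markov_spec, regulated_b, m0, n0, 1)
        ev = autoreg_gf_b(regulated_b, chi_markov_spec, m0, n0, w, z, 1e-12,
                          delta_order=1, eps_order=1)
        Pi = w ** m0 * z ** n0
        chi_d = chis[0] + regulated_b.delta * chis[1]
        assert abs(ev.total_F0 - chi_d * Pi) < 1e-9
        assert abs(ev.total_F1 - (1 - chi_d) * Pi) < 1e-9

    def test_delta_response_matches_fsp(self, regulated_b, chi_markov_spec):
        """First-order feedback response against the full master equation.

        Run at small eps so the feedback term's own eps truncation does not
        mask the delta response being checked.
        """
        from telprop.fsp import FSPConfig, fsp_propagate
        from telprop.params import chi_markov
        m0, n0 = 2, 3
        eps, t = 0.02, 0.04
        cfg = FSPConfig(m_trunc=14, n_trunc=27)
        base = ModelBParams(1.0, 1.0, 2.0, 1.0, eps)
        reg = ModelBParams(1.0, 1.0, 2.0, 1.0, eps, regulated_b.regulation,
                           delta=regulated_b.delta, reg_coeff=1.0)

        def table(p, d_order):
            gf = gf_total_b(p, chi_markov_spec, m0, n0, t, eps_order=1,
                            delta_order=d_order)
            ana = invert_2d(gf, 13, 26, default_contour_b(1.0), t=t).P
            fsp = fsp_propagate("B", p, (m0, n0), chi_markov(p, m0, n0), t,
                                cfg).P[:14, :27]
            return ana, fsp

        a0, f0 = table(base, 0)
        a1, f1 = table(reg, 1)
        # the delta-response of the propagator, analytic vs exact
        resp_err = np.max(np.abs((a1 - a0) - (f1 - f0)))
        resp_size = np.max(np.abs(f1 - f0))
        assert resp_err < 0.15 * resp_size

    def test_unsupported_orders(self, regulated_b, chi_markov_spec):
        with pytest.raises(InvalidParameterError):
            autoreg_gf_b(regulated_b, chi_markov_spec, 0, 0, 1.0, 1.0, 0.1,
                         delta_order=2, eps_order=1)
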