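import numpy as np
import pytest
from scipy.integrate import solve_ivp

from telprop.inversion import invert_1d
from telprop.model_a import (eval_gf_a, eval_leading_a, eval_leading_a_batch,
                             first_order_a, gf_total_a, leading_constants_a)
from telprop.params import (ChiSpec, InvalidParameterError, ModelAParams,
                            Regulation, chi_markov)


def brute_force_leading(params, chi0, n0, z, t):
    """Direct numerical integration of the characteristic ODE pair."""
    v0 = (z - 1) * np.exp(-t)

    def rhs(s, y):
        F0, F1 = y[0] + 1j * y[1], y[2] + 1j * y[3]
        d0 = -params.kappa_f * F0 + params.kappa_b * F1
        d1 = (params.kappa_f * F0 - params.kappa_b * F1
              + params.lam * v0 * np.exp(s) * F1)
        return [d0.real, d0.imag, d1.real, d1.imag]

    Pi = (1 + v0) ** n0
    y0 = [(chi0 * Pi).real, (chi0 * Pi).imag,
          ((1 - chi0) * Pi).real, ((1 - chi0) * Pi).imag]
    sol = solve_ivp(rhs, (0, t), y0, rtol=1e-12, atol=1e-14, method="DOP853")
    y = sol.y[:, -1]
    return y[0] + 1j * y[1], y[2] + 1j * y[3]


class TestLeadingOrder:
    @pytest.mark.parametrize("chi0,n0,t", [(0.3, 5, 1.7), (1.0, 0, 0.6),
                                           (0.0, 20, 2.5)])
    def test_normalised_at_z_equal_one(self, telegraph_a, chi0, n0, t):
        F0, F1 = eval_leading_a(telegraph_a, chi0, n0, 1.0, t)
        assert abs(F0 + F1 - 1) < 1e-12

    def test_initial_condition_split(self, telegraph_a):
        z = 0.4 + 0.7j
        F0, F1 = eval_leading_a(telegraph_a, 0.3, 5, z, 0.0)
        assert abs(F0 - 0.3 * z ** 5) < 1e-13
        assert abs(F0 + F1 - z ** 5) < 1e-13

    def test_immigration_death_limit(self):
        # promoter locked on: classical immigration-death generating function
        p = ModelAParams(1.0, 0.0, 2.0)
        z, t = -0.3 + 0.8j, 1.3
        F0, F1 = eval_leading_a(p, 0.0, 0, z, t)
        ref = np.exp(2.0 * (z - 1) * (1 - np.exp(-t)))
        assert abs(F0) < 1e-14
        assert abs(F1 - ref) < 1e-10
        # with surviving initial molecules the binomial factor appears
        F0, F1 = eval_leading_a(p, 0.0, 4, z, t)
        ref4 = (1 + (z - 1) * np.exp(-t)) ** 4 * ref
        assert abs(F1 - ref4) < 1e-10

    @pytest.mark.parametrize("params,chi0,n0,z,t", [
        (ModelAParams(0.5, 1.0, 2.0), 0.3, 5, 0.4 + 0.7j, 1.7),
        (ModelAParams(2.0, 0.3, 5.0), 0.2, 20, 0.8 - 0.5j, 2.5),
        (ModelAParams(1.0, 1.0, 10.0), 0.5, 0, -0.9 + 0.1j, 0.3),
    ])
    def test_matches_brute_force_integration(self, params, chi0, n0, z, t):
        # tolerance covers the ODE oracle and the 1e-8 relative parameter
        # nudge applied when kappa_f + kappa_b is an integer
        got = eval_leading_a(params, chi0, n0, z, t)
        ref = brute_force_leading(params, chi0, n0, z, t)
        assert abs(got[0] - ref[0]) < 5e-9
        assert abs(got[1] - ref[1]) < 5e-9

    def test_batch_path_equals_scalar_path(self, telegraph_a, rng):
        zs = np.exp(2j * np.pi * rng.random(12))
        F0b, F1b = eval_leading_a_batch(telegraph_a, 0.4, 6, zs, 0.9)
        for z, f0, f1 in zip(zs, F0b, F1b):
            s0, s1 = eval_leading_a(telegraph_a, 0.4, 6, z, 0.9)
            assert abs(f0 - s0) < 1e-13 and abs(f1 - s1) < 1e-13

    def test_continuity_along_unit_circle(self, telegraph_a):
        # no branch cuts: values along a fine contour vary smoothly
        zs = np.exp(2j * np.pi * np.linspace(0, 1, 257))
        F0, F1 = eval_leading_a_batch(telegraph_a, 0.4, 3, zs, 1.1)
        total = F0 + F1
        jumps = np.abs(np.diff(total))
        assert np.max(jumps) < 10 * np.median(jumps) + 1e-12

    def test_near_integer_switching_sum_is_nudged_not_fatal(self):
        p = ModelAParams(0.5, 0.5, 2.0)   # kappa_f + kappa_b = 1 exactly
        F0, F1 = eval_leading_a(p, 0.5, 2, 0.3 + 0.1j, 0.8)
        ref = brute_force_leading(p, 0.5, 2, 0.3 + 0.1j, 0.8)
        assert abs(F0 - ref[0]) < 1e-6
        assert abs(F1 - ref[1]) < 1e-6


class TestLeadingConstants:
    def test_reconstruction_satisfies_initial_conditions(self, rng):
        p = ModelAParams(0.8, 1.3, 2.0)
        for _ in range(5):
            v0 = complex(rng.uniform(-1, 1), rng.uniform(-1, 1)) / 2
            F0, F1 = eval_leading_a(p, 0.35, 4, 1 + v0, 0.0)
            Pi = (1 + v0) ** 4
            assert abs(F0 - 0.35 * Pi) < 1e-12
            assert abs(F1 - 0.65 * Pi) < 1e-12

    def test_zero_base_point_limit(self, telegraph_a):
        consts = leading_constants_a(telegraph_a, 0.3, 5, 0.0)
        # on the trivial characteristic the reconstruction at s=0 is chi0
        assert consts.c1 + consts.c2 == pytest.approx(0.3)

    def test_on_off_constant_ratio(self, rng):
        # hat_c1/c1 = kappa_f/kappa_b for generic parameters
        p = ModelAParams(0.8, 1.3, 2.0)
        v0 = 0.21 - 0.33j
        consts = leading_constants_a(p, chi_markov(p, None, 4), 4, v0)
        assert consts.hat_c1 / consts.c1 == pytest.approx(0.8 / 1.3, rel=1e-10)


@pytest.fixture(params=["autoactivation", "autorepression"])
def regulated_a(request):
    kw = {"alpha": 1.0} if request.param == "autoactivation" else {"rho": 1.0}
    return ModelAParams(1.0, 1.0, 2.0, Regulation(request.param),
                        delta=0.05, **kw)


class TestFirstOrder:
    def test_quadrature_and_ode_routes_agree(self, regulated_a, rng,
                                             chi_markov_spec):
        worst = 0.0
        for _ in range(10):
            z = np.exp(2j * np.pi * rng.random())
            t = rng.uniform(0.05, 3.0)
            q = first_order_a(regulated_a, chi_markov_spec, 4, z, t,
                              method="quadrature")
            o = first_order_a(regulated_a, chi_markov_spec, 4, z, t,
                              method="ode")
            scale = max(1e-12, abs(o[0]), abs(o[1]))
            worst = max(worst, abs(q[0] - o[0]) / scale,
                        abs(q[1] - o[1]) / scale)
        assert worst < 1e-7

    def test_short_time_limit_is_chi1_split(self, regulated_a,
                                            chi_markov_spec):
        from telprop.params import chi_series
        z = 1.3 + 0.1j
        chi1 = chi_series(chi_markov_spec, regulated_a, None, 4, 1)[1]
        F0_1, F1_1 = first_order_a(regulated_a, chi_markov_spec, 4, z, 1e-10,
                                   method="ode")
        assert abs(F0_1 - chi1 * z ** 4) < 1e-6
        assert abs(F1_1 + chi1 * z ** 4) < 1e-6

    def test_correction_sums_to_zero_at_z_equal_one(self, regulated_a,
                                                    chi_markov_spec):
        F0_1, F1_1 = first_order_a(regulated_a, chi_markov_spec, 4, 1.0, 1.5)
        assert abs(F0_1 + F1_1) < 1e-10

    def test_unregulated_model_rejected(self, telegraph_a, chi_markov_spec):
        with pytest.raises(InvalidParameterError):
            first_order_a(telegraph_a, chi_markov_spec, 4, 1.0, 1.0)


class TestAssembled:
    def test_order_zero_equals_leading(self, telegraph_a, chi_markov_spec):
        z, t = 0.2 + 0.5j, 1.2
        ev = eval_gf_a(telegraph_a, chi_markov_spec, 3, z, t, order=0)
        chi0 = chi_markov(telegraph_a, None, 3)
        F0, F1 = eval_leading_a(telegraph_a, chi0, 3, z, t)
        assert ev.total_F0 == pytest.approx(F0)
        assert ev.total_F1 == pytest.approx(F1)

    def test_order_one_normalisation(self, regulated_a, chi_markov_spec):
        ev = eval_gf_a(regulated_a, chi_markov_spec, 4, 1.0, 1.5, order=1)
        assert abs(ev.total_F0 + ev.total_F1 - 1) < 1e-10

    def test_unsupported_order(self, regulated_a, chi_markov_spec):
        with pytest.raises(InvalidParameterError):
            eval_gf_a(regulated_a, chi_markov_spec, 4, 1.0, 1.0, order=2)

    def test_radius_invariance_of_inverted_probabilities(self, telegraph_a,
                                                         chi_markov_spec):
        # the generating function is entire, so the contour radius is free
        from telprop.inversion import ContourSpec
        gf = gf_total_a(telegraph_a, chi_markov_spec, 5)
        tabs = [invert_1d(lambda z: gf(z, 1.0), 25,
                          ContourSpec(radius_z=r)) for r in (0.8, 1.0, 1.2)]
        for tab in tabs[1:]:
            assert np.max(np.abs(tab.P - tabs[0].P)) < 1e-9
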