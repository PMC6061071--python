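"""Generating functions of the two-stage (mRNA + protein) telegraph model.

Along the characteristics of the transport operator, the shifted variables
``u = w - 1`` and ``v = z - 1`` obey ``eps u' = u - mu v (u + 1)``,
``v' = v`` — a slow-fast system whose critical manifold is
``u = mu v / (1 - mu v)``.  On the fast time scale ``sigma = s / eps`` the
characteristic and the generating-function pair are expanded in powers of
eps; the expansion coefficients are exponential polynomials in sigma, and
the free constants are fixed by the initial conditions at sigma = 0.  The
solution of the PDE is recovered by flowing the evaluation point backward:
``v0 = v e^{-t}`` exactly, and ``u0`` through the eps-series inverse of the
fast characteristic.

The fast-time expansion is a boundary-layer (inner) expansion: its secular
terms grow *exponentially* in sigma on the inversion contour (where
``Re(1 - mu v0) >= 1``), so composed values are accurate for sampling
intervals up to a few mRNA lifetimes (sigma = t/eps of order one) and
degrade beyond; ``eval_gf_b`` warns when it is asked to leave that regime.
The exact characteristic (incomplete-Gamma closed form) is provided at
arbitrary precision as a validation oracle.

Weak promoter feedback through mRNA or protein copy number enters as a
regular perturbation in delta on top of the eps-hierarchy; the double-series
coefficients are assembled exactly with the ExpPoly algebra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exppoly import ExpPoly
from .params import (ChiSpec, InvalidParameterError, ModelBParams,
                     RegulationB, chi_series)

__all__ = ["CharacteristicPointB", "ModelBCoeffs", "GFEvaluationB",
           "char_exact_b", "inverse_u0_exact", "char_expansion_u",
           "inverse_u0", "coeffs_from_ics_b", "leading_closed_form_b",
           "eval_gf_b", "autoreg_gf_b", "gf_total_b"]

logger = logging.getLogger(__name__)

_POLE_TOL = 1e-8


class NearPoleError(ArithmeticError):
    """Contour point too close to the generating function's pole at
    z = 1 + 1/mu; reduce the contour radius."""


def _crit(mu: float, v: complex) -> complex:
    """Critical-manifold height mu*v/(1 - mu*v)."""
    d = 1.0 - mu * v
    if abs(d) < _POLE_TOL:
        raise NearPoleError(
            f"|1 - mu*v| = {abs(d):.2e}: contour point too close to the pole "
            "at z = 1 + 1/mu; reduce the z-contour radius")
    return mu * v / d


# --------------------------------------------------------------------------
# exact characteristics (arbitrary-precision oracle)
# --------------------------------------------------------------------------

def char_exact_b(u0: complex, v0: complex, s: float, gamma: float,
                 mu: float) -> tuple[complex, complex]:
    """Exact characteristic flow (u(s), v(s)) via the incomplete Gamma
    closed form; arbitrary-precision, oracle use only."""
    import mpmath
    if s < 0:
        raise InvalidParameterError("s must be >= 0")
    if v0 == 0:
        return complex(u0) * np.exp(gamma * s), 0.0j
    try:
        with mpmath.workdps(40):
            g = mpmath.mpf(gamma)
            x0 = -g * mu * mpmath.mpc(v0)
            x1 = x0 * mpmath.e ** mpmath.mpf(s)
            pref = mpmath.e ** (g * (s - mu * mpmath.mpc(v0) * mpmath.e ** s))
            inc = (mpmath.gammainc(1 - g, x0) - mpmath.gammainc(1 - g, x1))
            u = pref * (mpmath.mpc(u0) * mpmath.e ** (g * mu * mpmath.mpc(v0))
                        + x0 ** g * inc)
            v = mpmath.mpc(v0) * mpmath.e ** mpmath.mpf(s)
        return complex(u), complex(v)
    except (mpmath.libmp.NoConvergence, ValueError, ZeroDivisionError) as exc:
        raise ArithmeticError(f"exact-characteristic oracle unavailable: {exc}")


def inverse_u0_exact(u: complex, v: complex, t: float, gamma: float,
                     mu: float) -> complex:
    """Exact base point u0(t, u, v) of the characteristic through (u, v)."""
    import mpmath
    if v == 0:
        return complex(u) * np.exp(-gamma * t)
    with mpmath.workdps(40):
        g = mpmath.mpf(gamma)
        vv = mpmath.mpc(v)
        x1 = -g * mu * vv
        x0 = x1 * mpmath.e ** (-mpmath.mpf(t))
        pref = mpmath.e ** (-g * (t + mu * vv * mpmath.e ** (-t)))
        inc = (mpmath.gammainc(1 - g, x0) - mpmath.gammainc(1 - g, x1))
        u0 = pref * (mpmath.mpc(u) * mpmath.e ** (g * mu * vv) - x1 ** g * inc)
    return complex(u0)


# --------------------------------------------------------------------------
# fast-time expansion of the characteristic
# --------------------------------------------------------------------------

def char_expansion_u(u0: complex, v0: complex, sigma: float, eps: float,
                     mu: float, order: int = 1):
    """Fast-time expansion terms (u_hat_0(sigma), [u_hat_1(sigma)]) of the
    characteristic u-component at frozen base point."""
    if order not in (0, 1):
        raise InvalidParameterError("u-expansion implemented to order 1")
    c0 = _crit(mu, v0)
    q = 1.0 - mu * v0
    E = np.exp(q * sigma)
    u_hat_0 = c0 + (u0 - c0) * E
    if order == 0:
        return (u_hat_0,)
    W = mu * v0
    u_hat_1 = (W / q ** 2) * ((1.0 - E) / q + sigma) \
        - (u0 - c0) * W * sigma ** 2 / 2.0 * E
    return (u_hat_0, u_hat_1)


def inverse_u0(u: complex, v: complex, t: float, eps: float, mu: float,
               order: int = 1) -> complex:
    """Series inverse of the fast characteristic: base point u0(sigma, u, v)
    with sigma = t/eps, to the requested order in eps."""
    if order not in (0, 1):
        raise InvalidParameterError("inverse transform implemented to order 1")
    sigma = t / eps
    c0v = _crit(mu, v)
    q = 1.0 - mu * v
    Em = np.exp(-q * sigma)          # e^{(mu v - 1) sigma}, decaying
    u0 = c0v + Em * (u - c0v)
    if order >= 1:
        corr = (Em - 1.0) / q ** 3 + sigma / q ** 2 \
            + sigma ** 2 / 2.0 * Em * (u - c0v)
        u0 = u0 - eps * mu * v * corr
    return u0


# --------------------------------------------------------------------------
# fast-time hierarchy of the generating functions
# --------------------------------------------------------------------------

@dataclass
class ModelBCoeffs:
    """Free constants of the fast-time solution, fixed by the split initial
    condition at sigma = 0."""
    f0: complex
    f1: complex
    f2: complex
    g1: complex
    g2: complex


@dataclass
class CharacteristicPointB:
    sigma: float
    u: complex
    v: complex
    u0: complex
    v0: complex
    u_hat_terms: tuple[complex, ...]


@dataclass
class GFEvaluationB:
    eps_order: int
    delta_order: int
    F0_terms: dict
    F1_terms: dict
    total_F0: complex
    total_F1: complex


def coeffs_from_ics_b(chi0: float, params: ModelBParams, m0: int, n0: int,
                      u0: complex, v0: complex) -> ModelBCoeffs:
    """Constants (f0, f1, f2, g1, g2) from the off/on-split initial data on
    the characteristic with base point (u0, v0)."""
    if params.kappa_1 <= 0:
        raise InvalidParameterError(
            "kappa_1 must be positive: it divides the on-component of the "
            "fast-time solution")
    k0, k1, lam, mu = params.kappa_0, params.kappa_1, params.lam, params.mu
    Pi = (1 + u0) ** m0 * (1 + v0) ** n0
    c0 = _crit(mu, v0)
    q = 1.0 - mu * v0
    f0 = chi0 * Pi
    f1 = 0.0j
    f2 = -(1 - chi0) * Pi * lam * k1 / q ** 2 * (u0 - c0)
    g1 = (k1 * (1 - chi0) - k0 * chi0) * Pi
    g2 = -(1 - chi0) * Pi * lam * k1 / q * (u0 - c0)
    return ModelBCoeffs(f0=f0, f1=f1, f2=f2, g1=g1, g2=g2)


def _hierarchy_terms(co: ModelBCoeffs, params: ModelBParams, u0: complex,
                     v0: complex, sigma: float, eps_order: int):
    """Fast-time coefficients F^(j)_n(sigma) for n <= eps_order."""
    k0, k1, lam, mu = params.kappa_0, params.kappa_1, params.lam, params.mu
    c0 = _crit(mu, v0)
    q = 1.0 - mu * v0
    E = np.exp(q * sigma)
    F0 = {0: co.f0}
    F1 = {0: (co.f0 * k0 + co.g1) / k1}
    if eps_order >= 1:
        F0[1] = co.f1 + co.g1 * sigma
        F1[1] = (co.f1 * k0 + co.g2) / k1 \
            + lam * (co.f0 * k0 + co.g1) / (k1 * q) \
            * (E * (u0 - c0) + sigma * mu * v0) \
            - sigma * co.g1
    if eps_order >= 2:
        F0[2] = co.f2 + co.g2 * sigma \
            + lam * (co.f0 * k0 + co.g1) / q \
            * (E / q * (u0 - c0) + mu * v0 * sigma ** 2 / 2.0) \
            - co.g1 * (k0 + k1) * sigma ** 2 / 2.0
    return F0, F1


def leading_closed_form_b(params: ModelBParams, chi0: float, m0: int, n0: int,
                          w: complex, z: complex, t: float):
    """Hand-coded leading-order generating functions in the original
    variables (w, z, t): protein inherited binomially from the initial
    state, mRNA relaxing on the fast scale toward its quasi-steady value."""
    mu, eps = params.mu, params.eps
    denom = 1.0 + mu * (1.0 - z)
    if abs(denom) < _POLE_TOL:
        raise NearPoleError("z too close to the pole at 1 + 1/mu")
    F0 = chi0 * (1 + (z - 1) * np.exp(-t)) ** n0 \
        * (1.0 / denom + np.exp(-denom * t / eps) * (w - 1.0 / denom)) ** m0
    F1 = ((1 - chi0) / chi0) * F0 if chi0 != 0 else \
        (1 - chi0) * (1 + (z - 1) * np.exp(-t)) ** n0 \
        * (1.0 / denom + np.exp(-denom * t / eps) * (w - 1.0 / denom)) ** m0
    return F0, F1


def _validity_check(params: ModelBParams, v0: complex, t: float):
    sigma = t / params.eps
    growth = sigma * (1.0 - params.mu * v0.real)
    if growth > 40:
        warnings.warn(
            "fast-time expansion evaluated far outside its validity domain "
            f"(growth exponent {growth:.1f}); first- and second-order terms "
            "are exponentially amplified — reduce t or use the FSP engine",
            RuntimeWarning, stacklevel=3)


def eval_gf_b(params: ModelBParams, chi: ChiSpec, m0: int, n0: int,
              w: complex, z: complex, t: float,
              eps_order: int = 2) -> GFEvaluationB:
    """Generating functions (F0, F1) of the unregulated two-stage model at
    (w, z, t), to the requested order in eps.

    eps_order = 0 reproduces the leading closed form identically; orders 1
    and 2 add the fast-time corrections (the on-component is carried one
    order lower than the off-component, matching the depth at which the
    hierarchy closes).
    """
    if eps_order not in (0, 1, 2):
        raise InvalidParameterError("eps expansion implemented to order 2")
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    chi0 = chi_series(chi, params, m0, n0, 0)[0]
    u = complex(w) - 1.0
    v = complex(z) - 1.0
    v0 = v * np.exp(-t)
    sigma = t / params.eps
    u0 = inverse_u0(u, v, t, params.eps, params.mu,
                    order=min(eps_order, 1))
    if eps_order >= 1:
        _validity_check(params, v0, t)
    co = coeffs_from_ics_b(chi0, params, m0, n0, u0, v0)
    F0_terms, F1_terms = _hierarchy_terms(co, params, u0, v0, sigma,
                                          eps_order)
    eps = params.eps
    tot0 = sum(eps ** n * val for n, val in F0_terms.items())
    tot1 = sum(eps ** n * val for n, val in F1_terms.items()
               if n <= min(eps_order, 1))
    return GFEvaluationB(eps_order=eps_order, delta_order=0,
                         F0_terms={(0, n): val for n, val in F0_terms.items()},
                         F1_terms={(0, n): val for n, val in F1_terms.items()},
                         total_F0=tot0, total_F1=tot1)


# --------------------------------------------------------------------------
# weak autoregulation: double series in (delta, eps)
# --------------------------------------------------------------------------

def _delta0_exppolys(params: ModelBParams, chi0: float, m0: int, n0: int,
                     u0: complex, v0: complex):
    """Unregulated hierarchy terms F^(j)_{0,n}, n = 0, 1, as ExpPolys, plus
    the building blocks reused by the feedback source."""
    k0, k1, lam, mu = params.kappa_0, params.kappa_1, params.lam, params.mu
    c0 = _crit(mu, v0)
    q = 1.0 - mu * v0
    Pi = (1 + u0) ** m0 * (1 + v0) ** n0
    g1 = (k1 * (1 - chi0) - k0 * chi0) * Pi
    F0_00 = ExpPoly.const(q, chi0 * Pi)
    F1_00 = ExpPoly.const(q, (1 - chi0) * Pi)
    F0_01 = ExpPoly.sigma(q, 1, g1)
    # I0(sigma) = int_0^sigma u_hat_0 = c0 sigma + (u0-c0)(e^{q sigma}-1)/q
    I0 = (ExpPoly.sigma(q, 1, c0)
          + ExpPoly(q, {1: [(u0 - c0) / q], 0: [-(u0 - c0) / q]}))
    F1_01 = ExpPoly.sigma(q, 1, -g1) + lam * (1 - chi0) * Pi * I0
    return {"F0": {0: F0_00, 1: F0_01}, "F1": {0: F1_00, 1: F1_01},
            "I0": I0, "Pi": Pi, "g1": g1, "c0": c0, "q": q}


def _du0_of_delta0(params, chi0, m0, n0, u0, v0, base):
    """d/du0 of F^(j)_{0,n} at fixed (sigma, v0), as ExpPolys."""
    k0, k1, lam = params.kappa_0, params.kappa_1, params.lam
    q, c0, Pi = base["q"], base["c0"], base["Pi"]
    dPi = m0 * Pi / (1 + u0) if m0 else 0.0
    dg1 = (k1 * (1 - chi0) - k0 * chi0) * dPi
    dI0 = ExpPoly(q, {1: [1.0 / q], 0: [-1.0 / q]})   # d/du0 I0
    out = {
        "F0": {0: ExpPoly.const(q, chi0 * dPi),
               1: ExpPoly.sigma(q, 1, dg1)},
        "F1": {0: ExpPoly.const(q, (1 - chi0) * dPi),
               1: (ExpPoly.sigma(q, 1, -dg1)
                   + lam * (1 - chi0) * (dPi * base["I0"] + Pi * dI0))},
    }
    return out


def _dv0_of_delta0(params, chi0, m0, n0, u0, v0, base):
    """d/dv0 of F^(j)_{0,n} at fixed (sigma, u0), as ExpPolys."""
    k0, k1, lam, mu = params.kappa_0, params.kappa_1, params.lam, params.mu
    q, c0, Pi = base["q"], base["c0"], base["Pi"]
    dPi = n0 * Pi / (1 + v0) if n0 else 0.0
    dg1 = (k1 * (1 - chi0) - k0 * chi0) * dPi
    c0p = mu / q ** 2
    # d/dv0 I0 = c0p sigma + d/dv0[(u0-c0)(e^{q s}-1)/q]
    dI0 = (ExpPoly.sigma(q, 1, c0p)
           + ExpPoly(q, {1: [-c0p / q], 0: [c0p / q]})
           + (u0 - c0) * (ExpPoly(q, {1: [mu / q ** 2, -mu / q]})
                          + ExpPoly(q, {0: [-mu / q ** 2]})))
    out = {
        "F0": {0: ExpPoly.const(q, chi0 * dPi),
               1: ExpPoly.sigma(q, 1, dg1)},
        "F1": {0: ExpPoly.const(q, (1 - chi0) * dPi),
               1: (ExpPoly.sigma(q, 1, -dg1)
                   + lam * (1 - chi0) * (dPi * base["I0"] + Pi * dI0))},
    }
    return out


def _source_terms(params, chi0, m0, n0, u0, v0, base, eps_order):
    """Feedback-source expansion coefficients G_n(sigma), n <= eps_order,
    for the active channel, as ExpPolys.

    Built from the copy-number operators transported to characteristic
    coordinates: w d/dw = (1+u)(du/du0)^{-1} d/du0 and the corresponding
    two-term form for z d/dz.
    """
    mu = params.mu
    q, c0 = base["q"], base["c0"]
    W = mu * v0
    reg = params.regulation
    target = "F0" if reg in (RegulationB.MRNA_ACT, RegulationB.PROT_ACT) \
        else "F1"
    dU = _du0_of_delta0(params, chi0, m0, n0, u0, v0, base)[target]
    one_plus_u = ExpPoly(q, {0: [1 + c0], 1: [u0 - c0]})
    inv_e = ExpPoly.exp(q, -1)                     # e^{-q sigma}
    u_hat_1 = (ExpPoly(q, {0: [W / q ** 3, W / q ** 2],
                           1: [-W / q ** 3]})
               + ExpPoly(q, {1: np.array([0, 0, -(u0 - c0) * W / 2.0])}))

    if reg in (RegulationB.MRNA_ACT, RegulationB.MRNA_REP):
        G0 = one_plus_u * inv_e * dU[0]
        G = {0: G0}
        if eps_order >= 1:
            G[1] = (one_plus_u * inv_e
                    * (dU[1] + ExpPoly.sigma(q, 2, W / 2.0) * dU[0])
                    + u_hat_1 * inv_e * dU[0])
        return G

    # protein channels: z d/dz operator
    dV = _dv0_of_delta0(params, chi0, m0, n0, u0, v0, base)[target]
    c0p = mu / q ** 2
    # B0 = (du/dv0)(du/du0)^{-1} at order 0
    B0 = (ExpPoly(q, {-1: [c0p], 0: [-c0p]})
          + ExpPoly.sigma(q, 1, -mu * (u0 - c0)))
    zdz0 = lambda n: (1 + v0) * (-(B0 * dU[n]) + dV[n])
    G = {0: zdz0(0)}
    if eps_order >= 1:
        # d u_hat_0 / dv0 and d u_hat_1 / dv0 (u0 fixed)
        du0_hat_dv0 = (ExpPoly(q, {0: [c0p], 1: [-c0p]})
                       + ExpPoly(q, {1: np.array([0, -mu * (u0 - c0)])}))
        t1 = (ExpPoly(q, {0: [1.0 / q ** 3], 1: [-1.0 / q ** 3]})
              + ExpPoly(q, {1: np.array([0, W / q ** 3])})
              + ExpPoly(q, {0: [3 * W / q ** 4], 1: [-3 * W / q ** 4]}))
        t2 = ExpPoly.sigma(q, 1, 1.0 / q ** 2 + 2 * W / q ** 3)
        t3 = (ExpPoly(q, {1: np.array([0, 0, W / (2 * q ** 2)])})
              + ExpPoly(q, {1: np.array([0, 0, -(u0 - c0) / 2.0])})
              + ExpPoly(q, {1: np.array([0, 0, 0, (u0 - c0) * W / 2.0])}))
        du1_hat_dv0 = mu * (t1 + t2 + t3)
        B1 = inv_e * (du1_hat_dv0 + ExpPoly.sigma(q, 2, W / 2.0) * du0_hat_dv0)
        G[1] = ((1 + v0) * (-(B1 * dU[0]))
                - ExpPoly.sigma(q, 1) * (-(B0 * dU[0]) + dV[0])
                + (1 + v0) * (-(B0 * dU[1]) + dV[1]))
    return G


def _delta1_terms(params, chis, m0, n0, u0, v0, base, eps_order):
    """First-delta-order hierarchy F^(j)_{1,n}(sigma), n <= eps_order."""
    k0, k1, lam = params.kappa_0, params.kappa_1, params.lam
    q, c0 = base["q"], base["c0"]
    chi0, chi1 = chis
    Pi = base["Pi"]
    reg = params.regulation
    s0 = -1.0 if reg in (RegulationB.MRNA_ACT, RegulationB.PROT_ACT) else 1.0
    G = _source_terms(params, chi0, m0, n0, u0, v0, base, eps_order)

    F0_10 = ExpPoly.const(q, chi1 * Pi)
    F1_10 = ExpPoly.const(q, -chi1 * Pi)
    out0 = {0: F0_10}
    out1 = {0: F1_10}
    if eps_order >= 1:
        u_hat_0 = ExpPoly(q, {0: [c0], 1: [u0 - c0]})
        rhs0 = (-k0) * F0_10 + k1 * F1_10 + s0 * G[0]
        rhs1 = k0 * F0_10 + (-k1) * F1_10 + lam * (u_hat_0 * F1_10) \
            + (-s0) * G[0]
        out0[1] = rhs0.integrate()
        out1[1] = rhs1.integrate()
    return out0, out1


def autoreg_gf_b(params: ModelBParams, chi: ChiSpec, m0: int, n0: int,
                 w: complex, z: complex, t: float, delta_order: int = 1,
                 eps_order: int = 1) -> GFEvaluationB:
    """Generating functions of the autoregulated two-stage model as a double
    series in the feedback strength delta and the time-scale ratio eps.

    Supports all four feedback channels; the delta^1 coefficients are built
    by integrating the fast-time hierarchy with the transported copy-number
    operator as source.  delta_order <= 1 and eps_order <= 1.
    """
    if delta_order not in (0, 1) or eps_order not in (0, 1):
        raise InvalidParameterError(
            f"unsupported expansion orders (delta_order={delta_order}, "
            f"eps_order={eps_order}); implemented depth is (1, 1)")
    if params.regulation is RegulationB.NONE or delta_order == 0:
        ev = eval_gf_b(params, chi, m0, n0, w, z, t, eps_order=eps_order)
        return GFEvaluationB(eps_order=eps_order, delta_order=0,
                             F0_terms=ev.F0_terms, F1_terms=ev.F1_terms,
                             total_F0=ev.total_F0, total_F1=ev.total_F1)
    chis = chi_series(chi, params, m0, n0, 1)
    u = complex(w) - 1.0
    v = complex(z) - 1.0
    v0 = v * np.exp(-t)
    sigma = t / params.eps
    eps = params.eps
    u0 = inverse_u0(u, v, t, eps, params.mu, order=min(eps_order, 1))
    if eps_order >= 1:
        _validity_check(params, v0, t)
    base = _delta0_exppolys(params, chis[0], m0, n0, u0, v0)
    co = coeffs_from_ics_b(chis[0], params, m0, n0, u0, v0)
    F0_d0, F1_d0 = _hierarchy_terms(co, params, u0, v0, sigma, eps_order)
    F0_d1, F1_d1 = _delta1_terms(params, chis, m0, n0, u0, v0, base,
                                 eps_order)

    terms0 = {(0, n): val for n, val in F0_d0.items()}
    terms1 = {(0, n): val for n, val in F1_d0.items()}
    for n, ep in F0_d1.items():
        terms0[(1, n)] = ep.eval(sigma)
    for n, ep in F1_d1.items():
        terms1[(1, n)] = ep.eval(sigma)

    d = params.delta
    tot0 = sum(d ** m * eps ** n * val for (m, n), val in terms0.items())
    tot1 = sum(d ** m * eps ** n * val for (m, n), val in terms1.items())
    return GFEvaluationB(eps_order=eps_order, delta_order=delta_order,
                         F0_terms=terms0, F1_terms=terms1,
                         total_F0=tot0, total_F1=tot1)


def gf_total_b(params: ModelBParams, chi: ChiSpec, m0: int, n0: int,
               t: float, eps_order: int = 2, delta_order: int | None = None):
    """Return a callable (w, z) -> F0+F1 for contour sampling."""
    if delta_order is None:
        delta_order = 1 if params.regulation is not RegulationB.NONE else 0

    def gf(w, z):
        if delta_order:
            ev = autoreg_gf_b(params, chi, m0, n0, w, z, t,
                              delta_order=delta_order,
                              eps_order=min(eps_order, 1))
        else:
            ev = eval_gf_b(params, chi, m0, n0, w, z, t, eps_order=eps_order)
        return ev.total_F0 + ev.total_F1
    return gf
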