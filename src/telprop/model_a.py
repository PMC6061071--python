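"""Generating functions of the autoregulated one-stage telegraph model.

The joint generating functions ``F^(0), F^(1)`` (promoter off/on) satisfy a
pair of coupled first-order PDEs in (z, t).  Along the characteristics
``v = z - 1 = v0 e^s`` the transport operator becomes d/ds, and each
delta-order of the weak-feedback expansion solves a linear ODE system whose
homogeneous solutions are confluent hypergeometric functions of
``w = lam * v0 * e^s``.

Leading order (delta^0) is the exact unregulated telegraph model.  Both
components are represented in their own Kummer basis,

    F0 basis:  M(kf, 1+K, w),      e^{-Ks} M(-kb, 1-K, w)
    F1 basis:  M(1+kf, 1+K, w),    e^{-Ks} M(1-kb, 1-K, w)

with K = kf + kb, and the two free constants of each pair fixed by the value
and slope of the initial conditions at s = 0 (a 2x2 linear solve per
characteristic).  Writing the second basis function with the factor
``e^{-Ks}`` rather than ``w^{-K}`` keeps all expressions entire in v0 — no
fractional powers or branch cuts appear anywhere.

The first-order feedback correction is available through two independent
routes: variation of constants (a contour-wise quadrature in s) and direct
numerical integration of the characteristic ODE system with the analytic
leading order as source.  The source requires d/dv0 of the leading order,
which is computed analytically by differentiating the 2x2 constant system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kummer import kummer_m
from .params import (ChiSpec, InvalidParameterError, ModelAParams, Regulation,
                     chi_series)

__all__ = ["GFEvaluationA", "ModelAConstants", "eval_leading_a",
           "eval_leading_a_batch", "leading_constants_a", "first_order_a",
           "eval_gf_a", "gf_total_a"]

logger = logging.getLogger(__name__)

_GAUSS_NODES = 160


def _nudged(params: ModelAParams) -> ModelAParams:
    """Shift kappa_f slightly when kf+kb sits on a positive integer.

    There the second Kummer basis function has a non-positive-integer
    denominator parameter; the solution itself is continuous in the rates, so
    a relative 1e-8 nudge restores a well-conditioned basis.
    """
    K = params.kappa_f + params.kappa_b
    if abs(K - round(K)) < 1e-6 and round(K) >= 1:
        bump = max(params.kappa_f, params.kappa_b, 1.0) * 1e-8
        logger.info("kappa_f+kappa_b = %g is (near-)integer; nudging by %g",
                    K, bump)
        if params.kappa_f > 0:
            return ModelAParams(params.kappa_f + bump, params.kappa_b,
                                params.lam, params.regulation, params.delta,
                                params.alpha, params.rho)
        return ModelAParams(params.kappa_f, params.kappa_b + bump,
                            params.lam, params.regulation, params.delta,
                            params.alpha, params.rho)
    return params


@dataclass
class ModelAConstants:
    """Kummer-basis coefficients of the leading order on one characteristic.

    (c1, c2) multiply the F0 basis, (hat_c1, hat_c2) the F1 basis; the
    *_d attributes are their derivatives with respect to the base point v0,
    needed by the first-order feedback source.
    """
    c1: complex
    c2: complex
    hat_c1: complex
    hat_c2: complex
    c1_d: complex = 0.0j
    c2_d: complex = 0.0j
    hat_c1_d: complex = 0.0j
    hat_c2_d: complex = 0.0j


class _CharA:
    """Leading-order solution and its v0-derivative on one characteristic."""

    def __init__(self, params: ModelAParams, chi0: float, n0: int, v0: complex):
        self.p = params
        self.kf, self.kb, self.lam = params.kappa_f, params.kappa_b, params.lam
        self.K = self.kf + self.kb
        if self.K <= 0:
            raise InvalidParameterError("kappa_f + kappa_b must be positive")
        self.chi0 = chi0
        self.n0 = n0
        self.v0 = complex(v0)
        self.y = self.lam * self.v0
        self.consts = self._solve_constants()

    # -- basis functions -------------------------------------------------
    def _basis0(self, s, w, deriv_v0=False):
        """F0 basis (u1, u2) and s-derivatives at (s, w)."""
        kf, kb, K, lam = self.kf, self.kb, self.K, self.lam
        M1 = kummer_m(kf, 1 + K, w)
        M1p = kummer_m(kf, 1 + K, w, 1)
        M2 = kummer_m(-kb, 1 - K, w)
        M2p = kummer_m(-kb, 1 - K, w, 1)
        e = np.exp(-K * s)
        u1, u2 = M1, e * M2
        du1, du2 = w * M1p, e * (-K * M2 + w * M2p)
        if not deriv_v0:
            return u1, u2, du1, du2
        # d/dv0 at fixed s: dw/dv0 = lam e^s
        M1pp = kummer_m(kf, 1 + K, w, 2)
        M2pp = kummer_m(-kb, 1 - K, w, 2)
        les = lam * np.exp(s)
        v1, v2 = les * M1p, e * les * M2p
        dv1 = les * (M1p + w * M1pp)
        dv2 = e * les * ((1 - K) * M2p + w * M2pp)
        return u1, u2, du1, du2, v1, v2, dv1, dv2

    def _basis1(self, s, w, deriv_v0=False):
        """F1 basis (uh1, uh2) and s-derivatives at (s, w)."""
        kf, kb, K, lam = self.kf, self.kb, self.K, self.lam
        M1 = kummer_m(1 + kf, 1 + K, w)
        M1p = kummer_m(1 + kf, 1 + K, w, 1)
        M2 = kummer_m(1 - kb, 1 - K, w)
        M2p = kummer_m(1 - kb, 1 - K, w, 1)
        e = np.exp(-K * s)
        u1, u2 = M1, e * M2
        du1, du2 = w * M1p, e * (-K * M2 + w * M2p)
        if not deriv_v0:
            return u1, u2, du1, du2
        M1pp = kummer_m(1 + kf, 1 + K, w, 2)
        M2pp = kummer_m(1 - kb, 1 - K, w, 2)
        les = lam * np.exp(s)
        v1, v2 = les * M1p, e * les * M2p
        dv1 = les * (M1p + w * M1pp)
        dv2 = e * les * ((1 - K) * M2p + w * M2pp)
        return u1, u2, du1, du2, v1, v2, dv1, dv2

    # -- constants -------------------------------------------------------
    def _solve_constants(self) -> ModelAConstants:
        kf, kb, lam, y, chi0 = self.kf, self.kb, self.lam, self.y, self.chi0
        n0, v0 = self.n0, self.v0
        Pi = (1 + v0) ** n0
        Pi_d = n0 * (1 + v0) ** (n0 - 1) if n0 else 0.0

        u1, u2, du1, du2, v1, v2, dv1, dv2 = self._basis0(0.0, y, deriv_v0=True)
        A = np.array([[u1, u2], [du1, du2]])
        Ad = np.array([[v1, v2], [dv1, dv2]])
        # value and slope of F0 at s=0:  F0(0)=chi0*Pi,
        # F0'(0) = -kf F0(0) + kb F1(0)
        b = np.array([chi0 * Pi, (-kf * chi0 + kb * (1 - chi0)) * Pi])
        bd = np.array([chi0 * Pi_d, (-kf * chi0 + kb * (1 - chi0)) * Pi_d])
        c = np.linalg.solve(A, b)
        cd = np.linalg.solve(A, bd - Ad @ c)

        u1, u2, du1, du2, v1, v2, dv1, dv2 = self._basis1(0.0, y, deriv_v0=True)
        Ah = np.array([[u1, u2], [du1, du2]])
        Ahd = np.array([[v1, v2], [dv1, dv2]])
        # F1(0) = (1-chi0) Pi, F1'(0) = kf F0(0) - kb F1(0) + lam v0 F1(0)
        b2val = (kf * chi0 - kb * (1 - chi0) + lam * v0 * (1 - chi0))
        bh = np.array([(1 - chi0) * Pi, b2val * Pi])
        bhd = np.array([(1 - chi0) * Pi_d,
                        b2val * Pi_d + lam * (1 - chi0) * Pi])
        ch = np.linalg.solve(Ah, bh)
        chd = np.linalg.solve(Ah, bhd - Ahd @ ch)
        return ModelAConstants(c1=c[0], c2=c[1], hat_c1=ch[0], hat_c2=ch[1],
                               c1_d=cd[0], c2_d=cd[1],
                               hat_c1_d=chd[0], hat_c2_d=chd[1])

    # -- leading-order values along the characteristic -------------------
    def w_of(self, s):
        return self.y * np.exp(s)

    def F0_0(self, s):
        u1, u2, _, _ = self._basis0(s, self.w_of(s))
        return self.consts.c1 * u1 + self.consts.c2 * u2

    def F1_0(self, s):
        u1, u2, _, _ = self._basis1(s, self.w_of(s))
        return self.consts.hat_c1 * u1 + self.consts.hat_c2 * u2

    def dv0_F0_0(self, s, with_s_deriv=False):
        """d/dv0 of the leading off-component (optionally also d/ds of it)."""
        c = self.consts
        u1, u2, du1, du2, v1, v2, dv1, dv2 = \
            self._basis0(s, self.w_of(s), deriv_v0=True)
        D = c.c1_d * u1 + c.c2_d * u2 + c.c1 * v1 + c.c2 * v2
        if not with_s_deriv:
            return D
        Dp = c.c1_d * du1 + c.c2_d * du2 + c.c1 * dv1 + c.c2 * dv2
        return D, Dp

    def dv0_F1_0(self, s, with_s_deriv=False):
        c = self.consts
        u1, u2, du1, du2, v1, v2, dv1, dv2 = \
            self._basis1(s, self.w_of(s), deriv_v0=True)
        D = c.hat_c1_d * u1 + c.hat_c2_d * u2 + c.hat_c1 * v1 + c.hat_c2 * v2
        if not with_s_deriv:
            return D
        Dp = c.hat_c1_d * du1 + c.hat_c2_d * du2 + c.hat_c1 * dv1 + c.hat_c2 * dv2
        return D, Dp

    # -- feedback source -------------------------------------------------
    def source(self, s, with_s_deriv=False):
        """R(s): the order-delta source term on this characteristic.

        Autoactivation: R = alpha (v0 + e^{-s}) d/dv0 F0_0;
        autorepression: R = rho  (v0 + e^{-s}) d/dv0 F1_0.
        """
        p = self.p
        if p.regulation is Regulation.AUTOACTIVATION:
            coeff, dfun = p.alpha, self.dv0_F0_0
        elif p.regulation is Regulation.AUTOREPRESSION:
            coeff, dfun = p.rho, self.dv0_F1_0
        else:
            raise InvalidParameterError("no feedback channel selected")
        pref = self.v0 + np.exp(-s)
        if not with_s_deriv:
            return coeff * pref * dfun(s)
        D, Dp = dfun(s, with_s_deriv=True)
        R = coeff * pref * D
        Rp = coeff * (-np.exp(-s) * D + pref * Dp)
        return R, Rp


def eval_leading_a_batch(params: ModelAParams, chi0: float, n0: int,
                         zs: np.ndarray, t: float):
    """Vectorised leading-order (F0, F1) over an array of z values.

    Same mathematics as :func:`eval_leading_a` with the per-characteristic
    2x2 solves done in closed (Cramer) form elementwise; used for fast
    contour sampling.
    """
    params = _nudged(params)
    kf, kb, lam = params.kappa_f, params.kappa_b, params.lam
    K = kf + kb
    if K <= 0:
        raise InvalidParameterError("kappa_f + kappa_b must be positive")
    zs = np.asarray(zs, dtype=complex)
    v0 = (zs - 1.0) * np.exp(-t)
    y = lam * v0
    w = y * np.exp(t)
    Pi = (1 + v0) ** n0

    def solve_pair(a_lo, b_lo, a_hi, b_hi, rhs1, rhs2):
        # basis (M(a_lo, b_lo, .), e^{-Ks} M(a_hi, b_hi, .)) fixed by value
        # and slope at s=0, then evaluated at s=t
        M1_0 = kummer_m(a_lo, b_lo, y)
        M1p_0 = kummer_m(a_lo, b_lo, y, 1)
        M2_0 = kummer_m(a_hi, b_hi, y)
        M2p_0 = kummer_m(a_hi, b_hi, y, 1)
        a11, a12 = M1_0, M2_0
        a21, a22 = y * M1p_0, -K * M2_0 + y * M2p_0
        det = a11 * a22 - a12 * a21
        c1 = (rhs1 * a22 - rhs2 * a12) / det
        c2 = (a11 * rhs2 - a21 * rhs1) / det
        return c1 * kummer_m(a_lo, b_lo, w) \
            + c2 * np.exp(-K * t) * kummer_m(a_hi, b_hi, w)

    F0 = solve_pair(kf, 1 + K, -kb, 1 - K,
                    chi0 * Pi, (-kf * chi0 + kb * (1 - chi0)) * Pi)
    b2 = (kf * chi0 - kb * (1 - chi0)) * Pi + lam * v0 * (1 - chi0) * Pi
    F1 = solve_pair(1 + kf, 1 + K, 1 - kb, 1 - K, (1 - chi0) * Pi, b2)
    return F0, F1


def leading_constants_a(params: ModelAParams, chi0: float, n0: int,
                        v0: complex) -> ModelAConstants:
    """Free constants of the leading-order Kummer representation at base
    point v0, fixed by the initial conditions on the characteristic."""
    return _CharA(_nudged(params), chi0, n0, v0).consts


def eval_leading_a(params: ModelAParams, chi0: float, n0: int,
                   z: complex, t: float) -> tuple[complex, complex]:
    """Leading-order generating functions (F0, F1) at the point (z, t).

    For an unregulated model this is the exact generating-function pair of
    the telegraph master equation.
    """
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    params = _nudged(params)
    v0 = (complex(z) - 1.0) * np.exp(-t)
    ch = _CharA(params, chi0, n0, v0)
    return complex(ch.F0_0(t)), complex(ch.F1_0(t))


def _first_order_quadrature(ch: _CharA, chi1: float, t: float):
    """Variation-of-constants evaluation of the order-delta pair at s=t."""
    p, K, y = ch.p, ch.K, ch.y
    kf, kb, lam = ch.kf, ch.kb, ch.lam
    n0, v0 = ch.n0, ch.v0
    Pi = (1 + v0) ** n0
    act = p.regulation is Regulation.AUTOACTIVATION

    if t > 0:
        xg, wg = np.polynomial.legendre.leggauss(_GAUSS_NODES)
        sg = 0.5 * t * (xg + 1.0)
        wg = 0.5 * t * wg
        wvals = ch.w_of(sg)
        R, Rp = ch.source(sg, with_s_deriv=True)
        if act:
            # g*w = e^{-w} (w R - R')   [activation second-order form]
            q = np.exp(-wvals) * (wvals * R - Rp)
            Ma = kummer_m(kf, 1 + K, wvals)
            Mb = kummer_m(-kb, 1 - K, wvals)
        else:
            # repression drives the on-component:  h*w = -e^{-w} R'
            q = -np.exp(-wvals) * Rp
            Ma = kummer_m(1 + kf, 1 + K, wvals)
            Mb = kummer_m(1 - kb, 1 - K, wvals)
        I2 = np.sum(wg * Mb * q)
        I1 = np.sum(wg * np.exp(K * sg) * Ma * q)
    else:
        I1 = I2 = 0.0

    R0 = ch.source(0.0)
    Rt = ch.source(t)
    if act:
        u1, u2, du1, du2 = ch._basis0(t, ch.w_of(t))
        u10, u20, du10, du20 = ch._basis0(0.0, y)
        A = np.array([[u10, u20], [du10, du20]])
        # ICs: F0_1(0) = chi1 Pi ; F0_1'(0) = -(kf+kb) chi1 Pi - R(0)
        b = np.array([chi1 * Pi, -(kf + kb) * chi1 * Pi - R0])
        a = np.linalg.solve(A, b)
        Fp = (u1 * I2 - u2 * I1) / K
        dFp = (du1 * I2 - du2 * I1) / K
        F0_1 = a[0] * u1 + a[1] * u2 + Fp
        dF0_1 = a[0] * du1 + a[1] * du2 + dFp
        if kb == 0:
            raise InvalidParameterError(
                "quadrature route needs kappa_b > 0 for autoactivation; "
                "use method='ode'")
        F1_1 = (dF0_1 + kf * F0_1 + Rt) / kb
        return complex(F0_1), complex(F1_1)
    # autorepression: variation of constants acts on the on-component
    u1, u2, du1, du2 = ch._basis1(t, ch.w_of(t))
    u10, u20, du10, du20 = ch._basis1(0.0, y)
    A = np.array([[u10, u20], [du10, du20]])
    # ICs: F1_1(0) = -chi1 Pi ;
    # F1_1'(0) = kf F0_1 - kb F1_1 + lam v0 F1_1 - R  at s=0
    slope0 = (kf * chi1 + kb * chi1 - lam * v0 * chi1) * Pi - R0
    b = np.array([-chi1 * Pi, slope0])
    a = np.linalg.solve(A, b)
    Fp = (u1 * I2 - u2 * I1) / K
    dFp = (du1 * I2 - du2 * I1) / K
    F1_1 = a[0] * u1 + a[1] * u2 + Fp
    dF1_1 = a[0] * du1 + a[1] * du2 + dFp
    if kf == 0:
        raise InvalidParameterError(
            "quadrature route needs kappa_f > 0 for autorepression; "
            "use method='ode'")
    F0_1 = (dF1_1 + (kb - ch.w_of(t)) * F1_1 + Rt) / kf
    return complex(F0_1), complex(F1_1)


def _first_order_ode(ch: _CharA, chi1: float, t: float,
                     rtol=1e-10, atol=1e-12):
    """Direct integration of the order-delta characteristic system."""
    kf, kb, lam, v0 = ch.kf, ch.kb, ch.lam, ch.v0
    act = ch.p.regulation is Regulation.AUTOACTIVATION
    sign = -1.0 if act else 1.0

    def rhs(s, yv):
        F0 = yv[0] + 1j * yv[1]
        F1 = yv[2] + 1j * yv[3]
        R = ch.source(s)
        d0 = -kf * F0 + kb * F1 + sign * R
        d1 = kf * F0 - kb * F1 + lam * v0 * np.exp(s) * F1 - sign * R
        return [d0.real, d0.imag, d1.real, d1.imag]

    Pi = (1 + v0) ** ch.n0
    y0c = np.array([chi1 * Pi, -chi1 * Pi])
    y0 = [y0c[0].real, y0c[0].imag, y0c[1].real, y0c[1].imag]
    if t == 0:
        return complex(y0c[0]), complex(y0c[1])
    sol = solve_ivp(rhs, (0.0, t), y0, method="DOP853", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"first-order ODE integration failed: {sol.message}")
    yf = sol.y[:, -1]
    return complex(yf[0] + 1j * yf[1]), complex(yf[2] + 1j * yf[3])


def first_order_a(params: ModelAParams, chi: ChiSpec, n0: int,
                  z: complex, t: float,
                  method: str = "quadrature") -> tuple[complex, complex]:
    """Order-delta correction pair (F0_1, F1_1) at (z, t).

    ``method='quadrature'`` evaluates the variation-of-constants integrals
    along the characteristic; ``method='ode'`` integrates the characteristic
    system directly.  The two routes are independent and agree to roughly
    integrator tolerance; quadrature falls back to the ODE route if its
    linear solve or the Kummer basis is ill-conditioned.
    """
    if params.regulation is Regulation.NONE:
        raise InvalidParameterError("first-order term needs a feedback channel")
    params = _nudged(params)
    chi0, chi1 = chi_series(chi, params, None, n0, 1)
    v0 = (complex(z) - 1.0) * np.exp(-t)
    ch = _CharA(params, chi0, n0, v0)
    if method == "ode":
        return _first_order_ode(ch, chi1, t)
    if method != "quadrature":
        raise InvalidParameterError(f"unknown method {method!r}")
    try:
        return _first_order_quadrature(ch, chi1, t)
    except (np.linalg.LinAlgError, InvalidParameterError):
        logger.warning("quadrature route failed at z=%s, t=%s; "
                       "falling back to ODE route", z, t)
        return _first_order_ode(ch, chi1, t)


@dataclass
class GFEvaluationA:
    """delta-resummed generating-function values at one (z, t) point."""
    order: int
    F0_terms: tuple[complex, ...]
    F1_terms: tuple[complex, ...]
    total_F0: complex
    total_F1: complex


def eval_gf_a(params: ModelAParams, chi: ChiSpec, n0: int, z: complex,
              t: float, order: int = 0,
              method: str = "quadrature") -> GFEvaluationA:
    """Generating functions of the (possibly autoregulated) model to the
    requested order in the feedback strength delta."""
    if order not in (0, 1):
        raise InvalidParameterError(
            "expansion order capped at 1 (leading + first correction)")
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    params = _nudged(params)
    chi0 = chi_series(chi, params, None, n0, 0)[0]
    F0_0, F1_0 = eval_leading_a(params, chi0, n0, z, t)
    if order == 0 or params.regulation is Regulation.NONE:
        return GFEvaluationA(order=0, F0_terms=(F0_0,), F1_terms=(F1_0,),
                             total_F0=F0_0, total_F1=F1_0)
    F0_1, F1_1 = first_order_a(params, chi, n0, z, t, method=method)
    d = params.delta
    return GFEvaluationA(order=1, F0_terms=(F0_0, F0_1),
                         F1_terms=(F1_0, F1_1),
                         total_F0=F0_0 + d * F0_1,
                         total_F1=F1_0 + d * F1_1)


def gf_total_a(params: ModelAParams, chi: ChiSpec, n0: int, order: int = 0,
               method: str = "quadrature"):
    """Return a callable (z, t) -> F0+F1 for contour sampling.

    Array-valued z is evaluated through the vectorised leading-order path
    when no first-order correction is requested.
    """
    eff_order = 0 if params.regulation is Regulation.NONE else order

    def gf(z, t):
        if np.ndim(z) > 0 and eff_order == 0:
            chi0 = chi_series(chi, _nudged(params), None, n0, 0)[0]
            F0, F1 = eval_leading_a_batch(params, chi0, n0, z, t)
            return F0 + F1
        if np.ndim(z) > 0:
            return np.array([gf(zz, t) for zz in np.asarray(z).ravel()]
                            ).reshape(np.shape(z))
        ev = eval_gf_a(params, chi, n0, z, t, order=order, method=method)
        return ev.total_F0 + ev.total_F1
    return gf
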