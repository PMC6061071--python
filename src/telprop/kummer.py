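"""Confluent hypergeometric function 1F1 (Kummer's M) for complex arguments.

The generating-function formulas need M(a, b, x) at complex x of moderate
modulus (|x| up to a few tens) with real parameters a, b of order ten or
less.  In that regime the Taylor series converges quickly; for Re(x) < 0 the
Kummer transformation ``M(a,b,x) = e^x M(b-a, b, -x)`` is applied first so
that the dominant exponential growth sits in the prefactor.  Cancellation is
monitored by comparing the largest partial term against the result; when the
estimated loss of precision would push the relative error above ~1e-12 the
affected entries are recomputed with mpmath at elevated working precision.

``kummer_m`` accepts scalars or arrays in ``x`` and an optional derivative
order; derivatives use the parameter-shift rule
``d/dx M(a,b,x) = (a/b) M(a+1,b+1,x)``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["kummer_m", "KummerError"]

_MAXTERMS = 500
_TOL = 1e-17
# largest tolerable (max partial term)/(result): 2e-16 * 1e4 = 2e-12 rel. error
_CANCEL_RATIO = 1e4


class KummerError(ArithmeticError):
    pass


def _series(a: float, b: float, x: np.ndarray):
    """Taylor series; returns (sum, running max |term|) for cancellation check."""
    out = np.ones_like(x)
    term = np.ones_like(x)
    peak = np.ones(x.shape)
    for k in range(_MAXTERMS):
        term = term * ((a + k) / ((b + k) * (k + 1.0))) * x
        out = out + term
        np.maximum(peak, np.abs(term), out=peak)
        if np.all(np.abs(term) <= _TOL * np.maximum(np.abs(out), 1e-300)):
            return out, peak
    raise KummerError(f"1F1 series did not converge (a={a}, b={b})")


def _mpmath_eval(a: float, b: float, x: np.ndarray, extradps: int = 25) -> np.ndarray:
    import mpmath
    flat = np.ravel(x)
    with mpmath.workdps(mpmath.mp.dps + extradps):
        vals = [complex(mpmath.hyp1f1(a, b, complex(z))) for z in flat]
    return np.array(vals, dtype=complex).reshape(np.shape(x))


def _m_base(a: float, b: float, x: np.ndarray) -> np.ndarray:
    if abs(b - round(b)) < 1e-13 and round(b) <= 0:
        raise KummerError(
            f"1F1 denominator parameter b={b} is a non-positive integer")
    if a == 0.0:
        return np.ones_like(x)
    if a == b:
        return np.exp(x)
    neg = x.real < 0
    out = np.empty_like(x)
    bad = np.zeros(x.shape, dtype=bool)
    if np.any(~neg):
        val, peak = _series(a, b, x[~neg])
        out[~neg] = val
        bad[~neg] = peak > _CANCEL_RATIO * np.abs(val)
    if np.any(neg):
        val, peak = _series(b - a, b, -x[neg])
        out[neg] = np.exp(x[neg]) * val
        bad[neg] = peak > _CANCEL_RATIO * np.abs(val)
    if np.any(bad):
        out[bad] = _mpmath_eval(a, b, x[bad])
    return out


def kummer_m(a: float, b: float, x, deriv: int = 0):
    """Evaluate ``d^deriv/dx^deriv  M(a, b, x)`` for complex x.

    Parameters are real; x may be a scalar or array.  The result has the
    shape of x (scalar in, scalar out).
    """
    arr = np.asarray(x, dtype=complex)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    fac = 1.0
    for k in range(deriv):
        fac *= (a + k) / (b + k)
    try:
        val = fac * _m_base(a + deriv, b + deriv, arr)
    except KummerError:
        val = fac * _mpmath_eval(a + deriv, b + deriv, arr)
    if val.size and np.any(~np.isfinite(val)):
        val = fac * _mpmath_eval(a + deriv, b + deriv, arr)
    return val[0] if scalar else val.reshape(np.shape(x))
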