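"""Tiny exact algebra for exponential-polynomial functions of the fast time.

The fast-time hierarchy of the two-stage model is built from functions of
the form  sum_k  p_k(sigma) * e^{k q sigma}  with polynomials p_k and a
single complex base rate q = 1 - mu*v0.  Closure of this family under
addition, multiplication, differentiation and integration lets every term of
the weak-feedback double series be assembled exactly (no quadrature), which
matters because the polynomials carry secular growth that must not be
contaminated by integration error.

Terms are stored as ``{k: coeffs}`` with integer exponent multiple k and
ascending polynomial coefficients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ExpPoly"]


def _trim(c: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(c) > 0)[0]
    return c[: nz[-1] + 1] if len(nz) else np.zeros(1, dtype=complex)


class ExpPoly:
    """sum_k p_k(sigma) e^{k*q*sigma} with integer multiples k of rate q."""

    def __init__(self, q: complex, terms: dict[int, np.ndarray] | None = None):
        self.q = complex(q)
        self.terms: dict[int, np.ndarray] = {}
        for k, c in (terms or {}).items():
            c = _trim(np.asarray(c, dtype=complex))
            if np.any(c != 0):
                self.terms[int(k)] = c

    @classmethod
    def const(cls, q, value):
        return cls(q, {0: [value]})

    @classmethod
    def sigma(cls, q, power=1, coeff=1.0):
        c = np.zeros(power + 1, dtype=complex)
        c[power] = coeff
        return cls(q, {0: c})

    @classmethod
    def exp(cls, q, k, coeff=1.0):
        return cls(q, {k: [coeff]})

    def _like(self, terms):
        return ExpPoly(self.q, terms)

    def __add__(self, other):
        if not isinstance(other, ExpPoly):
            other = ExpPoly.const(self.q, other)
        out = {k: c.copy() for k, c in self.terms.items()}
        for k, c in other.terms.items():
            if k in out:
                n = max(len(out[k]), len(c))
                a = np.zeros(n, dtype=complex)
                a[: len(out[k])] += out[k]
                a[: len(c)] += c
                out[k] = a
            else:
                out[k] = c.copy()
        return self._like(out)

    __radd__ = __add__

    def __neg__(self):
        return self._like({k: -c for k, c in self.terms.items()})

    def __sub__(self, other):
        return self + (-other if isinstance(other, ExpPoly)
                       else ExpPoly.const(self.q, -other))

    def __mul__(self, other):
        if not isinstance(other, ExpPoly):
            return self._like({k: c * other for k, c in self.terms.items()})
        out: dict[int, np.ndarray] = {}
        for k1, c1 in self.terms.items():
            for k2, c2 in other.terms.items():
                prod = np.convolve(c1, c2)
                k = k1 + k2
                if k in out:
                    n = max(len(out[k]), len(prod))
                    a = np.zeros(n, dtype=complex)
                    a[: len(out[k])] += out[k]
                    a[: len(prod)] += prod
                    out[k] = a
                else:
                    out[k] = prod
        return self._like(out)

    __rmul__ = __mul__

    def deriv(self):
        out: dict[int, np.ndarray] = {}
        for k, c in self.terms.items():
            d = np.zeros(max(len(c), 1), dtype=complex)
            if len(c) > 1:
                d[: len(c) - 1] += c[1:] * np.arange(1, len(c))
            d[: len(c)] += (k * self.q) * c
            key = k
            prev = out.get(key)
            out[key] = d if prev is None else prev + d
        return self._like(out)

    def integrate(self):
        """Antiderivative vanishing at sigma = 0."""
        out = ExpPoly(self.q, {})
        for k, c in self.terms.items():
            a = k * self.q
            if a == 0:
                ic = np.zeros(len(c) + 1, dtype=complex)
                ic[1:] = c / np.arange(1, len(c) + 1)
                out = out + self._like({0: ic})
            else:
                # int sigma^n e^{a sigma} = e^{a sigma} * sum_j (-1)^j
                #   n!/(n-j)! sigma^{n-j} / a^{j+1}   (+ constant)
                poly = np.zeros(len(c), dtype=complex)
                for n, cn in enumerate(c):
                    if cn == 0:
                        continue
                    fac = cn
                    for j in range(n + 1):
                        poly[n - j] += fac * (-1) ** j / a ** (j + 1) * _ff(n, j)
                const = -poly[0]
                out = out + self._like({k: poly, 0: [const]})
        return out

    def eval(self, sigma: complex) -> complex:
        tot = 0.0 + 0.0j
        for k, c in self.terms.items():
            p = 0.0 + 0.0j
            for cn in reversed(c):
                p = p * sigma + cn
            tot += p * np.exp(k * self.q * sigma)
        return tot


def _ff(n: int, j: int) -> float:
    """Falling factorial n!/(n-j)!."""
    out = 1.0
    for i in range(j):
        out *= (n - i)
    return out
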