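"""Propagator probabilities from generating functions by contour integration.

A probability-generating function is holomorphic in a neighbourhood of the
origin, so its Taylor coefficients — the state probabilities — are Cauchy
integrals over a circle.  Discretising the circle with M equispaced nodes
turns the integral into a plain discrete Fourier transform of the contour
samples, with spectral accuracy in M for functions holomorphic past the
contour.  Samples are taken once per contour and reused for every
coefficient.

The two-variable (mRNA, protein) case uses a tensor-product contour and a
2-D DFT.  For the two-stage model the generating function generically has a
pole at ``z = 1 + 1/mu``, so the protein contour must keep radius <= 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContourSpec", "PropagatorTable", "invert_1d", "invert_2d",
           "protein_marginal", "default_contour_b"]


class AliasingError(ValueError):
    pass


def _pow2_at_least(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


@dataclass(frozen=True)
class ContourSpec:
    """Circular contour(s) for the inversion.

    nodes default to the smallest power of two >= max(64, 4*(index_max+1)),
    chosen when the inversion is called.
    """
    radius_z: float = 1.0
    radius_w: float = 1.0
    nodes_z: int | None = None
    nodes_w: int | None = None

    def __post_init__(self):
        if self.radius_z <= 0 or self.radius_w <= 0:
            raise ValueError("contour radii must be positive")

    def resolve_nodes(self, n_max: int, axis: str = "z") -> int:
        n = self.nodes_z if axis == "z" else self.nodes_w
        if n is None:
            n = _pow2_at_least(max(64, 4 * (n_max + 1)))
        if n_max >= n / 2:
            raise AliasingError(
                f"n_max={n_max} needs more than {n} contour nodes")
        return n


def default_contour_b(mu: float, n_max: int = 0, m_max: int = 0) -> ContourSpec:
    """Contour for the two-stage model: protein radius stays clear of the
    pole at z = 1 + 1/mu and never exceeds 1."""
    return ContourSpec(radius_z=min(1.0, 0.75 * (1.0 + 1.0 / mu)),
                       radius_w=1.0)


@dataclass
class PropagatorTable:
    """Inverted propagator probabilities with normalization diagnostics.

    P is indexed by protein count n (1-D) or by (m, n) (2-D).  Tiny negative
    entries and imaginary residues are diagnostics of truncation error in the
    underlying asymptotic generating function; they are reported, not hidden.
    """
    t: float
    n0: int
    P: np.ndarray
    m0: int | None = None
    mass: float = field(init=False)
    max_imag: float = 0.0

    def __post_init__(self):
        self.mass = float(np.sum(self.P))

    def clipped(self) -> np.ndarray:
        """Non-negative, renormalised copy (explicit opt-in)."""
        q = np.clip(self.P, 0.0, None)
        return q / q.sum()

    def to_tsv(self, metadata: dict | None = None) -> str:
        buf = io.StringIO()
        meta = {"t": self.t, "n0": self.n0}
        if self.m0 is not None:
            meta["m0"] = self.m0
        meta.update(metadata or {})
        for k, v in meta.items():
            buf.write(f"# {k}={v}\n")
        if self.P.ndim == 1:
            buf.write("n\tP\n")
            for n, p in enumerate(self.P):
                buf.write(f"{n}\t{p:.12e}\n")
        else:
            buf.write("m\tn\tP\n")
            for m in range(self.P.shape[0]):
                for n in range(self.P.shape[1]):
                    buf.write(f"{m}\t{n}\t{self.P[m, n]:.12e}\n")
        return buf.getvalue()


def contour_nodes(radius: float, M: int) -> np.ndarray:
    k = np.arange(M)
    return radius * np.exp(2j * np.pi * k / M)


def invert_1d(gf, n_max: int, contour: ContourSpec | None = None,
              t: float = np.nan, n0: int = 0) -> PropagatorTable:
    """Taylor coefficients 0..n_max of ``gf`` by the discretised Cauchy
    integral (equivalently, the DFT of the contour samples).

    gf : callable z -> complex, vectorised over numpy arrays or scalar-only.
    """
    contour = contour or ContourSpec()
    M = contour.resolve_nodes(n_max, "z")
    r = contour.radius_z
    zs = contour_nodes(r, M)
    try:
        samples = np.asarray(gf(zs), dtype=complex)
        if samples.shape != zs.shape:
            raise TypeError
    except (TypeError, ValueError):
        samples = np.array([gf(z) for z in zs], dtype=complex)
    if np.any(~np.isfinite(samples)):
        bad = int(np.argmax(~np.isfinite(samples)))
        raise ArithmeticError(
            f"generating function returned non-finite value at contour node "
            f"{bad} (z={zs[bad]})")
    coeff = np.fft.fft(samples)[:n_max + 1] / M
    coeff *= r ** -np.arange(n_max + 1)
    tab = PropagatorTable(t=t, n0=n0, P=coeff.real.copy())
    tab.max_imag = float(np.max(np.abs(coeff.imag)))
    return tab


def invert_2d(gf, m_max: int, n_max: int,
              contour: ContourSpec | None = None, t: float = np.nan,
              m0: int = 0, n0: int = 0) -> PropagatorTable:
    """Joint coefficients P_{m,n} from a two-variable generating function.

    gf : callable (w, z) -> complex, vectorised over broadcast arrays if
    possible.
    """
    contour = contour or ContourSpec()
    Mw = contour.resolve_nodes(m_max, "w")
    Mz = contour.resolve_nodes(n_max, "z")
    rw, rz = contour.radius_w, contour.radius_z
    ws = contour_nodes(rw, Mw)[:, None]
    zs = contour_nodes(rz, Mz)[None, :]
    try:
        samples = np.asarray(gf(ws, zs), dtype=complex)
        if samples.shape != (Mw, Mz):
            raise TypeError
    except (TypeError, ValueError):
        samples = np.array([[gf(w, z) for z in zs[0]] for w in ws[:, 0]],
                           dtype=complex)
    if np.any(~np.isfinite(samples)):
        raise ArithmeticError("generating function returned non-finite value "
                              "on the contour")
    coeff = np.fft.fft2(samples)[:m_max + 1, :n_max + 1] / (Mw * Mz)
    coeff *= rw ** -np.arange(m_max + 1)[:, None]
    coeff *= rz ** -np.arange(n_max + 1)[None, :]
    tab = PropagatorTable(t=t, n0=n0, m0=m0, P=coeff.real.copy())
    tab.max_imag = float(np.max(np.abs(coeff.imag)))
    return tab


def protein_marginal(gf2d, n_max: int, contour: ContourSpec | None = None,
                     t: float = np.nan, n0: int = 0) -> PropagatorTable:
    """Protein marginal of a joint generating function.

    Setting w = 1 sums the mRNA index out of the power series, so the
    marginal needs only a one-dimensional inversion.
    """
    return invert_1d(lambda z: gf2d(1.0, z), n_max, contour, t=t, n0=n0)
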