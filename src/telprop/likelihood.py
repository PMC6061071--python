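"""Transition log-likelihood of a protein time series under a telegraph
model.

A series sampled at a fixed interval dt yields transitions
``n_i -> n_{i+1}``; the log-likelihood of a parameter set is the sum of
``log P_{n_{i+1} | n_i}(dt)`` over the observed transitions.  Propagator
rows are computed once per distinct initial state (a "library" keyed by
parameters, dt and contour) from either the analytic generating functions
(``engine='analytic'``) or the finite-state-projection oracle
(``engine='fsp'``).

The off-state probability chi is re-evaluated from each transition's
initial state in markov mode, since it conditions on the state observed at
the start of the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fsp import FSPConfig, fsp_propagate
from .inversion import ContourSpec, PropagatorTable, default_contour_b, invert_1d
from .model_a import gf_total_a
from .model_b import gf_total_b
from .params import (ChiSpec, InvalidParameterError, ModelAParams,
                     ModelBParams, Regulation, RegulationB, chi_markov,
                     chi_series)
from .ssa import TransitionSeries

__all__ = ["LikelihoodResult", "log_likelihood", "propagator_grid"]

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class LikelihoodResult:
    loglik: float
    per_transition: list
    n_underflow: int
    engine: str


def _chi0_for(params, chi: ChiSpec, m0, n0) -> float:
    return chi_series(chi, params, m0, n0, 0)[0]


def _propagator_row(model: str, params, chi: ChiSpec, n0: int, dt: float,
                    n_max: int, engine: str, m0: int | None,
                    contour: ContourSpec | None,
                    fsp_config: FSPConfig | None) -> np.ndarray:
    if engine == "fsp":
        chi0 = _chi0_for(params, chi, m0, n0)
        init = n0 if model == "A" else (m0 or 0, n0)
        tab = fsp_propagate(model, params, init, chi0, dt, fsp_config)
        P = tab.P if model == "A" else tab.P.sum(axis=0)
        out = np.zeros(n_max + 1)
        k = min(len(P), n_max + 1)
        out[:k] = P[:k]
        return out
    if engine != "analytic":
        raise InvalidParameterError(f"unknown engine {engine!r}")
    if model == "A":
        order = 1 if params.regulation is not Regulation.NONE else 0
        gf = gf_total_a(params, chi, n0, order=order)
        tab = invert_1d(lambda z: np.array([gf(zz, dt)
                                            for zz in np.atleast_1d(z)]),
                        n_max, contour, t=dt, n0=n0)
    else:
        gf = gf_total_b(params, chi, m0 or 0, n0, dt)
        cont = contour or default_contour_b(params.mu)
        tab = invert_1d(lambda z: np.array([gf(1.0, zz)
                                            for zz in np.atleast_1d(z)]),
                        n_max, cont, t=dt, n0=n0)
    if np.min(tab.P) < -1e-6:
        raise ArithmeticError(
            f"propagator row for n0={n0} has negative mass "
            f"{np.min(tab.P):.2e}: the perturbative expansion is inaccurate "
            "here — reduce delta/eps or use engine='fsp'")
    return tab.P


def propagator_grid(model: str, params, chi: ChiSpec, dt: float,
                    n0_set, n_max: int, engine: str = "analytic",
                    m0: int | None = None,
                    contour: ContourSpec | None = None,
                    fsp_config: FSPConfig | None = None,
                    _cache: dict | None = None) -> dict[int, np.ndarray]:
    """One propagator row per initial state in ``n0_set``.

    Rows are cached per (engine, dt, n0) within the supplied cache dict, so
    repeated likelihood evaluations on the same series reuse contour
    samples.
    """
    cache = _cache if _cache is not None else {}
    out = {}
    for n0 in sorted(set(int(n) for n in n0_set)):
        key = (engine, float(dt), n0, n_max)
        if key not in cache:
            cache[key] = _propagator_row(model.upper(), params, chi, n0, dt,
                                         n_max, engine, m0, contour,
                                         fsp_config)
        out[n0] = cache[key]
    return out


def log_likelihood(series: TransitionSeries, model: str, params,
                   chi: ChiSpec | None = None, engine: str = "analytic",
                   m0: int | None = None, n_max: int | None = None,
                   contour: ContourSpec | None = None,
                   fsp_config: FSPConfig | None = None) -> LikelihoodResult:
    """Transition log-likelihood of ``series`` under the given model.

    For the two-stage model only protein is observed; the unobserved initial
    mRNA count of each interval is fixed to ``m0`` (default 0).  Propagator
    values below 1e-300 are floored before the log and counted as
    underflows.
    """
    trans = series.transitions
    if not trans:
        raise InvalidParameterError("series has no transitions")
    if series.dt <= 0:
        raise InvalidParameterError("sampling interval must be positive")
    chi = chi or ChiSpec(mode="markov")
    counts = np.asarray(series.counts, dtype=int)
    if n_max is None:
        n_max = int(counts.max()) + max(10, int(2 * np.sqrt(counts.max() + 1)))
    rows = propagator_grid(model, params, chi, series.dt,
                           counts[:-1], n_max, engine=engine, m0=m0,
                           contour=contour, fsp_config=fsp_config)
    loglik = 0.0
    per = []
    n_under = 0
    for a, b in trans:
        if b > n_max:
            raise InvalidParameterError(
                f"observed count {b} exceeds the propagator table (n_max={n_max})")
        p = float(rows[a][b])
        if p < _P_FLOOR:
            p = _P_FLOOR
            n_under += 1
        lp = float(np.log(p))
        loglik += lp
        per.append((a, b, p, lp))
    return LikelihoodResult(loglik=loglik, per_transition=per,
                            n_underflow=n_under, engine=engine)
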