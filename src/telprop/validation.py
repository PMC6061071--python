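"""End-to-end validation measurements.

Each function runs one of the package's headline checks from scratch —
generating its own inputs, running the analytic pipeline and the
independent oracle, and returning the measured figure of merit.  They are
used by the acceptance test suite and by ``scripts/acceptance.py``; sizes
are desk-scale (seconds to a couple of minutes each).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .closed_forms import binomial_decay, poisson_immigration_death
from .fsp import FSPConfig, fsp_propagate
from .inversion import ContourSpec, default_contour_b, invert_1d, invert_2d
from .likelihood import log_likelihood
from .model_a import eval_gf_a, gf_total_a
from .model_b import eval_gf_b, gf_total_b, leading_closed_form_b
from .params import (ChiSpec, ModelAParams, ModelBParams, Regulation,
                     RegulationB, chi_markov)
from .ssa import empirical_propagator, ssa_simulate, synth_series

__all__ = [
    "telegraph_exactness_a", "normalization_residuals",
    "initial_condition_error", "immigration_death_error",
    "leading_equivalence_b", "binomial_marginal_error", "eps_ladder_b",
    "delta_ladder_a", "delta_ladder_b", "dft_equivalence_errors",
    "ssa_fsp_total_variation", "likelihood_consistency", "loglog_slope",
]

_CHI = ChiSpec(mode="markov")


def loglog_slope(xs, errs) -> float:
    return float(np.polyfit(np.log(xs), np.log(errs), 1)[0])


def telegraph_exactness_a(param_grid=((0.5, 1.0, 2.0), (2.0, 0.3, 5.0),
                                      (1.0, 1.0, 10.0)),
                          n0s=(0, 5, 20), ts=(0.1, 1.0, 5.0)) -> float:
    """Max-abs propagator error of the exact (delta = 0) analytic route
    against the master-equation oracle over a parameter/initial-state/time
    grid."""
    worst = 0.0
    for kf, kb, lam in param_grid:
        p = ModelAParams(kf, kb, lam)
        chi0 = kb / (kf + kb)
        for n0 in n0s:
            for t in ts:
                fsp = fsp_propagate("A", p, n0, chi0, t)
                gf = gf_total_a(p, _CHI, n0)
                tab = invert_1d(lambda z: gf(z, t), len(fsp.P) - 1, t=t)
                worst = max(worst, float(np.max(np.abs(tab.P - fsp.P))))
    return worst


def normalization_residuals() -> dict:
    """Generating-function normalisation at z = 1 and inverted-table mass."""
    p0 = ModelAParams(0.7, 1.3, 3.0)
    ev = eval_gf_a(p0, _CHI, 4, 1.0, 1.2, order=0)
    gf_resid = abs(ev.total_F0 + ev.total_F1 - 1)

    gf = gf_total_a(p0, _CHI, 4)
    mass0 = invert_1d(lambda z: gf(z, 1.2), 45, t=1.2).mass

    preg = ModelAParams(1.0, 1.0, 2.0, Regulation.AUTOACTIVATION,
                        delta=0.05, alpha=1.0)
    ev1 = eval_gf_a(preg, _CHI, 4, 1.0, 1.2, order=1)
    gf1 = gf_total_a(preg, _CHI, 4, order=1)
    mass1 = invert_1d(lambda z: gf1(z, 1.2), 35, t=1.2).mass
    return {"gf_resid_order0": float(gf_resid),
            "order1_z1_resid": float(abs(ev1.total_F0 + ev1.total_F1 - 1)),
            "mass_err_order0": float(abs(mass0 - 1)),
            "mass_err_order1": float(abs(mass1 - 1)),
            "delta": preg.delta}


def initial_condition_error(t: float = 1e-12) -> dict:
    """Inverted propagators at vanishing time concentrate on the initial
    state, for both model families."""
    pa = ModelAParams(0.5, 1.0, 2.0)
    n0 = 5
    gf = gf_total_a(pa, _CHI, n0)
    tab = invert_1d(lambda z: gf(z, t), 30, t=t)
    target = np.zeros(31)
    target[n0] = 1.0
    err_a = float(np.max(np.abs(tab.P - target)))

    pb = ModelBParams(1.0, 1.0, 2.0, 1.0, 0.05)
    m0, n0b = 2, 3
    gfb = gf_total_b(pb, _CHI, m0, n0b, t, eps_order=2)
    tab2 = invert_2d(gfb, 8, 10, default_contour_b(pb.mu), t=t)
    target2 = np.zeros((9, 11))
    target2[m0, n0b] = 1.0
    err_b = float(np.max(np.abs(tab2.P - target2)))
    return {"model_a": err_a, "model_b": err_b}


def immigration_death_error(lam: float = 2.0, t: float = 1.3,
                            n_max: int = 30) -> float:
    """Promoter locked on: analytic propagator vs the closed Poisson pmf.

    With kappa_b = 0 and the promoter started on, the result is independent
    of kappa_f; a non-integer value keeps the Kummer basis away from its
    degenerate parameter set.
    """
    p = ModelAParams(0.7, 0.0, lam)
    chi = ChiSpec(mode="fixed", value=0.0)
    gf = gf_total_a(p, chi, 0)
    tab = invert_1d(lambda z: gf(z, t), n_max, t=t)
    ref = poisson_immigration_death(lam, t, n_max)
    return float(np.max(np.abs(tab.P - ref)))


def leading_equivalence_b(n_points: int = 100, seed: int = 0) -> float:
    """eps-series route at order 0 vs the hand-coded leading closed form on
    random contour points."""
    rng = np.random.default_rng(seed)
    p = ModelBParams(1.0, 1.0, 2.0, 1.0, 0.05)
    chi = ChiSpec(mode="fixed", value=0.4)
    worst = 0.0
    for _ in range(n_points):
        w = np.exp(2j * np.pi * rng.random())
        z = 0.9 * np.exp(2j * np.pi * rng.random())
        t = rng.uniform(0, 2)
        ev = eval_gf_b(p, chi, 2, 3, w, z, t, eps_order=0)
        F0c, F1c = leading_closed_form_b(p, 0.4, 2, 3, w, z, t)
        worst = max(worst, abs(ev.total_F0 - F0c), abs(ev.total_F1 - F1c))
    return float(worst)


def binomial_marginal_error(n0: int = 6, t: float = 0.7) -> float:
    """Zero initial mRNA: the protein marginal is a pure-death binomial."""
    p = ModelBParams(1.0, 1.0, 2.0, 1.0, 0.05)
    gf = gf_total_b(p, _CHI, 0, n0, t, eps_order=0)
    tab = invert_1d(lambda z: gf(1.0, z), n0 + 4, default_contour_b(p.mu),
                    t=t)
    return float(np.max(np.abs(tab.P - binomial_decay(n0, t, n0 + 4))))


def _model_b_error(eps: float, t: float, m0=2, n0=3, eps_order=2) -> float:
    p = ModelBParams(1.0, 1.0, 2.0, 1.0, eps)
    chi0 = chi_markov(p, m0, n0)
    cfg = FSPConfig(m_trunc=16, n_trunc=31)
    fsp = fsp_propagate("B", p, (m0, n0), chi0, t, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gf = gf_total_b(p, _CHI, m0, n0, t, eps_order=eps_order)
        tab = invert_2d(gf, 15, 30, default_contour_b(p.mu), t=t)
    return float(np.max(np.abs(tab.P - fsp.P[:16, :31])))


def eps_ladder_b(eps_values=(0.1, 0.05, 0.025), t: float | None = 1.0,
                 sigma: float | None = None) -> dict:
    """Propagator error vs the master-equation oracle over an eps ladder.

    With ``t`` fixed this probes the composed expansion at a fixed sampling
    interval; with ``sigma`` fixed it probes the fast-time regime the
    expansion is constructed in (t = sigma * eps).
    """
    errs = []
    for eps in eps_values:
        tt = sigma * eps if sigma is not None else t
        errs.append(_model_b_error(eps, tt))
    return {"eps": list(eps_values), "errors": errs,
            "slope": loglog_slope(eps_values, errs)}


def delta_ladder_a(regulation: Regulation,
                   deltas=(0.1, 0.05, 0.025), t: float = 1.0,
                   n0: int = 5) -> dict:
    """Order-1 analytic vs master-equation error over a feedback-strength
    ladder for the one-stage model."""
    kw = {"alpha": 1.0} if regulation is Regulation.AUTOACTIVATION \
        else {"rho": 1.0}
    errs = []
    for d in deltas:
        p = ModelAParams(1.0, 1.0, 2.0, regulation, delta=d, **kw)
        chi0 = chi_markov(p, None, n0)
        fsp = fsp_propagate("A", p, n0, chi0, t)
        gf = gf_total_a(p, _CHI, n0, order=1)
        tab = invert_1d(lambda z: gf(z, t), len(fsp.P) - 1, t=t)
        errs.append(float(np.max(np.abs(tab.P - fsp.P))))
    return {"delta": list(deltas), "errors": errs,
            "slope": loglog_slope(deltas, errs)}


def delta_ladder_b(deltas=(0.1, 0.05, 0.025), eps: float = 0.01,
                   sigma: float = 1.0, m0: int = 4, n0: int = 3) -> dict:
    """Feedback-strength ladder for the two-stage model (mRNA
    autoactivation), in the fast-time regime.

    The measured error is the paired difference
    [P_analytic(delta) - P_analytic(0)] - [P_exact(delta) - P_exact(0)],
    which isolates the feedback response from the (delta-independent)
    eps-truncation error.
    """
    t = sigma * eps
    cfg = FSPConfig(m_trunc=m0 + 14, n_trunc=n0 + 28)

    def tables(p, d_order):
        chi0 = chi_markov(p, m0, n0)
        fsp = fsp_propagate("B", p, (m0, n0), chi0, t, cfg)
        gf = gf_total_b(p, _CHI, m0, n0, t, eps_order=1, delta_order=d_order)
        tab = invert_2d(gf, m0 + 13, n0 + 27, default_contour_b(p.mu), t=t)
        return tab.P, fsp.P[:m0 + 14, :n0 + 28]

    base = ModelBParams(1.0, 1.0, 2.0, 1.0, eps)
    a0, f0 = tables(base, 0)
    errs = []
    for d in deltas:
        p = ModelBParams(1.0, 1.0, 2.0, 1.0, eps, RegulationB.MRNA_ACT,
                         delta=d, reg_coeff=1.0)
        a, f = tables(p, 1)
        errs.append(float(np.max(np.abs((a - a0) - (f - f0)))))
    return {"delta": list(deltas), "errors": errs,
            "slope": loglog_slope(deltas, errs)}


def dft_equivalence_errors() -> dict:
    """Trapezoidal Cauchy sum vs DFT, and closed-form recoveries."""
    rng = np.random.default_rng(1)
    coeffs = rng.random(8)
    gf = lambda z: sum(c * z ** k for k, c in enumerate(coeffs))
    M, r = 64, 0.9
    zs = r * np.exp(2j * np.pi * np.arange(M) / M)
    fft_ref = (np.fft.fft(gf(zs))[:8] / M * r ** -np.arange(8.0)).real
    tab = invert_1d(gf, 7, ContourSpec(radius_z=r, nodes_z=M))
    dft_err = float(np.max(np.abs(tab.P - fft_ref)))

    mono = invert_1d(lambda z: z ** 3, 6)
    target = np.zeros(7)
    target[3] = 1.0
    mono_err = float(np.max(np.abs(mono.P - target)))

    poi = invert_1d(lambda z: np.exp(2.0 * (z - 1)), 30,
                    ContourSpec(nodes_z=64))
    poi_err = float(np.max(np.abs(poi.P - stats.poisson.pmf(np.arange(31),
                                                            2.0))))
    return {"dft": dft_err, "monomial": mono_err, "poisson": poi_err}


def _ssa_configs():
    a = [("A", ModelAParams(1.0, 1.0, 2.0), 3),
         ("A", ModelAParams(1.0, 1.0, 2.0, Regulation.AUTOACTIVATION,
                            delta=0.3, alpha=1.0), 3),
         ("A", ModelAParams(1.0, 1.0, 2.0, Regulation.AUTOREPRESSION,
                            delta=0.3, rho=1.0), 3)]
    b = [("B", ModelBParams(1.0, 1.0, 2.0, 1.0, 0.1, reg,
                            delta=(0.3 if reg is not RegulationB.NONE else 0.0),
                            reg_coeff=(1.0 if reg is not RegulationB.NONE
                                       else 0.0)), (1, 3))
         for reg in RegulationB]
    return a + b


def ssa_fsp_total_variation(n_paths: int = 10000, t: float = 1.0,
                            seed: int = 0) -> list[dict]:
    """Empirical propagators vs the master equation for every reaction
    scheme, including each feedback channel of both models."""
    out = []
    for i, (model, p, init) in enumerate(_ssa_configs()):
        m0 = init[0] if model == "B" else None
        n0 = init[1] if model == "B" else init
        chi0 = chi_markov(p, m0, n0)
        run = ssa_simulate(model, p, init, chi0, t, n_paths,
                           seed=seed + 17 * i + 1, record_times=[t])
        emp = empirical_propagator(run, t)
        fsp = fsp_propagate(model, p, init, chi0, t)
        prot = fsp.P if model == "A" else fsp.P.sum(axis=0)
        K = len(emp.P)
        tv = float(0.5 * np.sum(np.abs(emp.P - prot[:K]))
                   + 0.5 * prot[K:].sum())
        out.append({"model": model, "regulation": p.regulation.value,
                    "tv": tv, "bound": float(3 * np.sqrt(K / n_paths))})
    return out


def likelihood_consistency(seed: int = 11) -> dict:
    """Analytic vs master-equation log-likelihood on synthetic series, and
    finiteness on every generated fixture."""
    pa = ModelAParams(0.5, 1.0, 2.0)
    series = synth_series("A", pa, chi_markov(pa, None, 3), 3, 0.5, 20,
                          seed=seed)
    la = log_likelihood(series, "A", pa, _CHI, engine="analytic").loglik
    lf = log_likelihood(series, "A", pa, _CHI, engine="fsp").loglik

    fixtures_finite = True
    configs = [("A", ModelAParams(1.0, 1.0, 2.0, Regulation.AUTOACTIVATION,
                                  delta=0.05, alpha=1.0), 2, 0.5),
               ("A", ModelAParams(1.0, 1.0, 2.0, Regulation.AUTOREPRESSION,
                                  delta=0.05, rho=1.0), 2, 0.5),
               ("B", ModelBParams(1.0, 1.0, 2.0, 1.0, 0.05), (0, 3), 0.05)]
    logliks = []
    for model, p, init, dt in configs:
        m0 = init[0] if model == "B" else None
        n0 = init[1] if model == "B" else init
        s = synth_series(model, p, chi_markov(p, m0, n0), init, dt, 12,
                         seed=seed + 1)
        res = log_likelihood(s, model, p, _CHI, engine="analytic", m0=m0)
        logliks.append(res.loglik)
        fixtures_finite &= bool(np.isfinite(res.loglik))
    return {"analytic": float(la), "fsp": float(lf),
            "abs_diff": float(abs(la - lf)),
            "fixtures_finite": fixtures_finite,
            "fixture_logliks": logliks}
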