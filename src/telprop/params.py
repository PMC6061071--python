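"""Parameter containers, nondimensional scaling, and the initial off-state
probability chi.

Two model families are supported:

* **Model A** — a telegraph gene (off/on promoter) producing protein directly,
  with optional weak positive (autoactivation) or negative (autorepression)
  feedback of the protein on the promoter.  Time is measured in units of the
  protein lifetime, so all rates are divided by the protein decay rate ``p_d``.

* **Model B** — the two-stage telegraph model with explicit mRNA and protein.
  Time is measured in protein lifetimes (rates divided by ``d_1``); the
  mRNA/protein decay-rate ratio ``gamma = d_0/d_1 = 1/eps`` is assumed large,
  and weak feedback may act through mRNA or protein copy number.

The feedback strength is factored as ``rate = coefficient * decay * delta``
with a small parameter ``0 <= delta < 1``.  By convention the Greek
coefficient (alpha, rho, ...) is stored as 1 and the whole scaled strength is
carried by ``delta``; only the product ever enters the equations.

``chi`` is the probability that the promoter is off at time zero, conditional
on the observed initial copy numbers.  In ``markov`` mode it is computed from
the switching/feedback rates; it can also be held ``fixed`` or supplied as an
explicit ``series`` in delta.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regulation",
    "RegulationB",
    "ChiMode",
    "ModelAParams",
    "ModelBParams",
    "ChiSpec",
    "InvalidParameterError",
    "AssumptionWarning",
    "scale_model_a",
    "scale_model_b",
    "chi_markov",
    "chi_series",
    "params_from_config",
]


class InvalidParameterError(ValueError):
    """Raised for parameter sets outside the model's domain."""


class AssumptionWarning(UserWarning):
    """Emitted when a smallness assumption (delta < 1, eps < 1) is violated.

    The evaluation proceeds, but the perturbative accuracy guarantees no
    longer hold.
    """


class Regulation(str, enum.Enum):
    NONE = "none"
    AUTOACTIVATION = "autoactivation"
    AUTOREPRESSION = "autorepression"


class RegulationB(str, enum.Enum):
    NONE = "none"
    MRNA_ACT = "mRNA_act"
    MRNA_REP = "mRNA_rep"
    PROT_ACT = "prot_act"
    PROT_REP = "prot_rep"


class ChiMode(str, enum.Enum):
    MARKOV = "markov"
    FIXED = "fixed"
    SERIES = "series"


def _check_nonneg(**rates: float) -> None:
    for name, val in rates.items():
        if val < 0:
            raise InvalidParameterError(f"rate {name} must be >= 0, got {val}")


@dataclass(frozen=True)
class ModelAParams:
    """Dimensionless rates of the one-stage autoregulated telegraph model.

    kappa_f, kappa_b : promoter on-/off-switching rates (in protein lifetimes)
    lam              : protein production rate of the active promoter
    regulation       : feedback channel (none / autoactivation / autorepression)
    delta            : scaled feedback strength (feedback rate / p_d)
    alpha, rho       : Greek coefficients of the delta-factorization (kept at 1
                       by convention when the channel is active, 0 otherwise)
    """

    kappa_f: float
    kappa_b: float
    lam: float
    regulation: Regulation = Regulation.NONE
    delta: float = 0.0
    alpha: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        _check_nonneg(kappa_f=self.kappa_f, kappa_b=self.kappa_b, lam=self.lam,
                      delta=self.delta, alpha=self.alpha, rho=self.rho)
        if self.regulation is Regulation.NONE:
            if self.delta != 0.0:
                raise InvalidParameterError("delta must be 0 without regulation")
        else:
            if self.delta >= 1.0:
                warnings.warn(
                    f"scaled feedback strength delta = {self.delta:.4g} >= 1; "
                    "the weak-feedback expansion is outside its stated domain",
                    AssumptionWarning, stacklevel=2)
        if self.regulation is Regulation.AUTOACTIVATION and self.rho != 0.0:
            raise InvalidParameterError("rho is only meaningful for autorepression")
        if self.regulation is Regulation.AUTOREPRESSION and self.alpha != 0.0:
            raise InvalidParameterError("alpha is only meaningful for autoactivation")

    @property
    def reg_strength(self) -> float:
        """delta * (alpha or rho): the full scaled feedback rate."""
        if self.regulation is Regulation.AUTOACTIVATION:
            return self.delta * self.alpha
        if self.regulation is Regulation.AUTOREPRESSION:
            return self.delta * self.rho
        return 0.0


@dataclass(frozen=True)
class ModelBParams:
    """Dimensionless rates of the two-stage (mRNA + protein) telegraph model.

    kappa_0, kappa_1 : promoter on-/off-switching rates (protein lifetimes)
    lam              : transcription rate of the active promoter (nu_0/d_1)
    mu               : translational burst parameter (nu_1/d_0)
    eps              : decay-rate ratio d_1/d_0 = 1/gamma, assumed < 1
    regulation       : feedback channel acting on the promoter
    delta, reg_coeff : weak-feedback factorization (rate = reg_coeff*d_1*delta)
    """

    kappa_0: float
    kappa_1: float
    lam: float
    mu: float
    eps: float
    regulation: RegulationB = RegulationB.NONE
    delta: float = 0.0
    reg_coeff: float = 0.0

    def __post_init__(self):
        _check_nonneg(kappa_0=self.kappa_0, kappa_1=self.kappa_1, lam=self.lam,
                      mu=self.mu, delta=self.delta, reg_coeff=self.reg_coeff)
        if self.eps <= 0:
            raise InvalidParameterError(f"eps must be positive, got {self.eps}")
        if self.mu <= 0:
            raise InvalidParameterError("mu must be positive")
        if self.eps >= 1.0:
            warnings.warn(
                f"time-scale ratio eps = {self.eps:.4g} >= 1; the slow-fast "
                "expansion assumes mRNA decays faster than protein",
                AssumptionWarning, stacklevel=2)
        if self.regulation is RegulationB.NONE and self.delta != 0.0:
            raise InvalidParameterError("delta must be 0 without regulation")
        if self.regulation is not RegulationB.NONE and self.delta >= 1.0:
            warnings.warn(
                f"scaled feedback strength delta = {self.delta:.4g} >= 1",
                AssumptionWarning, stacklevel=2)

    @property
    def gamma(self) -> float:
        return 1.0 / self.eps

    @property
    def reg_strength(self) -> float:
        return self.delta * self.reg_coeff


@dataclass
class ChiSpec:
    """How the initial off-state probability chi is obtained.

    markov : computed from the model's switching and feedback rates
    fixed  : a user-supplied constant in [0, 1]
    series : user-supplied delta-series coefficients (chi_0, chi_1, ...)
    """

    mode: ChiMode = ChiMode.MARKOV
    value: float | None = None
    coefficients: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.mode = ChiMode(self.mode)
        if self.mode is ChiMode.FIXED:
            if self.value is None or not (0.0 <= self.value <= 1.0):
                raise InvalidParameterError("fixed chi requires value in [0, 1]")
        if self.mode is ChiMode.SERIES:
            if not self.coefficients:
                raise InvalidParameterError("series chi requires coefficients")
            if not (0.0 <= self.coefficients[0] <= 1.0):
                raise InvalidParameterError("chi_0 must lie in [0, 1]")


def scale_model_a(c_f: float, c_b: float, p_b: float, p_d: float,
                  reg: Regulation | str = Regulation.NONE,
                  reg_rate: float = 0.0) -> ModelAParams:
    """Nondimensionalise dimensional model-A rates by the protein decay rate.

    ``kappa_f = c_f/p_d``, ``kappa_b = c_b/p_d``, ``lam = p_b/p_d``; the
    feedback rate is factored as ``reg_rate/p_d = delta`` with the Greek
    coefficient set to 1.
    """
    if p_d <= 0:
        raise InvalidParameterError(f"decay rate p_d must be positive, got {p_d}")
    _check_nonneg(c_f=c_f, c_b=c_b, p_b=p_b, reg_rate=reg_rate)
    reg = Regulation(reg)
    delta = reg_rate / p_d if reg is not Regulation.NONE else 0.0
    kwargs = {}
    if reg is Regulation.AUTOACTIVATION:
        kwargs["alpha"] = 1.0
    elif reg is Regulation.AUTOREPRESSION:
        kwargs["rho"] = 1.0
    return ModelAParams(kappa_f=c_f / p_d, kappa_b=c_b / p_d, lam=p_b / p_d,
                        regulation=reg, delta=delta, **kwargs)


def scale_model_b(k_0: float, k_1: float, nu_0: float, nu_1: float,
                  d_0: float, d_1: float,
                  reg: RegulationB | str = RegulationB.NONE,
                  reg_rate: float = 0.0) -> ModelBParams:
    """Nondimensionalise dimensional model-B rates by the protein decay rate."""
    if d_1 <= 0 or d_0 <= 0:
        raise InvalidParameterError("decay rates d_0, d_1 must be positive")
    _check_nonneg(k_0=k_0, k_1=k_1, nu_0=nu_0, nu_1=nu_1, reg_rate=reg_rate)
    reg = RegulationB(reg)
    delta = reg_rate / d_1 if reg is not RegulationB.NONE else 0.0
    return ModelBParams(kappa_0=k_0 / d_1, kappa_1=k_1 / d_1, lam=nu_0 / d_1,
                        mu=nu_1 / d_0, eps=d_1 / d_0, regulation=reg,
                        delta=delta, reg_coeff=1.0 if delta else 0.0)


def _switch_rates(params, m0, n0):
    """(off->on rate, on->off rate) at the initial state, feedback included.

    Returned in dimensionless units; only ratios enter chi.
    """
    if isinstance(params, ModelAParams):
        if n0 is None:
            raise InvalidParameterError("model A needs an initial protein count n0")
        up, down = params.kappa_f, params.kappa_b
        if params.regulation is Regulation.AUTOACTIVATION:
            up = up + params.reg_strength * n0
        elif params.regulation is Regulation.AUTOREPRESSION:
            down = down + params.reg_strength * n0
        return up, down
    up, down = params.kappa_0, params.kappa_1
    reg = params.regulation
    if reg is RegulationB.MRNA_ACT:
        up = up + params.reg_strength * (m0 or 0)
    elif reg is RegulationB.MRNA_REP:
        down = down + params.reg_strength * (m0 or 0)
    elif reg is RegulationB.PROT_ACT:
        up = up + params.reg_strength * n0
    elif reg is RegulationB.PROT_REP:
        down = down + params.reg_strength * n0
    return up, down


def chi_markov(params: ModelAParams | ModelBParams, m0: int | None,
               n0: int) -> float:
    """Off-state probability at t=0 from the promoter's own jump rates.

    With the promoter treated as a two-state Markov chain whose switching
    propensities are evaluated at the observed initial copy numbers, the
    off-state occupancy is ``down / (up + down)``.
    """
    up, down = _switch_rates(params, m0, n0)
    tot = up + down
    if tot == 0:
        raise ZeroDivisionError(
            "all switching and feedback rates vanish; the promoter state is "
            "undefined and chi must be supplied explicitly")
    return down / tot


def chi_series(spec: ChiSpec, params: ModelAParams | ModelBParams,
               m0: int | None, n0: int, order: int) -> tuple[float, ...]:
    """delta-series coefficients (chi_0 .. chi_order) of the off-state
    probability.

    In markov mode the geometric expansion of ``down/(up+down)`` in the weak
    feedback strength is generated; activation perturbs the numerator's
    complement, repression the numerator itself, so the two channels differ
    beyond leading order.  Fixed mode yields (chi, 0, 0, ...).
    """
    if order < 0:
        raise InvalidParameterError("series order must be >= 0")
    if spec.mode is ChiMode.FIXED:
        return (spec.value,) + (0.0,) * order
    if spec.mode is ChiMode.SERIES:
        coeffs = spec.coefficients[:order + 1]
        return tuple(coeffs) + (0.0,) * (order + 1 - len(coeffs))

    if isinstance(params, ModelAParams):
        ks, kd = params.kappa_f, params.kappa_b
        reg = params.regulation
        count = n0
        activating = reg is Regulation.AUTOACTIVATION
        coeff = params.alpha if activating else params.rho
        none = reg is Regulation.NONE
    else:
        ks, kd = params.kappa_0, params.kappa_1
        reg = params.regulation
        none = reg is RegulationB.NONE
        activating = reg in (RegulationB.MRNA_ACT, RegulationB.PROT_ACT)
        count = (m0 or 0) if reg in (RegulationB.MRNA_ACT, RegulationB.MRNA_REP) else n0
        coeff = params.reg_coeff
    tot = ks + kd
    if tot == 0:
        raise ZeroDivisionError("switching rates vanish; chi undefined")
    chi0 = kd / tot
    if none:
        return (chi0,) + (0.0,) * order
    # geometric expansion of (kd [+ d*c*count]) / (tot + d*c*count)
    ratio = -coeff * count / tot
    out = [chi0]
    for m in range(1, order + 1):
        if activating:
            out.append(chi0 * ratio ** m)
        else:
            out.append(-(ks / tot) * ratio ** m)
    return tuple(out)


def _reg_block(block: dict, model: str):
    reg_type = block.get("type", "none")
    rate = float(block.get("rate", 0.0))
    return reg_type, rate


def params_from_config(cfg: dict | str):
    """Build (params, ChiSpec) from a configuration mapping or YAML/JSON text.

    Keys: ``model`` ("A"/"B"), ``dimensionless`` (bool), a ``rates`` block,
    an optional ``regulation`` block (``type``, ``rate`` — the rate is the
    scaled strength delta when dimensionless), and an optional ``chi`` block
    (``mode``, ``value``, ``coefficients``).
    """
    if isinstance(cfg, str):
        import yaml
        cfg = yaml.safe_load(cfg)
    model = str(cfg["model"]).upper()
    rates = cfg["rates"]
    dimless = bool(cfg.get("dimensionless", False))
    reg_type, reg_rate = _reg_block(cfg.get("regulation", {}), model)
    if model == "A":
        if dimless:
            reg = Regulation(reg_type)
            kwargs = {"alpha": 1.0} if reg is Regulation.AUTOACTIVATION else \
                     ({"rho": 1.0} if reg is Regulation.AUTOREPRESSION else {})
            params = ModelAParams(
                kappa_f=float(rates["kappa_f"]), kappa_b=float(rates["kappa_b"]),
                lam=float(rates["lam"]), regulation=reg,
                delta=reg_rate if reg is not Regulation.NONE else 0.0, **kwargs)
        else:
            params = scale_model_a(float(rates["c_f"]), float(rates["c_b"]),
                                   float(rates["p_b"]), float(rates["p_d"]),
                                   reg_type, reg_rate)
    elif model == "B":
        if dimless:
            reg = RegulationB(reg_type)
            params = ModelBParams(
                kappa_0=float(rates["kappa_0"]), kappa_1=float(rates["kappa_1"]),
                lam=float(rates["lam"]), mu=float(rates["mu"]),
                eps=float(rates["eps"]), regulation=reg,
                delta=reg_rate if reg is not RegulationB.NONE else 0.0,
                reg_coeff=1.0 if (reg is not RegulationB.NONE and reg_rate) else 0.0)
        else:
            params = scale_model_b(float(rates["k_0"]), float(rates["k_1"]),
                                   float(rates["nu_0"]), float(rates["nu_1"]),
                                   float(rates["d_0"]), float(rates["d_1"]),
                                   reg_type, reg_rate)
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    chi_cfg = cfg.get("chi", {"mode": "markov"})
    chi = ChiSpec(mode=chi_cfg.get("mode", "markov"),
                  value=chi_cfg.get("value"),
                  coefficients=tuple(chi_cfg.get("coefficients", ())))
    return params, chi


def params_to_dict(params) -> dict:
    """Resolved dimensionless parameter set, for logging."""
    if isinstance(params, ModelAParams):
        return {"model": "A", "kappa_f": params.kappa_f, "kappa_b": params.kappa_b,
                "lam": params.lam, "regulation": params.regulation.value,
                "delta": params.delta, "alpha": params.alpha, "rho": params.rho}
    return {"model": "B", "kappa_0": params.kappa_0, "kappa_1": params.kappa_1,
            "lam": params.lam, "mu": params.mu, "eps": params.eps,
            "regulation": params.regulation.value, "delta": params.delta,
            "reg_coeff": params.reg_coeff}
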