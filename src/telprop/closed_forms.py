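"""Closed-form reference distributions for limiting regimes.

Used as independent oracles in tests: a permanently active promoter reduces
to an immigration-death (Poisson) process, and a two-stage model started
with zero mRNA and no transcription leaves a pure-death binomial for the
initial proteins.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["closed_forms", "poisson_immigration_death", "binomial_decay"]


def poisson_immigration_death(lam: float, t: float, n_max: int,
                              n0: int = 0) -> np.ndarray:
    """Poisson(lam (1 - e^-t)) pmf; exact for a permanently active promoter
    started from n0 = 0."""
    if n0 != 0:
        raise ValueError("closed Poisson form applies to n0 = 0 only")
    mean = lam * (1.0 - np.exp(-t))
    return stats.poisson.pmf(np.arange(n_max + 1), mean)


def binomial_decay(n0: int, t: float, n_max: int | None = None) -> np.ndarray:
    """Binomial(n0, e^-t) pmf: each initial molecule survives independently."""
    n_max = n0 if n_max is None else n_max
    return stats.binom.pmf(np.arange(n_max + 1), n0, np.exp(-t))


def closed_forms(kind: str, params: dict, t: float) -> np.ndarray:
    """Dispatch by name; ``params`` carries the kind-specific values."""
    if kind == "poisson_immigration_death":
        return poisson_immigration_death(params["lam"], t, params["n_max"],
                                         params.get("n0", 0))
    if kind == "binomial_decay":
        return binomial_decay(params["n0"], t, params.get("n_max"))
    raise ValueError(f"unknown closed form {kind!r}")
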