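"""Binomial model of organelle partitioning between daughter cells.

During division, each of the n cytoplasmic PML-body assemblies (CyPNs) of
a cell is assigned independently to one fixed daughter with probability
p_sym; complete asymmetry (all bodies in a single daughter) then occurs
with probability

    P(complete | n) = p_sym^n + (1 - p_sym)^n

which is 2^(1-n) for the fully symmetric p_sym = 0.5.  The module fits
p_sym by maximum likelihood from observed per-daughter counts and tests
for an excess of complete-asymmetric divisions against the binomial null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PartitionModel",
    "p_complete_asym",
    "fit_psym",
    "observed_asym_fraction",
    "asym_excess_test",
]

_P_LO = 1e-6  # lower optimisation bound; p_sym lives in (0, 0.5] by symmetry


@dataclass
class PartitionModel:
    """Fitted partition parameter and its complete-asymmetry curve."""

    p_sym: float
    curve: pd.DataFrame          # columns n, p_complete
    log_likelihood: float
    identifiable: bool           # False when every division has one body
    at_boundary: bool


def p_complete_asym(n, p_sym: float):
    """Probability that all n bodies end up in one daughter.

    Vectorised over ``n``; every n must be >= 1 and p_sym in (0, 1).
    """
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("total body count must be at least 1")
    if not 0.0 < p_sym < 1.0:
        raise ValueError("p_sym must lie strictly between 0 and 1")
    out = p_sym**n + (1.0 - p_sym) ** n
    return float(out) if out.ndim == 0 else out


def _totals_and_flags(data: pd.DataFrame):
    c1 = data["count1"].to_numpy()
    c2 = data["count2"].to_numpy()
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("counts must be non-negative")
    totals = c1 + c2
    keep = totals >= 1  # divisions without detectable bodies are uninformative
    complete = (c1 == 0) | (c2 == 0)
    return totals[keep], complete[keep]


def fit_psym(data: pd.DataFrame, n_max: int | None = None) -> PartitionModel:
    """Maximum-likelihood p_sym from daughter-pair counts.

    The likelihood uses, per division, the Bernoulli indicator of
    complete asymmetry with success probability p_complete_asym(n_i, p);
    the p <-> 1-p symmetry is resolved to the p <= 0.5 branch.  Data in
    which every division has a single body leave the likelihood flat and
    are flagged non-identifiable.
    """
    totals, complete = _totals_and_flags(data)
    if len(totals) == 0:
        raise ValueError("no division with at least one body")
    identifiable = bool(np.any(totals >= 2))

    def nll(p):
        f = p**totals + (1.0 - p) ** totals
        f = np.clip(f, 1e-300, 1.0 - 1e-12)
        return -np.sum(np.where(complete, np.log(f), np.log1p(-f)))

    if identifiable:
        res = minimize_scalar(nll, bounds=(_P_LO, 0.5), method="bounded",
                              options={"xatol": 1e-10})
        p_hat = float(res.x)
        ll = -float(res.fun)
    else:
        p_hat = float("nan")
        ll = 0.0
    at_boundary = identifiable and (p_hat <= 2.0 * _P_LO or p_hat >= 0.5 - 1e-6)

    nm = int(n_max if n_max is not None else max(totals.max(), 1))
    ns = np.arange(1, nm + 1)
    curve_p = (
        p_complete_asym(ns, p_hat) if identifiable else np.full(len(ns), np.nan)
    )
    curve = pd.DataFrame({"n": ns, "p_complete": curve_p})
    return PartitionModel(
        p_sym=p_hat,
        curve=curve,
        log_likelihood=ll,
        identifiable=identifiable,
        at_boundary=at_boundary,
    )


def observed_asym_fraction(data: pd.DataFrame) -> tuple[float, float]:
    """Fraction of divisions with all bodies in one daughter, with its
    binomial standard error; divisions with zero bodies are excluded."""
    totals, complete = _totals_and_flags(data)
    if len(totals) == 0:
        raise ValueError("no division with at least one body")
    f = complete.mean()
    se = np.sqrt(f * (1.0 - f) / len(totals))
    return float(f), float(se)


def asym_excess_test(
    data: pd.DataFrame,
    p_null: float = 0.5,
    n_mc: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Monte-Carlo exceedance probability of the observed number of
    complete-asymmetric divisions under the binomial partition null.

    Complete-asymmetry indicators are resampled per division with
    probability p_complete_asym(n_i, p_null); the returned value is the
    add-one-corrected fraction of resamples whose asymmetric count
    reaches the observed one (small value = significant excess).
    """
    if n_mc < 100:
        raise ValueError("need at least 100 Monte-Carlo resamples")
    totals, complete = _totals_and_flags(data)
    if len(totals) == 0:
        raise ValueError("no division with at least one body")
    observed = int(complete.sum())
    probs = p_complete_asym(totals, p_null)
    rng = np.random.default_rng(seed)
    draws = rng.random((n_mc, len(totals))) < probs
    counts = draws.sum(axis=1)
    return float((1 + np.sum(counts >= observed)) / (n_mc + 1))
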