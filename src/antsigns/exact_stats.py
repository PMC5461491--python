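"""Exact small-sample statistics.

All p-values here are computed from exact finite distributions, never from
normal approximations: the binomial upper tail ("weight of the tail", i.e.
the probability of k **or more** successes in n trials), the binomial point
mass, an exact power-based sample-size search, and an exact Wilcoxon
signed-rank test by full enumeration of the 2^n sign flips (practical for
the n<=15 experiments it is meant for).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, SizeError

__all__ = [
    "BinomialQuery",
    "binom_tail",
    "binom_pmf",
    "binom_sample_size",
    "signed_rank_exact",
    "surface_density",
]


@dataclass(frozen=True)
class BinomialQuery:
    """k successes in n trials against a null per-trial success probability p."""

    k: int
    n: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ParameterError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"null probability p={self.p} outside [0, 1]")


def _as_query(q, n=None, p=None) -> BinomialQuery:
    if isinstance(q, BinomialQuery):
        return q
    return BinomialQuery(int(q), int(n), float(p))


def binom_tail(q, n=None, p=None) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p).

    The observed count is included in the tail (k-or-more successes).
    Accepts either a :class:`BinomialQuery` or ``(k, n, p)``.
    """
    query = _as_query(q, n, p)
    # sf(k-1) = P(X >= k); scipy computes this via the regularized beta
    # function, which is exact to double precision.
    return float(stats.binom.sf(query.k - 1, query.n, query.p))


def binom_pmf(q, n=None, p=None) -> float:
    """Exact point probability P(X = k) for X ~ Binomial(n, p)."""
    query = _as_query(q, n, p)
    return float(stats.binom.pmf(query.k, query.n, query.p))


def binom_sample_size(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    power: float = 0.8,
    max_n: int = 10_000,
) -> dict:
    """Smallest n whose exact one-sided binomial test of p0 reaches the target power.

    For each n the critical count ``k_crit`` is the smallest k with
    P(X >= k | p0) <= alpha; the achieved power is P(X >= k_crit | p1).
    Returns ``{"n": ..., "k_crit": ..., "power": ...}``.
    """
    if not (0.0 < alpha < 1.0) or not (0.0 < power < 1.0):
        raise ParameterError("alpha and power must lie strictly in (0, 1)")
    if not (0.0 <= p0 < p1 <= 1.0):
        raise ParameterError(f"need p0 < p1 in [0, 1], got p0={p0}, p1={p1}")
    for n in range(1, max_n + 1):
        k = np.arange(n + 2)
        tails = stats.binom.sf(k - 1, n, p0)  # P(X >= k) under the null
        admissible = np.nonzero(tails <= alpha)[0]
        if admissible.size == 0:
            continue
        k_crit = int(k[admissible[0]])
        achieved = float(stats.binom.sf(k_crit - 1, n, p1))
        if achieved >= power:
            return {"n": n, "k_crit": k_crit, "power": achieved}
    raise ParameterError(f"no n <= {max_n} reaches power {power}")


def signed_rank_exact(
    differences,
    side: str = "one_sided_greater",
) -> dict:
    """Exact one-sided Wilcoxon signed-rank p-value by 2^n enumeration.

    Ranks the absolute paired differences (midranks on ties), forms the
    positive-rank sum W+, and enumerates the full permutation distribution of
    W+ over all 2^n sign assignments. Zero differences are dropped with a
    warning. Returns ``{"statistic": W+, "p_value": ..., "n": n_used}``.
    """
    if side != "one_sided_greater":
        raise ParameterError(f"unsupported side {side!r}")
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ParameterError("differences must be a non-empty 1-D sequence")
    zeros = d == 0
    if zeros.any():
        warnings.warn(f"dropping {int(zeros.sum())} zero difference(s)", stacklevel=2)
        d = d[~zeros]
    n = d.size
    if n == 0:
        raise ParameterError("all differences are zero")
    if n > 15:
        raise SizeError(
            f"n={n} exceeds the exact 2^n enumeration limit (15); "
            "use scipy.stats.wilcoxon for large samples"
        )
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    # Enumerate all 2^n sign patterns; under H0 each is equally likely.
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w_all = signs @ ranks
    p = float(np.mean(w_all >= w_obs - 1e-12))
    return {"statistic": w_obs, "p_value": p, "n": n}


def surface_density(volume_ul: float, concentration_ng_per_ul: float, area_cm2: float) -> float:
    """Deposited surface density (ng/cm^2) of an extract applied to a floor."""
    if volume_ul <= 0 or concentration_ng_per_ul <= 0:
        raise ParameterError("volume and concentration must be positive")
    if area_cm2 <= 0:
        raise ParameterError(f"area must be positive, got {area_cm2}")
    return volume_ul * concentration_ng_per_ul / area_cm2
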