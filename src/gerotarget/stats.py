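"""Exact-test statistics on 2x2 tables.

Core primitives of the drug-ageing association: the Fisher exact test
(one-sided upper tail, or the two-sided minimum-likelihood rule), the
conditional maximum-likelihood odds ratio of the Fisher noncentral
hypergeometric distribution, and the Benjamini-Yekutieli step-up adjustment
with an explicit total-test count so a head of the smallest p-values can be
adjusted exactly as if the full family had been supplied.

All hypergeometric point probabilities are evaluated in log space (via
log-gamma) so tables with margins in the thousands do not overflow.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

__all__ = [
    "fisher_exact",
    "conditional_mle_odds_ratio",
    "adjust_by",
    "sample_odds_ratio",
]

#: relative slack when comparing point probabilities in the
#: minimum-likelihood two-sided rule, absorbing float rounding of ties
_TWO_SIDED_EPS = 1e-7


def _support(row1: int, col1: int, total: int) -> tuple[int, int]:
    """Support of the table's k cell given margins (row1, col1, total)."""
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    return lo, hi


def fisher_exact(
    k: int, l: int, m: int, n: int, sidedness: str = "greater"
) -> float:
    """Fisher exact test on the 2x2 table [[k, l], [m, n]].

    ``greater`` (default) returns the upper-tail probability
    ``P(X >= k)`` under the central hypergeometric distribution with the
    table's margins fixed — the probability that a drug hits at least as
    many ageing-related terms by chance.  ``two_sided_min_likelihood``
    returns the sum of all point probabilities not exceeding the observed
    table's (with a small relative slack for float ties).

    A degenerate margin (an all-zero row or column) carries no evidence and
    returns p = 1 with a warning.
    """
    for v in (k, l, m, n):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    total = k + l + m + n
    row1, col1 = k + l, k + m
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        warnings.warn("degenerate margin; p = 1", stacklevel=2)
        return 1.0
    if sidedness == "greater":
        # sf(k-1) = P(X >= k), computed by scipy in log space
        return float(min(1.0, hypergeom.sf(k - 1, total, col1, row1)))
    if sidedness == "two_sided_min_likelihood":
        lo, hi = _support(row1, col1, total)
        xs = np.arange(lo, hi + 1)
        logp = hypergeom.logpmf(xs, total, col1, row1)
        log_obs = logp[k - lo]
        keep = logp <= log_obs + math.log1p(_TWO_SIDED_EPS)
        if keep.all():  # observed table is modal: whole support included
            return 1.0
        return float(min(1.0, math.exp(logsumexp(logp[keep]))))
    raise ValueError(f"unknown sidedness {sidedness!r}")


def _log_weights(xs: np.ndarray, row1: int, col1: int, total: int) -> np.ndarray:
    """log C(col1, x) + log C(total-col1, row1-x) over the support."""
    return (
        gammaln(col1 + 1)
        - gammaln(xs + 1)
        - gammaln(col1 - xs + 1)
        + gammaln(total - col1 + 1)
        - gammaln(row1 - xs + 1)
        - gammaln(total - col1 - row1 + xs + 1)
    )


def _noncentral_mean(log_psi: float, xs: np.ndarray, logw: np.ndarray) -> float:
    """E[X] under the Fisher noncentral hypergeometric with odds e^log_psi."""
    logterms = logw + xs * log_psi
    logz = logsumexp(logterms)
    return float(np.exp(logsumexp(logterms, b=xs) - logz))


def conditional_mle_odds_ratio(k: int, l: int, m: int, n: int) -> float:
    """Conditional MLE of the odds ratio for the table [[k, l], [m, n]].

    The estimate is the odds parameter psi of the Fisher noncentral
    hypergeometric distribution that maximises the conditional likelihood
    of k given the margins; because the expected count is strictly
    increasing in psi, it is found by root-finding E_psi[X] = k on the log
    scale.  Returns 0 when k sits at the lower bound of the support and
    +inf at the upper bound; a degenerate margin gives 1 with a warning.
    """
    for v in (k, l, m, n):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    total = k + l + m + n
    row1, col1 = k + l, k + m
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        warnings.warn("degenerate margin; odds ratio = 1", stacklevel=2)
        return 1.0
    lo, hi = _support(row1, col1, total)
    if k == lo:
        return 0.0
    if k == hi:
        return math.inf
    xs = np.arange(lo, hi + 1)
    logw = _log_weights(xs, row1, col1, total)

    def score(log_psi: float) -> float:
        return _noncentral_mean(log_psi, xs, logw) - k

    a, b = -1.0, 1.0
    while score(a) > 0:
        a *= 2
        if a < -500:  # pragma: no cover - guards pathological tables
            return 0.0
    while score(b) < 0:
        b *= 2
        if b > 500:  # pragma: no cover
            return math.inf
    root = brentq(score, a, b, xtol=1e-12, rtol=1e-12)
    return math.exp(root)


def sample_odds_ratio(k: int, l: int, m: int, n: int) -> float:
    """Cross-product (sample) odds ratio k*n / (l*m); inf if l*m == 0."""
    if l * m == 0:
        return math.inf if k * n > 0 else math.nan
    return (k * n) / (l * m)


def adjust_by(
    pvalues: list[float] | np.ndarray, total_tests: int | None = None
) -> list[float]:
    """Benjamini-Yekutieli step-up adjustment.

    With ``m = total_tests`` (default: the list length) and the harmonic
    constant ``c(m) = sum_{i=1..m} 1/i``, the i-th smallest p maps to
    ``min(1, m * c(m) * p_(i) / i)`` followed by the step-up cumulative
    minimum from the largest rank down.  Supplying ``total_tests`` larger
    than the list length adjusts a head of the m smallest p-values exactly
    as the full family would have been: the published adjusted values of a
    significant-results table can be reproduced from the table alone.

    Output order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(total_tests) if total_tests is not None else p.size
    if m < p.size:
        raise ValueError("total_tests must be >= number of p-values")
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    raw = np.minimum(1.0, m * c_m * p[order] / ranks)
    adjusted_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out.tolist()
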