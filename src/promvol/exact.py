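"""Conditional inference for 2x2 tables via Fisher's noncentral hypergeometric
distribution.

Provides the conditional maximum-likelihood odds ratio and the exact
(Cornfield) confidence interval, matching R's ``fisher.test`` and
``scipy.stats.contingency.odds_ratio(kind="conditional")`` but vectorized
over the conditional support, which keeps large tables (cell counts in the
thousands) fast enough for bootstrap/replicate studies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

_LOG_PSI_MAX = 80.0


def _support(table: np.ndarray):
    """Conditional support and log binomial weights given the margins."""
    (a, b), (c, d) = table
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(n1, m1)
    x = np.arange(lo, hi + 1)
    logw = (gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
            + gammaln(n2 + 1) - gammaln(m1 - x + 1) - gammaln(n2 - (m1 - x) + 1))
    return x, logw, a


def _pmf(x, logw, log_psi):
    z = logw + x * log_psi
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def conditional_mle_odds_ratio(table) -> float:
    """Conditional MLE of the odds ratio: solves E[X | psi] = a."""
    table = np.asarray(table, dtype=np.int64)
    x, logw, a = _support(table)
    if a == x[0] and a == x[-1]:
        return np.nan
    if a == x[0]:
        return 0.0
    if a == x[-1]:
        return np.inf

    def mean_minus_a(t):
        return float((x * _pmf(x, logw, t)).sum() - a)

    t = brentq(mean_minus_a, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-11)
    return float(np.exp(t))


def exact_odds_ratio_ci(table, confidence_level: float = 0.95) -> tuple[float, float]:
    """Exact conditional CI: psi_low solves P(X >= a) = alpha/2 and psi_high
    solves P(X <= a) = alpha/2; one-sided at the support edges."""
    table = np.asarray(table, dtype=np.int64)
    x, logw, a = _support(table)
    alpha = 1.0 - confidence_level
    if a == x[0] and a == x[-1]:
        return (np.nan, np.nan)

    def p_ge(t):
        return float(_pmf(x, logw, t)[x >= a].sum())

    def p_le(t):
        return float(_pmf(x, logw, t)[x <= a].sum())

    if a == x[0]:
        low = 0.0
    else:
        low = float(np.exp(brentq(lambda t: p_ge(t) - alpha / 2,
                                  -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-11)))
    if a == x[-1]:
        high = np.inf
    else:
        high = float(np.exp(brentq(lambda t: p_le(t) - alpha / 2,
                                   -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-11)))
    return (low, high)
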