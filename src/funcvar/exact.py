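"""Exact inference for 2x2 contingency tables.

Implements the classical conditional analysis of a 2x2 table with both
margins fixed: the two-sided Fisher exact p-value, the conditional
maximum-likelihood estimate (CMLE) of the odds ratio under the Fisher
noncentral hypergeometric model, and the exact conditional confidence
interval obtained by inverting the one-sided tail tests.  These are the
conventions of R's ``fisher.test`` and of standard exact-test software;
in particular a table with an empty carrier cell yields an unbounded
point estimate together with a finite one-sided confidence bound.

The table is laid out as::

        carrier   non-carrier
 case      a          b
 control   c          d

and all computations condition on the margins (a+b, c+d, a+c).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

# Relative slack when comparing table probabilities against the observed
# one, matching the convention of R and scipy for two-sided p-values.
_REL_EPS = 1.0 + 1e-7


def _support_log_weights(r1: int, r2: int, k: int):
    """Support of the case-carrier count and log central weights.

    With row margins r1 (cases), r2 (controls) and column margin k
    (carriers), the case-carrier count x ranges over
    [max(0, k - r2), min(k, r1)] and the central hypergeometric weight of
    x is C(r1, x) * C(r2, k - x).
    """
    lo = max(0, k - r2)
    hi = min(k, r1)
    x = np.arange(lo, hi + 1)
    lw = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(k - x + 1) - gammaln(r2 - k + x + 1)
    )
    return x, lw


def _validate(a: int, b: int, c: int, d: int) -> None:
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row margins must be positive")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of all conditional table
    probabilities no larger than that of the observed table."""
    _validate(a, b, c, d)
    if a + c == 0 or b + d == 0:
        return 1.0
    x, lw = _support_log_weights(a + b, c + d, a + c)
    lw = lw - lw.max()
    t = np.exp(lw)
    t_obs = t[a - x[0]]
    return float(t[t <= t_obs * _REL_EPS].sum() / t.sum())


def _conditional_moments(x, lw, log_psi: float):
    w = np.exp(lw + x * log_psi - (lw + x * log_psi).max())
    w /= w.sum()
    return float((x * w).sum()), w


def cmle_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio of the Fisher noncentral
    hypergeometric likelihood; 0 / inf at the support boundaries."""
    _validate(a, b, c, d)
    x, lw = _support_log_weights(a + b, c + d, a + c)
    if len(x) == 1:
        return np.nan
    if a == x[0]:
        return 0.0
    if a == x[-1]:
        return np.inf

    def gap(log_psi: float) -> float:
        mean, _ = _conditional_moments(x, lw, log_psi)
        return mean - a

    return float(np.exp(brentq(gap, -60.0, 60.0, xtol=1e-12)))


def _tail_ge(x, lw, a: int, log_psi: float) -> float:
    _, w = _conditional_moments(x, lw, log_psi)
    return float(w[x >= a].sum())


def _tail_le(x, lw, a: int, log_psi: float) -> float:
    _, w = _conditional_moments(x, lw, log_psi)
    return float(w[x <= a].sum())


def exact_or_ci(a: int, b: int, c: int, d: int, level: float = 0.95):
    """Exact conditional confidence interval for the odds ratio.

    Each bound inverts a one-sided exact test at (1 - level)/2, the
    convention of ``fisher.test``: the lower bound solves
    P(X >= a | psi) = alpha/2 and the upper bound P(X <= a | psi) =
    alpha/2.  A count at the support boundary yields a 0 or infinite
    bound on the corresponding side.
    """
    _validate(a, b, c, d)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    x, lw = _support_log_weights(a + b, c + d, a + c)
    if len(x) == 1:
        return (0.0, np.inf)

    if a == x[0]:
        lower = 0.0
    else:
        lower = float(np.exp(
            brentq(lambda lp: _tail_ge(x, lw, a, lp) - alpha, -80.0, 80.0,
                   xtol=1e-12)))
    if a == x[-1]:
        upper = np.inf
    else:
        upper = float(np.exp(
            brentq(lambda lp: _tail_le(x, lw, a, lp) - alpha, -80.0, 80.0,
                   xtol=1e-12)))
    return (lower, upper)


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio a*d / (b*c); inf/nan on zero cells."""
    _validate(a, b, c, d)
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)
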