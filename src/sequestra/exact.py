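"""Exact inference for 2x2 tables under the noncentral hypergeometric model.

Conditioning a 2x2 table on all four margins leaves a single free cell ``a``
whose law is Fisher's noncentral hypergeometric distribution with odds-ratio
parameter psi.  This module implements the three classical exact quantities
reported alongside Fisher's test:

* the two-sided Fisher p-value (minimum-likelihood criterion),
* the conditional maximum-likelihood odds ratio (the psi maximizing the
  conditional likelihood, found by solving the score equation
  ``E_psi[A] = a``),
* the exact central confidence interval obtained by inverting the conditional
  distribution's tail probabilities.

These match the conventions of the standard R ``fisher.test`` output.  A
display-rounding helper implements Cole's "rule of four" for ratios (two
significant digits when the leading digit is 4-9, three otherwise), the
convention used when odds ratios are reported in tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable2x2",
    "ExactTestResult",
    "fisher_exact_p",
    "conditional_mle_or",
    "exact_or_ci",
    "exact_test",
    "cole_round",
    "cole_format",
]

#: relative tolerance used when deciding probability ties in the two-sided p
TIE_RTOL = 1e-7
#: tolerance for the conditional-MLE / CI root finding (on psi, relative)
ROOT_XTOL = 1e-8


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): focal cases/controls vs everyone-else's.

    ``a`` = cases among the focal group, ``b`` = controls among the focal
    group, ``c``/``d`` the same among all other individuals.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table is empty: at least one positive margin needed")

    # margins
    @property
    def r1(self) -> int:  # focal-group size
        return self.a + self.b

    @property
    def r2(self) -> int:
        return self.c + self.d

    @property
    def n1(self) -> int:  # total cases
        return self.a + self.c

    @property
    def n2(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when some margin is zero: the conditional law is a point mass."""
        return min(self.r1, self.r2, self.n1, self.n2) == 0

    @property
    def support(self) -> np.ndarray:
        """Possible values of cell a given the margins."""
        lo = max(0, self.n1 - self.r2)
        hi = min(self.r1, self.n1)
        return np.arange(lo, hi + 1)

    @property
    def sample_odds_ratio(self) -> float:
        """Plain ad/(bc), with the usual 0 / inf boundary conventions."""
        if self.b == 0 or self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _log_base_weights(t: ContingencyTable2x2) -> np.ndarray:
    """log C(r1, k) + log C(r2, n1-k) over the support of k."""
    k = t.support
    return (
        gammaln(t.r1 + 1) - gammaln(k + 1) - gammaln(t.r1 - k + 1)
        + gammaln(t.r2 + 1) - gammaln(t.n1 - k + 1) - gammaln(t.r2 - t.n1 + k + 1)
    )


def _conditional_logpmf(t: ContingencyTable2x2, log_psi: float) -> np.ndarray:
    lw = _log_base_weights(t) + t.support * log_psi
    return lw - logsumexp(lw)


def fisher_exact_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood criterion).

    Sums the central hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed table
    (within relative tolerance 1e-7).  Zero margins give p = 1.
    """
    if t.degenerate:
        return 1.0
    logp = _conditional_logpmf(t, 0.0)
    p = np.exp(logp)
    obs = p[t.support == t.a][0]
    return float(min(1.0, p[p <= obs * (1.0 + TIE_RTOL)].sum()))


def _conditional_mean(t: ContingencyTable2x2, log_psi: float) -> float:
    logp = _conditional_logpmf(t, log_psi)
    return float(np.exp(logsumexp(logp, b=t.support.astype(float))))


def _solve_increasing(f, target: float) -> float:
    """Root of f(log_psi) = target for f strictly increasing in log_psi."""
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) < target:
            break
        lo *= 2.0
    for _ in range(200):
        if f(hi) > target:
            break
        hi *= 2.0
    return brentq(lambda x: f(x) - target, lo, hi, xtol=ROOT_XTOL, rtol=8.9e-16)


def conditional_mle_or(t: ContingencyTable2x2) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves the score equation E_psi[A] = a by bracketed root finding on
    log psi.  ``a`` at the bottom of its support gives 0, at the top +inf;
    degenerate margins give NaN (undefined).
    """
    if t.degenerate:
        return math.nan
    k = t.support
    if t.a == k[0] and t.a == k[-1]:
        return math.nan
    if t.a == k[0]:
        return 0.0
    if t.a == k[-1]:
        return math.inf
    log_psi = _solve_increasing(lambda x: _conditional_mean(t, x), float(t.a))
    return float(math.exp(log_psi))


def _tail_ge(t: ContingencyTable2x2, log_psi: float) -> float:
    """P(A >= a | psi); strictly increasing in psi."""
    logp = _conditional_logpmf(t, log_psi)
    return float(np.exp(logsumexp(logp[t.support >= t.a])))


def _tail_le(t: ContingencyTable2x2, log_psi: float) -> float:
    """P(A <= a | psi); strictly decreasing in psi."""
    logp = _conditional_logpmf(t, log_psi)
    return float(np.exp(logsumexp(logp[t.support <= t.a])))


def exact_or_ci(t: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Exact central confidence interval for the odds ratio.

    The lower bound solves ``P(A >= a | psi) = (1-level)/2`` and the upper
    bound ``P(A <= a | psi) = (1-level)/2``.  ``a`` at the boundary of its
    support gives 0 / +inf endpoints; degenerate margins give (nan, nan).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if t.degenerate:
        return (math.nan, math.nan)
    alpha = (1.0 - level) / 2.0
    k = t.support
    if k[0] == k[-1]:
        return (math.nan, math.nan)
    if t.a == k[0]:
        lo = 0.0
    else:
        lo = math.exp(_solve_increasing(lambda x: _tail_ge(t, x), alpha))
    if t.a == k[-1]:
        hi = math.inf
    else:
        hi = math.exp(_solve_increasing(lambda x: -_tail_le(t, x), -alpha))
    return (lo, hi)


@dataclass(frozen=True)
class ExactTestResult:
    """Bundle of exact 2x2 results for one focal group."""

    table: ContingencyTable2x2
    or_cmle: float
    or_sample: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    method: str = "conditional-MLE / exact central CI / two-sided Fisher"

    @property
    def or_display(self) -> str:
        return cole_format(self.or_cmle)


def exact_test(t: ContingencyTable2x2, level: float = 0.95) -> ExactTestResult:
    lo, hi = exact_or_ci(t, level)
    return ExactTestResult(
        table=t,
        or_cmle=conditional_mle_or(t),
        or_sample=t.sample_odds_ratio,
        ci_low=lo,
        ci_high=hi,
        p_value=fisher_exact_p(t),
        level=level,
    )


def _cole_sig_digits(x: float) -> int:
    lead = int(abs(x) / 10 ** math.floor(math.log10(abs(x))))
    return 2 if lead >= 4 else 3


def cole_round(x: float) -> float:
    """Round a ratio per Cole's rule of four.

    Two significant digits when the leading significant digit is 4-9, three
    when it is 1-3 (so 13.0, 2.94, 0.275 but 4.9, 0.45, 96).  Non-finite and
    non-positive values pass through unchanged.
    """
    if not math.isfinite(x) or x <= 0:
        return x
    sig = _cole_sig_digits(x)
    return float(f"{x:.{sig}g}")


def cole_format(x: float) -> str:
    """Cole-rounded value formatted with its trailing zeros kept (e.g. '1.80')."""
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "Inf"
    if x == 0:
        return "0"
    sig = _cole_sig_digits(x)
    decimals = sig - 1 - math.floor(math.log10(abs(x)))
    rounded = cole_round(x)
    if decimals <= 0:
        return f"{rounded:.0f}"
    return f"{rounded:.{decimals}f}"
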