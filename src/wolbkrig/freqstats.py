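"""Infection-frequency estimation and exact contingency tests.

Per-population wCer2 infection frequency is estimated as the observed
proportion ``k/n`` with a binomial confidence interval (Wilson score by
default, Clopper–Pearson on request), and populations are compared
pairwise — across space or across sampling years — with Fisher's exact
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.proportion import proportion_confint

from .datamodel import PoolingResult, PopulationSample, PopulationTable

__all__ = [
    "FrequencyEstimate",
    "TestResult",
    "wilson_ci",
    "clopper_pearson_ci",
    "estimate_frequency",
    "estimate_table",
    "fisher_exact_2x2",
    "compare_populations",
]

# Relative slack when comparing table probabilities to the observed one in
# the two-sided Fisher rule; guards against floating-point ties.
_FISHER_RELATIVE_SLACK = 1e-7


@dataclass(frozen=True)
class FrequencyEstimate:
    """A binomial proportion with its confidence interval."""

    p_hat: float
    ci_low: float
    ci_high: float
    conf_level: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0:
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket p_hat={self.p_hat}"
            )


@dataclass(frozen=True)
class TestResult:
    """Outcome of an exact 2x2 contingency test."""

    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    method: str = "fisher-exact-two-sided"


def wilson_ci(k: int, n: int, conf_level: float = 0.95, *, method: str = "wilson") -> tuple[float, float]:
    """Confidence interval for a binomial proportion.

    The Wilson score interval inverts the normal approximation to the
    score test: with z the (1+conf)/2 standard-normal quantile the
    interval is centred at (k + z^2/2)/(n + z^2) with half-width
    z*sqrt(p(1-p)/n + z^2/(4n^2))/(1 + z^2/n), clipped to [0, 1]. Pass
    ``method="clopper-pearson"`` for the conservative exact interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf_level, method=sm_method)
    # boundary cases are exact: p_hat = 0 or 1 pins the adjacent bound
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return lo, hi


def clopper_pearson_ci(k: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson ("exact") interval; conservative relative to Wilson."""
    return wilson_ci(k, n, conf_level, method="clopper-pearson")


def estimate_frequency(
    sample: PopulationSample | PoolingResult,
    conf_level: float = 0.95,
    *,
    method: str = "wilson",
) -> FrequencyEstimate:
    """Point estimate k/n with a binomial CI for one population (or pool)."""
    lo, hi = wilson_ci(sample.k, sample.n, conf_level, method=method)
    p = sample.k / sample.n
    return FrequencyEstimate(
        p_hat=p,
        ci_low=min(lo, p),
        ci_high=max(hi, p),
        conf_level=conf_level,
        n=sample.n,
        k=sample.k,
    )


def estimate_table(
    table: PopulationTable, conf_level: float = 0.95, *, method: str = "wilson"
) -> pd.DataFrame:
    """Per-population frequency estimates as a tidy frame (id, year, n, k, p_hat, CI)."""
    rows = []
    for s in table:
        est = estimate_frequency(s, conf_level, method=method)
        rows.append(
            {
                "id": s.id,
                "year": s.year,
                "n": s.n,
                "k": s.k,
                "p_hat": est.p_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows, columns=["id", "year", "n", "k", "p_hat", "ci_low", "ci_high"])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test for the table ``[[a, b], [c, d]]``.

    Conditional on all margins, the first cell follows a hypergeometric
    distribution. The two-sided P-value sums the probabilities of every
    admissible table whose probability does not exceed the observed
    table's (with a tiny relative slack against floating-point ties) —
    the probability-mass definition used by the standard R implementation.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"counts must be nonnegative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("at least one count must be positive")
    m = a + b  # row 1 margin
    total = a + b + c + d
    col1 = a + c
    dist = hypergeom(total, col1, m)
    support = np.arange(max(0, col1 + m - total), min(col1, m) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p_value = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELATIVE_SLACK)].sum())
    return TestResult(p_value=min(p_value, 1.0), table=((a, b), (c, d)))


def compare_populations(
    s1: PopulationSample | PoolingResult, s2: PopulationSample | PoolingResult
) -> TestResult:
    """Fisher exact comparison of two populations' infection frequencies.

    Builds the 2x2 table of (infected, uninfected) counts per population.
    Strictly pairwise: to compare against a region, pool it first.
    """
    return fisher_exact_2x2(s1.k, s1.n - s1.k, s2.k, s2.n - s2.k)


def round_sig(x: float, sig: int = 3) -> float:
    """Half-even rounding to ``sig`` significant figures (display helper)."""
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(float(x)))
    shift = sig - 1 - d.adjusted()
    return float(d.quantize(Decimal(1).scaleb(-shift), rounding=ROUND_HALF_EVEN))
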