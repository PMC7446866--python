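"""Risk-score assignment, weighted group counting, and rate-ratio estimation.

Three schemes turn model-predicted probabilities (and known-case flags) into a
per-person homelessness risk score in [0, 1]:

``threshold_binary``
    the principal analysis: 1 if p >= 0.5 else 0;
``known_override``
    known cases get 1, everyone else keeps their predicted probability;
``known_and_zeroed``
    known cases get 1, unknowns with p < 0.5 get 0, the rest keep p.

Group sizes and death counts are then fractional sums of scores (homeless
mass) and complements 1 - s (non-homeless mass); "inverse of the risk score"
is read as the complement, since a reciprocal would not yield person counts.
Rates are per 100,000 persons and compared as a rate ratio with a log-normal
95% confidence interval, exp(ln RR +/- z * sqrt(1/d1 + 1/d0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SCHEMES",
    "CONVENTIONS",
    "WeightedGroupCounts",
    "RateComparison",
    "assign_risk_scores",
    "weighted_group_counts",
    "rate_per_100k",
    "rate_ratio_ci",
]

SCHEMES = ("threshold_binary", "known_override", "known_and_zeroed")
CONVENTIONS = ("full_sum", "threshold_restricted")

#: two-sided 95% normal quantile
Z_95 = 1.959964


@dataclass(frozen=True)
class WeightedGroupCounts:
    n_homeless: float
    n_nonhomeless: float
    deaths_homeless: float
    deaths_nonhomeless: float
    convention: str

    def __post_init__(self):
        if self.deaths_homeless > self.n_homeless + 1e-9:
            raise ValueError("weighted homeless deaths exceed weighted homeless persons")
        if self.deaths_nonhomeless > self.n_nonhomeless + 1e-9:
            raise ValueError("weighted non-homeless deaths exceed weighted non-homeless persons")


@dataclass
class RateComparison:
    """Per-100,000 rates in the two groups and their ratio with a 95% CI.

    ``ci_low``/``ci_high`` are ``None`` when a CI is undefined (a zero death
    count); an infinite ``rate_ratio`` flags a zero comparison rate.
    """

    rate_homeless: float
    rate_nonhomeless: float
    rate_ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    counts: Optional[WeightedGroupCounts] = None
    scheme: Optional[str] = None

    def summary(self) -> str:
        ci = (
            f"({self.ci_low:.1f}-{self.ci_high:.1f})"
            if self.ci_low is not None
            else "(CI undefined)"
        )
        return (
            f"rate homeless {self.rate_homeless:.1f} vs non-homeless "
            f"{self.rate_nonhomeless:.1f} per 100,000; RR {self.rate_ratio:.1f} {ci}"
        )


def assign_risk_scores(probabilities, known_flags, scheme: str, threshold: float = 0.5) -> np.ndarray:
    """Per-person risk score in [0, 1] under one of the three schemes."""
    p = np.asarray(probabilities, dtype=float)
    known = np.asarray(known_flags).astype(bool)
    if p.shape != known.shape:
        raise ValueError("probabilities and known_flags must be aligned")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if scheme == "threshold_binary":
        return (p >= threshold).astype(float)
    if scheme == "known_override":
        return np.where(known, 1.0, p)
    if scheme == "known_and_zeroed":
        return np.where(known, 1.0, np.where(p < threshold, 0.0, p))
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def weighted_group_counts(
    scores,
    death_flags,
    convention: str = "full_sum",
    threshold: float = 0.5,
) -> WeightedGroupCounts:
    """Fractional group sizes and death counts from risk scores.

    ``full_sum`` (default) sums s and 1-s over *all* persons, so the two group
    sizes partition the sample exactly. ``threshold_restricted`` follows the
    literal two-step description: homeless mass only from scores >= threshold,
    non-homeless mass only from scores < threshold.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(death_flags).astype(float)
    if s.shape != d.shape:
        raise ValueError("scores and death_flags must be aligned")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("risk scores must lie in [0, 1]")
    if convention == "full_sum":
        return WeightedGroupCounts(
            n_homeless=float(s.sum()),
            n_nonhomeless=float((1.0 - s).sum()),
            deaths_homeless=float((s * d).sum()),
            deaths_nonhomeless=float(((1.0 - s) * d).sum()),
            convention=convention,
        )
    if convention == "threshold_restricted":
        hi = s >= threshold
        return WeightedGroupCounts(
            n_homeless=float(s[hi].sum()),
            n_nonhomeless=float((1.0 - s[~hi]).sum()),
            deaths_homeless=float((s[hi] * d[hi]).sum()),
            deaths_nonhomeless=float(((1.0 - s[~hi]) * d[~hi]).sum()),
            convention=convention,
        )
    raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")


def rate_per_100k(deaths: float, n: float) -> float:
    """Crude event rate per 100,000 persons."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if deaths < 0:
        raise ValueError("death count must be non-negative")
    return 100000.0 * deaths / n


def rate_ratio_ci(d1: float, n1: float, d0: float, n0: float, z: float = Z_95) -> RateComparison:
    """Rate ratio (group 1 vs group 0) with a log-normal 95% CI.

    CI = exp(ln RR +/- z * sqrt(1/d1 + 1/d0)); undefined (None) when either
    death count is zero. A zero rate in group 0 yields an infinite RR.
    """
    r1 = rate_per_100k(d1, n1)
    r0 = rate_per_100k(d0, n0)
    rr = math.inf if r0 == 0 else r1 / r0
    if d1 > 0 and d0 > 0 and math.isfinite(rr) and rr > 0:
        se = math.sqrt(1.0 / d1 + 1.0 / d0)
        # fractional weighted deaths near zero can overflow the exponent;
        # the interval is then effectively unbounded
        ci_low = rr * math.exp(-z * se) if z * se < 700 else 0.0
        ci_high = rr * math.exp(z * se) if z * se < 700 else math.inf
    else:
        ci_low = ci_high = None
    return RateComparison(
        rate_homeless=r1,
        rate_nonhomeless=r0,
        rate_ratio=rr,
        ci_low=ci_low,
        ci_high=ci_high,
    )
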