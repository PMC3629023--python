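"""Diagnostic validity of a criteria profile against maternal death.

The criteria set is treated as a diagnostic test (positive = meets at least
one included criterion) for the condition "maternal death", evaluated among
all women who delivered during the study period. Women who were never
registered as cases are test-negative survivors, so the true-negative cell is
inflated by the difference between the population denominator and the number
of case records supplied.

Binomial confidence intervals use the Wilson score interval by default; the
Wald (normal approximation) and Clopper–Pearson (exact) intervals are
selectable. Wilson is the default because the proportions that dominate this
analysis sit at the boundary (0/n false negatives, n/n sensitivity), where
the Wald interval degenerates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CIMethod",
    "ConfusionTable",
    "ValidityMetrics",
    "build_confusion",
    "validity_metrics",
    "binomial_ci",
]


class CIMethod(str, enum.Enum):
    wilson = "wilson"
    wald = "wald"
    clopper_pearson = "clopper_pearson"


_STATSMODELS_METHOD = {
    CIMethod.wilson: "wilson",
    CIMethod.wald: "normal",
    CIMethod.clopper_pearson: "beta",
}


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts: test = criteria-positive, condition = death."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricWithCI:
    """A percentage point estimate with its confidence bounds (all in %)."""

    estimate: Optional[float]
    lower: Optional[float]
    upper: Optional[float]

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "lower": self.lower, "upper": self.upper}


@dataclass(frozen=True)
class ValidityMetrics:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    ci_method: CIMethod
    alpha: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "ppv": self.ppv.to_dict(),
            "npv": self.npv.to_dict(),
            "ci_method": self.ci_method.value,
            "alpha": self.alpha,
        }


def build_confusion(
    test_positive_flags: Sequence[bool],
    death_flags: Sequence[bool],
    total_population: int,
) -> ConfusionTable:
    """Build the 2×2 table over the whole delivered population.

    ``test_positive_flags`` and ``death_flags`` are aligned per supplied case
    record; the ``total_population - len(flags)`` unlisted women count as
    test-negative survivors.
    """
    if len(test_positive_flags) != len(death_flags):
        raise ValueError("flag sequences must be aligned")
    n_cases = len(test_positive_flags)
    if total_population < n_cases:
        raise ValueError(
            f"total_population ({total_population}) smaller than the "
            f"{n_cases} supplied cases"
        )
    tp = fp = fn = tn = 0
    for pos, dead in zip(test_positive_flags, death_flags):
        if pos and dead:
            tp += 1
        elif pos:
            fp += 1
        elif dead:
            fn += 1
        else:
            tn += 1
    tn += total_population - n_cases
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_ci(
    k: int,
    n: int,
    method: CIMethod | str = CIMethod.wilson,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Two-sided (1-alpha) confidence interval for k/n, in percent.

    Bounds are clipped to [0, 100]; only the Wald interval can actually need
    clipping.  At k = 0 (k = n) every supported method has an analytic lower
    (upper) bound of exactly 0 (100), so those bounds are pinned rather than
    carrying floating-point residue from the closed-form evaluation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    method = CIMethod(method)
    lo, hi = proportion_confint(k, n, alpha=alpha, method=_STATSMODELS_METHOD[method])
    lo = 0.0 if k == 0 else max(0.0, 100.0 * lo)
    hi = 100.0 if k == n else min(100.0, 100.0 * hi)
    return (lo, hi)


def _metric(
    k: int, n: int, method: CIMethod, alpha: float
) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(None, None, None)
    lo, hi = binomial_ci(k, n, method, alpha)
    return MetricWithCI(100.0 * k / n, lo, hi)


def validity_metrics(
    ct: ConfusionTable,
    ci_method: CIMethod | str = CIMethod.wilson,
    alpha: float = 0.05,
) -> ValidityMetrics:
    """Sensitivity, specificity, PPV and NPV (in %) with confidence bounds.

    A metric whose denominator is zero is reported as missing (None) rather
    than 0, so degenerate cohorts cannot masquerade as perfect tests.
    """
    method = CIMethod(ci_method)
    return ValidityMetrics(
        sensitivity=_metric(ct.tp, ct.tp + ct.fn, method, alpha),
        specificity=_metric(ct.tn, ct.tn + ct.fp, method, alpha),
        ppv=_metric(ct.tp, ct.tp + ct.fp, method, alpha),
        npv=_metric(ct.tn, ct.tn + ct.fn, method, alpha),
        ci_method=method,
        alpha=alpha,
    )
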