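"""Analytical-validation statistics: sensitivity with exact binomial
confidence intervals, pooled multi-laboratory sensitivity, per-base
specificity, precision (%CV), extraction efficiency and cross-method
allele-fraction concordance."""

from __future__ import annotations

import dataclasses
import decimal
from typing import Sequence

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    pass


def _round_half_up(value: float, places: int = 2) -> float:
    """Display rounding: half-up at ``places`` decimals, via Decimal on the
    shortest repr so 89.725 -> 89.73 rather than falling on a float
    artifact."""
    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal(1).scaleb(-places), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI, returned as percentages.

    The bounds are beta quantiles: lower = B(alpha/2; x, n-x+1), upper =
    B(1-alpha/2; x+1, n-x). x = 0 pins the lower bound at 0%, x = n the
    upper at 100%.
    """
    if not 0 <= x <= n or n < 1:
        raise ValidationError(f"need 0 <= x <= n with n >= 1, got x={x} n={n}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return 100.0 * lower, 100.0 * upper


@dataclasses.dataclass
class SensitivityReport:
    """Sensitivity for one dilution tier / input stratum."""

    label: str
    x: int
    n: int
    level: float = 0.90

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValidationError(f"{self.label}: need 0 <= x <= n")
        if self.level not in (0.90, 0.95):
            raise ValidationError("CI level must be 0.90 or 0.95")

    @property
    def sensitivity_percent(self) -> float:
        return 100.0 * self.x / self.n

    @property
    def ci_percent(self) -> tuple[float, float]:
        return clopper_pearson(self.x, self.n, self.level)


@dataclasses.dataclass
class PooledSensitivity:
    pooled_percent: float
    display_percent: float
    equal_n_assumed: bool
    n_strata: int


def pooled_sensitivity(
    strata: Sequence[tuple[int, int] | float],
) -> PooledSensitivity:
    """Pool per-stratum sensitivities.

    Strata given as (x, n) pairs pool exactly as sum(x)/sum(n); strata
    given as percentages assume equal trial counts (recorded in the
    output) and pool as the plain mean. Display value rounds half-up to
    2 decimals; the full-precision value is kept alongside.
    """
    if not strata:
        raise ValidationError("no strata given")
    is_pair = [isinstance(s, (tuple, list)) for s in strata]
    if all(is_pair):
        xs = sum(int(s[0]) for s in strata)
        ns = sum(int(s[1]) for s in strata)
        if ns == 0:
            raise ValidationError("zero total trials")
        pooled = 100.0 * xs / ns
        equal_n = False
    elif not any(is_pair):
        vals = [decimal.Decimal(repr(float(s))) for s in strata]
        pooled = float(sum(vals) / len(vals))
        equal_n = True
    else:
        raise ValidationError(
            "cannot mix percentage strata with (x, n) strata; supply trial counts"
        )
    return PooledSensitivity(
        pooled_percent=pooled,
        display_percent=_round_half_up(pooled, 2),
        equal_n_assumed=equal_n,
        n_strata=len(strata),
    )


@dataclasses.dataclass
class SpecificityResult:
    specificity_percent: float
    false_positives: int
    n_samples: int
    footprint_bases: int
    denominator: int  # n_samples * footprint_bases, stated explicitly


def per_base_specificity(
    false_positive_calls: int, n_samples: int, footprint_bases: int
) -> SpecificityResult:
    """Cohort per-base specificity: 1 - FP / (samples x interrogated bases)."""
    if min(false_positive_calls, n_samples, footprint_bases) < 0:
        raise ValidationError("counts must be non-negative")
    denominator = n_samples * footprint_bases
    if denominator == 0:
        raise ValidationError("zero denominator (no screened bases)")
    spec = 100.0 * (1.0 - false_positive_calls / denominator)
    return SpecificityResult(
        specificity_percent=spec,
        false_positives=false_positive_calls,
        n_samples=n_samples,
        footprint_bases=footprint_bases,
        denominator=denominator,
    )


def percent_cv(measurements: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sample SD (ddof=1) / mean."""
    values = np.asarray(measurements, dtype=float)
    if values.size < 2:
        raise ValidationError("need >= 2 measurements")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("mean of measurements is zero; %CV undefined")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclasses.dataclass
class ExtractionEfficiency:
    efficiency: float
    over_recovery: bool


def extraction_efficiency(
    measured_copies: float, expected_spiked_copies: float
) -> ExtractionEfficiency:
    """Recovered fraction of a known spike-in; > 1 is flagged, not an error."""
    if expected_spiked_copies <= 0:
        raise ValidationError("expected spiked copies must be positive")
    eff = measured_copies / expected_spiked_copies
    return ExtractionEfficiency(efficiency=float(eff), over_recovery=eff > 1.0)


@dataclasses.dataclass
class ConcordanceSummary:
    mean_signed_difference: float  # mean(A - B)
    ratio_of_means: float  # mean(A) / mean(B)
    pearson_r: float  # nan when either input is constant
    constant_input: bool
    n_pairs: int


def af_concordance(
    pairs: Sequence[tuple[float, float]],
) -> ConcordanceSummary:
    """Agreement of paired allele-fraction measurements from two methods."""
    if len(pairs) < 3:
        raise ValidationError("need at least 3 measurement pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    constant = bool(a.std() == 0 or b.std() == 0)
    if constant:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceSummary(
        mean_signed_difference=float((a - b).mean()),
        ratio_of_means=float(a.mean() / b.mean()) if b.mean() != 0 else float("inf"),
        pearson_r=r,
        constant_input=constant,
        n_pairs=len(pairs),
    )
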