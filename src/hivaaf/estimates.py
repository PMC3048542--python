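"""Point-estimate containers shared across the package.

Every quantity entering the attributable-fraction chain is carried as a
point estimate together with a variance on the scale the arithmetic
happens on (the linear scale).  Published 95% confidence intervals are
converted to variances once, at construction time, under an explicit
distributional assumption:

* proportions — interval symmetric on the linear scale (``normal``);
* ratio measures (RR / OR / HR) — interval symmetric on the log scale
  (``log_normal``), the convention of meta-analytic reporting.

For a log-normally reported ratio X the linear-scale variance follows
from the first-order transform ``Var[X] ≅ X² · Var[ln X]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "Z95",
    "InputValidationError",
    "ConfigurationError",
    "ProportionEstimate",
    "RatioEstimate",
    "FractionEstimate",
]

#: standard-normal 97.5% quantile used for all 95% intervals
Z95 = 1.959964


class InputValidationError(ValueError):
    """An input table cell or estimate violates its domain constraints."""


class ConfigurationError(ValueError):
    """A parameter set or run configuration is incomplete or malformed."""


def _halfwidth_variance(lower: float, upper: float, z: float) -> float:
    # half-width taken as (full width)/2 regardless of where the point
    # estimate sits inside the interval
    return ((upper - lower) / (2.0 * z)) ** 2


@dataclass(frozen=True)
class ProportionEstimate:
    """A prevalence or proportion in [0, 1] with linear-scale variance.

    ``variance = 0`` marks a quantity treated as fixed (no published
    uncertainty), which is the default for drinker prevalences.
    """

    value: float
    lower: float
    upper: float
    variance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.value <= self.upper <= 1.0):
            raise InputValidationError(
                f"proportion bounds must satisfy 0 <= lower <= value <= upper <= 1, "
                f"got lower={self.lower}, value={self.value}, upper={self.upper}"
            )
        if self.variance < 0.0:
            raise InputValidationError(f"variance must be >= 0, got {self.variance}")

    @classmethod
    def fixed(cls, value: float) -> "ProportionEstimate":
        """A proportion with no sampling uncertainty."""
        return cls(value=value, lower=value, upper=value, variance=0.0)

    @classmethod
    def from_interval(
        cls, value: float, lower: float, upper: float, z: float = Z95
    ) -> "ProportionEstimate":
        """Derive the variance from a CI assumed symmetric on the linear scale."""
        return cls(
            value=value,
            lower=lower,
            upper=upper,
            variance=_halfwidth_variance(lower, upper, z),
        )

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def complement(self) -> "ProportionEstimate":
        """1 - p, treated as deterministic given p (no own variance)."""
        return ProportionEstimate(
            value=1.0 - self.value,
            lower=1.0 - self.upper,
            upper=1.0 - self.lower,
            variance=0.0,
        )


@dataclass(frozen=True)
class RatioEstimate:
    """A ratio measure (RR/OR/HR) with variance on both scales.

    ``variance`` is the linear-scale variance consumed by the
    delta-method formulas; ``log_variance`` is Var[ln X], which is
    invariant under ratio inversion and drives log-normal sampling in
    the Monte Carlo oracle.
    """

    value: float
    lower: float
    upper: float
    variance: float = 0.0
    log_variance: float = 0.0
    scale_assumption: str = "log_normal"

    def __post_init__(self) -> None:
        if not (0.0 < self.lower <= self.value <= self.upper):
            raise InputValidationError(
                f"ratio bounds must satisfy 0 < lower <= value <= upper, "
                f"got lower={self.lower}, value={self.value}, upper={self.upper}"
            )
        if self.variance < 0.0 or self.log_variance < 0.0:
            raise InputValidationError("ratio variances must be >= 0")
        if self.scale_assumption not in ("log_normal", "normal"):
            raise InputValidationError(
                f"unknown scale_assumption {self.scale_assumption!r}"
            )

    @classmethod
    def fixed(cls, value: float) -> "RatioEstimate":
        return cls(value=value, lower=value, upper=value)

    @classmethod
    def from_interval(
        cls,
        value: float,
        lower: float,
        upper: float,
        scale_assumption: str = "log_normal",
        z: float = Z95,
    ) -> "RatioEstimate":
        """Derive both variances from a 95% (or other z) confidence interval."""
        if scale_assumption == "log_normal":
            if lower <= 0.0:
                raise InputValidationError(
                    "log_normal scale requires strictly positive bounds"
                )
            log_var = _halfwidth_variance(math.log(lower), math.log(upper), z)
            lin_var = value**2 * log_var
        elif scale_assumption == "normal":
            lin_var = _halfwidth_variance(lower, upper, z)
            log_var = lin_var / value**2
        else:
            raise InputValidationError(f"unknown scale_assumption {scale_assumption!r}")
        return cls(
            value=value,
            lower=lower,
            upper=upper,
            variance=lin_var,
            log_variance=log_var,
            scale_assumption=scale_assumption,
        )

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class FractionEstimate:
    """An attributable-fraction component with a Wald uncertainty interval.

    The interval is ``value ± z·sqrt(variance)`` on the fraction scale and
    is deliberately *not* truncated to [0, 1]: a fraction whose interval
    crosses zero is how a non-significant attributable effect shows up.
    """

    value: float
    variance: float
    ci_lower: float
    ci_upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0.0:
            raise InputValidationError(f"variance must be >= 0, got {self.variance}")
        if not (self.ci_lower <= self.value <= self.ci_upper):
            raise InputValidationError(
                f"interval must bracket the value: "
                f"({self.ci_lower}, {self.value}, {self.ci_upper})"
            )

    @classmethod
    def from_variance(
        cls, value: float, variance: float, label: str = "", z: float = Z95
    ) -> "FractionEstimate":
        half = z * math.sqrt(variance)
        return cls(
            value=value,
            variance=variance,
            ci_lower=value - half,
            ci_upper=value + half,
            label=label,
        )

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def relabel(self, label: str) -> "FractionEstimate":
        return replace(self, label=label)
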