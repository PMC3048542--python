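"""Transforms between published risk measures and the form the AAF math needs.

Published sources report ratio measures in heterogeneous forms: a hazard
ratio with a log-symmetric CI, a protective relative risk that must be
inverted to express the harmful direction, an odds ratio that must be
converted to a relative risk.  This module performs those conversions and
propagates variance through each one with first-order (delta-method)
approximations:

* CI → variance under a normal or log-normal reporting assumption,
* ratio inversion (Var[ln X] is invariant under X → 1/X),
* odds-ratio → relative-risk conversion ``RR = OR / ((1-P) + P·OR)``
  with two-variable propagation,
* the exact variance of a product of independent random variables,
  ``Var[XY] = Var[X]Var[Y] + E[Y]²Var[X] + E[X]²Var[Y]``.

It also loads the bundled risk-parameter table: nonadherence prevalence
among people on antiretroviral therapy (P_na), the nonadherence risk ratio
for current drinkers vs abstainers (RR_drink), the mortality risk ratio
for nonadherence (RR_na), and the mortality hazard ratio for untreated vs
treated patients (HR_nontreat).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .estimates import (
    Z95,
    ConfigurationError,
    InputValidationError,
    ProportionEstimate,
    RatioEstimate,
)

__all__ = [
    "variance_from_interval",
    "invert_ratio",
    "odds_to_risk",
    "product_variance",
    "RiskParameterSet",
    "load_parameters",
    "BUNDLED_PARAMETERS",
]

#: identifier accepted by :func:`load_parameters` for the packaged table
BUNDLED_PARAMETERS = "bundled"

_REQUIRED_PARAMETERS = ("P_na", "RR_drink", "RR_na", "HR_nontreat")


def variance_from_interval(
    value: float,
    lower: float,
    upper: float,
    scale_assumption: str = "log_normal",
    z: float = Z95,
) -> float:
    """Linear-scale variance implied by a confidence interval.

    Under ``normal`` the interval is symmetric on the linear scale and
    ``Var[X] = ((upper - lower) / 2z)²``.  Under ``log_normal`` the
    interval is symmetric on the log scale; ``Var[ln X]`` is computed the
    same way from the log bounds and mapped back via
    ``Var[X] ≅ X² · Var[ln X]``.

    The half-width is taken as (full width)/2, ignoring where the point
    estimate sits, so mildly asymmetric published intervals yield a single
    well-defined variance.
    """
    if lower > upper:
        raise InputValidationError(f"lower bound {lower} exceeds upper bound {upper}")
    if z <= 0.0:
        raise InputValidationError(f"z must be positive, got {z}")
    if scale_assumption == "normal":
        return ((upper - lower) / (2.0 * z)) ** 2
    if scale_assumption == "log_normal":
        if lower <= 0.0:
            raise InputValidationError(
                "log_normal scale requires strictly positive bounds"
            )
        log_var = ((math.log(upper) - math.log(lower)) / (2.0 * z)) ** 2
        return value**2 * log_var
    raise InputValidationError(f"unknown scale_assumption {scale_assumption!r}")


def invert_ratio(est: RatioEstimate) -> RatioEstimate:
    """Invert a ratio measure, X → 1/X, swapping the interval bounds.

    The log-scale variance is unchanged (ln(1/X) = -ln X), and the
    linear-scale variance is re-derived as ``(1/X)² · Var[ln X]``.  Used
    to turn a protective adherence ratio into the harmful nonadherence
    direction, e.g. a treated-vs-untreated mortality rate ratio of 0.38
    into the untreated-vs-treated hazard ratio 2.63.
    """
    if est.value <= 0.0:
        raise InputValidationError(f"cannot invert nonpositive ratio {est.value}")
    inv_value = 1.0 / est.value
    return RatioEstimate(
        value=inv_value,
        lower=1.0 / est.upper,
        upper=1.0 / est.lower,
        variance=inv_value**2 * est.log_variance,
        log_variance=est.log_variance,
        scale_assumption=est.scale_assumption,
    )


def odds_to_risk(or_est: RatioEstimate, p: ProportionEstimate) -> RatioEstimate:
    """Convert an odds ratio to a relative risk given baseline prevalence.

    Uses ``RR = OR / ((1-P) + P·OR)`` where ``P`` is the outcome
    prevalence in the unexposed group.  Variance comes from two-variable
    first-order propagation,

        Var[RR] ≅ D_P² Var[P] + D_OR² Var[OR]

    with partials ``D_OR = (1-P) / ((1-P) + P·OR)²`` and
    ``D_P = OR(1-OR) / ((1-P) + P·OR)²``.  The CI bounds map through the
    conversion at fixed P (the formula is increasing in OR).
    """
    if or_est.value <= 0.0:
        raise InputValidationError("odds ratio must be positive")
    p_val, or_val = p.value, or_est.value

    def _rr(odds: float) -> float:
        return odds / ((1.0 - p_val) + p_val * odds)

    denom = ((1.0 - p_val) + p_val * or_val) ** 2
    d_or = (1.0 - p_val) / denom
    d_p = or_val * (1.0 - or_val) / denom
    variance = d_p**2 * p.variance + d_or**2 * or_est.variance
    rr = _rr(or_val)
    return RatioEstimate(
        value=rr,
        lower=_rr(or_est.lower),
        upper=_rr(or_est.upper),
        variance=variance,
        log_variance=variance / rr**2,
        scale_assumption=or_est.scale_assumption,
    )


def product_variance(
    mean_x: float, var_x: float, mean_y: float, var_y: float
) -> float:
    """Exact variance of a product of two *independent* random variables.

    ``Var[XY] = Var[X]Var[Y] + E[Y]²Var[X] + E[X]²Var[Y]``.  This is the
    identity (not an approximation) when X and Y are independent, and it
    is the building block for the variance of AdAF, NAAAF, and the final
    three-way AAF product.
    """
    if var_x < 0.0 or var_y < 0.0:
        raise InputValidationError("input variances must be >= 0")
    return var_x * var_y + mean_y**2 * var_x + mean_x**2 * var_y


@dataclass(frozen=True)
class RiskParameterSet:
    """The four risk parameters driving the AAF chain.

    Attributes
    ----------
    p_na
        Proportion of people on antiretroviral therapy adhering to fewer
        than 95% of doses.
    rr_drink
        Risk ratio of nonadherence for current drinkers vs abstainers.
    rr_na
        Mortality risk ratio for nonadherent vs adherent patients.
    hr_nontreat
        Mortality hazard ratio for untreated vs treated patients.
    """

    p_na: ProportionEstimate
    rr_drink: RatioEstimate
    rr_na: RatioEstimate
    hr_nontreat: RatioEstimate

    @property
    def nonadherence_among_drinkers(self) -> ProportionEstimate:
        """Prevalence of nonadherence among drinkers.

        No direct estimate is published, so the whole-population
        nonadherence prevalence is used as a conservative stand-in.
        """
        return self.p_na


def _bundled_parameter_document() -> dict:
    text = (
        resources.files("hivaaf").joinpath("data/parameters.json").read_text("utf-8")
    )
    return json.loads(text)


def _coerce_fraction(raw: float, unit: str, context: str) -> float:
    if unit == "percent":
        return raw / 100.0
    if unit == "fraction":
        return raw
    raise ConfigurationError(f"{context}: unknown unit {unit!r}")


def parse_parameter_document(doc: dict, z: float = Z95) -> RiskParameterSet:
    """Build a :class:`RiskParameterSet` from a parsed parameter document."""
    entries = {p.get("name"): p for p in doc.get("parameters", [])}
    missing = [name for name in _REQUIRED_PARAMETERS if name not in entries]
    if missing:
        raise ConfigurationError(
            f"parameter file is missing required parameter(s): {', '.join(missing)}"
        )

    def _ratio(name: str) -> RatioEstimate:
        e = entries[name]
        try:
            return RatioEstimate.from_interval(
                value=float(e["value"]),
                lower=float(e["lower"]),
                upper=float(e["upper"]),
                scale_assumption=e.get("scale_assumption", "log_normal"),
                z=z,
            )
        except KeyError as err:
            raise ConfigurationError(f"parameter {name!r} is missing field {err}")

    e = entries["P_na"]
    unit = e.get("unit", "fraction")
    try:
        p_na = ProportionEstimate.from_interval(
            value=_coerce_fraction(float(e["value"]), unit, "P_na"),
            lower=_coerce_fraction(float(e["lower"]), unit, "P_na"),
            upper=_coerce_fraction(float(e["upper"]), unit, "P_na"),
            z=z,
        )
    except KeyError as err:
        raise ConfigurationError(f"parameter 'P_na' is missing field {err}")

    return RiskParameterSet(
        p_na=p_na,
        rr_drink=_ratio("RR_drink"),
        rr_na=_ratio("RR_na"),
        hr_nontreat=_ratio("HR_nontreat"),
    )


def load_parameters(
    source: Union[str, Path, None] = None, z: float = Z95
) -> RiskParameterSet:
    """Load a risk-parameter set from the bundled table or a JSON/YAML file.

    ``source=None`` (or ``"bundled"``) returns the packaged table.  A path
    ending in ``.yaml``/``.yml`` is parsed as YAML, anything else as JSON;
    both use the same schema: ``{"parameters": [{"name", "value", "lower",
    "upper", "scale_assumption"[, "unit"]}, ...]}``.
    """
    if source is None or source == BUNDLED_PARAMETERS:
        doc = _bundled_parameter_document()
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"parameter file not found: {path}")
        text = path.read_text("utf-8")
        try:
            if path.suffix.lower() in (".yaml", ".yml"):
                doc = yaml.safe_load(text)
            else:
                doc = json.loads(text)
        except (json.JSONDecodeError, yaml.YAMLError) as err:
            raise ConfigurationError(f"cannot parse parameter file {path}: {err}")
        if not isinstance(doc, dict):
            raise ConfigurationError(
                f"parameter file {path} must contain a mapping at top level"
            )
    return parse_parameter_document(doc, z=z)
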