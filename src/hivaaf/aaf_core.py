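"""The stepwise attributable-fraction chain and its delta-method variances.

The alcohol-attributable fraction (AAF) of HIV/AIDS mortality mediated by
nonadherence to antiretroviral therapy is built from three components:

* **AdAF** — the fraction of deaths among treated patients attributable
  to nonadherence, the Levin attributable fraction of nonadherence
  prevalence ``P_na`` and its mortality risk ratio ``RR_na``;
* **NAAAF** — the fraction of nonadherence attributable to current
  drinking, the Levin fraction of drinker prevalence ``P_drink`` and the
  nonadherence risk ratio ``RR_drink``;
* **PDT** — the share of all HIV/AIDS deaths occurring under treatment,
  reconstructed from treatment coverage ``P_treat`` and the untreated
  mortality hazard ratio ``HR_nontreat`` as
  ``P_treat / (P_treat + HR·(1 − P_treat))``.

The final fraction is the product ``AAF = AdAF · NAAAF · PDT``.  Each
component's variance comes from a first-order Taylor expansion in its two
inputs, and the product's variance from the exact independent-product
identity applied twice.  Intervals are Wald-type on the fraction scale
and untruncated, so non-significant strata show intervals crossing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .estimates import (
    Z95,
    ConfigurationError,
    FractionEstimate,
    InputValidationError,
    ProportionEstimate,
    RatioEstimate,
)
from .region_data import RegionRecord
from .risk_transforms import RiskParameterSet, product_variance

__all__ = [
    "levin_af",
    "adherence_af",
    "alcohol_nonadherence_af",
    "treated_death_share",
    "overall_treated_risk",
    "untreated_risk",
    "combine_aaf",
    "StratumResult",
    "compute_stratum",
    "compute_all",
]

logger = logging.getLogger(__name__)


def levin_af(prevalence, relative_risk):
    """Generic (Levin) attributable fraction ``P(RR−1) / (P(RR−1) + 1)``.

    Accepts scalars or numpy arrays; the array form is what the Monte
    Carlo oracle pushes its parameter draws through.
    """
    excess = prevalence * (relative_risk - 1.0)
    return excess / (1.0 + excess)


def _levin_with_variance(
    p: ProportionEstimate, rr: RatioEstimate, label: str, z: float
) -> FractionEstimate:
    # Var[AF] ≅ Var[P·RR] / (1 + P(RR−1))^4, with Var[P·RR] the exact
    # independent-product variance
    value = levin_af(p.value, rr.value)
    denom = 1.0 + p.value * (rr.value - 1.0)
    variance = product_variance(p.value, p.variance, rr.value, rr.variance) / denom**4
    return FractionEstimate.from_variance(value, variance, label=label, z=z)


def adherence_af(
    p_na: ProportionEstimate, rr_na: RatioEstimate, z: float = Z95
) -> FractionEstimate:
    """Fraction of treated-patient deaths attributable to nonadherence (AdAF).

    ``AdAF = P_na(RR_na − 1) / (1 + P_na(RR_na − 1))``, algebraically the
    same as ``(P_adher + P_na·RR_na − 1)/(P_adher + P_na·RR_na)`` with
    ``P_adher = 1 − P_na`` but better conditioned near small fractions.
    The complement ``P_adher`` carries no variance of its own: it is
    deterministic given ``P_na``.
    """
    if rr_na.value <= 0.0:
        raise InputValidationError("RR_na must be positive")
    return _levin_with_variance(p_na, rr_na, "AdAF", z)


def alcohol_nonadherence_af(
    p_drink: ProportionEstimate, rr_drink: RatioEstimate, z: float = Z95
) -> FractionEstimate:
    """Fraction of nonadherence attributable to current drinking (NAAAF)."""
    if rr_drink.value <= 0.0:
        raise InputValidationError("RR_drink must be positive")
    return _levin_with_variance(p_drink, rr_drink, "NAAAF", z)


def treated_death_share(
    p_treat: ProportionEstimate, hr_nontreat: RatioEstimate, z: float = Z95
) -> FractionEstimate:
    """Share of all HIV/AIDS deaths occurring among treated people (PDT).

    ``PDT = P_treat / (P_treat + HR·(1 − P_treat))``; strictly decreasing
    in the hazard ratio and equal to ``P_treat`` when HR = 1.  Variance is
    the two-variable first-order propagation with partials

        D_Ptreat = HR / (P_treat + HR(1 − P_treat))²
        D_HR     = P_treat(1 − P_treat) / (P_treat + HR(1 − P_treat))²

    (each enters squared, so only magnitudes matter).
    """
    if hr_nontreat.value <= 0.0:
        raise InputValidationError("HR_nontreat must be positive")
    pt, hr = p_treat.value, hr_nontreat.value
    if pt == 0.0:
        logger.warning(
            "treatment coverage is 0: no treated deaths, so the "
            "nonadherence-mediated AAF is 0 under this model"
        )
    denom = pt + hr * (1.0 - pt)
    value = pt / denom
    d_pt = hr / denom**2
    d_hr = pt * (1.0 - pt) / denom**2
    variance = d_pt**2 * p_treat.variance + d_hr**2 * hr_nontreat.variance
    return FractionEstimate.from_variance(value, variance, label="PDT", z=z)


def overall_treated_risk(p_na: float, rr_na: float) -> float:
    """Mean mortality risk of the treated population, adherent-treated = 1.

    The adherence-weighted mixture ``1 + P_na(RR_na − 1)`` on the
    arbitrary scale where an adherent treated patient has risk 1; e.g.
    with 40.1% nonadherence and RR_na = 3.13 the treated population sits
    at 1.85.
    """
    if not 0.0 <= p_na <= 1.0:
        raise InputValidationError(f"p_na must be in [0, 1], got {p_na}")
    if rr_na <= 0.0:
        raise InputValidationError(f"rr_na must be positive, got {rr_na}")
    return 1.0 + p_na * (rr_na - 1.0)


def untreated_risk(p_na: float, rr_na: float, hr_nontreat: float) -> float:
    """Mortality risk of the untreated population on the same scale.

    The treated-population mixture times the untreated hazard ratio;
    with the bundled parameters, 1.85 × 2.63 ≈ 4.88.
    """
    if hr_nontreat <= 0.0:
        raise InputValidationError(f"hr_nontreat must be positive, got {hr_nontreat}")
    return overall_treated_risk(p_na, rr_na) * hr_nontreat


def combine_aaf(
    adaf: FractionEstimate,
    naaaf: FractionEstimate,
    pdt: FractionEstimate,
    z: float = Z95,
) -> FractionEstimate:
    """Combine the three components into the final AAF.

    ``AAF = AdAF · NAAAF · PDT``; the variance applies the exact
    independent-product identity twice, first to AdAF·NAAAF and then to
    (AdAF·NAAAF)·PDT.  The interval is ``value ± z·sqrt(variance)``,
    untruncated.
    """
    m12 = adaf.value * naaaf.value
    v12 = product_variance(adaf.value, adaf.variance, naaaf.value, naaaf.variance)
    value = m12 * pdt.value
    variance = product_variance(m12, v12, pdt.value, pdt.variance)
    return FractionEstimate.from_variance(value, variance, label="AAF", z=z)


@dataclass(frozen=True)
class StratumResult:
    """Full AAF decomposition for one region × sex × age-band stratum."""

    region: str
    sex: str
    age_band: str
    adaf: FractionEstimate
    naaaf: FractionEstimate
    pdt: FractionEstimate
    aaf: FractionEstimate


def compute_stratum(
    record: RegionRecord,
    sex: str,
    age_band: str,
    params: RiskParameterSet,
    z: float = Z95,
) -> StratumResult:
    """Run the full chain for one stratum.

    AdAF and PDT depend only on region-level and global parameters, so
    they are identical across the sex × age strata of one region; only
    NAAAF varies with drinker prevalence.
    """
    if params is None:
        raise ConfigurationError("risk parameter set is required")
    p_drink = record.drinker_prevalence(sex, age_band)
    adaf = adherence_af(params.p_na, params.rr_na, z=z)
    naaaf = alcohol_nonadherence_af(p_drink, params.rr_drink, z=z)
    pdt = treated_death_share(record.coverage, params.hr_nontreat, z=z)
    aaf = combine_aaf(adaf, naaaf, pdt, z=z)
    return StratumResult(
        region=record.region,
        sex=sex,
        age_band=age_band,
        adaf=adaf,
        naaaf=naaaf,
        pdt=pdt,
        aaf=aaf,
    )


def compute_all(
    records: Iterable[RegionRecord],
    params: RiskParameterSet,
    z: float = Z95,
    regions: Optional[Sequence[str]] = None,
) -> list[StratumResult]:
    """Run :func:`compute_stratum` over every stratum of the given records.

    ``regions`` optionally restricts to a subset of region names; an
    unknown name raises a :class:`ConfigurationError`.
    """
    records = list(records)
    if regions is not None:
        known = {r.region for r in records}
        unknown = [name for name in regions if name not in known]
        if unknown:
            raise ConfigurationError(f"unknown region(s): {', '.join(unknown)}")
        records = [r for r in records if r.region in set(regions)]
    results = []
    for record in records:
        for sex in record.sexes:
            for band in record.age_bands:
                results.append(compute_stratum(record, sex, band, params, z=z))
    return results
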