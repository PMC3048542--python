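"""Monte Carlo validation of the closed-form (delta-method) variances.

The analytic variances are first-order Taylor approximations, accurate
when each input parameter's coefficient of variation is small.  This
module provides the independent check: sample every input parameter from
its assumed distribution, push each draw through the deterministic
point-estimate chain, and compare the empirical variance and percentile
interval of the resulting AAF draws with the delta-method results.

Sampling models
---------------
* ratios — log-normal with log-mean ``ln(value)`` and log-SD
  ``sqrt(Var[ln X])`` (matching the log-symmetric CI assumption);
* proportions — either a normal truncated (renormalized) to [0, 1]
  with the linear-scale mean/SD (default), or a beta distribution with
  matched mean and variance (``beta_matched``) for sensitivity analysis;
* zero-variance parameters — constant columns;
* all parameters independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Union

import numpy as np
from scipy import stats

from .aaf_core import StratumResult, compute_stratum, levin_af
from .estimates import (
    ConfigurationError,
    FractionEstimate,
    InputValidationError,
    ProportionEstimate,
    RatioEstimate,
    Z95,
)
from .region_data import RegionRecord
from .risk_transforms import RiskParameterSet

__all__ = [
    "McSettings",
    "McResult",
    "ComparisonReport",
    "draw_parameters",
    "mc_aaf",
    "compare",
    "validate_all",
]

logger = logging.getLogger(__name__)

_PROPORTION_MODELS = ("normal_truncated", "beta_matched")


@dataclass(frozen=True)
class McSettings:
    """Simulation settings; the seed is mandatory for reproducibility."""

    seed: int
    n_draws: int = 200_000
    proportion_model: str = "normal_truncated"
    ratio_model: str = "log_normal"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.proportion_model not in _PROPORTION_MODELS:
            raise ConfigurationError(
                f"proportion_model must be one of {_PROPORTION_MODELS}, "
                f"got {self.proportion_model!r}"
            )
        if self.ratio_model != "log_normal":
            raise ConfigurationError("ratio_model is fixed as 'log_normal'")


@dataclass(frozen=True)
class McResult:
    """Empirical moments and percentile interval of the simulated AAF."""

    empirical_mean: float
    empirical_variance: float
    percentile_interval: tuple[float, float]
    n_effective: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.empirical_variance < 0.0:
            raise InputValidationError("empirical variance must be >= 0")
        lo, hi = self.percentile_interval
        if lo > hi:
            raise InputValidationError("percentile interval must be ordered")


def _draw_proportion(
    rng: np.random.Generator, p: ProportionEstimate, model: str, n: int
) -> np.ndarray:
    if p.variance == 0.0:
        return np.full(n, p.value)
    sd = p.sd
    if model == "normal_truncated":
        a, b = (0.0 - p.value) / sd, (1.0 - p.value) / sd
        return stats.truncnorm.rvs(
            a, b, loc=p.value, scale=sd, size=n, random_state=rng
        )
    # beta with matched mean and variance; requires var < m(1-m)
    m, v = p.value, p.variance
    if v >= m * (1.0 - m):
        raise ConfigurationError(
            f"beta_matched needs variance < mean(1-mean); got {v} vs {m * (1 - m)}"
        )
    k = m * (1.0 - m) / v - 1.0
    return rng.beta(m * k, (1.0 - m) * k, size=n)


def _draw_ratio(rng: np.random.Generator, r: RatioEstimate, n: int) -> np.ndarray:
    if r.log_variance == 0.0:
        return np.full(n, r.value)
    return rng.lognormal(np.log(r.value), np.sqrt(r.log_variance), n)


def draw_parameters(
    params: Mapping[str, Union[ProportionEstimate, RatioEstimate]],
    settings: McSettings,
) -> dict[str, np.ndarray]:
    """Sample every named parameter independently from its distribution.

    Columns are drawn in the mapping's iteration order from a single
    generator seeded with ``settings.seed``, so an identical mapping and
    settings always reproduce the identical sample matrix.  Parameters
    with zero variance come back as constant columns.
    """
    rng = np.random.default_rng(settings.seed)
    draws: dict[str, np.ndarray] = {}
    for name, est in params.items():
        if isinstance(est, ProportionEstimate):
            draws[name] = _draw_proportion(
                rng, est, settings.proportion_model, settings.n_draws
            )
        elif isinstance(est, RatioEstimate):
            draws[name] = _draw_ratio(rng, est, settings.n_draws)
        else:
            raise ConfigurationError(
                f"parameter {name!r} is neither a proportion nor a ratio estimate"
            )
    return draws


def mc_aaf(
    record: RegionRecord,
    sex: str,
    age_band: str,
    params: RiskParameterSet,
    settings: McSettings,
) -> McResult:
    """Simulate the AAF for one stratum and summarize its distribution.

    Each draw applies the deterministic chain — Levin fraction for
    adherence, Levin fraction for drinking, treated-death share, triple
    product — to one joint sample of the six input parameters.
    """
    if settings.n_draws < 1000:
        logger.warning(
            "n_draws=%d is below 1000; moment estimates will be noisy",
            settings.n_draws,
        )
    draws = draw_parameters(
        {
            "P_na": params.p_na,
            "RR_na": params.rr_na,
            "RR_drink": params.rr_drink,
            "HR_nontreat": params.hr_nontreat,
            "P_treat": record.coverage,
            "P_drink": record.drinker_prevalence(sex, age_band),
        },
        settings,
    )
    adaf = levin_af(draws["P_na"], draws["RR_na"])
    naaaf = levin_af(draws["P_drink"], draws["RR_drink"])
    pt, hr = draws["P_treat"], draws["HR_nontreat"]
    pdt = pt / (pt + hr * (1.0 - pt))
    aaf = adaf * naaaf * pdt
    lo, hi = np.percentile(aaf, [2.5, 97.5])
    if aaf.size > 1 and not np.all(aaf == aaf[0]):
        variance = float(aaf.var(ddof=1))
    else:
        variance = 0.0  # degenerate inputs: no float summation noise
    return McResult(
        empirical_mean=float(aaf.mean()),
        empirical_variance=variance,
        percentile_interval=(float(lo), float(hi)),
        n_effective=int(aaf.size),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Machine-readable agreement report between analytic and MC variances."""

    analytic_variance: float
    mc_variance: float
    variance_rel_diff: float
    analytic_width: float
    mc_width: float
    width_rel_diff: float
    rel_tol: float
    variance_within: bool
    width_within: bool

    @property
    def passed(self) -> bool:
        return self.variance_within and self.width_within

    def to_dict(self) -> dict:
        return {
            "analytic_variance": self.analytic_variance,
            "mc_variance": self.mc_variance,
            "variance_rel_diff": self.variance_rel_diff,
            "analytic_width": self.analytic_width,
            "mc_width": self.mc_width,
            "width_rel_diff": self.width_rel_diff,
            "rel_tol": self.rel_tol,
            "pass": self.passed,
        }


def _rel_diff(a: float, b: float) -> float:
    """|a - b| relative to the reference b; 0 when both are 0."""
    if b == 0.0:
        return 0.0 if a == 0.0 else float("inf")
    return abs(a - b) / abs(b)


def compare(
    analytic: FractionEstimate, mc: McResult, rel_tol: float = 0.10
) -> ComparisonReport:
    """Compare a delta-method estimate with its Monte Carlo counterpart.

    The MC quantities are the reference in the relative differences.
    Interval widths compare the Wald width ``2z·sqrt(variance)`` against
    the central-percentile width, which also probes the asymmetry the
    delta method cannot represent.
    """
    var_rel = _rel_diff(analytic.variance, mc.empirical_variance)
    an_width = analytic.ci_upper - analytic.ci_lower
    mc_width = mc.percentile_interval[1] - mc.percentile_interval[0]
    width_rel = _rel_diff(an_width, mc_width)
    return ComparisonReport(
        analytic_variance=analytic.variance,
        mc_variance=mc.empirical_variance,
        variance_rel_diff=var_rel,
        analytic_width=an_width,
        mc_width=mc_width,
        width_rel_diff=width_rel,
        rel_tol=rel_tol,
        variance_within=var_rel <= rel_tol,
        width_within=width_rel <= rel_tol,
    )


def validate_all(
    records: Iterable[RegionRecord],
    params: RiskParameterSet,
    settings: McSettings,
    rel_tol: float = 0.10,
    z: float = Z95,
) -> list[dict]:
    """Sweep every stratum: analytic vs Monte Carlo, one report per stratum.

    Per-stratum seeds are derived deterministically from the master seed
    (via :class:`numpy.random.SeedSequence`), so the full sweep is
    reproducible and strata remain independent.
    """
    records = list(records)
    strata = [
        (rec, sex, band)
        for rec in records
        for sex in rec.sexes
        for band in rec.age_bands
    ]
    child_seeds = np.random.SeedSequence(settings.seed).generate_state(len(strata))
    reports = []
    for (rec, sex, band), child in zip(strata, child_seeds):
        stratum_settings = replace(settings, seed=int(child))
        analytic = compute_stratum(rec, sex, band, params, z=z)
        mc = mc_aaf(rec, sex, band, params, stratum_settings)
        report = compare(analytic.aaf, mc, rel_tol=rel_tol)
        reports.append(
            {
                "region": rec.region,
                "sex": sex,
                "age_band": band,
                "analytic_aaf": analytic.aaf.value,
                "mc_mean_aaf": mc.empirical_mean,
                **report.to_dict(),
            }
        )
    return reports
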