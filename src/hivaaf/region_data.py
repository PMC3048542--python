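"""Regional input tables: loading, validation, aggregation and result I/O.

A :class:`RegionRecord` holds one population stratum's inputs — the
antiretroviral treatment coverage of the region and the prevalence of
current drinkers for each sex × age-band cell.  The bundled dataset
(``africa_gbd_2005``) covers the five African Global Burden of Disease
regions with 2005 treatment-coverage and drinking-prevalence data.

Units
-----
Internally every proportion is a fraction in [0, 1].  Input files declare
their unit explicitly: JSON documents carry a top-level ``"unit":
"fraction"|"percent"`` field; CSV files may start with a ``# unit:
percent`` comment line (default ``fraction``).

Country membership of the bundled regions (documentation only; regional
aggregation always goes through explicit user-supplied weights):

* North Africa/Middle East — Algeria, Bahrain, Egypt, Iran, Iraq, Jordan,
  Kuwait, Lebanon, Libya, Morocco, Occupied Palestinian Territory, Oman,
  Qatar, Saudi Arabia, Syria, Tunisia, Turkey, United Arab Emirates,
  Western Sahara, Yemen
* Sub-Saharan Africa, Central — Angola, Central African Republic, Congo,
  the Democratic Republic of the Congo, Equatorial Guinea, Gabon
* Sub-Saharan Africa, East — Burundi, Comoros, Djibouti, Eritrea,
  Ethiopia, Kenya, Madagascar, Malawi, Mayotte, Mozambique, Rwanda,
  Somalia, Sudan, Tanzania, Uganda, Zambia
* Sub-Saharan Africa, South — Botswana, Lesotho, Namibia, South Africa,
  Swaziland, Zimbabwe
* Sub-Saharan Africa, West — Benin, Burkina Faso, Cameroon, Cape Verde,
  Chad, Côte d'Ivoire, Gambia, Ghana, Guinea, Guinea-Bissau, Liberia,
  Mali, Mauritania, Niger, Nigeria, Saint Helena, Sao Tome and Principe,
  Senegal, Sierra Leone, Togo
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .estimates import Z95, InputValidationError, ProportionEstimate

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "BUNDLED_TABLE",
    "RegionRecord",
    "load_region_table",
    "load_region_table_csv",
    "weighted_coverage",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

SEXES = ("men", "women")
AGE_BANDS = ("15-34", "35-54", "55+")

#: identifier accepted by :func:`load_region_table` for the packaged dataset
BUNDLED_TABLE = "africa_gbd_2005"

RESULT_COLUMNS = (
    "region",
    "sex",
    "age_band",
    "adaf",
    "naaaf",
    "pdt",
    "aaf",
    "aaf_variance",
    "ci_lower",
    "ci_upper",
)


@dataclass(frozen=True)
class RegionRecord:
    """One region's inputs: treatment coverage and drinker prevalence cells.

    ``drinkers`` maps ``(sex, age_band)`` to a :class:`ProportionEstimate`.
    Every sex must carry the same set of age bands (a complete grid);
    band labels beyond the bundled ones are accepted as opaque strings.
    """

    region: str
    coverage: ProportionEstimate
    drinkers: Mapping[tuple[str, str], ProportionEstimate]

    def __post_init__(self) -> None:
        if not self.region:
            raise InputValidationError("region name must be nonempty")
        if not self.drinkers:
            raise InputValidationError(
                f"region {self.region!r}: no drinker-prevalence cells"
            )
        sexes = sorted({s for s, _ in self.drinkers})
        bands = sorted({b for _, b in self.drinkers})
        missing = [
            (s, b) for s in sexes for b in bands if (s, b) not in self.drinkers
        ]
        if missing:
            raise InputValidationError(
                f"region {self.region!r}: missing drinker cell(s) {missing}"
            )

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.drinkers}))

    @property
    def age_bands(self) -> tuple[str, ...]:
        # preserve insertion order of first appearance
        seen: list[str] = []
        for _, band in self.drinkers:
            if band not in seen:
                seen.append(band)
        return tuple(seen)

    def drinker_prevalence(self, sex: str, age_band: str) -> ProportionEstimate:
        try:
            return self.drinkers[(sex, age_band)]
        except KeyError:
            raise InputValidationError(
                f"region {self.region!r} has no drinker cell for "
                f"sex={sex!r}, age_band={age_band!r}"
            )


def _to_fraction(raw: float, unit: str, context: str) -> float:
    if unit == "percent":
        return float(raw) / 100.0
    if unit == "fraction":
        return float(raw)
    raise InputValidationError(f"{context}: unknown unit {unit!r}")


def _proportion(
    value: float,
    lower: float | None,
    upper: float | None,
    unit: str,
    context: str,
    z: float,
) -> ProportionEstimate:
    v = _to_fraction(value, unit, context)
    try:
        if lower is None or upper is None:
            return ProportionEstimate.fixed(v)
        return ProportionEstimate.from_interval(
            v,
            _to_fraction(lower, unit, context),
            _to_fraction(upper, unit, context),
            z=z,
        )
    except InputValidationError as err:
        raise InputValidationError(f"{context}: {err}")


def _records_from_document(doc: dict, z: float) -> list[RegionRecord]:
    unit = doc.get("unit", "fraction")
    cov_rows = doc["coverage"]["rows"] if "rows" in doc.get("coverage", {}) else doc.get("coverage", [])
    drink_rows = doc["drinkers"]["rows"] if "rows" in doc.get("drinkers", {}) else doc.get("drinkers", [])

    coverage: dict[str, ProportionEstimate] = {}
    for row in cov_rows:
        region = row.get("region", "")
        if region in coverage:
            raise InputValidationError(f"duplicate coverage row for region {region!r}")
        coverage[region] = _proportion(
            row["value"],
            row.get("lower"),
            row.get("upper"),
            unit,
            f"coverage[{region!r}]",
            z,
        )

    drinkers: dict[str, dict[tuple[str, str], ProportionEstimate]] = {}
    for row in drink_rows:
        region, sex, band = row.get("region", ""), row["sex"], str(row["age_band"])
        cell = f"drinkers[{region!r}, {sex!r}, {band!r}]"
        cells = drinkers.setdefault(region, {})
        if (sex, band) in cells:
            raise InputValidationError(f"duplicate cell {cell}")
        cells[(sex, band)] = _proportion(
            row["value"], row.get("lower"), row.get("upper"), unit, cell, z
        )

    missing_cov = sorted(set(drinkers) - set(coverage))
    missing_drink = sorted(set(coverage) - set(drinkers))
    if missing_cov or missing_drink:
        raise InputValidationError(
            f"coverage and drinker tables disagree on regions: "
            f"no coverage for {missing_cov}, no drinkers for {missing_drink}"
        )
    return [
        RegionRecord(region=r, coverage=coverage[r], drinkers=drinkers[r])
        for r in coverage
    ]


def load_region_table(
    source: Union[str, Path, None] = None, z: float = Z95
) -> list[RegionRecord]:
    """Load region records from the bundled dataset or a JSON document.

    ``source=None`` or ``"africa_gbd_2005"`` loads the packaged table
    (5 regions × 2 sexes × 3 age bands).  Otherwise ``source`` is a path
    to a JSON document with ``unit``, ``coverage`` and ``drinkers`` keys
    (see the bundled file for the schema).  Coverage bounds translate to
    a linear-scale variance via the half-width rule at quantile ``z``.
    """
    if source is None or source == BUNDLED_TABLE:
        text = (
            resources.files("hivaaf")
            .joinpath(f"data/{BUNDLED_TABLE}.json")
            .read_text("utf-8")
        )
        doc = json.loads(text)
    else:
        path = Path(source)
        if not path.exists():
            raise InputValidationError(f"region table not found: {path}")
        doc = json.loads(path.read_text("utf-8"))
    return _records_from_document(doc, z)


def _csv_unit(path: Path) -> str:
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        body = first.lstrip("#").strip()
        if body.lower().startswith("unit:"):
            return body.split(":", 1)[1].strip()
    return "fraction"


def load_region_table_csv(
    coverage_path: Union[str, Path],
    drinkers_path: Union[str, Path],
    z: float = Z95,
) -> list[RegionRecord]:
    """Load region records from the two-file CSV dialect.

    ``coverage_path`` columns: region, lower, value, upper.
    ``drinkers_path`` columns: region, sex, age_band, value[, lower, upper].
    An optional leading ``# unit: percent`` comment line switches the unit
    of either file (default ``fraction``).
    """
    cov_path, drink_path = Path(coverage_path), Path(drinkers_path)
    cov = pd.read_csv(cov_path, comment="#")
    drink = pd.read_csv(drink_path, comment="#")
    doc = {
        "unit": "fraction",  # per-file units handled below
        "coverage": [
            {
                "region": r.region,
                "value": _to_fraction(r.value, _csv_unit(cov_path), "coverage"),
                "lower": _to_fraction(r.lower, _csv_unit(cov_path), "coverage")
                if "lower" in cov.columns and pd.notna(r.lower)
                else None,
                "upper": _to_fraction(r.upper, _csv_unit(cov_path), "coverage")
                if "upper" in cov.columns and pd.notna(r.upper)
                else None,
            }
            for r in cov.itertuples()
        ],
        "drinkers": [
            {
                "region": r.region,
                "sex": r.sex,
                "age_band": r.age_band,
                "value": _to_fraction(r.value, _csv_unit(drink_path), "drinkers"),
                "lower": _to_fraction(r.lower, _csv_unit(drink_path), "drinkers")
                if "lower" in drink.columns and pd.notna(r.lower)
                else None,
                "upper": _to_fraction(r.upper, _csv_unit(drink_path), "drinkers")
                if "upper" in drink.columns and pd.notna(r.upper)
                else None,
            }
            for r in drink.itertuples()
        ],
    }
    return _records_from_document(doc, z)


def weighted_coverage(
    values: Sequence[float], weights: Sequence[float]
) -> float:
    """Population-weighted average of coverage fractions.

    Used to aggregate country-level treatment coverage up to a region,
    ``Σ wᵢvᵢ / Σ wᵢ``.  Weights are typically population counts; they
    need only be nonnegative with a positive sum.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.ndim != 1 or v.shape != w.shape or v.size == 0:
        raise InputValidationError(
            f"values and weights must be equal-length nonempty 1-d sequences, "
            f"got lengths {v.size} and {w.size}"
        )
    if np.any(w < 0.0):
        raise InputValidationError("weights must be nonnegative")
    if not np.any(w > 0.0):
        raise InputValidationError("at least one weight must be positive")
    return float(np.average(v, weights=w))


def results_to_frame(results: Iterable) -> pd.DataFrame:
    """Flatten stratum results into the canonical output table."""
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.region,
                "sex": r.sex,
                "age_band": r.age_band,
                "adaf": r.adaf.value,
                "naaaf": r.naaaf.value,
                "pdt": r.pdt.value,
                "aaf": r.aaf.value,
                "aaf_variance": r.aaf.variance,
                "ci_lower": r.aaf.ci_lower,
                "ci_upper": r.aaf.ci_upper,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results_table(
    results: Sequence, destination: Union[str, Path], format: str = "csv"
) -> None:
    """Write stratum results to CSV or JSON.

    Columns/keys: region, sex, age_band, adaf, naaaf, pdt, aaf,
    aaf_variance, ci_lower, ci_upper.  All fractions are written as
    fractions at full float precision, so a write → read cycle is the
    identity on every numeric field.
    """
    results = list(results)
    if not results:
        raise InputValidationError("cannot write an empty result set")
    frame = results_to_frame(results)
    path = Path(destination)
    if format == "csv":
        # .17g guarantees the written decimal parses back to the same float
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        path.write_text(
            json.dumps(
                {"unit": "fraction", "results": frame.to_dict(orient="records")},
                indent=1,
            ),
            "utf-8",
        )
    else:
        raise InputValidationError(f"unknown output format {format!r}")


def read_results_table(source: Union[str, Path]) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    path = Path(source)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text("utf-8"))
        return pd.DataFrame(doc["results"], columns=list(RESULT_COLUMNS))
    # round_trip: the default fast parser is not correctly rounded
    return pd.read_csv(path, comment="#", float_precision="round_trip")
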