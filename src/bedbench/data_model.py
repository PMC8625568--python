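"""Domain types, CSV input/output and packaged fixtures.

The unit of analysis is a sub-national geographic unit (a U.S. state in the
shipped fixtures): its population, its psychiatric inpatient bed rate per
100,000 residents, three community-mental-health (CMH) service rates
(outpatient clients, residential beds, day programs, each per 100,000), an
adult mental-disability proportion, the percentage of persons 15+ who are
married, and life expectancy at birth.

Rates are stored per 100,000 population throughout; the disability share is
stored as a proportion in [0, 1] so the published U.S. coefficient vector
applies directly.

Packaged fixtures
-----------------
``table1_us`` / ``table1_intl``
    The published coefficient tables (reciprocal-rate scale for the U.S.
    model; the international model is reference-only).
``table2``
    The 50-state benchmark table: actual bed rate, unadjusted and
    CMH-adjusted model estimates, 95% limits and the printed gap label.
``regions``
    The U.S. Census 4-region / 9-division map for the 50 states.
``table4``
    Prior published bed-need estimates, shipped as static reference data.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FixtureLookupError, SchemaError, ValidationError

__all__ = [
    "StateRecord",
    "StateTable",
    "Table2Fixture",
    "read_state_table",
    "write_state_table",
    "load_fixture",
    "census_region_map",
    "DIVISIONS",
    "REGIONS",
]

#: Canonical numeric columns of a state table, in storage order.
NUMERIC_COLUMNS = (
    "population",
    "bed_rate",
    "outpatient_rate",
    "residential_rate",
    "dayprog_rate",
    "disability_pct",
    "married_pct",
    "life_expectancy",
)

COLUMNS = ("name", "division", "region") + NUMERIC_COLUMNS

#: Count-style schema keys convertible to per-100,000 rates via population.
_COUNT_KEYS = {
    "bed_count": "bed_rate",
    "outpatient_count": "outpatient_rate",
    "residential_count": "residential_rate",
    "dayprog_count": "dayprog_rate",
}

DIVISIONS = (
    "New England",
    "Middle Atlantic",
    "East North Central",
    "West North Central",
    "South Atlantic",
    "East South Central",
    "West South Central",
    "Mountain",
    "Pacific",
)

REGIONS = ("Northeast", "Midwest", "South", "West")

_DIVISION_TO_REGION = {
    "New England": "Northeast",
    "Middle Atlantic": "Northeast",
    "East North Central": "Midwest",
    "West North Central": "Midwest",
    "South Atlantic": "South",
    "East South Central": "South",
    "West South Central": "South",
    "Mountain": "West",
    "Pacific": "West",
}


def _fixture_path(filename: str):
    return importlib.resources.files("bedbench.fixtures").joinpath(filename)


def census_region_map() -> pd.DataFrame:
    """Return the 50-state Census division/region map as a DataFrame."""
    with importlib.resources.as_file(_fixture_path("census_regions.csv")) as p:
        return pd.read_csv(p)


@dataclass
class StateRecord:
    """One geographic unit's covariates, population and observed bed rate."""

    name: str
    division: str
    region: str
    population: int
    bed_rate: float
    outpatient_rate: float
    residential_rate: float
    dayprog_rate: float
    disability_pct: float  # proportion in [0, 1]
    married_pct: float  # percent of persons 15+ married, in [0, 100]
    life_expectancy: float  # years from birth

    def validate(self) -> None:
        u = self.name
        if not self.population > 0:
            raise ValidationError(f"{u}: population must be positive, got {self.population}")
        if not self.bed_rate > 0:
            raise ValidationError(
                f"{u}: bed rate must be positive (the reciprocal transform requires it), "
                f"got {self.bed_rate}"
            )
        for col in ("outpatient_rate", "residential_rate", "dayprog_rate"):
            if getattr(self, col) < 0:
                raise ValidationError(f"{u}: {col} must be non-negative")
        if not 0.0 <= self.disability_pct <= 1.0:
            raise ValidationError(
                f"{u}: disability_pct is a proportion and must lie in [0, 1], "
                f"got {self.disability_pct} (divide a percentage by 100)"
            )
        if not 0.0 <= self.married_pct <= 100.0:
            raise ValidationError(f"{u}: married_pct must lie in [0, 100], got {self.married_pct}")
        if not 40.0 <= self.life_expectancy <= 100.0:
            raise ValidationError(
                f"{u}: life_expectancy must lie in [40, 100] years, got {self.life_expectancy}"
            )
        expected = _DIVISION_TO_REGION.get(self.division)
        if expected is None:
            raise ValidationError(f"{u}: unknown Census division {self.division!r}")
        if self.region != expected:
            raise ValidationError(
                f"{u}: division {self.division!r} belongs to region {expected!r}, "
                f"got {self.region!r}"
            )


@dataclass
class StateTable:
    """An ordered collection of :class:`StateRecord` with a vintage label."""

    records: list[StateRecord] = field(default_factory=list)
    vintage: str = "2018"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"unit names must be unique; duplicated: {sorted(dupes)}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Materialize as a DataFrame with the canonical column order."""
        return pd.DataFrame(
            [{f.name: getattr(r, f.name) for f in dataclass_fields(StateRecord)} for r in self.records],
            columns=list(COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, vintage: str = "2018") -> "StateTable":
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        records = [
            StateRecord(
                name=str(row["name"]),
                division=str(row["division"]),
                region=str(row["region"]),
                population=int(row["population"]),
                bed_rate=float(row["bed_rate"]),
                outpatient_rate=float(row["outpatient_rate"]),
                residential_rate=float(row["residential_rate"]),
                dayprog_rate=float(row["dayprog_rate"]),
                disability_pct=float(row["disability_pct"]),
                married_pct=float(row["married_pct"]),
                life_expectancy=float(row["life_expectancy"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls(records=records, vintage=vintage)


@dataclass
class Table2Fixture:
    """The published 50-state benchmark table.

    The printed gap labels are stored verbatim but never trusted downstream:
    the classification step recomputes categories from the printed actual
    rate and interval bounds.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if len(self.frame) != 50:
            raise ValidationError(f"benchmark fixture must have 50 rows, got {len(self.frame)}")
        bad = self.frame[self.frame["ci_low"] >= self.frame["ci_high"]]
        if len(bad):
            raise ValidationError(f"ci_low >= ci_high for: {bad['state'].tolist()}")

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, state: str) -> pd.Series:
        match = self.frame[self.frame["state"] == state]
        if match.empty:
            raise KeyError(state)
        return match.iloc[0]


def _default_schema() -> dict:
    return {c: c for c in COLUMNS}


def read_state_table(path, schema: Mapping[str, str] | None = None, vintage: str = "2018") -> StateTable:
    """Read a state table from CSV.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, header row required).
    schema
        Mapping from canonical field names to CSV column names. Besides the
        canonical fields, three kinds of convenience keys are accepted:
        ``bed_count`` / ``outpatient_count`` / ``residential_count`` /
        ``dayprog_count`` (converted to per-100,000 rates using the mapped
        ``population`` column) and ``disability_percent`` (divided by 100).
        ``division``/``region`` may be omitted when every unit name appears
        in the packaged Census map, from which they are then filled in.
        With ``schema=None`` the CSV is expected to carry the canonical
        column names already.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    schema = dict(schema) if schema is not None else _default_schema()

    for key, csv_col in schema.items():
        if csv_col not in frame.columns:
            raise SchemaError(f"schema maps {key!r} to missing CSV column {csv_col!r}")

    out = pd.DataFrame()
    out["name"] = frame[schema.get("name", "name")] if "name" in schema else None
    if "name" not in schema:
        raise SchemaError("schema must map 'name'")

    if "population" not in schema:
        raise SchemaError("schema must map 'population'")
    out["population"] = pd.to_numeric(frame[schema["population"]], errors="raise")
    if (out["population"] <= 0).any():
        bad = out.loc[out["population"] <= 0, "name"].tolist()
        raise ValidationError(f"non-positive population for: {bad}")

    for count_key, rate_col in _COUNT_KEYS.items():
        if count_key in schema and rate_col in schema:
            raise SchemaError(f"map either {count_key!r} or {rate_col!r}, not both")

    for rate_col in ("bed_rate", "outpatient_rate", "residential_rate", "dayprog_rate"):
        count_key = {v: k for k, v in _COUNT_KEYS.items()}[rate_col]
        if rate_col in schema:
            out[rate_col] = pd.to_numeric(frame[schema[rate_col]], errors="raise")
        elif count_key in schema:
            counts = pd.to_numeric(frame[schema[count_key]], errors="raise")
            out[rate_col] = 1e5 * counts / out["population"]
        else:
            raise SchemaError(f"schema must map {rate_col!r} or {count_key!r}")

    if "disability_pct" in schema:
        out["disability_pct"] = pd.to_numeric(frame[schema["disability_pct"]], errors="raise")
    elif "disability_percent" in schema:
        out["disability_pct"] = pd.to_numeric(frame[schema["disability_percent"]], errors="raise") / 100.0
    else:
        raise SchemaError("schema must map 'disability_pct' (proportion) or 'disability_percent'")

    for col in ("married_pct", "life_expectancy"):
        if col not in schema:
            raise SchemaError(f"schema must map {col!r}")
        out[col] = pd.to_numeric(frame[schema[col]], errors="raise")

    if "division" in schema:
        out["division"] = frame[schema["division"]].astype(str)
        if "region" in schema:
            out["region"] = frame[schema["region"]].astype(str)
        else:
            out["region"] = out["division"].map(_DIVISION_TO_REGION)
    else:
        regions = census_region_map().set_index("state")
        unknown = [n for n in out["name"] if n not in regions.index]
        if unknown:
            raise SchemaError(
                f"no 'division' column mapped and units not in the Census map: {unknown}"
            )
        out["division"] = out["name"].map(regions["division"])
        out["region"] = out["name"].map(regions["region"])

    return StateTable.from_frame(out[list(COLUMNS)], vintage=vintage)


def write_state_table(table: StateTable, path) -> None:
    """Write a state table as CSV with full float precision (round-trip safe)."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table1_us`` / ``table1_intl`` return the published coefficient tables
    as dicts; ``table2`` returns a :class:`Table2Fixture`; ``regions`` and
    ``table4`` return DataFrames. Printed values are shipped bit-exactly.
    """
    if name in ("table1_us", "table1_intl"):
        fn = "coefficients_us.json" if name == "table1_us" else "coefficients_intl.json"
        with importlib.resources.as_file(_fixture_path(fn)) as p:
            with open(p, encoding="utf-8") as fh:
                return json.load(fh)
    if name == "table2":
        with importlib.resources.as_file(_fixture_path("table2_state_benchmarks.csv")) as p:
            return Table2Fixture(pd.read_csv(p))
    if name == "regions":
        return census_region_map()
    if name == "table4":
        with importlib.resources.as_file(_fixture_path("prior_estimates.csv")) as p:
            return pd.read_csv(p)
    raise FixtureLookupError(
        f"unknown fixture {name!r}; expected one of "
        "'table1_us', 'table1_intl', 'table2', 'regions', 'table4'"
    )
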