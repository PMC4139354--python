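"""Historical world-population observation series.

The packaged data set is a compilation of global population estimates for
1--1950 CE from six historical reconstructions plus UN census values for
1955--2012, together with a per-year aggregate column used as the fitting
target for 19 benchmark years between 1750 and 2012.  Values are stored on
disk in millions of people (as published) and converted to persons on load.

The packaged aggregate column is canonical: recomputing per-year means from
the raw records does not reproduce every published aggregate exactly
(duplicate-estimate exclusions in the original compilation are not fully
recoverable), so the aggregate is shipped verbatim and never silently
replaced by a recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "ObservationSeries",
    "load_observations",
    "recompute_average",
    "AGGREGATE_YEARS",
    "ObservationLoadError",
]

MILLION = 1e6

#: the 19 benchmark years carrying a published aggregate value
AGGREGATE_YEARS: tuple[int, ...] = (
    1750, 1800, 1850, 1875, 1900, 1920, 1930, 1940, 1950,
    1955, 1960, 1965, 1970, 1975, 1980, 1985, 1990, 1999, 2012,
)


class ObservationLoadError(ValueError):
    """Raised when an observation CSV is malformed."""


@dataclass(frozen=True)
class ObservationSeries:
    """Sparse year -> population observations with per-year aggregates.

    records : one row per (year, source) with the value in persons.
    aggregate : mapping year -> P-hat in persons, defined only for years
        with a published aggregate.
    """

    records: pd.DataFrame  # columns: year (int), source (str), value (persons)
    aggregate: Mapping[int, float]

    def __post_init__(self) -> None:
        df = self.records
        required = {"year", "source", "value"}
        if not required.issubset(df.columns):
            raise ObservationLoadError(
                f"records must have columns {sorted(required)}, got {list(df.columns)}"
            )
        if len(df) == 0:
            raise ObservationLoadError("observation series is empty")
        bad = df[(df["year"] < 1) | (df["year"] > 2012)]
        if len(bad):
            raise ObservationLoadError(f"years outside [1, 2012]: {sorted(bad['year'])}")
        nonpos = df[df["value"] <= 0]
        if len(nonpos):
            raise ObservationLoadError(
                f"non-positive values for years {sorted(nonpos['year'])}"
            )
        for y, v in self.aggregate.items():
            if v <= 0:
                raise ObservationLoadError(f"non-positive aggregate for year {y}")

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique())

    def aggregate_at(self, year: int) -> float:
        return self.aggregate[year]

    def values_for(self, year: int) -> dict[str, float]:
        sub = self.records[self.records["year"] == year]
        return dict(zip(sub["source"], sub["value"]))

    def to_csv(self, records_path, aggregate_path=None) -> None:
        """Write back in the on-disk dialect (values in millions)."""
        out = self.records.copy()
        out["value_millions"] = out["value"] / MILLION
        out[["year", "source", "value_millions"]].to_csv(records_path, index=False)
        if aggregate_path is not None:
            agg = pd.DataFrame(
                {
                    "year": sorted(self.aggregate),
                    "value_millions": [
                        self.aggregate[y] / MILLION for y in sorted(self.aggregate)
                    ],
                }
            )
            agg.to_csv(aggregate_path, index=False)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("popcap").joinpath("data", name)))


def _read_records(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ObservationLoadError(f"observation file {path} is empty") from None
    required = {"year", "source", "value_millions"}
    if not required.issubset(raw.columns):
        raise ObservationLoadError(
            f"{path}: expected columns {sorted(required)}, got {list(raw.columns)}"
        )
    if len(raw) == 0:
        raise ObservationLoadError(f"{path}: no observation rows")
    for i, row in raw.iterrows():
        try:
            int(row["year"])
            float(row["value_millions"])
        except (TypeError, ValueError):
            raise ObservationLoadError(f"{path}: malformed row {i + 2}: {row.to_dict()}") from None
        if pd.isna(row["value_millions"]) or pd.isna(row["year"]):
            raise ObservationLoadError(f"{path}: missing field in row {i + 2}")
    df = pd.DataFrame(
        {
            "year": raw["year"].astype(int),
            "source": raw["source"].astype(str),
            "value": raw["value_millions"].astype(float) * MILLION,
        }
    )
    return df


def load_observations(
    records_path=None,
    aggregate_path=None,
) -> ObservationSeries:
    """Load an observation series; defaults to the packaged compilation.

    The CSV dialect is ``year, source, value_millions``; the aggregate file
    is ``year, value_millions``.
    """
    if records_path is None:
        records_path = _packaged("table1_observations.csv")
        if aggregate_path is None:
            aggregate_path = _packaged("table1_average.csv")
    records = _read_records(records_path)
    aggregate: dict[int, float] = {}
    if aggregate_path is not None:
        try:
            agg = pd.read_csv(aggregate_path)
        except pd.errors.EmptyDataError:
            raise ObservationLoadError(f"aggregate file {aggregate_path} is empty") from None
        if not {"year", "value_millions"}.issubset(agg.columns):
            raise ObservationLoadError(
                f"{aggregate_path}: expected columns ['year', 'value_millions']"
            )
        aggregate = {
            int(y): float(v) * MILLION
            for y, v in zip(agg["year"], agg["value_millions"])
        }
    return ObservationSeries(records=records, aggregate=aggregate)


def recompute_average(
    records: pd.DataFrame,
    exclusions: Iterable[tuple[int, str]] = (),
) -> dict[int, float]:
    """Arithmetic mean per year after dropping listed (year, source) pairs.

    Non-normative utility: the packaged aggregate column remains the fitting
    target regardless of what this returns.  Years whose every source is
    excluded are absent from the result.
    """
    excl = set(exclusions)
    keep = records[
        ~records.apply(lambda row: (int(row["year"]), row["source"]) in excl, axis=1)
    ]
    return {int(y): float(g["value"].mean()) for y, g in keep.groupby("year")}
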