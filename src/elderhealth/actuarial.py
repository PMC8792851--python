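"""Actuarial aggregation of projected populations into expenditure totals.

Total medical expenditure for a state and year is the projected number
of persons in that state multiplied by the per-capita expenditure of
the state: ``ME_j(t) = N_j(t) * ME_bar_j``, summed over whatever
grouping is requested.  Death (state 5) contributes nothing.

Three bases are exposed.  ``monthly`` multiplies population counts
directly by the *monthly* individual per-capita value — the arithmetic
behind published national totals built this way — while ``annual``
multiplies by twelve times the monthly value and is the economically
meaningful default for new analyses.  A
``family_annual`` basis using the per-household yearly value is also
available.  Totals are nominal yuan; reports print billions at three
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .forecast import ProjectionSeries
from .states import TRANSIENT_STATES

BASES = ("monthly", "annual", "family_annual")

YUAN_PER_BILLION = 1e9


def _per_capita(table: pd.DataFrame, basis: str) -> tuple[pd.Series, float]:
    """Per-capita factor and a scalar multiplier applied after the product.

    The multiplier keeps ``annual`` totals exactly 12 x the ``monthly``
    ones (identical floating-point operations, scaled afterwards).
    """
    if basis == "monthly":
        return table["individual_monthly"], 1.0
    if basis == "annual":
        return table["individual_monthly"], 12.0
    if basis == "family_annual":
        return table["family_annual"], 1.0
    raise ValidationError(f"unknown basis {basis!r}; expected one of {BASES}")


@dataclass
class ForecastResult:
    """Per year (x age group) x state expenditure totals in yuan."""

    data: pd.DataFrame  # columns: year, age_group, state, population, per_capita, total_yuan
    basis: str
    provenance: dict = field(default_factory=dict)

    def total(self, year: int, state: int, age_group: str | None = None) -> float:
        """Total expenditure in yuan (summed over age groups unless given)."""
        sel = (self.data["year"] == year) & (self.data["state"] == state)
        if age_group is not None:
            sel &= self.data["age_group"] == age_group
        if not sel.any():
            raise ValidationError(f"no forecast entry for year {year}, state {state}")
        return float(self.data.loc[sel, "total_yuan"].sum())

    def total_billions(self, year: int, state: int, age_group: str | None = None) -> float:
        return self.total(year, state, age_group) / YUAN_PER_BILLION

    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())


def total_expenditure(
    series: ProjectionSeries,
    table: pd.DataFrame,
    basis: str = "annual",
) -> ForecastResult:
    """Combine a population projection with a per-capita table (Eq. of
    population x per-capita, per state and year).

    ``table`` is a per-state frame (optionally (age_group, state)
    indexed, in which case matching is by both); it must cover states
    1-4 for every cell the projection contains.
    """
    per_capita, multiplier = _per_capita(table, basis)
    pop = series.data[series.data["state"].isin(TRANSIENT_STATES)].copy()

    if isinstance(table.index, pd.MultiIndex):
        keys = list(zip(pop["age_group"], pop["state"]))
        missing = sorted({k for k in keys if k not in per_capita.index})
        if missing:
            raise ValidationError(f"per-capita table missing cells {missing[:5]}")
        pop["per_capita"] = [float(per_capita.loc[k]) for k in keys]
    else:
        missing = sorted(set(pop["state"]) - set(per_capita.index))
        if missing:
            raise ValidationError(f"per-capita table missing states {missing}")
        pop["per_capita"] = pop["state"].map(per_capita).astype(float)

    pop = pop.rename(columns={"count": "population"})
    pop["total_yuan"] = (pop["population"] * pop["per_capita"]) * multiplier
    pop["per_capita"] = pop["per_capita"] * multiplier
    pop = pop.sort_values(["year", "age_group", "state"]).reset_index(drop=True)
    return ForecastResult(
        pop[["year", "age_group", "state", "population", "per_capita", "total_yuan"]],
        basis=basis,
        provenance=dict(series.provenance),
    )


def forecast_from_populations(
    populations: pd.Series,
    table: pd.DataFrame,
    basis: str = "annual",
    year: int = 2035,
    age_group: str = "all",
) -> ForecastResult:
    """Totals from an explicit per-state population vector (persons)."""
    rows = pd.DataFrame(
        {
            "year": year,
            "age_group": age_group,
            "state": populations.index.astype(int),
            "count": populations.to_numpy(dtype=float),
        }
    )
    return total_expenditure(ProjectionSeries(rows), table, basis=basis)


def expenditure_gap(result: ForecastResult, year: int, state_a: int, state_b: int) -> float:
    """total(state_a) - total(state_b) at ``year``, in yuan."""
    return result.total(year, state_a) - result.total(year, state_b)


def expenditure_change(
    result_t1: ForecastResult,
    result_t2: ForecastResult,
    state: int,
    age_group: str | None = None,
    year_t1: int | None = None,
    year_t2: int | None = None,
) -> float:
    """Change in total expenditure between two forecast results, in yuan.

    If a result covers several years the year must be named explicitly.
    Both results must share the same basis (units).
    """
    if result_t1.basis != result_t2.basis:
        raise ValidationError(
            f"basis mismatch: {result_t1.basis!r} vs {result_t2.basis!r}"
        )

    def _year(result: ForecastResult, year: int | None) -> int:
        if year is not None:
            return year
        years = result.years()
        if len(years) != 1:
            raise ValidationError("result spans several years; pass the year explicitly")
        return years[0]

    y1, y2 = _year(result_t1, year_t1), _year(result_t2, year_t2)
    return result_t2.total(y2, state, age_group) - result_t1.total(y1, state, age_group)


def render_report(result: ForecastResult, path: str | Path) -> pd.DataFrame:
    """Write the forecast as CSV: yuan internally, billions at 3 dp added.

    Rows are ordered (year, age_group, state) so repeated runs produce
    identical files.
    """
    out = result.data.copy()
    out["basis"] = result.basis
    out["total_billions"] = (out["total_yuan"] / YUAN_PER_BILLION).round(3)
    out = out.sort_values(["year", "age_group", "state"]).reset_index(drop=True)
    out.to_csv(path, index=False)
    return out
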