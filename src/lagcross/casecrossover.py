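"""Bidirectional case-crossover strata with seasonal referents and lag-grid exposures.

Each hospital event (the *case*) is matched to three *controls* that are the
same person with exposure drawn from fixed referent month sets instead of the
event quarter:

* case: mean exposure over the three months of the event's calendar quarter;
* control 1: mean over months {1, 4, 7, 10} (one month per quarter);
* control 2: mean over {2, 5, 8, 11};
* control 3: mean over {3, 6, 9, 12}.

Because the referent months fall both before and after the event quarter, the
design is bidirectional: quarter-1 and quarter-2 cases have referent mean
monthly ranks above the case rank, quarter-3 and quarter-4 cases below.

Exposures are evaluated not only in the event's grid of residence (lag 0) but
in each spatial lag grid of its :class:`~lagcross.lattice.LagSequence`, and at
span-averaged summary lags (01, 24, 04).  Apparent temperature is carried per
lag grid the same way; pollen, holiday, and snowstorm covariates are index-grid
referent-month means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lattice import (
    LAG_LABELS,
    Lattice,
    assign_lag_grids,
    assign_point_to_grid,
    canonical_lag_label,
    lag_span,
)

logger = logging.getLogger(__name__)

SURFACES = ("PMB", "PMC", "PMCK", "PMCQ", "PMCKQ")
OUTCOMES = ("ED_asthma", "IP_asthma", "IP_MI", "IP_HF")

#: Referent month sets for the three controls, keyed by control number.
CONTROL_MONTHS: Mapping[int, tuple[int, ...]] = {
    1: (1, 4, 7, 10),
    2: (2, 5, 8, 11),
    3: (3, 6, 9, 12),
}

QUARTER_MONTHS: Mapping[str, tuple[int, ...]] = {
    "Q1": (1, 2, 3),
    "Q2": (4, 5, 6),
    "Q3": (7, 8, 9),
    "Q4": (10, 11, 12),
}

#: Default warm season: April-September; cold is the complement.
DEFAULT_WARM_MONTHS = frozenset(range(4, 10))

#: Matching variables shared by a case and its three controls.
MATCHING_KEY = ("age_band", "gender", "race", "insurance", "zip", "year", "day_of_week")

EXPOSURE_KEY = ("row", "col", "year", "month")


class CaseCrossoverError(ValueError):
    """Invalid month, missing exposure, or malformed stratum input."""


class MissingExposureError(CaseCrossoverError):
    """No exposure value available in any month of the requested set."""


def quarter_of_month(month: int) -> str:
    """Calendar quarter of a month: Q1={1,2,3} (winter) ... Q4={10,11,12} (fall)."""
    if not 1 <= int(month) <= 12:
        raise CaseCrossoverError(f"month must be in 1..12, got {month}")
    return f"Q{(int(month) - 1) // 3 + 1}"


def mean_monthly_rank(months: Iterable[int]) -> float:
    """Arithmetic mean of month ordinals (January=1 ... December=12)."""
    months = list(months)
    if not months:
        raise CaseCrossoverError("month set is empty")
    for m in months:
        if not 1 <= int(m) <= 12:
            raise CaseCrossoverError(f"month must be in 1..12, got {m}")
    if len(set(months)) != len(months):
        raise CaseCrossoverError("months must be distinct")
    return float(np.mean(months))


def season_label(month_or_quarter, warm_months: frozenset[int] = DEFAULT_WARM_MONTHS) -> str:
    """``warm``/``cold`` label for a month (1-12) or quarter ("Q1".."Q4").

    A quarter is warm when the majority of its months are warm.
    """
    if isinstance(month_or_quarter, str) and month_or_quarter.startswith("Q"):
        months = QUARTER_MONTHS.get(month_or_quarter)
        if months is None:
            raise CaseCrossoverError(f"unknown quarter {month_or_quarter!r}")
        n_warm = sum(m in warm_months for m in months)
        return "warm" if n_warm * 2 > len(months) else "cold"
    month = int(month_or_quarter)
    if not 1 <= month <= 12:
        raise CaseCrossoverError(f"month must be in 1..12, got {month}")
    return "warm" if month in warm_months else "cold"


def _monthly_mean(values: np.ndarray, months: Sequence[int]) -> tuple[float, int]:
    """Mean of ``values[m-1]`` over ``months`` ignoring NaN; (value, n_missing)."""
    sel = np.asarray(values, dtype=float)[[m - 1 for m in months]]
    n_missing = int(np.isnan(sel).sum())
    if n_missing == len(months):
        raise MissingExposureError(f"no exposure value in months {tuple(months)}")
    return float(np.nanmean(sel)), n_missing


class ExposureIndex:
    """Monthly exposure table indexed for O(1) (grid, year) -> month-array lookup."""

    def __init__(self, exposure: pd.DataFrame, columns: Sequence[str] | None = None):
        missing = set(EXPOSURE_KEY) - set(exposure.columns)
        if missing:
            raise CaseCrossoverError(f"exposure table missing key columns {sorted(missing)}")
        self.columns = tuple(
            columns
            if columns is not None
            else [c for c in exposure.columns if c not in EXPOSURE_KEY]
        )
        self._arrays: dict[tuple[int, int, int], dict[str, np.ndarray]] = {}
        for (row, col, year), grp in exposure.groupby(["row", "col", "year"], sort=False):
            months = grp["month"].to_numpy(dtype=int)
            store: dict[str, np.ndarray] = {}
            for name in self.columns:
                arr = np.full(12, np.nan)
                arr[months - 1] = grp[name].to_numpy(dtype=float)
                store[name] = arr
            self._arrays[(int(row), int(col), int(year))] = store

    def months(self, row: int, col: int, year: int, column: str) -> np.ndarray:
        try:
            return self._arrays[(int(row), int(col), int(year))][column]
        except KeyError:
            raise MissingExposureError(
                f"no exposure rows for grid ({row},{col}), year {year}, column {column}"
            ) from None


def case_exposure(exposure: ExposureIndex, grid, year: int, month: int, surface: str) -> float:
    """Quarterly mean of ``surface`` in ``grid`` for the event's calendar quarter."""
    row, col = (grid.row, grid.col) if hasattr(grid, "row") else grid
    months = QUARTER_MONTHS[quarter_of_month(month)]
    value, _ = _monthly_mean(exposure.months(row, col, year, surface), months)
    return value


def control_exposures(exposure: ExposureIndex, grid, year: int, surface: str) -> tuple[float, float, float]:
    """The three referent-month-set means of ``surface`` in ``grid``/``year``."""
    row, col = (grid.row, grid.col) if hasattr(grid, "row") else grid
    arr = exposure.months(row, col, year, surface)
    return tuple(_monthly_mean(arr, CONTROL_MONTHS[k])[0] for k in (1, 2, 3))


def age_band(age: float, width: int = 5) -> str:
    """Closed-width age matching band, e.g. 5-year bands '40-44'."""
    lo = (int(age) // width) * width
    return f"{lo}-{lo + width - 1}"


@dataclass
class StrataBuild:
    """Result of :func:`build_strata`: the long stratum table plus drop accounting."""

    strata: pd.DataFrame
    drops: pd.DataFrame

    @property
    def n_strata(self) -> int:
        return self.strata["stratum_id"].nunique() if len(self.strata) else 0


def build_strata(
    events: pd.DataFrame,
    exposure: pd.DataFrame | ExposureIndex,
    lattice: Lattice,
    condition: str,
    surfaces: Sequence[str] = SURFACES,
    lag_labels: Sequence[str] = LAG_LABELS,
    warm_months: frozenset[int] = DEFAULT_WARM_MONTHS,
    age_band_years: int = 5,
) -> StrataBuild:
    """Build 1 case : 3 control strata with per-lag-grid exposure covariates.

    One stratum per event.  For each requested surface and lag label the four
    members get an exposure column ``{surface}_l{label}``: individual lag *k*
    is the case/control exposure computed in the lag-*k* grid of the index
    grid's lag sequence; summary labels are means of the individual-lag
    exposures over their span.  Apparent temperature is carried per lag as
    ``AT_l{label}``; pollen/holiday/snowstorm are index-grid means.

    Events whose index grid is outside the ``condition`` subset, cannot be
    resolved, or has no usable exposure are dropped with a logged reason.
    """
    if not isinstance(exposure, ExposureIndex):
        exposure = ExposureIndex(exposure)
    labels = [canonical_lag_label(l) for l in lag_labels]
    max_lag = max((max(lag_span(l)) for l in labels), default=0)
    rows: list[dict] = []
    drops: list[dict] = []
    seq_cache: dict[tuple[int, int], object] = {}

    for ev in events.itertuples(index=False):
        ev = ev._asdict() if hasattr(ev, "_asdict") else dict(ev)
        event_id = ev.get("event_id")
        try:
            if "row" in ev and not pd.isna(ev.get("row")):
                index_cell = lattice.cell(int(ev["row"]), int(ev["col"]))
            elif "centroid_x" in ev:
                index_cell = assign_point_to_grid(lattice, ev["centroid_x"], ev["centroid_y"])
            else:
                raise CaseCrossoverError("event has neither grid coordinates nor centroid")
            key = index_cell.coords
            if key not in seq_cache:
                seq_cache[key] = assign_lag_grids(lattice, index_cell, condition, n_lags=max_lag)
            seq = seq_cache[key]
        except (CaseCrossoverError, ValueError) as exc:
            drops.append({"event_id": event_id, "reason": "unresolvable_grid", "detail": str(exc)})
            continue

        date = pd.Timestamp(ev["date"])
        year, month = int(date.year), int(date.month)
        quarter = quarter_of_month(month)
        q_months = QUARTER_MONTHS[quarter]

        # per-member, per-surface-lag exposure values; member 0 is the case
        try:
            values: dict[str, list[float]] = {}
            incomplete = False
            for name in surfaces + ("AT",):
                per_lag: dict[int, list[float]] = {}
                for k in range(max_lag + 1):
                    grid = seq.cell_at_lag(k)
                    arr = exposure.months(grid.row, grid.col, year, name)
                    case_v, n_miss = _monthly_mean(arr, q_months)
                    incomplete = incomplete or n_miss > 0
                    member_vals = [case_v]
                    for cnum in (1, 2, 3):
                        v, n_miss = _monthly_mean(arr, CONTROL_MONTHS[cnum])
                        incomplete = incomplete or n_miss > 0
                        member_vals.append(v)
                    per_lag[k] = member_vals
                for label in labels:
                    span = lag_span(label)
                    values[f"{name}_l{label}"] = [
                        float(np.mean([per_lag[k][j] for k in span])) for j in range(4)
                    ]
            covs: dict[str, list[float]] = {}
            for name in ("pollen", "holiday", "snowstorm"):
                arr = exposure.months(index_cell.row, index_cell.col, year, name)
                covs[name] = [_monthly_mean(arr, q_months)[0]] + [
                    _monthly_mean(arr, CONTROL_MONTHS[c])[0] for c in (1, 2, 3)
                ]
        except MissingExposureError as exc:
            drops.append({"event_id": event_id, "reason": "missing_exposure", "detail": str(exc)})
            continue

        shared = {
            "stratum_id": event_id,
            "outcome": ev.get("outcome"),
            "year": year,
            "quarter": quarter,
            "season": season_label(quarter, warm_months),
            "condition": condition,
            "index_row": index_cell.row,
            "index_col": index_cell.col,
            "wrapped_around_lattice": seq.wrapped_around_lattice,
            "incomplete_months": incomplete,
            "age": ev.get("age"),
            "age_band": age_band(ev["age"], age_band_years) if "age" in ev else None,
            "gender": ev.get("gender"),
            "race": ev.get("race"),
            "insurance": ev.get("insurance"),
            "zip": ev.get("zip"),
            "day_of_week": int(date.dayofweek),
            "atherosclerosis": ev.get("atherosclerosis"),
            "diabetes": ev.get("diabetes"),
            "hypertension": ev.get("hypertension"),
        }
        roles = ("case", "control1", "control2", "control3")
        for j, role in enumerate(roles):
            rec = dict(shared)
            rec["role"] = role
            rec["is_case"] = int(j == 0)
            for col_name, member_vals in values.items():
                rec[col_name] = member_vals[j]
            for col_name, member_vals in covs.items():
                rec[col_name] = member_vals[j]
            rows.append(rec)

    strata = pd.DataFrame(rows)
    drops_df = pd.DataFrame(drops, columns=["event_id", "reason", "detail"])
    if len(drops_df):
        logger.info(
            "build_strata dropped %d of %d events: %s",
            len(drops_df), len(events), drops_df["reason"].value_counts().to_dict(),
        )
    return StrataBuild(strata=strata, drops=drops_df)
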