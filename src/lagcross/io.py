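"""Delimited-text readers/writers and run configuration.

All tabular interchange is header-first delimited text; reports are JSON plus
plain text.  Readers validate required columns and report the offending file
(and a line estimate) on parse failure; writers use fixed column order and
fixed float precision so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .casecrossover import OUTCOMES, SURFACES
from .lattice import CONDITIONS, LAG_LABELS

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("event_id", "outcome", "date")
EXPOSURE_COLUMNS = ("row", "col", "year", "month")

#: fixed float format for all CSV output (re-run reproducibility)
CSV_FLOAT_FORMAT = "%.6g"


class IOError_(ValueError):
    """File-format problem, with file name and location where determinable."""


def read_table(path, required: Sequence[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        line = getattr(exc, "lineno", None)
        loc = f" at line {line}" if line else ""
        raise IOError_(f"cannot parse {name} file {path}{loc}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise IOError_(f"{name} file {path} missing columns {sorted(missing)}")
    return df


def read_events(path) -> pd.DataFrame:
    df = read_table(path, EVENT_COLUMNS, "health-event")
    try:
        df["date"] = pd.to_datetime(df["date"])
    except Exception as exc:
        raise IOError_(f"health-event file {path}: unparseable date column: {exc}") from exc
    return df


def read_exposure(path) -> pd.DataFrame:
    return read_table(path, EXPOSURE_COLUMNS, "exposure")


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (pd.Timestamp,)):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    out_dir: str = "lagcross_out"
    seed: int = 0
    lattice_file: str | None = None  # None: packaged fixture
    exposure_file: str | None = None  # None: simulate
    events_file: str | None = None
    surfaces: tuple[str, ...] = SURFACES
    baseline_surface: str = "PMB"
    outcomes: tuple[str, ...] = OUTCOMES
    conditions: tuple[str, ...] = CONDITIONS
    lag_labels: tuple[str, ...] = LAG_LABELS
    p_screen: float = 0.09
    p_final: float = 0.05
    or_scale: float = 10.0  # exposure unit of reported ORs (ug/m3)
    warm_months: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    moran_weights: str = "rook"
    season_split: bool = True
    events_per_outcome: int = 400  # simulation size when no events file given

    def __post_init__(self) -> None:
        bad = set(self.lag_labels) - set(LAG_LABELS)
        if bad:
            raise IOError_(f"unknown lag labels {sorted(bad)}; allowed: {LAG_LABELS}")
        for attr in ("lattice_file", "exposure_file", "events_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise IOError_(f"{attr} {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise IOError_(f"unknown config keys in {path}: {sorted(unknown)}")
        for key in ("surfaces", "outcomes", "conditions", "lag_labels", "warm_months"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "lag_labels" in raw:
            raw["lag_labels"] = tuple(str(l) for l in raw["lag_labels"])
        return cls(**raw)
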