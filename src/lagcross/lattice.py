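"""Regular grid lattice, spatial lag-grid assignment, and HOSA geometry.

The study area is an ``n_rows x n_cols`` lattice of square cells (12 km by
default), indexed 1-based with rows running south to north and columns west
to east.  A subset of cells hosts ambient PM2.5 air monitors ("urban" cells);
the rest are "rural".  The spatial lag-grid case-crossover design assigns, to
every index cell, the four cells that *precede* it in a canonical serpentine
ordering of its monitor-condition subset; exposure measured in lag cell *k*
is the lag-``k`` covariate.

Canonical ordering
------------------
Cells of a condition subset are sorted by row **descending** (north first)
then column **ascending** (west first), and the ordering is treated as a ring
so every cell has four predecessors.  This is the unique simple sort that
reproduces all published worked lag sequences, including the monitor-only
sequence (6,7) -> (6,6),(7,7),(7,6),(7,5) and the wrap of a column-4 index
cell to column 9 of the next row north.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Monitor-condition subsets: cells without monitors, with monitors, or all.
CONDITIONS = ("No", "Yes", "Both")

#: Individual lag labels (grid offsets) and span-averaged summary labels.
INDIVIDUAL_LAGS = ("0", "1", "2", "3", "4")
SUMMARY_LAGS: Mapping[str, tuple[int, ...]] = {
    "01": (0, 1),
    "24": (2, 3, 4),
    "04": (0, 1, 2, 3, 4),
}
LAG_LABELS = INDIVIDUAL_LAGS + tuple(SUMMARY_LAGS)


class LatticeError(ValueError):
    """Invalid lattice, condition subset, or point-assignment input."""


def canonical_lag_label(label: object) -> str:
    """Normalize a lag label (``1``, ``"1"``, ``"01"`` ...) to its string form."""
    text = str(label)
    if text in LAG_LABELS:
        return text
    raise LatticeError(f"unknown lag label {label!r}; expected one of {LAG_LABELS}")


def lag_span(label: object) -> tuple[int, ...]:
    """Individual lag offsets covered by a label ("01" -> (0, 1), "3" -> (3,))."""
    text = canonical_lag_label(label)
    if text in SUMMARY_LAGS:
        return SUMMARY_LAGS[text]
    return (int(text),)


@dataclass(frozen=True)
class GridCell:
    """One lattice cell: 1-based (row, col), monitor and health-data status."""

    row: int
    col: int
    has_monitor: bool = False
    n_monitors: int = 0
    has_health_data: bool = True
    jurisdiction: str | None = None

    def __post_init__(self) -> None:
        if self.row < 1 or self.col < 1:
            raise LatticeError(f"cell coordinates must be >= 1, got {(self.row, self.col)}")
        if self.has_monitor and self.n_monitors < 1:
            raise LatticeError(f"monitor cell {(self.row, self.col)} must have n_monitors >= 1")
        if self.n_monitors < 0:
            raise LatticeError("n_monitors must be non-negative")

    @property
    def coords(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class Lattice:
    """A complete rectangular lattice of :class:`GridCell`.

    ``cell_width_km``/``cell_height_km`` give the physical cell size; the
    lattice origin (x=0, y=0) is the south-west corner of cell (1, 1).
    """

    n_rows: int
    n_cols: int
    cells: tuple[GridCell, ...]
    cell_width_km: float = 12.0
    cell_height_km: float = 12.0
    _index: Mapping[tuple[int, int], GridCell] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.cell_width_km <= 0 or self.cell_height_km <= 0:
            raise LatticeError("cell dimensions must be positive")
        index = {}
        for cell in self.cells:
            if not (1 <= cell.row <= self.n_rows and 1 <= cell.col <= self.n_cols):
                raise LatticeError(f"cell {cell.coords} outside {self.n_rows}x{self.n_cols} lattice")
            if cell.coords in index:
                raise LatticeError(f"duplicate cell {cell.coords}")
            index[cell.coords] = cell
        if len(index) != self.n_rows * self.n_cols:
            raise LatticeError(
                f"lattice needs {self.n_rows * self.n_cols} cells, got {len(index)}"
            )
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, row: int, col: int) -> GridCell:
        try:
            return self._index[(row, col)]
        except KeyError:
            raise LatticeError(f"no cell at {(row, col)}") from None

    def subset(self, condition: str) -> tuple[GridCell, ...]:
        """Cells belonging to a monitor condition (``No``/``Yes``/``Both``)."""
        if condition not in CONDITIONS:
            raise LatticeError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        if condition == "Both":
            return self.cells
        want = condition == "Yes"
        return tuple(c for c in self.cells if c.has_monitor == want)

    @property
    def monitor_cells(self) -> tuple[GridCell, ...]:
        return self.subset("Yes")

    @property
    def total_monitors(self) -> int:
        return sum(c.n_monitors for c in self.cells)


@dataclass(frozen=True)
class LagSequence:
    """Index cell (lag 0) plus its spatial lag cells 1..n in one condition subset.

    ``wrapped[k-1]`` is True when lag cell *k* sits in a different row than the
    index cell (the serpentine ordering stepped to the next row); a sequence
    that cycled past the start of the whole ordering sets
    ``wrapped_around_lattice`` so downstream analyses can exclude it.
    """

    condition: str
    index_cell: GridCell
    lag_cells: tuple[GridCell, ...]
    wrapped: tuple[bool, ...]
    wrapped_around_lattice: bool = False

    @property
    def cells(self) -> tuple[GridCell, ...]:
        """All cells, lag 0 first."""
        return (self.index_cell,) + self.lag_cells

    def cell_at_lag(self, k: int) -> GridCell:
        if k == 0:
            return self.index_cell
        return self.lag_cells[k - 1]

    def to_record(self) -> dict:
        return {
            "condition": self.condition,
            "index": list(self.index_cell.coords),
            "lags": [list(c.coords) for c in self.lag_cells],
            "wrapped": list(self.wrapped),
            "wrapped_around_lattice": self.wrapped_around_lattice,
        }


def canonical_order(lattice: Lattice, condition: str) -> tuple[GridCell, ...]:
    """Cells of a condition subset sorted row-descending then column-ascending.

    The ordering is used as a ring: the last cell precedes the first.
    """
    cells = lattice.subset(condition)
    if not cells:
        raise LatticeError(f"condition {condition!r} selects no cells")
    return tuple(sorted(cells, key=lambda c: (-c.row, c.col)))


def assign_lag_grids(
    lattice: Lattice, index: GridCell | tuple[int, int], condition: str, n_lags: int = 4
) -> LagSequence:
    """Assign the ``n_lags`` cells preceding ``index`` in the canonical ordering.

    Lag *k* is the cell *k* positions earlier in :func:`canonical_order` of the
    condition subset, with cyclic wrap past the start of the ordering.
    """
    if isinstance(index, tuple):
        index = lattice.cell(*index)
    order = canonical_order(lattice, condition)
    try:
        pos = order.index(index)
    except ValueError:
        raise LatticeError(
            f"index cell {index.coords} is not in the {condition!r} condition subset"
        ) from None
    lags = tuple(order[(pos - k) % len(order)] for k in range(1, n_lags + 1))
    wrapped = tuple(c.row != index.row for c in lags)
    return LagSequence(
        condition=condition,
        index_cell=index,
        lag_cells=lags,
        wrapped=wrapped,
        wrapped_around_lattice=pos - n_lags < 0,
    )


def classify_precede_follow(seq: LagSequence) -> tuple[str, ...]:
    """Label each lag cell ``precede`` (index cell's row) or ``follow`` (other row).

    Lag cells west of the index cell in the same row precede it spatially;
    cells the ordering pulled from another row follow it.
    """
    return tuple("precede" if not w else "follow" for w in seq.wrapped)


def precede_follow_percentages(
    lattice: Lattice,
    condition: str,
    n_lags: int = 4,
    weights: Mapping[tuple[int, int], float] | None = None,
) -> dict[str, float]:
    """Percent of lag cells preceding/following index cells over a condition subset.

    ``weights`` optionally weights each index cell (e.g. by its observation
    count); the default tallies every index cell equally.
    """
    totals = {"precede": 0.0, "follow": 0.0}
    for cell in lattice.subset(condition):
        w = 1.0 if weights is None else float(weights.get(cell.coords, 0.0))
        for label in classify_precede_follow(assign_lag_grids(lattice, cell, condition, n_lags)):
            totals[label] += w
    grand = totals["precede"] + totals["follow"]
    if grand == 0:
        raise LatticeError("no weighted lag cells to tabulate")
    return {k: 100.0 * v / grand for k, v in totals.items()}


def assign_point_to_grid(lattice: Lattice, x: float, y: float) -> GridCell:
    """Map a centroid in lattice km coordinates to its unique containing cell.

    Cells are half-open squares: the west and south edges belong to the cell,
    the east and north edges to the neighbor, so every in-bounds point maps to
    exactly one cell.
    """
    if not (0 <= x < lattice.n_cols * lattice.cell_width_km):
        raise LatticeError(f"x={x} outside lattice extent")
    if not (0 <= y < lattice.n_rows * lattice.cell_height_km):
        raise LatticeError(f"y={y} outside lattice extent")
    col = int(x // lattice.cell_width_km) + 1
    row = int(y // lattice.cell_height_km) + 1
    return lattice.cell(row, col)


def hosa_geometry(n_grids: int, cell_width_km: float = 12.0) -> tuple[float, float]:
    """Width (km) and area (km^2) of a homogeneous spatial area of ``n_grids`` cells.

    A HOSA is a run of adjacent square cells one cell tall, so its width is
    ``n * w`` km and its area ``n * w**2`` km^2 (multiples of 144 km^2 at the
    default 12-km cell).
    """
    if n_grids < 0:
        raise LatticeError("n_grids must be non-negative")
    return n_grids * cell_width_km, n_grids * cell_width_km**2


def count_design_combinations(n_years: int, n_quarters: int, n_days: int, n_grids: int) -> int:
    """Number of distinct year x quarter x day-of-week x grid exposure cells."""
    for name, v in (
        ("n_years", n_years), ("n_quarters", n_quarters), ("n_days", n_days), ("n_grids", n_grids)
    ):
        if v < 1:
            raise LatticeError(f"{name} must be a positive integer")
    return n_years * n_quarters * n_days * n_grids


# ---------------------------------------------------------------------------
# Lattice I/O and the packaged Baltimore-style fixture
# ---------------------------------------------------------------------------

LATTICE_HEADER = ("row", "col", "has_monitor", "n_monitors", "has_health_data", "jurisdiction")


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "yes"}


def read_lattice(path_or_lines, cell_width_km: float = 12.0, cell_height_km: float = 12.0) -> Lattice:
    """Read a lattice from delimited text with the standard header."""
    if hasattr(path_or_lines, "read") or isinstance(path_or_lines, (list, tuple)):
        rows = list(csv.DictReader(path_or_lines))
    else:
        with open(path_or_lines, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise LatticeError("empty lattice file")
    missing = set(LATTICE_HEADER) - set(rows[0])
    if missing:
        raise LatticeError(f"lattice file missing columns: {sorted(missing)}")
    cells = tuple(
        GridCell(
            row=int(r["row"]),
            col=int(r["col"]),
            has_monitor=_parse_bool(r["has_monitor"]),
            n_monitors=int(r["n_monitors"]),
            has_health_data=_parse_bool(r["has_health_data"]),
            jurisdiction=(r["jurisdiction"] or None),
        )
        for r in rows
    )
    n_rows = max(c.row for c in cells)
    n_cols = max(c.col for c in cells)
    return Lattice(n_rows, n_cols, cells, cell_width_km, cell_height_km)


def write_lattice(lattice: Lattice, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LATTICE_HEADER)
        for c in sorted(lattice.cells, key=lambda c: (c.row, c.col)):
            writer.writerow(
                [c.row, c.col, int(c.has_monitor), c.n_monitors,
                 int(c.has_health_data), c.jurisdiction or ""]
            )


def build_baltimore_lattice() -> Lattice:
    """The packaged 11x9 Baltimore-area lattice fixture.

    99 cells of 12 km; 15 monitor cells holding 17 ambient PM2.5 monitors
    (cell (6,6) has three).  72 cells carry hospital-event data; because the
    identities of the 27 rural cells without health data are confidential,
    the fixture marks the 27 no-monitor cells nearest the south-east corner
    (the bay corner of the study area) — a synthetic, deterministic stand-in.
    """
    with resources.files("lagcross.data").joinpath("baltimore_lattice.csv").open() as fh:
        lattice = read_lattice(fh)
    logger.debug(
        "canonical lag ordering is row-descending/column-ascending, the unique "
        "sort consistent with all published worked lag sequences"
    )
    return lattice


#: Monitor cells of the Baltimore fixture: (row, col) -> (n_monitors, jurisdiction).
BALTIMORE_MONITORS: Mapping[tuple[int, int], tuple[int, str]] = {
    (8, 6): (1, "B"),
    (8, 8): (1, "H"),
    (7, 5): (1, "BC"),
    (7, 6): (1, "BC"),
    (7, 7): (1, "B"),
    (6, 6): (3, "BC"),
    (6, 7): (1, "BC"),
    (5, 6): (1, "AA"),
    (5, 7): (1, "AA"),
    (4, 3): (1, "M"),
    (4, 5): (1, "PG"),
    (4, 6): (1, "AA"),
    (3, 5): (1, "PG"),
    (3, 7): (1, "AA"),
    (2, 6): (1, "PG"),
}
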