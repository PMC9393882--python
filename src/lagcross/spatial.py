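"""Spatial and categorical diagnostics: correlations, Moran's I, CI-rule tables.

Moran's I on the lattice uses binary contiguity weights (rook by default,
queen and distance-band selectable) with the null expectation ``-1/(n-1)``
and the variance under the randomization (permutation) assumption; the
normality-assumption variance is available as a switch.  Correlations between
fused surfaces are summarized as ``r`` and the shared-variance percent
``r2% = 100 r^2``; the ``Delta%`` contrast is the monitor-condition difference
of two r2% values.  Grid-level means are classified Below/Within/Above an
overall 95% CI and compared across monitor conditions with a Pearson
chi-square.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("rook", "queen", "distance_band")
CATEGORIES = ("Below", "Within", "Above")


class SpatialError(ValueError):
    """Invalid correlation, weights, or degenerate surface input."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up, matching printed-table rounding conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def r2_percent(r: float) -> float:
    """Shared-variance percent 100*r^2, reported to one decimal (half-up)."""
    if abs(r) > 1:
        raise SpatialError(f"|r| must be <= 1, got {r}")
    return round_half_up(100.0 * r * r, 1)


def delta_percent(r2_yes: float, r2_no: float) -> float:
    """Monitor-condition contrast of two shared-variance percents (Yes - No)."""
    for v in (r2_yes, r2_no):
        if not 0.0 <= v <= 100.0:
            raise SpatialError(f"r2% values must lie in [0, 100], got {v}")
    return round_half_up(r2_yes - r2_no, 1)


@dataclass(frozen=True)
class CorrelationSummary:
    surface_a: str
    surface_b: str
    condition: str
    r: float
    r2_pct: float
    n: int


def surface_correlations(
    df: pd.DataFrame,
    baseline: str = "PMB",
    surfaces: Sequence[str] = ("PMC", "PMCK", "PMCQ", "PMCKQ"),
    condition_col: str | None = "condition",
) -> list[CorrelationSummary]:
    """Pearson correlations of each surface against the baseline, per condition.

    Rows with a missing value in either column are excluded pairwise.
    """
    results = []
    groups = (
        [("Both", df)]
        + ([(c, g) for c, g in df.groupby(condition_col)] if condition_col in df.columns else [])
        if condition_col
        else [("Both", df)]
    )
    for cond, grp in groups:
        for s in surfaces:
            sub = grp[[baseline, s]].dropna()
            if len(sub) < 3:
                continue
            r = float(np.corrcoef(sub[baseline], sub[s])[0, 1])
            results.append(CorrelationSummary(baseline, s, str(cond), r, r2_percent(r), len(sub)))
    return results


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    Z: float
    p: float
    n: int
    weight_scheme: str


def contiguity_weights(
    coords: Sequence[tuple[int, int]], scheme: str = "rook", band: float = 1.5
) -> np.ndarray:
    """Symmetric binary weight matrix over (row, col) lattice positions.

    ``rook``: shared edge; ``queen``: shared edge or corner; ``distance_band``:
    Euclidean center distance <= ``band`` (in cell units).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise SpatialError(f"weight scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}")
    pts = np.asarray(coords, dtype=float)
    dr = np.abs(pts[:, 0:1] - pts[:, 0:1].T)
    dc = np.abs(pts[:, 1:2] - pts[:, 1:2].T)
    if scheme == "rook":
        w = (dr + dc == 1)
    elif scheme == "queen":
        w = (np.maximum(dr, dc) == 1)
    else:
        w = (np.hypot(dr, dc) <= band) & (dr + dc > 0)
    return w.astype(float)


def morans_i(
    values: Mapping[tuple[int, int], float] | pd.Series,
    weight_scheme: str = "rook",
    variance: str = "randomization",
    band: float = 1.5,
) -> MoranResult:
    """Global Moran's I with analytic Z test for grid-keyed values.

    ``values`` maps (row, col) -> value (a pandas Series with a 2-level index
    works).  ``I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i
    (x_i - xbar)^2`` with binary contiguity weights; E[I] = -1/(n-1); the
    variance is computed under the randomization assumption by default
    (``variance="normality"`` switches to the normal-approximation form).
    """
    if isinstance(values, pd.Series):
        coords = [tuple(map(int, k)) for k in values.index]
        x = values.to_numpy(dtype=float)
    else:
        coords = [tuple(map(int, k)) for k in values.keys()]
        x = np.asarray(list(values.values()), dtype=float)
    n = len(x)
    if n < 3:
        raise SpatialError(f"need at least 3 grids, got {n}")
    z = x - x.mean()
    s2 = float(z @ z)
    if s2 == 0:
        raise SpatialError("zero-variance surface: Moran's I undefined")
    w = contiguity_weights(coords, weight_scheme, band)
    W = float(w.sum())
    if W == 0:
        raise SpatialError("weight matrix has no neighbors")
    I = (n / W) * float(z @ w @ z) / s2
    e_i = -1.0 / (n - 1)

    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2_w = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    if variance == "randomization":
        b2 = n * float((z**4).sum()) / s2**2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2_w + 3 * W * W) - b2 * (
            (n * n - n) * s1 - 2 * n * s2_w + 6 * W * W
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * W * W) - e_i**2
    elif variance == "normality":
        var = (n * n * s1 - n * s2_w + 3 * W * W) / (W * W * (n * n - 1)) - e_i**2
    else:
        raise SpatialError(f"unknown variance assumption {variance!r}")
    if var <= 0:
        raise SpatialError("non-positive Moran variance (degenerate weights)")
    Z = (I - e_i) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(Z))
    return MoranResult(I=I, expected=e_i, variance=var, Z=Z, p=p, n=n, weight_scheme=weight_scheme)


# ---------------------------------------------------------------------------
# Mean-vs-CI rule and Below/Within/Above categorical tables
# ---------------------------------------------------------------------------


def mean_ci_compare(mean_a: float, ci_b: Sequence[float]) -> str:
    """Compare a mean to a reference 95% CI: strictly above -> ``higher``,
    strictly below -> ``lower``, at or inside the bounds -> ``not_significant``.
    """
    lo, hi = float(ci_b[0]), float(ci_b[1])
    if not lo < hi:
        raise SpatialError(f"malformed CI {ci_b!r}")
    if mean_a > hi:
        return "higher"
    if mean_a < lo:
        return "lower"
    return "not_significant"


def mean_ci(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI of the mean."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise SpatialError("need at least 2 values for a CI")
    m = float(arr.mean())
    half = 1.959963984540054 * float(arr.std(ddof=1)) / math.sqrt(len(arr))
    return m, (m - half, m + half)


@dataclass
class CategoryTable:
    """Below/Within/Above counts per group with a Pearson chi-square."""

    variable: str
    counts: pd.DataFrame  # index: group, columns: Below/Within/Above
    percents: pd.DataFrame
    chi2: float | None
    df: int | None
    p: float | None
    degenerate: bool


def categorize_grids(
    grid_means: Mapping[tuple[int, int], float] | pd.Series,
    overall_ci: Sequence[float],
    groups: Mapping[tuple[int, int], str] | None = None,
    variable: str = "",
) -> CategoryTable:
    """Classify grid means Below/Within/Above a reference 95% CI.

    Strict comparison to the CI bounds; with ``groups`` (grid -> group label,
    e.g. monitor condition) a group x category contingency table is tested
    with Pearson chi-square.  A table with an all-zero category column or a
    single group is flagged degenerate and left untested.
    """
    lo, hi = float(overall_ci[0]), float(overall_ci[1])
    if not lo < hi:
        raise SpatialError(f"malformed CI {overall_ci!r}")
    if isinstance(grid_means, pd.Series):
        items = [(tuple(map(int, k)), float(v)) for k, v in grid_means.items()]
    else:
        items = [(tuple(map(int, k)), float(v)) for k, v in grid_means.items()]
    labels = {}
    for key, v in items:
        labels[key] = "Above" if v > hi else ("Below" if v < lo else "Within")
    if groups is None:
        groups = {key: "all" for key, _ in items}
    table = pd.DataFrame(0, index=sorted(set(groups.values())), columns=list(CATEGORIES))
    for key, cat in labels.items():
        table.loc[groups[key], cat] += 1
    percents = table.div(table.sum(axis=1), axis=0) * 100.0
    nonzero_cols = table.loc[:, (table.sum(axis=0) > 0)]
    degenerate = len(table.index) < 2 or nonzero_cols.shape[1] < 2
    if degenerate:
        logger.info("categorical table for %r degenerate; chi-square skipped", variable)
        chi2 = dof = p = None
    else:
        chi2, p, dof, _ = stats.chi2_contingency(nonzero_cols.to_numpy())
        chi2, p = float(chi2), float(p)
    return CategoryTable(variable=variable, counts=table, percents=percents,
                         chi2=chi2, df=dof, p=p, degenerate=degenerate)
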