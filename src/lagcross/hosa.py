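"""Homogeneous spatial area (HOSA) delineation and OR contrasts.

A lag label is *significant* for an experimental surface when its OR exceeds
the baseline surface's OR by the point-outside-reference-CI rule: the
comparison OR must fall above the upper (or below the lower) 95% confidence
limit of the reference OR.  The HOSA is the maximal run of adjacent
individual lag grids, starting at the index grid (lag 0), implied by the
significant lag labels; its width is a multiple of the cell width (12 km) and
its area a multiple of the cell area (144 km^2).

The point-vs-CI rule is the field convention this package reproduces; it is
anti-conservative relative to a two-sample test on the log-OR difference, so
a formal z-test mode is provided as an alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .lattice import canonical_lag_label, hosa_geometry, lag_span

logger = logging.getLogger(__name__)

VERDICTS = ("higher", "lower", "not_significant")


class HOSAError(ValueError):
    """Malformed CI, lag set, or fit collection."""


@dataclass(frozen=True)
class ORComparison:
    """Verdict of comparing OR ``a`` against reference OR ``b`` and its CI."""

    or_a: float
    ci_a: tuple[float, float]
    or_b: float
    ci_b: tuple[float, float]
    verdict: str


@dataclass(frozen=True)
class HOSAResult:
    """Significant-lag set and derived HOSA geometry for one analysis cell."""

    surface: str
    outcome: str
    condition: str
    significant_lags: tuple[str, ...]
    implied_lags: tuple[int, ...]
    hosa_grids: int
    hosa_km: float
    hosa_km2: float
    noncontiguous: bool = False  # significant span excludes lag 0

    def render(self) -> str:
        """Compact rendering: count of significant labels and the labels."""
        if not self.significant_lags:
            return "0"
        return f"{len(self.significant_lags)} ({', '.join(self.significant_lags)})"


@dataclass(frozen=True)
class DeltaORResult:
    """Signed percent contrast between two ORs (e.g. no-monitor vs monitor)."""

    contrast: str
    surface: str
    outcome: str
    lag: str
    or_a: float
    or_b: float
    delta_or_pct: float
    verdict: str = "not_significant"


def _check_ci(ci: Sequence[float], point: float | None = None) -> tuple[float, float]:
    lo, hi = float(ci[0]), float(ci[1])
    if not (math.isfinite(lo) and math.isfinite(hi)) or not lo < hi:
        raise HOSAError(f"malformed CI {ci!r}")
    if point is not None and not lo < point < hi:
        raise HOSAError(f"point {point} outside its own CI {ci!r}")
    return lo, hi


def compare_or_to_reference(
    or_a: float, ci_a: Sequence[float], or_b: float, ci_b: Sequence[float]
) -> ORComparison:
    """Compare OR ``a`` to reference OR ``b`` by the point-outside-CI rule.

    ``higher`` iff ``or_a`` exceeds the upper 95% limit of ``b``; ``lower``
    iff it falls below the lower limit; else ``not_significant``.
    """
    lo_a, hi_a = _check_ci(ci_a, or_a)
    lo_b, hi_b = _check_ci(ci_b, or_b)
    if or_a > hi_b:
        verdict = "higher"
    elif or_a < lo_b:
        verdict = "lower"
    else:
        verdict = "not_significant"
    return ORComparison(or_a, (lo_a, hi_a), or_b, (lo_b, hi_b), verdict)


def compare_or_ztest(
    or_a: float, ci_a: Sequence[float], or_b: float, ci_b: Sequence[float], alpha: float = 0.05
) -> ORComparison:
    """Two-sample z-test on the log-OR difference (SEs recovered from the CIs)."""
    lo_a, hi_a = _check_ci(ci_a, or_a)
    lo_b, hi_b = _check_ci(ci_b, or_b)
    se_a = (math.log(hi_a) - math.log(lo_a)) / (2 * 1.959963984540054)
    se_b = (math.log(hi_b) - math.log(lo_b)) / (2 * 1.959963984540054)
    z = (math.log(or_a) - math.log(or_b)) / math.hypot(se_a, se_b)
    p = 2.0 * stats.norm.sf(abs(z))
    if p <= alpha:
        verdict = "higher" if z > 0 else "lower"
    else:
        verdict = "not_significant"
    return ORComparison(or_a, (lo_a, hi_a), or_b, (lo_b, hi_b), verdict)


def implied_span(significant_lag_set: Iterable) -> set[int]:
    """Union of individual lag grids covered by a set of significant lag labels."""
    span: set[int] = set()
    for label in significant_lag_set:
        span.update(lag_span(canonical_lag_label(label)))
    return span


def hosa_width(
    significant_lag_set: Iterable,
    surface: str = "",
    outcome: str = "",
    condition: str = "",
    cell_width_km: float = 12.0,
) -> HOSAResult:
    """HOSA size implied by a significant-lag set.

    The HOSA is the maximal contiguous run of implied individual lags starting
    at lag 0; a significant span that does not contain lag 0 yields width 0
    and is flagged ``noncontiguous`` (never observed in practice).
    """
    labels = tuple(sorted((canonical_lag_label(l) for l in significant_lag_set),
                          key=lambda t: (len(t), t)))
    span = implied_span(labels)
    n = 0
    while n in span:
        n += 1
    km, km2 = hosa_geometry(n, cell_width_km)
    return HOSAResult(
        surface=surface,
        outcome=outcome,
        condition=condition,
        significant_lags=labels,
        implied_lags=tuple(sorted(span)),
        hosa_grids=n,
        hosa_km=km,
        hosa_km2=km2,
        noncontiguous=bool(span) and 0 not in span,
    )


def delta_or_pct(or_a: float, or_b: float) -> float:
    """Signed percent difference ``100 * (or_a - or_b) / or_b``."""
    if not or_b > 0:
        raise HOSAError(f"reference OR must be positive, got {or_b}")
    return 100.0 * (or_a - or_b) / or_b


@dataclass(frozen=True)
class ORCell:
    """One fitted exposure OR with its 95% CI, as consumed by the HOSA analysis."""

    or_: float
    lo: float
    hi: float


FitKey = tuple[str, str, str, str]  # (surface, outcome, condition, lag)


def run_hosa_analysis(
    fits: Mapping[FitKey, ORCell],
    baseline: str = "PMB",
    lag_labels: Sequence[str] = ("0", "1", "2", "3", "4", "01", "24", "04"),
    comparison: str = "ci_rule",
    cell_width_km: float = 12.0,
) -> tuple[list[HOSAResult], list[DeltaORResult]]:
    """Delineate HOSAs and compute OR contrasts from a collection of fitted ORs.

    ``fits`` is keyed by (surface, outcome, condition, lag).  Per experimental
    surface x outcome x condition, each lag's OR is compared against the
    baseline surface's OR at the same lag; the significant labels define the
    HOSA.  Additionally, no-monitor vs monitor and warm vs cold contrasts are
    emitted as :class:`DeltaORResult` (season conditions are encoded as
    ``"<condition>:warm"`` / ``"<condition>:cold"`` keys when present).
    """
    compare = compare_or_to_reference if comparison == "ci_rule" else compare_or_ztest
    surfaces = sorted({k[0] for k in fits})
    outcomes = sorted({k[1] for k in fits})
    conditions = sorted({k[2] for k in fits})
    if baseline not in surfaces:
        raise HOSAError(f"no baseline {baseline!r} fits present")

    hosa_results: list[HOSAResult] = []
    n_comparisons = 0
    for surface in surfaces:
        if surface == baseline:
            continue
        for outcome in outcomes:
            for condition in conditions:
                if ":" in condition:
                    continue  # season-split cells feed the warm/cold contrast only
                sig: list[str] = []
                seen_any = False
                for lag in lag_labels:
                    exp_cell = fits.get((surface, outcome, condition, lag))
                    base_cell = fits.get((baseline, outcome, condition, lag))
                    if exp_cell is None:
                        continue
                    if base_cell is None:
                        raise HOSAError(
                            f"missing baseline {baseline} fit for {(outcome, condition, lag)}"
                        )
                    seen_any = True
                    n_comparisons += 1
                    cmp_ = compare(exp_cell.or_, (exp_cell.lo, exp_cell.hi),
                                   base_cell.or_, (base_cell.lo, base_cell.hi))
                    if cmp_.verdict == "higher":
                        sig.append(lag)
                if seen_any:
                    hosa_results.append(
                        hosa_width(sig, surface, outcome, condition, cell_width_km)
                    )

    delta_results: list[DeltaORResult] = []
    for surface in surfaces:
        for outcome in outcomes:
            for lag in lag_labels:
                no_ = fits.get((surface, outcome, "No", lag))
                yes = fits.get((surface, outcome, "Yes", lag))
                if no_ is not None and yes is not None:
                    n_comparisons += 1
                    cmp_ = compare(yes.or_, (yes.lo, yes.hi), no_.or_, (no_.lo, no_.hi))
                    delta_results.append(DeltaORResult(
                        contrast="noMonitor_vs_monitor", surface=surface, outcome=outcome,
                        lag=lag, or_a=no_.or_, or_b=yes.or_,
                        delta_or_pct=delta_or_pct(no_.or_, yes.or_),
                        # verdict expressed for the *monitor* OR relative to the
                        # no-monitor reference CI: "lower" mirrors the "<" rows
                        verdict=cmp_.verdict,
                    ))
                for condition in conditions:
                    warm = fits.get((surface, outcome, f"{condition}:warm", lag))
                    cold = fits.get((surface, outcome, f"{condition}:cold", lag))
                    if warm is not None and cold is not None:
                        n_comparisons += 1
                        cmp_ = compare(warm.or_, (warm.lo, warm.hi),
                                       cold.or_, (cold.lo, cold.hi))
                        delta_results.append(DeltaORResult(
                            contrast="warm_vs_cold", surface=surface, outcome=outcome,
                            lag=lag, or_a=warm.or_, or_b=cold.or_,
                            delta_or_pct=delta_or_pct(warm.or_, cold.or_),
                            verdict=cmp_.verdict,
                        ))
    logger.info("run_hosa_analysis performed %d OR comparisons (no multiplicity "
                "correction applied)", n_comparisons)
    return hosa_results, delta_results
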