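"""Seeded synthetic study generator.

The real study data — hospital event records and the fused PM2.5 exposure
surfaces — are confidential, so every pipeline stage is exercised on a
synthetic study generated here.  The generator emulates the *structure* of
the real inputs, never their confidential values:

* five correlated monthly exposure surfaces on the lattice, sharing a
  spatially smoothed latent field with per-surface loadings ordered so the
  baseline correlates most with PMCQ, then PMCKQ, PMC, PMCK;
* a warm>cold seasonal cycle in every surface, and monitor/no-monitor level
  offsets with the observed sign pattern (all surfaces but PMCK higher in
  monitor cells);
* missing values in the non-Kriged surfaces (PMC, PMCQ) only;
* hospital events whose within-year month is drawn with log-odds linear in
  the exposure of the index grid at a configurable true OR per 10 ug/m3.

Two stratum-level benchmark generators are also provided:
:func:`simulate_strata` draws matched 1:3 sets directly from the conditional
model (the distributional benchmark for the fitting machinery), and
:func:`planted_hosa_replicate` plants a homogeneous spatial area of known
width for end-to-end HOSA recovery checks.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .casecrossover import OUTCOMES, SURFACES
from .clr import fit_conditional_logit, or_ci
from .hosa import HOSAResult, compare_or_to_reference, hosa_width
from .lattice import (
    LAG_LABELS,
    Lattice,
    build_baltimore_lattice,
    canonical_order,
    lag_span,
)

#: per-surface (latent-field loading, independent-noise sd, monitor offset ug/m3);
#: loadings order the baseline correlations PMCQ > PMCKQ > PMC > PMCK and the
#: offsets reproduce the observed monitor/no-monitor mean sign pattern.
SURFACE_PARAMS: Mapping[str, tuple[float, float, float]] = {
    "PMB": (1.00, 0.30, 0.48),
    "PMC": (0.70, 0.70, 0.28),
    "PMCK": (0.55, 0.90, -0.12),
    "PMCQ": (0.95, 0.25, 0.57),
    "PMCKQ": (0.85, 0.45, 0.39),
}

#: approximate count of major-holiday days (holiday or day after) per month
HOLIDAYS_PER_MONTH = {1: 2, 2: 1, 5: 1, 7: 1, 9: 1, 11: 2, 12: 2}

WINTER_MONTHS = (12, 1, 2, 3)


@dataclass
class SimulationConfig:
    """All generator knobs, recorded verbatim in the truth record."""

    seed: int = 0
    years: tuple[int, ...] = (2004, 2005, 2006)
    lattice: Lattice | None = None  # default: packaged Baltimore fixture
    baseline_monthly_mean: float = 14.0  # ug/m3
    seasonal_amplitude: float = 3.0  # ug/m3 warm-cold half-swing
    monthly_anomaly_sd: float = 2.0  # ug/m3 regional month-to-month deviation
    grid_month_sd: float = 2.0  # ug/m3 grid-specific monthly deviation (all surfaces)
    temperature_anomaly_sd: float = 3.0  # deg F regional monthly deviation
    spatial_correlation_range: int = 2  # grids; moving-average smoothing radius
    missingness_rate: float = 0.25  # PMC / PMCQ monthly missingness
    true_or_per_10ug: Mapping[str, float] = field(
        default_factory=lambda: {o: 1.25 for o in OUTCOMES}
    )
    effect_surface: str = "PMCK"
    effect_spatial_range_grids: int | None = None  # None: effect everywhere
    source_grids: tuple[tuple[int, int], ...] = ()
    events_per_outcome: int = 400
    temperature_mean: float = 56.4  # deg F annual mean
    temperature_amplitude: float = 13.8
    monitor_temperature_offset: float = 1.55  # urban heat-island analogue
    gender_mix: Mapping[str, float] = field(default_factory=lambda: {"F": 0.55, "M": 0.45})
    race_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Black": 0.35, "White": 0.55, "Other": 0.10}
    )
    insurance_mix: Mapping[str, float] = field(
        default_factory=lambda: {"private": 0.5, "medicare": 0.3, "medicaid": 0.2}
    )
    comorbidity_rates: Mapping[str, float] = field(
        default_factory=lambda: {"atherosclerosis": 0.25, "diabetes": 0.30, "hypertension": 0.45}
    )
    # modest confounder log-odds contributions to the event-month draw
    confounder_logodds: Mapping[str, float] = field(
        default_factory=lambda: {"AT": 0.004, "pollen": 0.002, "holiday": 0.5, "snowstorm": -0.5}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0, 1]")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if any(v <= 0 for v in self.true_or_per_10ug.values()):
            raise ValueError("true ORs must be positive")
        if self.events_per_outcome < 0:
            raise ValueError("events_per_outcome must be >= 0")

    def resolved_lattice(self) -> Lattice:
        return self.lattice if self.lattice is not None else build_baltimore_lattice()

    def truth(self) -> dict:
        rec = asdict(self)
        rec["lattice"] = None if self.lattice is None else "custom"
        return rec


@dataclass
class SimulatedStudy:
    exposure: pd.DataFrame
    events: pd.DataFrame
    truth: dict


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Moving-average-smoothed standard-normal field, rescaled to unit variance."""
    noise = rng.standard_normal(shape)
    if radius <= 0:
        return noise
    sm = uniform_filter(noise, size=2 * radius + 1, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _seasonal(month: np.ndarray | int, amplitude: float, peak_month: float = 7.0) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (np.asarray(month, dtype=float) - peak_month) / 12.0)


def simulate_exposure_surfaces(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Monthly exposure table: one row per (grid, year, month).

    Each surface value is baseline + seasonal cosine (July peak) + loading x
    shared smoothed spatial field + monitor offset + smoothed surface noise,
    truncated at zero.  PMC and PMCQ are masked at the missingness rate; the
    Kriged surfaces (PMCK, PMCKQ) are always complete.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lattice = config.resolved_lattice()
    shape = (lattice.n_rows, lattice.n_cols)
    cells = sorted(lattice.cells, key=lambda c: (c.row, c.col))
    rows_idx = np.array([c.row - 1 for c in cells])
    cols_idx = np.array([c.col - 1 for c in cells])
    is_monitor = np.array([c.has_monitor for c in cells], dtype=float)

    records = []
    radius = config.spatial_correlation_range
    for year in config.years:
        for month in range(1, 13):
            latent = _smooth_field(rng, shape, radius)[rows_idx, cols_idx]
            # shared regional month anomaly: real monthly grid means deviate
            # from the climatological cycle region-wide
            base = (
                config.baseline_monthly_mean
                + _seasonal(month, config.seasonal_amplitude)
                + rng.normal(0.0, config.monthly_anomaly_sd)
            )
            at = (
                config.temperature_mean
                + _seasonal(month, config.temperature_amplitude)
                + rng.normal(0.0, config.temperature_anomaly_sd)
                + config.monitor_temperature_offset * is_monitor
                + 1.5 * _smooth_field(rng, shape, radius)[rows_idx, cols_idx]
            )
            pollen = np.clip(
                30.0 + 25.0 * np.cos(2.0 * np.pi * (month - 5.0) / 12.0)
                + 8.0 * rng.standard_normal(len(cells)),
                0.0, None,
            )
            holiday = np.full(len(cells), HOLIDAYS_PER_MONTH.get(month, 0) / 30.0)
            snow_rate = 0.25 if month in WINTER_MONTHS else 0.0
            snowstorm = np.full(len(cells), float(rng.random() < snow_rate) * 0.1)

            # grid-specific monthly deviation of the true PM field, common to
            # every surface (they estimate the same underlying concentrations)
            grid_dev = config.grid_month_sd * rng.standard_normal(len(cells))
            surf_vals = {}
            for name, (loading, noise_sd, offset) in SURFACE_PARAMS.items():
                noise = _smooth_field(rng, shape, max(radius - 1, 0))[rows_idx, cols_idx]
                vals = base + loading * latent + grid_dev + noise_sd * noise + offset * is_monitor
                surf_vals[name] = np.clip(vals, 0.0, None)
            for name in ("PMC", "PMCQ"):
                mask = rng.random(len(cells)) < config.missingness_rate
                surf_vals[name] = np.where(mask, np.nan, surf_vals[name])

            for i, cell in enumerate(cells):
                records.append({
                    "row": cell.row, "col": cell.col, "year": year, "month": month,
                    **{name: surf_vals[name][i] for name in SURFACE_PARAMS},
                    "AT": at[i], "pollen": pollen[i],
                    "holiday": holiday[i], "snowstorm": snowstorm[i],
                })
    return pd.DataFrame.from_records(records)


def _draw_categorical(rng: np.random.Generator, mix: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=size, p=probs)


def _effect_mask(lattice: Lattice, config: SimulationConfig) -> Mapping[tuple[int, int], float]:
    """Per-grid multiplier for the exposure effect (1 inside the planted area)."""
    cells = [c.coords for c in lattice.cells]
    if config.effect_spatial_range_grids is None or not config.source_grids:
        return {c: 1.0 for c in cells}
    order = [c.coords for c in canonical_order(lattice, "Both")]
    pos = {c: i for i, c in enumerate(order)}
    n = len(order)
    src = [pos[tuple(s)] for s in config.source_grids]
    mask = {}
    for c in cells:
        d = min(min(abs(pos[c] - s), n - abs(pos[c] - s)) for s in src)
        mask[c] = 1.0 if d <= config.effect_spatial_range_grids else 0.0
    return mask


def simulate_health_events(
    config: SimulationConfig,
    exposure: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hospital events with event-month log-odds linear in index-grid exposure.

    For each event the index grid (restricted to cells with health data) and
    year are drawn uniformly; the within-year event month is then drawn with
    probability proportional to ``exp(log(OR)/10 * PM + confounder terms)``,
    which is exactly the conditional model the case-crossover analysis fits.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lattice = config.resolved_lattice()
    eligible = [c for c in lattice.cells if c.has_health_data]
    effect = _effect_mask(lattice, config)
    conf = config.confounder_logodds

    # month-profile lookup per (grid, year): exposure effect + confounders
    surf = config.effect_surface
    exp_idx = exposure.set_index(["row", "col", "year", "month"]).sort_index()

    records = []
    event_id = 0
    for outcome in OUTCOMES:
        beta = np.log(config.true_or_per_10ug.get(outcome, 1.0)) / 10.0
        n = config.events_per_outcome
        if n == 0:
            continue
        grids = rng.integers(0, len(eligible), size=n)
        years = rng.choice(config.years, size=n)
        ages = np.clip(rng.normal(55.0, 20.0, size=n), 0, 95).astype(int)
        genders = _draw_categorical(rng, config.gender_mix, n)
        races = _draw_categorical(rng, config.race_mix, n)
        insurances = _draw_categorical(rng, config.insurance_mix, n)
        for j in range(n):
            cell = eligible[grids[j]]
            year = int(years[j])
            try:
                sub = exp_idx.loc[(cell.row, cell.col, year)]
            except KeyError:
                continue
            months = sub.index.to_numpy(dtype=int)
            pm = sub[surf].to_numpy(dtype=float)
            pm = np.where(np.isnan(pm), np.nanmean(pm), pm)
            logodds = beta * effect[cell.coords] * pm
            logodds = logodds + conf["AT"] * sub["AT"].to_numpy(dtype=float)
            logodds = logodds + conf["pollen"] * sub["pollen"].to_numpy(dtype=float)
            logodds = logodds + conf["holiday"] * sub["holiday"].to_numpy(dtype=float)
            logodds = logodds + conf["snowstorm"] * sub["snowstorm"].to_numpy(dtype=float)
            p = np.exp(logodds - logodds.max())
            p /= p.sum()
            month = int(rng.choice(months, p=p))
            day = int(rng.integers(1, calendar.monthrange(year, month)[1] + 1))
            event_id += 1
            records.append({
                "event_id": f"E{event_id:06d}",
                "outcome": outcome,
                "date": pd.Timestamp(year=year, month=month, day=day),
                "row": cell.row, "col": cell.col,
                "age": int(ages[j]),
                "gender": genders[j], "race": races[j], "insurance": insurances[j],
                "zip": f"Z{cell.row:02d}{cell.col:02d}",
                "atherosclerosis": bool(rng.random() < config.comorbidity_rates["atherosclerosis"]),
                "diabetes": bool(rng.random() < config.comorbidity_rates["diabetes"]),
                "hypertension": bool(rng.random() < config.comorbidity_rates["hypertension"]),
            })
    columns = ["event_id", "outcome", "date", "row", "col", "age", "gender", "race",
               "insurance", "zip", "atherosclerosis", "diabetes", "hypertension"]
    return pd.DataFrame.from_records(records, columns=columns)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full synthetic study: exposure table + events + truth record.

    Deterministic per (config, seed): identical configs produce byte-identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    exposure = simulate_exposure_surfaces(config, rng)
    events = simulate_health_events(config, exposure, rng)
    return SimulatedStudy(exposure=exposure, events=events, truth=config.truth())


# ---------------------------------------------------------------------------
# Stratum-level benchmark generators
# ---------------------------------------------------------------------------


def _case_first(x: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw the case member with prob proportional to exp(gamma * x); reorder case first."""
    w = np.exp(gamma * (x - x.max(axis=1, keepdims=True)))
    p = w / w.sum(axis=1, keepdims=True)
    u = rng.random((len(x), 1))
    case = (p.cumsum(axis=1) > u).argmax(axis=1)
    out = x.copy()
    idx = np.arange(len(x))
    out[idx, 0], out[idx, case] = x[idx, case], x[idx, 0]
    return out


def simulate_strata(
    n_strata: int,
    true_or_per_10ug: float,
    rng: np.random.Generator,
    exposure_mean: float = 14.0,
    exposure_sd: float = 10.0,
    n_controls: int = 3,
) -> np.ndarray:
    """Matched 1:M strata drawn exactly from the conditional logistic model.

    Returns a ``(n_strata, 1 + n_controls)`` exposure array (ug/m3) with the
    case in column 0: member exposures are iid normal and the case is the
    member drawn with probability proportional to
    ``exp(log(OR)/10 * exposure)``.
    """
    beta = np.log(true_or_per_10ug) / 10.0
    x = rng.normal(exposure_mean, exposure_sd, size=(n_strata, 1 + n_controls))
    return _case_first(x, beta, rng)


def planted_hosa_replicate(
    planted_range: int,
    rng: np.random.Generator,
    n_strata: int = 250,
    planted_or_per_sd: float = 1.5,
    lag_labels: Sequence[str] = LAG_LABELS,
) -> HOSAResult:
    """One synthetic study with a homogeneous spatial area of known width.

    The planted area spans lag grids 0..``planted_range``.  The experimental
    surface carries the exposure-outcome association (log-odds
    ``log(planted_or_per_sd)`` per SD of exposure) at exactly those lag labels
    whose grid span lies wholly inside the area; a span straddling the area
    boundary mixes unrelated exposures and carries no association.  The
    baseline surface is null everywhere.  Per label, both surfaces are fitted
    by conditional logistic regression on ``n_strata`` 1:3 strata and compared
    by the point-outside-reference-CI rule; the significant labels delineate
    the recovered HOSA, whose true width is ``planted_range + 1`` grids.
    """
    if planted_range < 0:
        raise ValueError("planted_range must be >= 0")
    beta = np.log(planted_or_per_sd)
    sig: list[str] = []
    for label in lag_labels:
        inside = max(lag_span(label)) <= planted_range
        gamma = beta if inside else 0.0
        x_exp = _case_first(rng.standard_normal((n_strata, 4)), gamma, rng)
        x_base = _case_first(rng.standard_normal((n_strata, 4)), 0.0, rng)
        fit_exp = fit_conditional_logit(x_exp[:, :, None], terms=("exposure",))
        fit_base = fit_conditional_logit(x_base[:, :, None], terms=("exposure",))
        o_e, lo_e, hi_e, _ = or_ci(fit_exp, "exposure")
        o_b, lo_b, hi_b, _ = or_ci(fit_base, "exposure")
        if compare_or_to_reference(o_e, (lo_e, hi_e), o_b, (lo_b, hi_b)).verdict == "higher":
            sig.append(str(label))
    return hosa_width(sig, surface="planted", outcome="synthetic", condition="Both")
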