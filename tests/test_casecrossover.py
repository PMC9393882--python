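"""Referent construction, quarterly exposures, and stratum building."""

import numpy as np
import pandas as pd
import pytest

from lagcross import (
    CONTROL_MONTHS,
    ExposureIndex,
    build_strata,
    case_exposure,
    control_exposures,
    mean_monthly_rank,
    quarter_of_month,
    season_label,
)
from lagcross.casecrossover import (
    QUARTER_MONTHS,
    CaseCrossoverError,
    MissingExposureError,
)


def month_indexed_exposure(values_by_month, grid=(5, 5), year=2004, surface="PMB"):
    """One grid-year of monthly values for one surface (plus required covariates)."""
    rows = []
    for m in range(1, 13):
        rows.append({
            "row": grid[0], "col": grid[1], "year": year, "month": m,
            surface: values_by_month.get(m, np.nan),
            "AT": 50.0, "pollen": 10.0, "holiday": 0.0, "snowstorm": 0.0,
        })
    return ExposureIndex(pd.DataFrame(rows))


class TestRanksAndSeasons:
    @pytest.mark.parametrize("month,quarter", [(2, "Q1"), (7, "Q3"), (12, "Q4"), (4, "Q2")])
    def test_quarter_of_month(self, month, quarter):
        assert quarter_of_month(month) == quarter

    def test_quarter_out_of_range(self):
        with pytest.raises(CaseCrossoverError):
            quarter_of_month(13)

    def test_case_mean_monthly_ranks_by_quarter(self):
        ranks = [mean_monthly_rank(QUARTER_MONTHS[q]) for q in ("Q1", "Q2", "Q3", "Q4")]
        assert ranks == [2.0, 5.0, 8.0, 11.0]

    def test_control_mean_monthly_ranks(self):
        ranks = [mean_monthly_rank(CONTROL_MONTHS[k]) for k in (1, 2, 3)]
        assert ranks == [5.5, 6.5, 7.5]

    def test_full_year_rank(self):
        assert mean_monthly_rank(range(1, 13)) == 6.5

    def test_bidirectional_rank_pattern(self):
        """Referent ranks sit above Q1/Q2 case ranks and below Q3/Q4 case ranks."""
        controls = [mean_monthly_rank(CONTROL_MONTHS[k]) for k in (1, 2, 3)]
        for q in ("Q1", "Q2"):
            assert all(c > mean_monthly_rank(QUARTER_MONTHS[q]) for c in controls)
        for q in ("Q3", "Q4"):
            assert all(c < mean_monthly_rank(QUARTER_MONTHS[q]) for c in controls)

    def test_season_label_defaults_and_override(self):
        assert season_label(7) == "warm"
        assert season_label(1) == "cold"
        assert season_label("Q3") == "warm"
        flipped = frozenset({10, 11, 12, 1, 2, 3})
        assert season_label(1, warm_months=flipped) == "warm"
        assert season_label(7, warm_months=flipped) == "cold"


class TestExposureAssignment:
    def test_case_quarterly_mean(self):
        exp = month_indexed_exposure({7: 10.0, 8: 12.0, 9: 14.0})
        assert case_exposure(exp, (5, 5), 2004, 7, "PMB") == pytest.approx(12.0)

    def test_referent_means_on_month_index_surface(self):
        exp = month_indexed_exposure({m: float(m) for m in range(1, 13)})
        assert control_exposures(exp, (5, 5), 2004, "PMB") == pytest.approx((5.5, 6.5, 7.5))

    def test_constant_surface_referents(self):
        exp = month_indexed_exposure({m: 3.25 for m in range(1, 13)})
        assert control_exposures(exp, (5, 5), 2004, "PMB") == pytest.approx((3.25,) * 3)

    def test_missing_month_uses_available_mean(self):
        exp = month_indexed_exposure({7: 10.0, 9: 14.0, 5: 20.0, 11: 30.0})
        # August missing from the Q3 quarter mean
        assert case_exposure(exp, (5, 5), 2004, 8, "PMB") == pytest.approx(12.0)
        # referent set {1,4,7,10} has only July present
        assert control_exposures(exp, (5, 5), 2004, "PMB")[0] == pytest.approx(10.0)

    def test_all_months_missing_errors(self):
        exp = month_indexed_exposure({1: 5.0})
        with pytest.raises(MissingExposureError):
            case_exposure(exp, (5, 5), 2004, 7, "PMB")

    def test_unknown_grid_errors(self):
        exp = month_indexed_exposure({m: 1.0 for m in range(1, 13)})
        with pytest.raises(MissingExposureError):
            case_exposure(exp, (9, 9), 2004, 7, "PMB")


def constant_exposure_table(lattice, value=10.0, year=2004):
    rows = []
    for c in lattice.cells:
        for m in range(1, 13):
            rows.append({"row": c.row, "col": c.col, "year": year, "month": m,
                         "PMB": value, "AT": 50.0, "pollen": 5.0,
                         "holiday": 0.0, "snowstorm": 0.0})
    return pd.DataFrame(rows)


def toy_events(n, rng, grids, year=2004):
    dates = [pd.Timestamp(year=year, month=int(m), day=10)
             for m in rng.integers(1, 13, size=n)]
    picks = rng.integers(0, len(grids), size=n)
    return pd.DataFrame({
        "event_id": [f"E{i}" for i in range(n)],
        "outcome": "ED_asthma",
        "date": dates,
        "row": [grids[i][0] for i in picks],
        "col": [grids[i][1] for i in picks],
        "age": rng.integers(5, 90, size=n),
        "gender": "F", "race": "Black", "insurance": "private",
        "zip": "Z1", "atherosclerosis": False, "diabetes": False,
        "hypertension": True,
    })


class TestBuildStrata:
    def test_one_to_three_structure(self, baltimore, small_study):
        events = small_study.events[small_study.events["outcome"] == "ED_asthma"]
        build = build_strata(events, small_study.exposure, baltimore, "Both",
                             surfaces=("PMB", "PMCK"))
        n = build.n_strata
        assert n + len(build.drops) == len(events)
        assert len(build.strata) == 4 * n
        assert build.strata["is_case"].mean() == pytest.approx(0.25)
        sizes = build.strata.groupby("stratum_id")["is_case"].agg(["size", "sum"])
        assert (sizes["size"] == 4).all() and (sizes["sum"] == 1).all()

    def test_matching_key_shared_within_stratum(self, baltimore, small_study):
        events = small_study.events[small_study.events["outcome"] == "IP_HF"].head(25)
        build = build_strata(events, small_study.exposure, baltimore, "Both",
                             surfaces=("PMB",))
        for col in ("age_band", "gender", "race", "insurance", "zip", "year",
                    "day_of_week", "quarter", "season"):
            assert (build.strata.groupby("stratum_id")[col].nunique() == 1).all()

    def test_summary_lag_is_mean_of_individual_lags(self, baltimore, small_study):
        events = small_study.events[small_study.events["outcome"] == "IP_MI"].head(30)
        build = build_strata(events, small_study.exposure, baltimore, "Both",
                             surfaces=("PMB",))
        df = build.strata
        np.testing.assert_allclose(
            df["PMB_l01"], (df["PMB_l0"] + df["PMB_l1"]) / 2.0, rtol=1e-12)
        np.testing.assert_allclose(
            df["PMB_l24"], (df["PMB_l2"] + df["PMB_l3"] + df["PMB_l4"]) / 3.0, rtol=1e-12)
        np.testing.assert_allclose(
            df["PMB_l04"],
            df[[f"PMB_l{k}" for k in range(5)]].mean(axis=1), rtol=1e-12)

    def test_constant_surface_is_lag_invariant(self, baltimore, rng):
        """On a spatially constant surface every lag carries the same exposure."""
        exposure = constant_exposure_table(baltimore, value=7.5)
        grids = [c.coords for c in baltimore.cells]
        events = toy_events(20, rng, grids)
        build = build_strata(events, exposure, baltimore, "Both", surfaces=("PMB",))
        lag_cols = [c for c in build.strata.columns if c.startswith("PMB_l")]
        vals = build.strata[lag_cols].to_numpy()
        np.testing.assert_allclose(vals, 7.5)

    def test_condition_mismatch_drops_with_reason(self, baltimore, rng):
        exposure = constant_exposure_table(baltimore)
        events = toy_events(10, rng, [(9, 7)])  # no-monitor grid
        build = build_strata(events, exposure, baltimore, "Yes", surfaces=("PMB",))
        assert build.n_strata == 0
        assert set(build.drops["reason"]) == {"unresolvable_grid"}

    def test_centroid_resolution(self, baltimore, rng):
        exposure = constant_exposure_table(baltimore)
        events = toy_events(5, rng, [(1, 1)]).drop(columns=["row", "col"])
        events["centroid_x"] = 54.0  # center of column 5
        events["centroid_y"] = 54.0  # center of row 5
        build = build_strata(events, exposure, baltimore, "Both", surfaces=("PMB",))
        assert (build.strata["index_row"] == 5).all()
        assert (build.strata["index_col"] == 5).all()
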