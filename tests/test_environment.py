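"""Synthetic climate, ENSO and landscape generation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snakesim.environment import (
    ClimateGenParams,
    LandCover,
    OniSeries,
    Season,
    classify_rainy_day,
    generate_daily_rainfall,
    generate_landscape,
    generate_oni_series,
    load_default_climatology,
    load_landscape,
    load_oni_csv,
    load_rainfall_csv,
    month_to_season,
    monthly_totals,
    save_landscape,
    save_oni_csv,
)

from conftest import neutral_oni


class TestSeasons:
    @pytest.mark.parametrize(
        "month,season",
        [(12, Season.NEM), (1, Season.NEM), (2, Season.NEM),
         (3, Season.FIM), (4, Season.FIM),
         (5, Season.SWM), (6, Season.SWM), (9, Season.SWM),
         (10, Season.SIM), (11, Season.SIM)],
    )
    def test_month_mapping(self, month, season):
        assert month_to_season(month) is season

    def test_mapping_partitions_the_year(self):
        by_season = {s: [m for m in range(1, 13) if month_to_season(m) is s] for s in Season}
        all_months = sorted(m for ms in by_season.values() for m in ms)
        assert all_months == list(range(1, 13))

    @pytest.mark.parametrize("month", [0, 13, -1])
    def test_out_of_range_month_rejected(self, month):
        with pytest.raises(ValueError):
            month_to_season(month)


class TestRainyDay:
    @pytest.mark.parametrize(
        "rain,threshold,expected",
        [(0.0, 2.5, False), (2.5, 2.5, True), (10.0, 2.5, True), (2.4999, 2.5, False)],
    )
    def test_threshold_is_inclusive(self, rain, threshold, expected):
        assert classify_rainy_day(rain, threshold) is expected

    def test_negative_rainfall_rejected(self):
        with pytest.raises(ValueError):
            classify_rainy_day(-1.0, 2.5)


class TestEnsoSigns:
    """The season-block sign structure of ENSO rainfall anomalies."""

    def test_january_march_both_phases_dry(self, climatology):
        for month in (1, 2, 3):
            assert climatology.enso_shift_mm(month, +2.0) < 0
            assert climatology.enso_shift_mm(month, -2.0) < 0

    def test_april_june_el_nino_wet_la_nina_dry(self, climatology):
        for month in (4, 5, 6):
            assert climatology.enso_shift_mm(month, +2.0) > 0
            assert climatology.enso_shift_mm(month, -2.0) < 0

    def test_july_september_la_nina_wet_el_nino_dry(self, climatology):
        for month in (7, 8, 9):
            assert climatology.enso_shift_mm(month, -2.0) > 0
            assert climatology.enso_shift_mm(month, +2.0) < 0

    def test_october_december_el_nino_wet(self, climatology):
        for month in (10, 11, 12):
            assert climatology.enso_shift_mm(month, +2.0) > 0
            assert climatology.enso_shift_mm(month, -2.0) < 0

    def test_neutral_oni_no_shift(self, climatology):
        assert climatology.enso_shift_mm(5, 0.3) == 0.0
        assert climatology.enso_shift_mm(5, -0.49) == 0.0

    def test_non_finite_oni_rejected(self, climatology):
        with pytest.raises(ValueError):
            climatology.enso_shift_mm(5, float("nan"))


class TestRainfallGenerator:
    def test_zero_enso_monthly_expectation(self):
        """With flat 100 mm climatology the mean monthly total is ~100 mm."""
        params = ClimateGenParams(
            monthly_mean_rain_mm=[100.0] * 12,
            monthly_mean_rainy_days=[10.0] * 12,
            enso_gain=0.0,
        )
        frames = [
            monthly_totals(generate_daily_rainfall(params, neutral_oni(1), 1, seed=s))
            for s in range(85)
        ]
        totals = pd.concat(frames)["rain_mm"].to_numpy()
        # 1020 monthly draws; SE = sd/sqrt(n)
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - 100.0) < 3 * se

    def test_replicate_january_mean_matches_climatology(self, climatology):
        """Monte-Carlo check of the January expectation against its setting."""
        rng = np.random.default_rng(7)
        jans = []
        for _ in range(1000):
            params = climatology
            oni = neutral_oni(1)
            clim = generate_daily_rainfall(params, oni, 1, seed=rng)
            jans.append(clim[clim["month"] == 1]["rainfall_mm"].sum())
        jans = np.asarray(jans)
        se = jans.std(ddof=1) / np.sqrt(jans.size)
        assert abs(jans.mean() - climatology.monthly_mean_rain_mm[0]) < 3 * se

    def test_el_nino_may_wetter_than_neutral(self, climatology):
        """April-June block: a strong positive ONI in May raises May's total."""
        may_neutral, may_nino = [], []
        nino = OniSeries({(2008, m): (2.0 if m == 5 else 0.0) for m in range(1, 13)})
        for s in range(500):
            c0 = generate_daily_rainfall(climatology, neutral_oni(1), 1, seed=s)
            c1 = generate_daily_rainfall(climatology, nino, 1, seed=s)
            may_neutral.append(c0[c0["month"] == 5]["rainfall_mm"].sum())
            may_nino.append(c1[c1["month"] == 5]["rainfall_mm"].sum())
        assert np.mean(may_nino) > np.mean(may_neutral)

    def test_rainy_day_counts_bounded_and_totals_nonnegative(self, climatology):
        oni = generate_oni_series(10, seed=3)
        clim = generate_daily_rainfall(climatology, oni, 10, seed=3)
        assert (clim["rainfall_mm"] >= 0).all()
        m = monthly_totals(clim)
        days_in = clim.groupby(["year", "month"])["day"].count()
        assert (m.set_index(["year", "month"])["rainy_days"] <= days_in).all()

    def test_is_rainy_consistent_with_threshold(self, climatology):
        clim = generate_daily_rainfall(climatology, neutral_oni(2), 2, seed=9)
        expected = clim["rainfall_mm"] >= climatology.rainy_day_threshold_mm
        assert (clim["is_rainy"] == expected).all()

    def test_deterministic_for_fixed_seed(self, climatology):
        a = generate_daily_rainfall(climatology, neutral_oni(2), 2, seed=5)
        b = generate_daily_rainfall(climatology, neutral_oni(2), 2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_oni_coverage_rejected(self, climatology):
        with pytest.raises(ValueError, match="cover"):
            generate_daily_rainfall(climatology, neutral_oni(1), 3, seed=0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClimateGenParams(
                monthly_mean_rain_mm=[2000.0] * 12, monthly_mean_rainy_days=[10.0] * 12
            )
        with pytest.raises(ValueError):
            ClimateGenParams(
                monthly_mean_rain_mm=[100.0] * 12, monthly_mean_rainy_days=[35.0] * 12
            )


class TestOniGenerator:
    def test_zero_amplitude_is_all_zero(self):
        oni = generate_oni_series(3, amplitude=0.0, seed=1)
        assert all(v == 0.0 for v in oni.entries.values())

    def test_waveform_spans_both_phases(self):
        oni = generate_oni_series(8, amplitude=2.0, period_months=48, seed=2)
        vals = np.array(list(oni.entries.values()))
        assert vals.min() <= -1.0 and vals.max() >= 1.0

    def test_deterministic(self):
        a = generate_oni_series(4, seed=11)
        b = generate_oni_series(4, seed=11)
        assert a.entries == b.entries

    def test_short_period_rejected(self):
        with pytest.raises(ValueError):
            generate_oni_series(2, period_months=6)

    def test_missing_month_rejected_naming_the_gap(self):
        entries = {(2010, m): 0.0 for m in range(1, 13)}
        entries.update({(2011, m): 0.0 for m in range(1, 13)})
        entries.update({(2012, m): 0.0 for m in range(1, 13)})
        del entries[(2011, 7)]
        with pytest.raises(ValueError, match=r"\[7\] of year 2011"):
            OniSeries(entries)


class TestLandscape:
    def test_single_class_fills_grid(self):
        ls = generate_landscape(10, 10, {LandCover.FOREST: 1.0}, seed=0)
        assert (ls.grid == LandCover.FOREST.value).all()
        assert ls.area_fraction()[LandCover.FOREST] == 1.0

    def test_equal_sixths_counts_within_two_cells(self):
        fracs = {c: 1 / 6 for c in LandCover}
        ls = generate_landscape(20, 20, fracs, seed=1)
        counts = np.bincount(ls.grid.ravel(), minlength=6)
        assert all(abs(c - 400 / 6) <= 2 for c in counts)

    def test_positive_fraction_gets_at_least_one_cell(self):
        fracs = {LandCover.FOREST: 0.999, LandCover.HOME: 0.001}
        ls = generate_landscape(10, 10, fracs, seed=2)
        assert ls.cells_of(LandCover.HOME).size >= 1

    def test_deterministic(self):
        fracs = {c: 1 / 6 for c in LandCover}
        a = generate_landscape(15, 15, fracs, clustering=0.7, seed=3)
        b = generate_landscape(15, 15, fracs, clustering=0.7, seed=3)
        assert np.array_equal(a.grid, b.grid)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_landscape(5, 5, {LandCover.FOREST: 0.5})

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_fractions_sum_to_one_for_random_seeds(self, seed):
        fracs = {LandCover.RICE: 0.3, LandCover.FOREST: 0.5, LandCover.HOME: 0.2}
        ls = generate_landscape(8, 8, fracs, seed=seed)
        assert sum(ls.area_fraction().values()) == pytest.approx(1.0)


class TestFileRoundTrips:
    def test_landscape_round_trip(self, tmp_path):
        fracs = {c: 1 / 6 for c in LandCover}
        ls = generate_landscape(5, 5, fracs, seed=4)
        path = tmp_path / "grid.txt"
        save_landscape(ls, path)
        back = load_landscape(path)
        assert np.array_equal(ls.grid, back.grid)

    def test_landscape_unknown_code_located(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("RRX\nRRR\nRRR\n")
        with pytest.raises(ValueError, match="line 1, column 3"):
            load_landscape(path)

    def test_oni_round_trip_and_gap_detection(self, tmp_path):
        oni = generate_oni_series(2, seed=5)
        path = tmp_path / "oni.csv"
        save_oni_csv(oni, path)
        back = load_oni_csv(path)
        assert back.entries == pytest.approx(oni.entries)

        frame = oni.to_frame()
        frame = frame[~((frame.year == frame.year.min()) & (frame.month == 6))]
        bad = tmp_path / "gap.csv"
        frame.to_csv(bad, index=False)
        with pytest.raises(ValueError, match=r"missing months \[6\]"):
            load_oni_csv(bad)

    def test_rainfall_csv_row(self, tmp_path):
        path = tmp_path / "rain.csv"
        path.write_text("date,rainfall_mm\n2008-01-01,12.5\n")
        clim = load_rainfall_csv(path)
        assert len(clim) == 1
        row = clim.iloc[0]
        assert (row.year, row.month, row.day) == (2008, 1, 1)
        assert row.rainfall_mm == 12.5
        assert bool(row.is_rainy) is True

    def test_rainfall_csv_negative_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("date,rainfall_mm\n2008-01-01,-3.0\n")
        with pytest.raises(ValueError, match="negative rainfall"):
            load_rainfall_csv(path)
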