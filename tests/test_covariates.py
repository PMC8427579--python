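"""Covariate derivations: slope/aspect factor, PET, water balance, degree days."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ingrowth.covariates import (
    ClimateSeries,
    TerrainSoil,
    bucket_size,
    degree_day_sum,
    monthly_pet,
    seasonal_water_balance,
    site_environment,
    site_environment_table,
    slope_aspect_factor,
    thornthwaite_pet,
)
from tests.conftest import make_daily_climate


def climate_from_frame(frame: pd.DataFrame, plot_id: str = "A") -> ClimateSeries:
    return ClimateSeries.from_frame(frame, plot_id)


class TestSlopeAspectFactor:
    def test_flat_ground_is_neutral(self):
        for aspect in (0.0, 90.0, 180.0, 359.0):
            assert slope_aspect_factor(0.0, aspect) == 1.0

    def test_south_facing_45_degrees(self):
        assert slope_aspect_factor(45.0, 180.0) == pytest.approx(1.25)

    def test_north_facing_45_degrees(self):
        assert slope_aspect_factor(45.0, 0.0) == pytest.approx(0.874)

    def test_steepness_capped_at_45_degrees(self):
        assert slope_aspect_factor(90.0, 180.0) == pytest.approx(1.25)

    def test_binary_mode_matches_endpoints(self):
        assert slope_aspect_factor(45.0, 170.0, mode="binary") == pytest.approx(1.25)
        assert slope_aspect_factor(45.0, 10.0, mode="binary") == pytest.approx(0.874)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            slope_aspect_factor(-1.0, 0.0)
        with pytest.raises(ValueError):
            slope_aspect_factor(10.0, 360.0)

    @given(
        slope=st.floats(0, 90),
        aspect=st.floats(0, 359.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, slope, aspect):
        k = slope_aspect_factor(slope, aspect)
        assert 0.874 <= k <= 1.25

    @given(slope=st.floats(0.1, 90), a=st.floats(0, 179), b=st.floats(0, 179))
    @settings(max_examples=100, deadline=None)
    def test_monotone_toward_south(self, slope, a, b):
        # On the eastern half-plane, aspect closer to 180 (south) never lowers k.
        lo, hi = sorted((a, b))
        assert slope_aspect_factor(slope, hi) >= slope_aspect_factor(slope, lo) - 1e-12


class TestThornthwaitePet:
    def test_zero_below_freezing(self):
        pet = thornthwaite_pet([-5.0] * 12, latitude=47.0)
        assert np.all(pet == 0.0)

    def test_equator_constant_10c_matches_hand_formula(self):
        # Independent oracle: published Thornthwaite formula, hand-coded.
        heat_index = 12 * (10.0 / 5.0) ** 1.514
        a = (
            6.75e-7 * heat_index**3
            - 7.71e-5 * heat_index**2
            + 1.792e-2 * heat_index
            + 0.49239
        )
        unadj = 16.0 * (10.0 * 10.0 / heat_index) ** a
        days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        expected = [unadj * 1.0 * (n / 30.0) for n in days]  # L = 12h at equator
        pet = thornthwaite_pet([10.0] * 12, latitude=0.0)
        assert pet == pytest.approx(expected, rel=1e-9)

    def test_kpmod_is_pure_scaling(self):
        tmean = [1, 3, 6, 9, 13, 16, 18, 17, 13, 9, 4, 1]
        base = monthly_pet(tmean, latitude=47.0, kpmod=1.0)
        scaled = monthly_pet(tmean, latitude=47.0, kpmod=1.25)
        assert scaled == pytest.approx(1.25 * base)

    def test_nonnegative_and_zero_months(self):
        tmean = [-3, -1, 0, 5, 12, 18, 20, 19, 14, 8, 2, -2]
        pet = thornthwaite_pet(tmean, latitude=50.0)
        assert np.all(pet >= 0)
        assert pet[0] == pet[1] == pet[2] == 0.0  # tmean <= 0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            thornthwaite_pet([10.0] * 11, latitude=0.0)


class TestDegreeDaySum:
    def test_all_days_at_base_gives_zero(self):
        climate = climate_from_frame(make_daily_climate("A", [2000], 5.5, 0.0))
        assert degree_day_sum(climate) == 0.0

    def test_three_day_toy_window(self):
        # Base case: a season at exactly 5.5 degC except three known days.
        frame = make_daily_climate("A", [2000], 5.5, 0.0)
        frame.loc[frame["date"] == "2000-05-01", "tmean_c"] = 10.0
        frame.loc[frame["date"] == "2000-05-02", "tmean_c"] = 5.0
        frame.loc[frame["date"] == "2000-05-03", "tmean_c"] = 7.0
        climate = climate_from_frame(frame)
        assert degree_day_sum(climate) == pytest.approx(6.0)  # 4.5 + 0 + 1.5

    def test_constant_15c_full_season(self):
        climate = climate_from_frame(make_daily_climate("A", [2001], 15.0, 0.0))
        # April-October is 214 days; 214 * 9.5
        assert degree_day_sum(climate) == pytest.approx(2033.0)

    def test_mean_over_years(self):
        frame = pd.concat(
            [
                make_daily_climate("A", [2000], 15.0, 0.0),
                make_daily_climate("A", [2001], 5.5, 0.0),
            ],
            ignore_index=True,
        )
        climate = climate_from_frame(frame)
        assert degree_day_sum(climate) == pytest.approx(2033.0 / 2)

    def test_missing_days_raise(self):
        frame = make_daily_climate("A", [2000], 15.0, 0.0)
        frame = frame[frame["date"] != "2000-07-15"]
        with pytest.raises(ValueError, match="2000"):
            degree_day_sum(climate_from_frame(frame))

    def test_agrees_with_naive_loop_oracle(self):
        rng = np.random.default_rng(42)
        frame = make_daily_climate("A", [2000, 2001], 0.0, 0.0)
        frame["tmean_c"] = rng.uniform(-5, 25, len(frame))
        climate = climate_from_frame(frame)
        # brute-force day-by-day loop
        by_year = {}
        for _, row in frame.iterrows():
            date = pd.Timestamp(row["date"])
            if 4 <= date.month <= 10:
                by_year.setdefault(date.year, 0.0)
                by_year[date.year] += max(row["tmean_c"] - 5.5, 0.0)
        expected = np.mean(list(by_year.values()))
        assert degree_day_sum(climate) == pytest.approx(expected)


class TestSeasonalWaterBalance:
    TERRAIN = TerrainSoil(
        plot_id="A", slope=0.0, aspect=0.0, sdr=1.0, awc=0.2, cfv=0.1, latitude=47.0
    )

    def test_precip_equal_to_pet_gives_zero(self):
        tmean = {m: 12.0 for m in range(1, 13)}
        pet = monthly_pet([12.0] * 12, latitude=47.0, kpmod=1.0)
        precip = {m: float(pet[m - 1]) for m in range(1, 13)}
        climate = climate_from_frame(make_daily_climate("A", [2000], tmean, precip))
        assert seasonal_water_balance(climate, self.TERRAIN) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_constant_surplus(self):
        tmean = {m: 12.0 for m in range(1, 13)}
        pet = monthly_pet([12.0] * 12, latitude=47.0, kpmod=1.0)
        precip = {m: float(pet[m - 1]) + 50.0 for m in range(1, 13)}
        climate = climate_from_frame(make_daily_climate("A", [2000], tmean, precip))
        assert seasonal_water_balance(climate, self.TERRAIN) == pytest.approx(
            350.0, abs=1e-9
        )

    def test_mean_of_per_year_balances(self):
        # Per-year balances {-100, 0, +250} -> mean +50 (brute-force oracle).
        tmean = {m: 12.0 for m in range(1, 13)}
        pet = monthly_pet([12.0] * 12, latitude=47.0, kpmod=1.0)
        frames = []
        for year, offset in ((2000, -100.0), (2001, 0.0), (2002, 250.0)):
            precip = {m: float(pet[m - 1]) + offset / 7.0 for m in range(1, 13)}
            frames.append(make_daily_climate("A", [year], tmean, precip))
        climate = climate_from_frame(pd.concat(frames, ignore_index=True))
        assert seasonal_water_balance(climate, self.TERRAIN) == pytest.approx(
            50.0, abs=1e-8
        )

    def test_incomplete_season_raises(self):
        frame = make_daily_climate("A", [2000], 12.0, 50.0)
        frame = frame[~frame["date"].str.startswith("2000-06")]
        with pytest.raises(ValueError, match="2000"):
            seasonal_water_balance(climate_from_frame(frame), self.TERRAIN)


class TestBucketSize:
    def test_basic(self):
        t = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=2.0, awc=0.20, cfv=0.0)
        assert bucket_size(t) == pytest.approx(40.0)

    def test_all_coarse_gives_zero(self):
        t = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=1.5, awc=0.30, cfv=1.0)
        assert bucket_size(t) == 0.0

    def test_depth_capped_at_two_meters(self):
        deep = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=3.0, awc=0.20, cfv=0.0)
        assert bucket_size(deep) == pytest.approx(40.0)

    @given(
        sdr=st.floats(0, 10),
        awc=st.floats(0, 1),
        cfv=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, sdr, awc, cfv):
        t = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=sdr, awc=awc, cfv=cfv)
        bs = bucket_size(t)
        assert 0 <= bs <= 200.0 * awc + 1e-9

    def test_invariant_above_cap(self):
        a = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=2.5, awc=0.2, cfv=0.3)
        b = TerrainSoil(plot_id="A", slope=0, aspect=0, sdr=9.9, awc=0.2, cfv=0.3)
        assert bucket_size(a) == bucket_size(b)


class TestSiteEnvironment:
    def test_end_to_end_table(self):
        tmean = {m: t for m, t in zip(range(1, 13), [0, 2, 5, 9, 13, 17, 19, 18, 14, 9, 4, 1])}
        climate = make_daily_climate("A", [2000, 2001], tmean, 60.0)
        terrain = pd.DataFrame(
            [
                {
                    "plot_id": "A",
                    "slope_deg": 20.0,
                    "aspect_deg": 200.0,
                    "sdr_m": 1.2,
                    "awc_frac": 0.25,
                    "cfv_frac": 0.2,
                }
            ]
        )
        table = site_environment_table(climate, terrain)
        assert list(table.columns) == ["plot_id", "dds", "wb", "bs", "kpmod"]
        row = table.iloc[0]
        assert row["dds"] > 0
        assert row["bs"] == pytest.approx(120 * 0.25 * 0.8)
        assert 1.0 < row["kpmod"] <= 1.25  # south-ish facing

    def test_plot_mismatch_raises(self):
        climate = climate_from_frame(make_daily_climate("A", [2000], 10.0, 50.0))
        terrain = TerrainSoil(plot_id="B", slope=0, aspect=0, sdr=1, awc=0.2, cfv=0.0)
        with pytest.raises(ValueError, match="mismatch"):
            site_environment(climate, terrain)

    def test_climate_invariants(self):
        with pytest.raises(ValueError, match="non-negative"):
            ClimateSeries(
                plot_id="A",
                dates=pd.DatetimeIndex(["2000-01-01", "2000-01-02"]),
                tmean=np.array([1.0, 2.0]),
                precip=np.array([1.0, -3.0]),
            )
        with pytest.raises(ValueError, match="increasing"):
            ClimateSeries(
                plot_id="A",
                dates=pd.DatetimeIndex(["2000-01-02", "2000-01-01"]),
                tmean=np.array([1.0, 2.0]),
                precip=np.array([1.0, 3.0]),
            )
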