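"""Environmental site covariates from climate, terrain and soil inputs.

Three plot-level covariates are derived here:

* seasonal degree-day sum (April--October, base 5.5 degC), averaged over years,
* seasonal water balance (monthly precipitation minus slope/aspect-corrected
  Thornthwaite potential evapotranspiration, April--October), averaged over years,
* soil "bucket size" (maximum plant-available water store, cm).

All functions operate on plain numpy/pandas inputs; :func:`site_environment`
is the per-plot driver that combines them.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "TerrainSoil",
    "SiteEnvironment",
    "SEASON_MONTHS",
    "DEGREE_DAY_BASE",
    "slope_aspect_factor",
    "thornthwaite_pet",
    "monthly_pet",
    "seasonal_water_balance",
    "degree_day_sum",
    "bucket_size",
    "site_environment",
]

#: April--October, the growing season used for water balance and degree days.
SEASON_MONTHS = tuple(range(4, 11))

#: Base temperature (degC) above which daily mean temperature accumulates.
DEGREE_DAY_BASE = 5.5

_DAYS_PER_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MID_MONTH_DOY = (15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)

# Slope/aspect PET correction constants: the multiplier spans
# [1 - 2*0.063, 1 + 2*0.125] between a fully north- and south-facing
# 45-degree (or steeper) slope.
_KP_SOUTH = 0.125
_KP_NORTH = 0.063


@dataclasses.dataclass(frozen=True)
class ClimateSeries:
    """Daily climate record for one plot.

    Parameters
    ----------
    plot_id : str
        Plot identifier.
    dates : pandas.DatetimeIndex
        Strictly increasing calendar days.
    tmean : numpy.ndarray
        Daily mean temperature, degC.
    precip : numpy.ndarray
        Daily precipitation, mm; non-negative.
    """

    plot_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        tmean = np.asarray(self.tmean, dtype=float)
        precip = np.asarray(self.precip, dtype=float)
        if len(dates) != len(tmean) or len(dates) != len(precip):
            raise ValueError("dates, tmean and precip must have equal length")
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if len(dates) != dates.nunique():
            raise ValueError("dates contain duplicates")
        if np.any(precip < 0):
            raise ValueError("precip must be non-negative")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "tmean", tmean)
        object.__setattr__(self, "precip", precip)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, plot_id: str) -> "ClimateSeries":
        """Build a series from a climate table (columns date, tmean_c, precip_mm)."""
        sub = frame.loc[frame["plot_id"] == plot_id]
        if sub.empty:
            raise KeyError(f"no climate rows for plot {plot_id!r}")
        return cls(
            plot_id=plot_id,
            dates=pd.DatetimeIndex(pd.to_datetime(sub["date"])),
            tmean=sub["tmean_c"].to_numpy(dtype=float),
            precip=sub["precip_mm"].to_numpy(dtype=float),
        )

    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)


@dataclasses.dataclass(frozen=True)
class TerrainSoil:
    """Terrain and soil attributes for one plot."""

    plot_id: str
    slope: float  # degrees, >= 0
    aspect: float  # degrees clockwise from north, [0, 360)
    sdr: float  # soil depth to bedrock, m
    awc: float  # plant-available water capacity, fraction
    cfv: float  # volumetric coarse-fragment fraction
    latitude: float = 47.0  # degrees, used for PET daylength correction

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0, got {self.slope}")
        if not 0 <= self.aspect < 360:
            raise ValueError(f"aspect must lie in [0, 360), got {self.aspect}")
        if self.sdr < 0:
            raise ValueError(f"sdr must be >= 0, got {self.sdr}")
        if not 0 <= self.awc <= 1:
            raise ValueError(f"awc must lie in [0, 1], got {self.awc}")
        if not 0 <= self.cfv <= 1:
            raise ValueError(f"cfv must lie in [0, 1], got {self.cfv}")
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude must lie in [-90, 90], got {self.latitude}")


@dataclasses.dataclass(frozen=True)
class SiteEnvironment:
    """Derived per-plot environmental covariates."""

    plot_id: str
    dds: float  # mean seasonal degree-day sum, degC * d
    wb: float  # mean seasonal water balance, mm
    bs: float  # bucket size, cm
    kpmod: float  # PET slope/aspect multiplier

    def __post_init__(self) -> None:
        if self.dds < 0:
            raise ValueError("dds must be >= 0")
        if self.bs < 0:
            raise ValueError("bs must be >= 0")
        lo, hi = 1 - 2 * _KP_NORTH, 1 + 2 * _KP_SOUTH
        if not lo <= self.kpmod <= hi:
            raise ValueError(f"kpmod must lie in [{lo}, {hi}], got {self.kpmod}")


def slope_aspect_factor(
    slope: float,
    aspect: float,
    mode: Literal["cosine", "binary"] = "cosine",
) -> float:
    """PET correction multiplier from slope steepness and aspect.

    The steepness score ``s = min(slope/45 * 2, 2)`` is signed by exposure:
    -1 due north, +1 due south.  ``mode='cosine'`` interpolates continuously
    with ``-cos(aspect)``; ``mode='binary'`` uses the sign of the north/south
    component only.  The signed score maps to the multiplier with an
    asymmetric gain (south-facing slopes gain more PET than north-facing
    slopes lose).

    Returns a value in ``[1 - 2*0.063, 1 + 2*0.125] = [0.874, 1.25]``.
    """
    if slope < 0:
        raise ValueError(f"slope must be >= 0, got {slope}")
    if not 0 <= aspect < 360:
        raise ValueError(f"aspect must lie in [0, 360), got {aspect}")
    s = min(slope / 45.0 * 2.0, 2.0)
    cos_a = math.cos(math.radians(aspect))
    if mode == "cosine":
        k_sl_asp = -s * cos_a
    elif mode == "binary":
        k_sl_asp = -s if cos_a > 0 else (s if cos_a < 0 else 0.0)
    else:
        raise ValueError(f"unknown aspect mode {mode!r}")
    if k_sl_asp > 0:
        return 1.0 + k_sl_asp * _KP_SOUTH
    return 1.0 + k_sl_asp * _KP_NORTH


def _heat_index(monthly_tmean: np.ndarray) -> float:
    pos = np.clip(monthly_tmean, 0.0, None)
    return float(np.sum((pos / 5.0) ** 1.514))


def _daylength_hours(latitude: float, doy: int) -> float:
    """Mean day length (hours) at a latitude for a day of year."""
    decl = 0.409 * math.sin(2.0 * math.pi / 365.0 * doy - 1.39)
    x = -math.tan(math.radians(latitude)) * math.tan(decl)
    x = min(1.0, max(-1.0, x))  # polar day/night clamp
    return 24.0 / math.pi * math.acos(x)


def thornthwaite_pet(monthly_tmean: Sequence[float], latitude: float) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), Thornthwaite (1948).

    Uses the annual heat index ``I = sum((T_i/5)^1.514)`` over months with
    positive mean temperature, the cubic exponent
    ``a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239`` and the
    standard daylength / day-count correction ``(L/12) * (N/30)``.
    Months with mean temperature <= 0 degC yield zero.
    """
    t = np.asarray(monthly_tmean, dtype=float)
    if t.shape != (12,):
        raise ValueError("monthly_tmean must have exactly 12 values")
    if not -90 <= latitude <= 90:
        raise ValueError(f"latitude must lie in [-90, 90], got {latitude}")
    heat = _heat_index(t)
    pet = np.zeros(12)
    if heat <= 0:
        return pet
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    for m in range(12):
        if t[m] <= 0:
            continue
        unadj = 16.0 * (10.0 * t[m] / heat) ** a
        corr = (_daylength_hours(latitude, _MID_MONTH_DOY[m]) / 12.0) * (
            _DAYS_PER_MONTH[m] / 30.0
        )
        pet[m] = unadj * corr
    return pet


def monthly_pet(
    monthly_tmean: Sequence[float], latitude: float, kpmod: float = 1.0
) -> np.ndarray:
    """Slope/aspect-corrected monthly PET: Thornthwaite PET scaled by ``kpmod``."""
    return thornthwaite_pet(monthly_tmean, latitude) * float(kpmod)


def _monthly_frame(climate: ClimateSeries) -> pd.DataFrame:
    """Monthly mean temperature and precipitation sums with day counts."""
    df = pd.DataFrame(
        {
            "year": climate.dates.year,
            "month": climate.dates.month,
            "tmean": climate.tmean,
            "precip": climate.precip,
        }
    )
    out = df.groupby(["year", "month"], as_index=False).agg(
        tmean=("tmean", "mean"), precip=("precip", "sum"), ndays=("tmean", "size")
    )
    return out


def _check_season_coverage(
    monthly: pd.DataFrame, years: Iterable[int], what: str
) -> None:
    missing: list[int] = []
    for year in years:
        season = monthly[(monthly["year"] == year) & monthly["month"].isin(SEASON_MONTHS)]
        expected_days = sum(_DAYS_PER_MONTH[m - 1] for m in SEASON_MONTHS)
        if len(season) != len(SEASON_MONTHS) or season["ndays"].sum() < expected_days:
            missing.append(int(year))
    if missing:
        raise ValueError(
            f"incomplete April-October coverage for {what} in year(s) {missing}"
        )


def seasonal_water_balance(
    climate: ClimateSeries,
    terrain: TerrainSoil,
    years: Iterable[int] | None = None,
    aspect_mode: Literal["cosine", "binary"] = "cosine",
) -> float:
    """Mean seasonal (April--October) water balance over years, mm.

    Per year: sum over season months of monthly precipitation minus
    slope/aspect-corrected monthly Thornthwaite PET; the PET heat index is
    computed from that year's 12 monthly means.
    """
    monthly = _monthly_frame(climate)
    years = sorted(climate.years() if years is None else years)
    _check_season_coverage(monthly, years, climate.plot_id)
    kpmod = slope_aspect_factor(terrain.slope, terrain.aspect, mode=aspect_mode)
    balances = []
    for year in years:
        ydat = monthly[monthly["year"] == year].set_index("month")
        tm = np.full(12, np.nan)
        for m, row in ydat.iterrows():
            tm[m - 1] = row["tmean"]
        # PET needs a full 12-month heat index; months absent from the series
        # outside the season contribute 0 (treated as dormant).
        tm = np.nan_to_num(tm, nan=0.0)
        pet = monthly_pet(tm, terrain.latitude, kpmod)
        balance = sum(
            float(ydat.loc[m, "precip"]) - pet[m - 1] for m in SEASON_MONTHS
        )
        balances.append(balance)
    return float(np.mean(balances))


def degree_day_sum(climate: ClimateSeries, years: Iterable[int] | None = None) -> float:
    """Mean seasonal degree-day sum over years, degC * d.

    Per year: sum of ``max(T_d - 5.5, 0)`` over April 1 -- October 31; missing
    days raise (no imputation).
    """
    years = sorted(climate.years() if years is None else years)
    df = pd.DataFrame(
        {
            "year": climate.dates.year,
            "month": climate.dates.month,
            "tmean": climate.tmean,
        }
    )
    sums = []
    for year in years:
        season = df[(df["year"] == year) & df["month"].isin(SEASON_MONTHS)]
        expected = sum(_DAYS_PER_MONTH[m - 1] for m in SEASON_MONTHS)
        if len(season) < expected:
            raise ValueError(
                f"missing days in April-October {year} for plot {climate.plot_id!r}: "
                f"have {len(season)}, need {expected}"
            )
        sums.append(np.maximum(season["tmean"].to_numpy() - DEGREE_DAY_BASE, 0.0).sum())
    return float(np.mean(sums))


def bucket_size(terrain: TerrainSoil) -> float:
    """Maximum plant-available soil water store, cm.

    Soil depth is capped at 2 m and converted to cm, then scaled by the
    available water capacity and the non-coarse soil fraction.
    """
    sdr_cm = min(terrain.sdr, 2.0) * 100.0
    return sdr_cm * terrain.awc * (1.0 - terrain.cfv)


def site_environment(
    climate: ClimateSeries,
    terrain: TerrainSoil,
    years: Iterable[int] | None = None,
    aspect_mode: Literal["cosine", "binary"] = "cosine",
) -> SiteEnvironment:
    """Combine the three covariates into one per-plot record."""
    if climate.plot_id != terrain.plot_id:
        raise ValueError(
            f"plot mismatch: climate {climate.plot_id!r} vs terrain {terrain.plot_id!r}"
        )
    kpmod = slope_aspect_factor(terrain.slope, terrain.aspect, mode=aspect_mode)
    return SiteEnvironment(
        plot_id=climate.plot_id,
        dds=degree_day_sum(climate, years),
        wb=seasonal_water_balance(climate, terrain, years, aspect_mode=aspect_mode),
        bs=bucket_size(terrain),
        kpmod=kpmod,
    )


def site_environment_table(
    climate_frame: pd.DataFrame,
    terrain_frame: pd.DataFrame,
    years: Iterable[int] | None = None,
    aspect_mode: Literal["cosine", "binary"] = "cosine",
) -> pd.DataFrame:
    """Vectorized driver over a climate table and a terrain table.

    Returns a frame with columns plot_id, dds, wb, bs, kpmod (one row per
    plot in the terrain table).
    """
    records = []
    for row in terrain_frame.itertuples(index=False):
        terrain = TerrainSoil(
            plot_id=row.plot_id,
            slope=row.slope_deg,
            aspect=row.aspect_deg,
            sdr=row.sdr_m,
            awc=row.awc_frac,
            cfv=row.cfv_frac,
            latitude=getattr(row, "latitude", 47.0),
        )
        climate = ClimateSeries.from_frame(climate_frame, row.plot_id)
        env = site_environment(climate, terrain, years, aspect_mode=aspect_mode)
        records.append(dataclasses.asdict(env))
    return pd.DataFrame.from_records(records)
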