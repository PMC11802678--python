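"""Growing-season detection and ozone exposure metrics.

The growing season (GS) is delimited at month granularity by a 5 °C rule: a
month belongs to the GS iff it contains no day whose 24 hourly air
temperatures are all below the threshold.  Exposure metrics over the GS:

* sumO₃  — sum of hourly concentrations (ppb) / 1000, in ppm;
* avgO₃  — 1000 · sumO₃ / GS hours, in ppb (exact inverse conversion);
* AOT40 — sum of hourly exceedances over 40 ppb during daylight
  (global radiation ≥ 50 W m⁻²), / 1000, in ppm·h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

log = logging.getLogger(__name__)

GS_TEMP_THRESHOLD_C = 5.0
DAYLIGHT_RAD_WM2 = 50.0
COVERAGE_FLOOR = 0.9

ENV_CSV_COLUMNS = ["timestamp", "t_air_c", "o3_ppb", "glob_rad_wm2"]


@dataclass(frozen=True)
class GrowingSeason:
    start: pd.Timestamp  # first day of the first qualifying month
    end: pd.Timestamp    # last day of the last qualifying month

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def hours(self) -> int:
        return 24 * self.days

    def mask(self, timestamps: pd.Series) -> pd.Series:
        end_excl = self.end + pd.Timedelta(days=1)
        return (timestamps >= self.start) & (timestamps < end_excl)


def read_env_csv(path) -> pd.DataFrame:
    """Hourly met + O₃ record (left-labelled local-time timestamps)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in ENV_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return validate_env_series(df)


def validate_env_series(df: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"])
    steps = ts.diff().dropna()
    if not (steps == pd.Timedelta(hours=1)).all():
        raise ValidationError("timestamps must increase in strict 1 h steps")
    if (df["o3_ppb"].dropna() < 0).any():
        raise ValidationError("negative O3 concentrations")
    if "rh_pct" in df.columns:
        rh = df["rh_pct"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValidationError("relative humidity outside [0, 100]")
    out = df.copy()
    out["timestamp"] = ts
    return out


def detect_growing_season(df: pd.DataFrame,
                          threshold: float = GS_TEMP_THRESHOLD_C
                          ) -> GrowingSeason:
    """Longest contiguous run of months with no all-cold day.

    A day is "all-cold" when each of its 24 hourly temperatures is below
    ``threshold``.  Ties between equally long runs are broken toward the run
    containing the warmest month (highest monthly mean temperature).

    Raises
    ------
    CoverageError
        If the series does not cover whole calendar months.
    """
    ts = df["timestamp"]
    months = ts.dt.to_period("M")
    for month, grp in df.groupby(months):
        if len(grp) != 24 * month.days_in_month:
            raise CoverageError(
                f"month {month} has {len(grp)} hourly records, expected "
                f"{24 * month.days_in_month}")
    daily_max = df.groupby(ts.dt.normalize())["t_air_c"].max()
    # month qualifies iff no day has all 24 temps < threshold
    all_cold_day = daily_max < threshold
    month_of_day = daily_max.index.to_period("M")
    qualifies = ~pd.Series(all_cold_day.values, index=month_of_day) \
        .groupby(level=0).any()
    monthly_mean = df.groupby(months)["t_air_c"].mean()

    runs: list[list[pd.Period]] = []
    for month in sorted(qualifies.index):
        if not qualifies[month]:
            continue
        if runs and runs[-1][-1] + 1 == month:
            runs[-1].append(month)
        else:
            runs.append([month])
    if not runs:
        raise CoverageError(f"no month qualifies under the {threshold} degC rule")
    best_len = max(len(r) for r in runs)
    candidates = [r for r in runs if len(r) == best_len]
    best = max(candidates, key=lambda r: max(monthly_mean[m] for m in r))
    start = best[0].to_timestamp()
    end = best[-1].to_timestamp(how="end").normalize()
    gs = GrowingSeason(start=start, end=end)
    log.info("growing season %s .. %s (%d days)", gs.start.date(),
             gs.end.date(), gs.days)
    return gs


def _coverage_check(df: pd.DataFrame, gs: GrowingSeason, column: str,
                    floor: float) -> pd.DataFrame:
    sub = df.loc[gs.mask(df["timestamp"])]
    valid = sub[column].notna()
    coverage = valid.sum() / gs.hours
    if coverage < floor:
        raise CoverageError(
            f"{column} coverage {coverage:.1%} of GS hours below the "
            f"{floor:.0%} floor")
    n_missing = gs.hours - int(valid.sum())
    if n_missing:
        log.warning("%d GS hours without valid %s excluded", n_missing, column)
    return sub.loc[valid]


def cumulative_exposure(df: pd.DataFrame, gs: GrowingSeason,
                        coverage_floor: float = COVERAGE_FLOOR,
                        round_to: float | None = None) -> float:
    """sumO₃ over the GS in ppm; optionally rounded to a multiple of
    ``round_to`` ppm (e.g. 10 for a tens-rounded headline figure)."""
    sub = _coverage_check(df, gs, "o3_ppb", coverage_floor)
    sum_ppm = float(sub["o3_ppb"].sum()) / 1000.0
    if round_to is not None:
        sum_ppm = round(sum_ppm / round_to) * round_to
    return sum_ppm


def sum_to_avg(sum_o3_ppm: float, gs: GrowingSeason) -> float:
    """Seasonal average hourly concentration, ppb."""
    if gs.hours <= 0:
        raise ValidationError("growing season has no hours")
    return 1000.0 * sum_o3_ppm / gs.hours


def avg_to_sum(avg_o3_ppb: float, gs: GrowingSeason) -> float:
    """Inverse of :func:`sum_to_avg`: cumulative sum in ppm."""
    if gs.hours <= 0:
        raise ValidationError("growing season has no hours")
    return avg_o3_ppb * gs.hours / 1000.0


def aot40(df: pd.DataFrame, gs: GrowingSeason,
          daylight_wm2: float = DAYLIGHT_RAD_WM2,
          coverage_floor: float = COVERAGE_FLOOR) -> float:
    """Accumulated exposure over 40 ppb during daylight GS hours, ppm·h."""
    if "glob_rad_wm2" not in df.columns or df["glob_rad_wm2"].isna().all():
        raise ValidationError("global radiation required to define daylight")
    sub = _coverage_check(df, gs, "o3_ppb", coverage_floor)
    daylight = sub["glob_rad_wm2"] >= daylight_wm2
    exceed = np.maximum(0.0, sub.loc[daylight, "o3_ppb"] - 40.0)
    return float(exceed.sum()) / 1000.0
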