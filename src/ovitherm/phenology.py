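"""Degree-day accumulation, hatch forecasting and oviposition-window
back-calculation.

Thermal time is accumulated by the temperature-mean method: each day
contributes ``max(0, Tmean − T0)`` degree-days (DD), with no upper cutoff.
An egg laid on day d starts accumulating on d+1 (the day of laying itself
can be included via a switch) and hatches on the first day the running sum
reaches the thermal constant K. The oviposition window is inferred from
winter field stage records by back-dating: the first larva (or first
head-capsule egg) bounds the start, validated against the first
reproductive-adult capture; the last yellow-cluster record bounds the end,
with an uncertainty of one yellow-stage duration at the reference
temperature (8 °C, the winter mean in the study region).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .cohort import FieldRecord, TemperatureSeries
from .errors import ParameterError, RangeError, ValidationError, WindowError

__all__ = [
    "StageDurations",
    "DegreeDaySeries",
    "HatchForecast",
    "OvipositionWindow",
    "weekly_mean_series",
    "accumulate_degree_days",
    "forecast_hatch",
    "estimate_oviposition_window",
]


class StageDurations(NamedTuple):
    """Colour-stage durations (days) at the reference temperature."""

    yellow: int
    brown: int
    blackhead: int

    @property
    def total(self) -> int:
        return self.yellow + self.brown + self.blackhead


@dataclass(frozen=True)
class DegreeDaySeries:
    """Daily and cumulative thermal accumulation above T0 for one area."""

    area: str
    dates: tuple[dt.date, ...]
    daily_dd: tuple[float, ...]
    cumulative_dd: tuple[float, ...]


@dataclass(frozen=True)
class HatchForecast:
    """Predicted hatch date for one lay date on one temperature series."""

    lay_date: dt.date
    hatch_date: dt.date | None
    dd_at_hatch: float
    horizon_exhausted: bool


@dataclass(frozen=True)
class OvipositionWindow:
    """Inferred egg-laying interval with the field evidence bounding it.

    ``evidence`` pairs each record used with its back-dated lay interval
    (earliest, latest plausible lay date).
    """

    area: str
    start: dt.date
    end: dt.date
    evidence: tuple[tuple[FieldRecord, tuple[dt.date, dt.date]], ...]


def weekly_mean_series(
    series: TemperatureSeries,
    years: int = 15,
    target_start: dt.date | None = None,
    target_end: dt.date | None = None,
) -> TemperatureSeries:
    """Weekly climatology expanded back to a daily series.

    Days are binned into 52 calendar weeks by day-of-year (the last week
    absorbs the remainder days); each week's multi-year mean over the final
    ``years`` years of ``series`` becomes the constant daily value for that
    week in the target period (default: the last 365 days of the series).
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    if target_start is None or target_end is None:
        target_end = series.end
        target_start = target_end - dt.timedelta(days=364)
        if target_start < series.start:
            target_start = series.start
    if target_start > target_end:
        raise ParameterError("target_start after target_end")

    window_start = series.end - dt.timedelta(days=round(years * 365.25) - 1)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for date, temp in zip(series.dates, series.tmean_c):
        if date < window_start:
            continue
        w = _week_of_year(date)
        sums[w] = sums.get(w, 0.0) + temp
        counts[w] = counts.get(w, 0) + 1
    weekly = {w: sums[w] / counts[w] for w in sums}

    n_days = (target_end - target_start).days + 1
    dates = tuple(target_start + dt.timedelta(days=i) for i in range(n_days))
    missing = sorted({_week_of_year(d) for d in dates} - set(weekly))
    if missing:
        raise RangeError(
            f"series for {series.area} has no data for calendar week(s) "
            f"{', '.join(str(w + 1) for w in missing)}"
        )
    values = tuple(weekly[_week_of_year(d)] for d in dates)
    return TemperatureSeries(area=series.area, dates=dates, tmean_c=values)


def _week_of_year(date: dt.date) -> int:
    return min((date.timetuple().tm_yday - 1) // 7, 51)


def accumulate_degree_days(
    series: TemperatureSeries, t0: float, from_date: dt.date
) -> DegreeDaySeries:
    """Daily DD = max(0, Tmean − T0), accumulated from ``from_date``."""
    try:
        start = series.index_of(from_date)
    except KeyError as exc:
        raise RangeError(str(exc)) from exc
    temps = np.asarray(series.tmean_c[start:])
    daily = np.maximum(0.0, temps - t0)
    cumulative = np.cumsum(daily)
    return DegreeDaySeries(
        area=series.area,
        dates=series.dates[start:],
        daily_dd=tuple(float(x) for x in daily),
        cumulative_dd=tuple(float(x) for x in cumulative),
    )


def forecast_hatch(
    series: TemperatureSeries,
    lay_date: dt.date,
    t0: float,
    k: float,
    include_lay_date: bool = False,
) -> HatchForecast:
    """First date on which K degree-days have accumulated since laying.

    By default thermal time starts the day after laying, so at constant
    temperature the egg hatches ``ceil(K / (T − T0))`` days after the lay
    date. If the series ends before K is reached the forecast reports
    ``horizon_exhausted`` with the DD accumulated so far.
    """
    if k <= 0:
        raise ParameterError(f"thermal constant must be positive, got {k}")
    series.index_of(lay_date)  # validates lay_date in range
    start = lay_date if include_lay_date else lay_date + dt.timedelta(days=1)
    if start > series.end:
        return HatchForecast(lay_date, None, 0.0, True)
    dd = accumulate_degree_days(series, t0, start)
    for date, cum in zip(dd.dates, dd.cumulative_dd):
        if cum >= k:
            return HatchForecast(lay_date, date, cum, False)
    total = dd.cumulative_dd[-1] if dd.cumulative_dd else 0.0
    return HatchForecast(lay_date, None, total, True)


def estimate_oviposition_window(
    field_records: Sequence[FieldRecord],
    stage_durations_ref: StageDurations | tuple[int, int, int],
    adult_records: Sequence[FieldRecord] | None = None,
    larval_age_at_detection: int = 0,
) -> OvipositionWindow:
    """Back-date field stage records to the interval when eggs were laid.

    Start: the earlier of (first larva date − total egg duration −
    ``larval_age_at_detection``) and (first head-capsule-egg date − yellow −
    brown durations), clipped to be no earlier than the first
    reproductive-adult capture when adult records exist. End: the date of
    the last yellow-cluster record, whose lay date lies within the preceding
    yellow-stage duration (recorded in the evidence); when no yellow record
    exists the latest-possible lay bound of the oldest egg stage present is
    used instead.
    """
    stages = StageDurations(*stage_durations_ref)
    if stages.total < 1:
        raise ParameterError("stage durations must be positive")
    records = list(field_records)
    if adult_records:
        records += list(adult_records)
    areas = {r.area for r in records}
    if len(areas) > 1:
        raise ParameterError(
            f"records span several areas {sorted(areas)}; estimate one area at a time"
        )
    if not records:
        raise WindowError("no field records supplied")
    area = records[0].area

    larvae = [r for r in records if r.record_kind == "larva"]
    blackhead = [r for r in records if r.record_kind == "egg_blackhead"]
    brown = [r for r in records if r.record_kind == "egg_brown"]
    yellow = [r for r in records if r.record_kind == "egg_yellow"]
    adults = [r for r in records if r.record_kind == "adult_reproductive"]
    if not larvae and not blackhead and not yellow:
        raise WindowError(
            f"area {area}: no larva, head-capsule-egg or yellow-cluster records; "
            f"window undeterminable"
        )

    evidence: list[tuple[FieldRecord, tuple[dt.date, dt.date]]] = []
    start_candidates: list[dt.date] = []
    if larvae:
        first = min(larvae, key=lambda r: r.date)
        lay = first.date - dt.timedelta(days=stages.total + larval_age_at_detection)
        start_candidates.append(lay)
        evidence.append((first, (lay, lay)))
    if blackhead:
        first = min(blackhead, key=lambda r: r.date)
        lo = first.date - dt.timedelta(days=stages.total - 1)
        hi = first.date - dt.timedelta(days=stages.yellow + stages.brown)
        start_candidates.append(hi)
        evidence.append((first, (lo, hi)))
    if not start_candidates:  # only yellow clusters: start bounded by earliest one
        first = min(yellow, key=lambda r: r.date)
        lo = first.date - dt.timedelta(days=stages.yellow - 1)
        start_candidates.append(lo)
        evidence.append((first, (lo, first.date)))
    start = min(start_candidates)
    if adults:
        first_adult = min(adults, key=lambda r: r.date)
        if first_adult.date > start:
            start = first_adult.date
        evidence.append((first_adult, (first_adult.date, first_adult.date)))

    if yellow:
        last = max(yellow, key=lambda r: r.date)
        end = last.date
        lo = last.date - dt.timedelta(days=stages.yellow - 1)
        evidence.append((last, (lo, last.date)))
    elif blackhead or brown:
        # latest-possible lay bound of the oldest stage still present
        bounds = []
        for r in brown:
            bounds.append(r.date - dt.timedelta(days=stages.yellow))
        for r in blackhead:
            bounds.append(r.date - dt.timedelta(days=stages.yellow + stages.brown))
        end = max(bounds)
    else:
        end = start
    if end < start:
        raise ValidationError(
            f"area {area}: inferred end {end} precedes start {start}; "
            f"field records are inconsistent with the stage durations"
        )
    return OvipositionWindow(area=area, start=start, end=end, evidence=tuple(evidence))
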