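"""Career segmentation and the exercise-variable panel.

A career runs from the first recorded event to the index date.  Any gap of
strictly more than 60 days (configurable) between consecutive events is a
*layup*; everything else is the *active* portion of the career.  From the
truncated timeline we compute counts, distances and rates of races, works
and events over the whole career and its active portion, windowed distances
before the index date and after the first event, and workload-intensity
slopes (ordinary least-squares slope of cumulative furlongs against time in
months over a short window).

A variable is missing (``None``) exactly when its denominator or
prerequisite is absent: between-race intervals need two races, per-race
distance needs one race, slopes need two events inside their window, and
all rates need a positive time denominator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gallop.config import AnalysisConfig, DEFAULT_CONFIG
from gallop.events import CareerTimeline, HorseRecord, ValidationError

BEFORE_HORIZONS = (1, 2, 4, 6, 8, 10, 12)
AFTER_HORIZONS = (1, 2, 4, 6, 8, 10, 12)


@dataclass(frozen=True)
class Layup:
    """A period of more than the threshold days without a race or work.

    The interval is bounded by the event that opens the gap and the next
    event; its duration is the full day difference between the two.
    """

    start: dt.date
    end: dt.date

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class LayupSegmentation:
    """Layup/active split of one career."""

    layups: tuple[Layup, ...]
    career_length_days: int
    active_days: int

    @property
    def layup_time_days(self) -> int:
        return sum(l.duration_days for l in self.layups)

    @property
    def n_layups(self) -> int:
        return len(self.layups)


def segment_layups(
    timeline: CareerTimeline, config: AnalysisConfig = DEFAULT_CONFIG
) -> LayupSegmentation:
    """Split a career into layup and active periods.

    A layup exists for each pair of consecutive events whose day gap is
    strictly greater than ``config.layup_threshold_days``.  The trailing gap
    from the last event to the index date is never a layup (a case's index
    follows its precipitating event closely and a control's index is itself
    an event).  Conservation holds by construction:
    ``active_days + layup_time_days == career_length_days``.
    """

    if timeline.is_empty:
        raise ValidationError(
            f"timeline {timeline.horse_id}: no events on or before the index date; "
            "exercise variables cannot be computed"
        )
    dates = [e.date for e in timeline.events]
    layups = []
    for d1, d2 in zip(dates, dates[1:]):
        if (d2 - d1).days > config.layup_threshold_days:
            layups.append(Layup(start=d1, end=d2))
    career = (timeline.index_date - dates[0]).days
    total_layup = sum(l.duration_days for l in layups)
    return LayupSegmentation(
        layups=tuple(layups), career_length_days=career, active_days=career - total_layup
    )


@dataclass(frozen=True)
class CumulativeDistanceCurve:
    """Right-continuous step function: date -> cumulative furlongs to date."""

    dates: tuple[dt.date, ...]  # distinct jump dates, ascending
    values: tuple[float, ...]  # cumulative furlongs at and after each jump

    def value(self, date: dt.date) -> float:
        idx = np.searchsorted([d.toordinal() for d in self.dates], date.toordinal(), side="right")
        return 0.0 if idx == 0 else self.values[idx - 1]

    @property
    def terminal(self) -> float:
        return self.values[-1]


def cumulative_curve(timeline: CareerTimeline) -> CumulativeDistanceCurve:
    """Cumulative event furlongs over time; the jump at each event date
    equals the total distance exercised that day."""

    if timeline.is_empty:
        raise ValidationError(f"timeline {timeline.horse_id}: empty; no cumulative curve")
    per_day: dict[dt.date, float] = {}
    for e in timeline.events:
        per_day[e.date] = per_day.get(e.date, 0.0) + e.distance
    dates = tuple(sorted(per_day))
    values = tuple(np.cumsum([per_day[d] for d in dates]).tolist())
    return CumulativeDistanceCurve(dates=dates, values=values)


def slope(
    curve: CumulativeDistanceCurve,
    window: tuple[dt.date, dt.date],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[float]:
    """OLS slope of cumulative furlongs against time, in furlongs/month.

    Fits the (date, cumulative distance) points of events falling inside the
    closed window.  Returns ``None`` when fewer than two distinct event
    dates fall inside the window.
    """

    lo, hi = window
    xs, ys = [], []
    for d, v in zip(curve.dates, curve.values):
        if lo <= d <= hi:
            xs.append((d - lo).days / config.month_days)
            ys.append(v)
    if len(xs) < 2:
        return None
    b, _a = np.polyfit(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float), 1)
    return float(b)


def windowed_distance(
    timeline: CareerTimeline,
    horizon_months: float,
    anchor: str = "before_index",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Total event furlongs inside a monthly window.

    ``before_index``: half-open window ``(index - h, index]`` — an event on
    the index date counts in every horizon.  ``after_first_event``:
    ``[first, first + h)``.  A month is ``config.month_days`` days.  An
    empty window sums to zero.
    """

    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    if timeline.is_empty:
        return 0.0
    span = horizon_months * config.month_days
    total = 0.0
    if anchor == "before_index":
        for e in timeline.events:
            if (timeline.index_date - e.date).days < span:
                total += e.distance
    elif anchor == "after_first_event":
        first = timeline.first_event_date
        for e in timeline.events:
            if (e.date - first).days < span:
                total += e.distance
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return total


@dataclass(frozen=True)
class ExerciseVariables:
    """The per-horse workload panel.

    Units: days for durations, furlongs (F) for distances, #/year and
    F/month for rates.  ``None`` marks a missing value (undefined for this
    horse).  ``pct_career_in_layup`` is a percentage on [0, 100].
    """

    horse_id: str
    # signalment
    age_days: Optional[float] = None
    age_years: Optional[float] = None
    # career
    career_length_days: Optional[float] = None
    active_days: Optional[float] = None
    n_races: Optional[float] = None
    n_works: Optional[float] = None
    n_events: Optional[float] = None
    race_dist_f: Optional[float] = None
    work_dist_f: Optional[float] = None
    event_dist_f: Optional[float] = None
    between_races_days: Optional[float] = None
    between_works_days: Optional[float] = None
    between_events_days: Optional[float] = None
    # layup
    n_layups: Optional[float] = None
    layup_time_days: Optional[float] = None
    mean_layup_time_days: Optional[float] = None
    pct_career_in_layup: Optional[float] = None
    time_since_last_layup_days: Optional[float] = None
    events_since_last_layup: Optional[float] = None
    slope_after_last_layup_f_per_month: Optional[float] = None
    # career rates
    races_per_year: Optional[float] = None
    works_per_year: Optional[float] = None
    events_per_year: Optional[float] = None
    dist_per_race_f: Optional[float] = None
    dist_per_work_f: Optional[float] = None
    dist_per_event_f: Optional[float] = None
    career_race_rate_f_per_month: Optional[float] = None
    career_work_rate_f_per_month: Optional[float] = None
    career_event_rate_f_per_month: Optional[float] = None
    # active rates
    active_races_per_year: Optional[float] = None
    active_works_per_year: Optional[float] = None
    active_events_per_year: Optional[float] = None
    active_race_rate_f_per_month: Optional[float] = None
    active_work_rate_f_per_month: Optional[float] = None
    active_event_rate_f_per_month: Optional[float] = None
    between_races_active_days: Optional[float] = None
    between_works_active_days: Optional[float] = None
    between_events_active_days: Optional[float] = None
    # activity before the index date
    slope_at_fracture_f_per_month: Optional[float] = None
    days_fracture_to_previous_event: Optional[float] = None
    dist_before_1m_f: Optional[float] = None
    dist_before_2m_f: Optional[float] = None
    dist_before_4m_f: Optional[float] = None
    dist_before_6m_f: Optional[float] = None
    dist_before_8m_f: Optional[float] = None
    dist_before_10m_f: Optional[float] = None
    dist_before_12m_f: Optional[float] = None
    dist_month2_f: Optional[float] = None
    dist_months3_4_f: Optional[float] = None
    dist_months5_6_f: Optional[float] = None
    dist_month1_minus_month2_f: Optional[float] = None
    # activity at career beginning
    slope_at_start_f_per_month: Optional[float] = None
    dist_after_first_1m_f: Optional[float] = None
    dist_after_first_2m_f: Optional[float] = None
    dist_after_first_4m_f: Optional[float] = None
    dist_after_first_6m_f: Optional[float] = None
    dist_after_first_8m_f: Optional[float] = None
    dist_after_first_10m_f: Optional[float] = None
    dist_after_first_12m_f: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


VARIABLE_NAMES: tuple[str, ...] = tuple(
    f.name for f in fields(ExerciseVariables) if f.name != "horse_id"
)


def _mean_gap(dates: Sequence[dt.date]) -> Optional[float]:
    if len(dates) < 2:
        return None
    gaps = [(d2 - d1).days for d1, d2 in zip(dates, dates[1:])]
    return float(np.mean(gaps))


def _mean_active_gap(dates: Sequence[dt.date], layups: Sequence[Layup]) -> Optional[float]:
    """Mean inter-event gap after subtracting overlapping layup days."""

    if len(dates) < 2:
        return None
    gaps = []
    for d1, d2 in zip(dates, dates[1:]):
        gap = (d2 - d1).days
        for l in layups:
            overlap = (min(l.end, d2) - max(l.start, d1)).days
            if overlap > 0:
                gap -= overlap
        gaps.append(gap)
    return float(np.mean(gaps))


def _rate(numer: float, denom_days: Optional[float], per_days: float) -> Optional[float]:
    if denom_days is None or denom_days <= 0:
        return None
    return numer / (denom_days / per_days)


def compute_variables(
    timeline: CareerTimeline,
    horse: Optional[HorseRecord] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ExerciseVariables:
    """Compute the full workload panel for one truncated career.

    Deterministic; identical timelines yield identical panels.  The horse
    record supplies the birth date for age variables and may be omitted.
    """

    seg = segment_layups(timeline, config)  # raises on empty timeline
    events = timeline.events
    index = timeline.index_date
    first = timeline.first_event_date
    race_dates = [e.date for e in events if e.is_race]
    work_dates = [e.date for e in events if not e.is_race]
    event_dates = [e.date for e in events]

    n_races, n_works = len(race_dates), len(work_dates)
    n_events = n_races + n_works
    race_dist = float(sum(e.distance for e in events if e.is_race))
    work_dist = float(sum(e.distance for e in events if not e.is_race))
    event_dist = race_dist + work_dist

    birth = horse.birth_date if horse is not None else None
    age_days = float((index - birth).days) if birth is not None else None
    age_years: Optional[float] = None
    if birth is not None:
        if config.racing_age:
            age_years = float(index.year - birth.year)
        else:
            age_years = float(int(age_days // config.year_days))

    career = float(seg.career_length_days)
    active = float(seg.active_days)
    layup_time = float(seg.layup_time_days)
    pct_layup = 100.0 * layup_time / career if career > 0 else None
    mean_layup = layup_time / seg.n_layups if seg.n_layups else 0.0

    if seg.layups:
        last_end = seg.layups[-1].end
        since_layup = float((index - last_end).days)
        events_since = float(sum(1 for d in event_dates if d >= last_end))
    else:
        last_end = first
        since_layup = float((index - first).days)
        events_since = float(n_events)

    curve = cumulative_curve(timeline)
    win = dt.timedelta(days=config.slope_window_days)
    slope_fracture = slope(curve, (index - win, index), config)
    slope_start = slope(curve, (first, first + win), config)
    slope_after_layup = (
        slope(curve, (seg.layups[-1].end, seg.layups[-1].end + win), config)
        if seg.layups
        else None
    )

    before = {
        h: windowed_distance(timeline, h, "before_index", config) for h in BEFORE_HORIZONS
    }
    after = {
        h: windowed_distance(timeline, h, "after_first_event", config) for h in AFTER_HORIZONS
    }

    return ExerciseVariables(
        horse_id=timeline.horse_id,
        age_days=age_days,
        age_years=age_years,
        career_length_days=career,
        active_days=active,
        n_races=float(n_races),
        n_works=float(n_works),
        n_events=float(n_events),
        race_dist_f=race_dist,
        work_dist_f=work_dist,
        event_dist_f=event_dist,
        between_races_days=_mean_gap(race_dates),
        between_works_days=_mean_gap(work_dates),
        between_events_days=_mean_gap(event_dates),
        n_layups=float(seg.n_layups),
        layup_time_days=layup_time,
        mean_layup_time_days=float(mean_layup),
        pct_career_in_layup=pct_layup,
        time_since_last_layup_days=since_layup,
        events_since_last_layup=events_since,
        slope_after_last_layup_f_per_month=slope_after_layup,
        races_per_year=_rate(n_races, career, config.year_days),
        works_per_year=_rate(n_works, career, config.year_days),
        events_per_year=_rate(n_events, career, config.year_days),
        dist_per_race_f=race_dist / n_races if n_races else None,
        dist_per_work_f=work_dist / n_works if n_works else None,
        dist_per_event_f=event_dist / n_events if n_events else None,
        career_race_rate_f_per_month=_rate(race_dist, career, config.month_days),
        career_work_rate_f_per_month=_rate(work_dist, career, config.month_days),
        career_event_rate_f_per_month=_rate(event_dist, career, config.month_days),
        active_races_per_year=_rate(n_races, active, config.year_days),
        active_works_per_year=_rate(n_works, active, config.year_days),
        active_events_per_year=_rate(n_events, active, config.year_days),
        active_race_rate_f_per_month=_rate(race_dist, active, config.month_days),
        active_work_rate_f_per_month=_rate(work_dist, active, config.month_days),
        active_event_rate_f_per_month=_rate(event_dist, active, config.month_days),
        between_races_active_days=_mean_active_gap(race_dates, seg.layups),
        between_works_active_days=_mean_active_gap(work_dates, seg.layups),
        between_events_active_days=_mean_active_gap(event_dates, seg.layups),
        slope_at_fracture_f_per_month=slope_fracture,
        days_fracture_to_previous_event=float((index - events[-1].date).days),
        dist_before_1m_f=before[1],
        dist_before_2m_f=before[2],
        dist_before_4m_f=before[4],
        dist_before_6m_f=before[6],
        dist_before_8m_f=before[8],
        dist_before_10m_f=before[10],
        dist_before_12m_f=before[12],
        dist_month2_f=before[2] - before[1],
        dist_months3_4_f=before[4] - before[2],
        dist_months5_6_f=before[6] - before[4],
        dist_month1_minus_month2_f=before[1] - (before[2] - before[1]),
        slope_at_start_f_per_month=slope_start,
        dist_after_first_1m_f=after[1],
        dist_after_first_2m_f=after[2],
        dist_after_first_4m_f=after[4],
        dist_after_first_6m_f=after[6],
        dist_after_first_8m_f=after[8],
        dist_after_first_10m_f=after[10],
        dist_after_first_12m_f=after[12],
    )


def variables_frame(panels: Sequence[ExerciseVariables]) -> pd.DataFrame:
    """Stack per-horse panels into a DataFrame (one row per horse, missing
    encoded as NaN), suitable for variables.csv export."""

    rows = [p.as_dict() for p in panels]
    df = pd.DataFrame(rows, columns=["horse_id", *VARIABLE_NAMES])
    return df.set_index("horse_id")
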