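"""Tunable analysis constants.

All durations are integer calendar-day differences.  Rates are expressed per
month or per year using fixed average lengths so that "furlongs per month"
and "events per year" are well defined for arbitrary spans.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants shared by career segmentation and variable computation.

    Parameters
    ----------
    month_days : average month length in days used for f/month rates and
        monthly distance windows.
    year_days : average year length in days used for #/year rates and age.
    layup_threshold_days : an inter-event gap strictly greater than this is
        a layup (a period without a race or timed work).
    slope_window_days : length of the window used for the three workload
        intensity slopes (at career start, after the last layup, and
        immediately before the index date).
    include_index_day_event : whether an event dated exactly on the index
        date is retained when a career is truncated.  The default keeps it:
        fractures occur during an event, so the precipitating event is
        typically the last retained record.
    racing_age : if True, age in years is the North American racing age
        (calendar years since the January 1st of the birth year); if False,
        the integer floor of age_days / year_days.
    """

    month_days: float = 30.4375
    year_days: float = 365.25
    layup_threshold_days: int = 60
    slope_window_days: int = 60
    include_index_day_event: bool = True
    racing_age: bool = False


DEFAULT_CONFIG = AnalysisConfig()
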