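"""Synthetic racehorse career and study-bundle generator.

Real past-performance records (race and official timed work histories) are
proprietary, so this module generates careers with the exposure structure
the analysis assumes: a backbone of timed works separated by right-skewed
(log-normal) gaps of roughly two weeks, races interleaved during active
periods at a per-year rate, layups (gaps > 60 days) injected by a hazard
per active year with log-normal durations, and distances of ~4 F for works
and ~6–7 F for races recorded to the nearest half furlong.

Presets pin the group medians the two fracture-location phenotypes show:
``nonpsg_like`` horses race often with few layups, ``psg_like`` horses race
less, spend more of their career in layup, and work at a slightly higher
active-period frequency; ``control_like`` sits between the two.

:func:`simulate_study` assembles a full analysable bundle — case careers,
fracture annotations, and per-case control pools that share the case's
last event, sex, and birth year by construction — so every downstream
stage (validation, matching, modelling, outcome analysis) runs without any
external data.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from gallop.config import AnalysisConfig, DEFAULT_CONFIG
from gallop.events import (
    CaseRecord,
    EventRecord,
    HorseRecord,
    ValidationError,
    write_cases,
    write_events,
    write_horses,
)


@dataclass(frozen=True)
class CareerParams:
    """Generator parameters for one career phenotype.

    Gaps and durations are log-normal (median + log-scale sd); distances
    are truncated normal in furlongs, recorded to the nearest 0.5 F.
    ``layup_hazard_per_active_year`` is the expected number of layups
    injected per active year; layup durations are always > 60 days.
    """

    interwork_median_days: float = 13.5
    interwork_log_sd: float = 0.25
    races_per_year: float = 7.0
    race_dist_mean_f: float = 6.6
    race_dist_sd_f: float = 0.9
    work_dist_mean_f: float = 4.2
    work_dist_sd_f: float = 0.5
    layup_hazard_per_active_year: float = 0.6
    layup_duration_median_days: float = 140.0
    layup_duration_log_sd: float = 0.35
    career_span_median_days: float = 400.0
    career_span_log_sd: float = 0.45
    start_age_mean_days: float = 900.0
    start_age_sd_days: float = 120.0
    p_male: float = 0.67
    return_to_racing_prob: float = 0.65

    def validate(self) -> None:
        if self.interwork_median_days > 60:
            raise ValidationError(
                "interwork_median_days > 60: ordinary work gaps would register as layups"
            )
        positive = [
            self.interwork_median_days,
            self.race_dist_mean_f,
            self.work_dist_mean_f,
            self.layup_duration_median_days,
            self.career_span_median_days,
            self.start_age_mean_days,
        ]
        if any(v <= 0 for v in positive):
            raise ValidationError("all scale parameters must be positive")
        if not (0 <= self.p_male <= 1 and 0 <= self.return_to_racing_prob <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")

    def targets(self, config: AnalysisConfig = DEFAULT_CONFIG) -> dict[str, float]:
        """Cohort medians the preset is designed to produce.

        Used by the generator/extractor round-trip checks.  The median
        per-horse mean *active* between-works interval equals the mean of
        the log-normal gap distribution (median times ``exp(sd^2/2)``);
        the active works-per-year rate is the year length over that mean
        gap; and the median percent of career in layup is zero when the
        median horse draws no layup, else the median layup duration over
        the median career span.
        """

        mean_gap = self.interwork_median_days * math.exp(self.interwork_log_sd**2 / 2)
        lam = (
            self.layup_hazard_per_active_year
            * (self.career_span_median_days - self.layup_duration_median_days)
            / config.year_days
        )
        if math.exp(-lam) >= 0.5:  # median horse has no layup
            pct_layup = 0.0
        else:
            pct_layup = 100.0 * self.layup_duration_median_days / self.career_span_median_days
        return {
            "between_works_active_days": mean_gap,
            "active_works_per_year": config.year_days / mean_gap,
            "pct_career_in_layup": pct_layup,
        }


# Preset phenotypes.  The two case presets emulate the published group
# medians (non-PSG: ~13.2-day work gaps, ~8 races/yr, layups rare;
# PSG: ~14.8-day gaps, ~4.7 races/yr, ~27% of career in layup); controls
# sit between them.
PRESETS: dict[str, CareerParams] = {
    "nonpsg_like": CareerParams(
        interwork_median_days=13.2,
        races_per_year=8.2,
        race_dist_mean_f=6.5,
        work_dist_mean_f=4.2,
        layup_hazard_per_active_year=0.35,
        layup_duration_median_days=150.0,
        career_span_median_days=420.0,
        start_age_mean_days=910.0,
        return_to_racing_prob=23 / 39,
    ),
    "psg_like": CareerParams(
        interwork_median_days=14.8,
        races_per_year=4.7,
        race_dist_mean_f=6.8,
        work_dist_mean_f=4.1,
        layup_hazard_per_active_year=1.3,
        layup_duration_median_days=125.0,
        career_span_median_days=460.0,
        start_age_mean_days=890.0,
        return_to_racing_prob=28 / 38,
    ),
    "control_like": CareerParams(),
}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _lognormal(rng: np.random.Generator, median: float, log_sd: float) -> float:
    return float(math.exp(rng.normal(math.log(median), log_sd)))


def _half_furlong(x: float, lo: float, hi: float) -> float:
    return min(max(round(x * 2.0) / 2.0, lo), hi)


def _career_offsets(
    params: CareerParams, rng: np.random.Generator, config: AnalysisConfig
) -> tuple[list[int], list[int], list[tuple[int, int]]]:
    """Day offsets (from the first event) of works and races, plus layup
    gap intervals.  Non-layup gaps are clipped to the layup threshold."""

    span = int(round(_lognormal(rng, params.career_span_median_days, params.career_span_log_sd)))
    span = max(90, min(span, 1500))
    thresh = config.layup_threshold_days
    works = [0]
    layups: list[tuple[int, int]] = []
    day = 0
    while True:
        active_gap = int(round(_lognormal(rng, params.interwork_median_days, params.interwork_log_sd)))
        active_gap = max(3, min(active_gap, thresh))
        p_layup = params.layup_hazard_per_active_year * active_gap / config.year_days
        if rng.random() < p_layup:
            gap = int(round(_lognormal(rng, params.layup_duration_median_days, params.layup_duration_log_sd)))
            gap = max(thresh + 1, gap)
            is_layup = True
        else:
            gap = active_gap
            is_layup = False
        nxt = day + gap
        if nxt > span:
            break
        if is_layup:
            layups.append((day, nxt))
        works.append(nxt)
        day = nxt

    # candidate race days: strictly inside active inter-work gaps
    candidates: list[int] = []
    for d1, d2 in zip(works, works[1:]):
        if (d1, d2) in layups:
            continue
        candidates.extend(range(d1 + 1, d2))
    active_days = works[-1] - sum(e - s for s, e in layups)
    n_races = rng.poisson(params.races_per_year * active_days / config.year_days)
    n_races = int(min(n_races, len(candidates)))
    races = sorted(rng.choice(candidates, size=n_races, replace=False).tolist()) if n_races else []
    return works, races, layups


def simulate_career(
    params: CareerParams,
    seed,
    horse_id: str = "horse",
    first_event_date: dt.date = dt.date(2018, 1, 15),
    sex: Optional[str] = None,
    birth_date: Optional[dt.date] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    with_earnings: bool = True,
) -> HorseRecord:
    """Generate one horse's event history; deterministic given the seed."""

    params.validate()
    rng = _rng(seed)
    works, races, _ = _career_offsets(params, rng, config)
    if sex is None:
        sex = "male" if rng.random() < params.p_male else "female"
    if birth_date is None:
        age = int(round(rng.normal(params.start_age_mean_days, params.start_age_sd_days)))
        birth_date = first_event_date - dt.timedelta(days=max(550, age))
    events = []
    for d in works:
        dist = _half_furlong(rng.normal(params.work_dist_mean_f, params.work_dist_sd_f), 2.0, 6.0)
        events.append(
            EventRecord(horse_id, first_event_date + dt.timedelta(days=d), "work", dist)
        )
    for d in races:
        dist = _half_furlong(rng.normal(params.race_dist_mean_f, params.race_dist_sd_f), 4.5, 10.0)
        earnings = None
        finish = None
        if with_earnings:
            finish = bool(rng.random() < 0.33)
            earnings = float(round(math.exp(rng.normal(math.log(9000), 0.9)), 2))
        events.append(
            EventRecord(
                horse_id,
                first_event_date + dt.timedelta(days=d),
                "race",
                dist,
                finish_top3=finish,
                earnings=earnings,
            )
        )
    return HorseRecord(
        horse_id=horse_id, sex=sex, birth_date=birth_date, events=tuple(sorted(events, key=lambda e: e.date))
    )


@dataclass
class StudyBundle:
    """In-memory synthetic study: all horses (cases + pool) and case roster."""

    horses: dict[str, HorseRecord]
    cases: list[CaseRecord]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": out / "events.csv",
            "horses": out / "horses.csv",
            "cases": out / "cases.csv",
        }
        write_events(self.horses, paths["events"])
        write_horses(self.horses, paths["horses"])
        write_cases(self.cases, paths["cases"])
        return paths


def _case_anatomy(rng: np.random.Generator, location: str) -> dict:
    sub = None
    if location == "nonPSG":
        sub = ["axial", "central", "abaxial"][int(rng.choice(3, p=[0.79, 0.16, 0.05]))]
    return {
        "location": location,
        "sublocation": sub,
        "limb": "left" if rng.random() < 0.49 else "right",
        "end": "forelimb" if rng.random() < 0.77 else "hindlimb",
        "condyle": "lateral" if rng.random() < 0.83 else "medial",
    }


def _post_repair_events(
    rng: np.random.Generator,
    horse_id: str,
    repair_date: dt.date,
    params: CareerParams,
) -> list[EventRecord]:
    """Races after fracture repair for the outcome analysis."""

    if rng.random() >= params.return_to_racing_prob:
        return []
    day = int(rng.integers(150, 320))  # convalescence plus retraining
    events = []
    # post-return race count follows the phenotype's racing rate, so the
    # before/after earnings windows are comparable
    n = max(1, int(rng.poisson(params.races_per_year * 0.8)))
    for _ in range(n):
        date = repair_date + dt.timedelta(days=day)
        dist = _half_furlong(rng.normal(params.race_dist_mean_f, params.race_dist_sd_f), 4.5, 10.0)
        events.append(
            EventRecord(
                horse_id,
                date,
                "race",
                dist,
                finish_top3=bool(rng.random() < 0.33),
                earnings=float(round(math.exp(rng.normal(math.log(9000), 0.9)), 2)),
            )
        )
        day += int(rng.integers(20, 50))
    return events


def _matched_control(
    params: CareerParams,
    rng_seed,
    horse_id: str,
    case_horse: HorseRecord,
    match_event: EventRecord,
    config: AnalysisConfig,
) -> HorseRecord:
    """A control career ending exactly at the case's last event."""

    rng = _rng(rng_seed)
    works, races, _ = _career_offsets(params, rng, config)
    # birth in the case's foal year, early enough that the career fits
    birth = dt.date(case_horse.birth_date.year, 1, 1) + dt.timedelta(
        days=int(rng.integers(0, 110))
    )
    span = works[-1]
    max_span = (match_event.date - birth).days - 550
    cutoff = span - max_span  # offsets earlier than this fall too early in life
    events: list[EventRecord] = []
    offsets = [("work", d) for d in works] + [("race", d) for d in races]
    offsets.sort(key=lambda t: t[1])
    # drop the backbone's own final event; the shared match event replaces it
    offsets = offsets[:-1]
    first_date = match_event.date - dt.timedelta(days=span)
    for kind, d in offsets:
        if d < cutoff:
            continue  # keep the career inside the horse's lifetime
        date = first_date + dt.timedelta(days=d)
        if kind == "work":
            dist = _half_furlong(rng.normal(params.work_dist_mean_f, params.work_dist_sd_f), 2.0, 6.0)
            events.append(EventRecord(horse_id, date, "work", dist))
        else:
            dist = _half_furlong(rng.normal(params.race_dist_mean_f, params.race_dist_sd_f), 4.5, 10.0)
            events.append(
                EventRecord(
                    horse_id,
                    date,
                    "race",
                    dist,
                    finish_top3=bool(rng.random() < 0.33),
                    earnings=float(round(math.exp(rng.normal(math.log(9000), 0.9)), 2)),
                )
            )
        # shared last event: same date, type, and distance as the case's
    shared = EventRecord(
        horse_id,
        match_event.date,
        match_event.event_type,
        match_event.distance,
        finish_top3=(bool(rng.random() < 0.33) if match_event.is_race else None),
        earnings=(
            float(round(math.exp(rng.normal(math.log(9000), 0.9)), 2))
            if match_event.is_race
            else None
        ),
    )
    events.append(shared)
    return HorseRecord(
        horse_id=horse_id,
        sex=case_horse.sex,
        birth_date=birth,
        events=tuple(sorted(events, key=lambda e: e.date)),
    )


def simulate_study(
    psg_n: int = 40,
    nonpsg_n: int = 40,
    controls_per_case: int = 3,
    seed: int = 0,
    presets: Optional[dict[str, CareerParams]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    extra_pool_per_case: int = 1,
) -> StudyBundle:
    """Generate a full synthetic study bundle.

    Every case receives ``controls_per_case + extra_pool_per_case``
    eligible pool horses by construction (same last event, sex, and birth
    year), so 1:m matching never fails.  Byte-identical output for a fixed
    seed.
    """

    if psg_n <= 0 or nonpsg_n <= 0 or controls_per_case <= 0:
        raise ValidationError("counts must be positive")
    presets = presets or PRESETS
    for p in presets.values():
        p.validate()
    ss = np.random.SeedSequence(seed)
    horses: dict[str, HorseRecord] = {}
    cases: list[CaseRecord] = []
    groups = [("psg", presets["psg_like"], psg_n), ("nonpsg", presets["nonpsg_like"], nonpsg_n)]
    n_total = psg_n + nonpsg_n
    children = iter(ss.spawn(n_total))
    window_start = dt.date(2018, 1, 1)
    window_days = 1000
    for label, params, n in groups:
        for i in range(n):
            child = next(children)
            rng = _rng(child)
            horse_id = f"{label}{i:03d}"
            last_event_date = window_start + dt.timedelta(days=int(rng.integers(0, window_days)))
            horse = simulate_career(
                params, child.spawn(1)[0], horse_id=horse_id, config=config
            )
            # anchor the career backwards from the drawn last-event date
            delta = last_event_date - horse.events[-1].date
            horse = dc_replace(
                horse,
                birth_date=horse.birth_date + delta,
                events=tuple(
                    dc_replace(e, date=e.date + delta) for e in horse.events
                ),
            )
            last_event = horse.events[-1]
            fracture = last_event.date + dt.timedelta(days=int(rng.integers(0, 22)))
            repair = fracture + dt.timedelta(days=int(rng.integers(1, 11)))
            post = _post_repair_events(rng, horse_id, repair, params)
            horse = dc_replace(horse, events=tuple(sorted(horse.events + tuple(post), key=lambda e: e.date)))
            horses[horse_id] = horse
            cases.append(
                CaseRecord(
                    horse_id=horse_id,
                    fracture_date=fracture,
                    repair_date=repair,
                    **_case_anatomy(rng, "PSG" if label == "psg" else "nonPSG"),
                )
            )
            n_pool = controls_per_case + extra_pool_per_case
            for j, cc in enumerate(child.spawn(2 + n_pool)[2:]):
                cid = f"ctl_{horse_id}_{j}"
                horses[cid] = _matched_control(
                    presets["control_like"], cc, cid, horse, last_event, config
                )
    return StudyBundle(horses=horses, cases=cases)
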