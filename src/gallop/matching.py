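"""1:m matched case-control set construction.

Each fracture case is matched to ``k`` (default 3) control horses that

* participated in the case's last event before fracture (same calendar
  date and event type — the synthetic-world contract for "same race or
  official timed work"),
* are of the same sex (female/male; geldings and colts are male), and
* are of equivalent age, meaning the same birth year (foal crop).

A control's career is truncated at the match event's date, so its index
date is the shared event.  A control may serve several strata; the
downstream conditional-likelihood analysis treats strata as independent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from gallop.config import AnalysisConfig, DEFAULT_CONFIG
from gallop.events import CareerTimeline, CaseRecord, EventRecord, HorseRecord, truncate_career
from gallop.metrics import ExerciseVariables, compute_variables


class MatchingError(ValueError):
    """Raised when a matched set cannot be formed for a stratum."""


def event_key(event: EventRecord) -> str:
    """Identity of an event for matching: its date and type."""

    return f"{event.date.isoformat()}:{event.event_type}"


@dataclass(frozen=True)
class MatchedSet:
    """One case plus its matched controls sharing the case's last event."""

    stratum_id: str
    match_event_id: str
    case_id: str
    case_timeline: CareerTimeline
    case_variables: ExerciseVariables
    control_ids: tuple[str, ...]
    control_timelines: tuple[CareerTimeline, ...]
    control_variables: tuple[ExerciseVariables, ...]

    @property
    def size(self) -> int:
        return 1 + len(self.control_ids)

    def frame(self) -> pd.DataFrame:
        """Variables of all members, with a case indicator column."""

        rows = []
        for role, var in [("case", self.case_variables)] + [
            ("control", v) for v in self.control_variables
        ]:
            d = var.as_dict()
            d["role"] = role
            d["stratum_id"] = self.stratum_id
            rows.append(d)
        return pd.DataFrame(rows)


def _eligible(
    case_horse: HorseRecord,
    match_key: str,
    pool: Mapping[str, HorseRecord],
) -> list[str]:
    if case_horse.sex not in ("female", "male"):
        raise MatchingError(
            f"case {case_horse.horse_id}: sex is {case_horse.sex!r}; cannot match on sex"
        )
    if case_horse.birth_date is None:
        raise MatchingError(f"case {case_horse.horse_id}: birth date unknown; cannot match on age")
    out = []
    for horse_id in sorted(pool):
        cand = pool[horse_id]
        if horse_id == case_horse.horse_id:
            continue
        if cand.sex != case_horse.sex:
            continue
        if cand.birth_date is None or cand.birth_date.year != case_horse.birth_date.year:
            continue
        if any(event_key(e) == match_key for e in cand.events):
            out.append(horse_id)
    return out


def select_controls(
    case_horse: HorseRecord,
    case_timeline: CareerTimeline,
    pool: Mapping[str, HorseRecord],
    k: int = 3,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MatchedSet:
    """Draw ``k`` matched controls for one case.

    When more than ``k`` candidates are eligible, a uniform draw without
    replacement is made with ``numpy`` seeded by ``seed`` (deterministic).
    Fewer than ``k`` eligible candidates raises :class:`MatchingError`
    naming the stratum and the shortfall.
    """

    if case_timeline.is_empty:
        raise MatchingError(f"case {case_horse.horse_id}: no events before index; no last event")
    match_event = case_timeline.events[-1]
    match_key = event_key(match_event)
    eligible = _eligible(case_horse, match_key, pool)
    if len(eligible) < k:
        raise MatchingError(
            f"stratum {case_horse.horse_id}: only {len(eligible)} eligible controls "
            f"(need {k}, short {k - len(eligible)}) for event {match_key}"
        )
    if len(eligible) == k:
        chosen = list(eligible)
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(eligible, size=k, replace=False).tolist())

    control_timelines = []
    control_vars = []
    for horse_id in chosen:
        tl = truncate_career(pool[horse_id], match_event.date, config)
        control_timelines.append(tl)
        control_vars.append(compute_variables(tl, pool[horse_id], config))
    return MatchedSet(
        stratum_id=case_horse.horse_id,
        match_event_id=match_key,
        case_id=case_horse.horse_id,
        case_timeline=case_timeline,
        case_variables=compute_variables(case_timeline, case_horse, config),
        control_ids=tuple(chosen),
        control_timelines=tuple(control_timelines),
        control_variables=tuple(control_vars),
    )


@dataclass
class StrataBuildReport:
    """Outcome of building all strata: the sets plus per-stratum failures."""

    strata: list[MatchedSet] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    reused_controls: dict[str, int] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "stratum_id": s.stratum_id,
                    "role": "case",
                    "horse_id": s.case_id,
                    "match_event_id": s.match_event_id,
                }
            )
            for cid in s.control_ids:
                rows.append(
                    {
                        "stratum_id": s.stratum_id,
                        "role": "control",
                        "horse_id": cid,
                        "match_event_id": s.match_event_id,
                    }
                )
        return pd.DataFrame(rows, columns=["stratum_id", "role", "horse_id", "match_event_id"])


def build_strata(
    cases: Sequence[CaseRecord],
    horses: Mapping[str, HorseRecord],
    k: int = 3,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
    pool: Optional[Mapping[str, HorseRecord]] = None,
) -> StrataBuildReport:
    """Build one matched set per case.

    The control pool defaults to every horse that is not itself a case.
    Per-stratum failures (unknown horse, unmatched sex, shortfall) are
    collected into the report rather than aborting the build.  Controls may
    be reused across strata; reuse counts are reported.
    """

    case_ids = {c.horse_id for c in cases}
    if pool is None:
        pool = {hid: h for hid, h in horses.items() if hid not in case_ids}
    report = StrataBuildReport()
    usage: dict[str, int] = {}
    ss = np.random.SeedSequence(seed)
    for case, child in zip(
        sorted(cases, key=lambda c: c.horse_id), ss.spawn(len(cases))
    ):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        horse = horses.get(case.horse_id)
        if horse is None:
            report.failures.append(f"stratum {case.horse_id}: horse not in roster")
            continue
        try:
            tl = truncate_career(horse, case.fracture_date, config)
            matched = select_controls(horse, tl, pool, k=k, seed=sub_seed, config=config)
        except (MatchingError, ValueError) as exc:
            report.failures.append(str(exc))
            continue
        report.strata.append(matched)
        for cid in matched.control_ids:
            usage[cid] = usage.get(cid, 0) + 1
    report.reused_controls = {cid: n for cid, n in sorted(usage.items()) if n > 1}
    return report
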