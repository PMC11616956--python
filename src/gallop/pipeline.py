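"""End-to-end study orchestration.

Reproduces the shape of the fracture-location analysis: a per-variable
group-comparison report (medians, quartiles, Wilcoxon p), the matched
case-control modelling battery (univariable simple + conditional logistic
screen, Box–Tidwell linearity checks with quartile categorisation,
AIC-selected multivariable model, Hosmer–Lemeshow and ROC-AUC
diagnostics), the return-to-racing outcome contrast with exact post-hoc
power, and representative-career cumulative-distance plots.

Randomness is fanned out from a single master seed; reports are written as
full-precision CSV/JSON (display rounding happens only when printing).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from gallop.config import AnalysisConfig, DEFAULT_CONFIG
from gallop.events import CareerTimeline, CaseRecord, HorseRecord, truncate_career
from gallop.matching import MatchedSet, StrataBuildReport, build_strata
from gallop.metrics import (
    VARIABLE_NAMES,
    ExerciseVariables,
    compute_variables,
    cumulative_curve,
    segment_layups,
    variables_frame,
)
from gallop import stats as gstats


def derive_seeds(master_seed: int, stages: Sequence[str]) -> dict[str, int]:
    """Deterministically derive one sub-seed (< 2^31) per pipeline stage."""

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


# ---------------------------------------------------------------------------
# Group comparison (per-variable Wilcoxon report)


def run_group_comparison(
    panels_a: Sequence[ExerciseVariables],
    panels_b: Sequence[ExerciseVariables],
    labels: tuple[str, str] = ("nonPSG", "PSG"),
) -> pd.DataFrame:
    """Compare every workload variable between two cohorts.

    One row per variable: per-group non-missing n, mean, SD, median, Q1,
    Q3 and the two-sided Wilcoxon rank-sum p-value.  Missing values are
    excluded per variable; a variable missing for an entire group is
    flagged and gets no p-value.
    """

    if not panels_a or not panels_b:
        raise ValueError("both groups must be non-empty")
    fa, fb = variables_frame(panels_a), variables_frame(panels_b)
    la, lb = labels
    rows = []
    for var in VARIABLE_NAMES:
        xa = fa[var].dropna().to_numpy(dtype=float)
        xb = fb[var].dropna().to_numpy(dtype=float)
        row: dict = {"variable": var, f"n_{la}": len(xa), f"n_{lb}": len(xb)}
        for label, x in ((la, xa), (lb, xb)):
            if len(x):
                row[f"mean_{label}"] = float(np.mean(x))
                row[f"sd_{label}"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
                row[f"median_{label}"] = float(np.median(x))
                row[f"q1_{label}"] = float(np.quantile(x, 0.25))
                row[f"q3_{label}"] = float(np.quantile(x, 0.75))
            else:
                for stat in ("mean", "sd", "median", "q1", "q3"):
                    row[f"{stat}_{label}"] = float("nan")
        if len(xa) and len(xb):
            row["wilcoxon_p"] = gstats.wilcoxon_rank_sum(xa, xb).p_value
            row["flag"] = ""
        else:
            row["wilcoxon_p"] = float("nan")
            row["flag"] = "missing for an entire group"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Matched case-control modelling


@dataclass
class CaseControlReport:
    """Univariable screen, final multivariable model, and diagnostics."""

    group_label: str
    univariable: pd.DataFrame
    selection: gstats.StepwiseResult
    final_fit: gstats.LogisticModelFit
    hosmer_lemeshow: Optional[gstats.TestResult]
    auc: Optional[float]
    categorized: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def final_table(self) -> pd.DataFrame:
        return self.final_fit.coef_frame()


def _strata_frame(strata: Sequence[MatchedSet], sex_of: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for s in strata:
        for role, var in [("case", s.case_variables)] + [
            ("control", v) for v in s.control_variables
        ]:
            d = var.as_dict()
            d["stratum_id"] = s.stratum_id
            d["case"] = 1 if role == "case" else 0
            d["sex_male"] = 1.0 if sex_of.get(d["horse_id"]) == "male" else 0.0
            rows.append(d)
    return pd.DataFrame(rows)


def run_case_control(
    strata: Sequence[MatchedSet],
    horses: Mapping[str, HorseRecord],
    group_label: str = "cases",
    screen_p: float = 0.20,
    direction: str = "stepwise",
    hl_groups: int = 10,
    linearity_alpha: float = 0.05,
    candidate_vars: Optional[Sequence[str]] = None,
) -> CaseControlReport:
    """Run the full matched case-control battery for one fracture group.

    Every complete, non-degenerate workload variable is screened with
    univariable simple and conditional logistic regression; variables with
    simple-model p < ``screen_p`` (plus age and sex, always candidates)
    enter AIC-driven multivariable selection on the simple logistic model.
    Continuous screened candidates failing the Box–Tidwell linearity check
    are replaced by quartile bands (lowest band as reference).  The final
    model is reported with Hosmer–Lemeshow and ROC-AUC diagnostics.
    """

    if len(strata) < 2:
        raise ValueError("need at least two matched strata")
    sex_of = {hid: h.sex for hid, h in horses.items()}
    df = _strata_frame(strata, sex_of)
    y = df["case"].to_numpy()
    groups = df["stratum_id"].to_numpy()
    notes: list[str] = []

    pool_vars = list(candidate_vars) if candidate_vars is not None else list(VARIABLE_NAMES)
    candidates: list[str] = []
    for var in pool_vars:
        col = df[var]
        if col.isna().any():
            notes.append(f"{var}: dropped (missing values)")
            continue
        if col.nunique() <= 1:
            notes.append(f"{var}: dropped (no variance)")
            continue
        candidates.append(var)
    if df["sex_male"].nunique() > 1:
        candidates.append("sex_male")
    else:
        notes.append("sex_male: dropped (no variance)")

    uni_rows = []
    for var in candidates:
        x = df[[var]]
        row = {"term": var}
        try:
            fit = gstats.logistic_fit(x, y)
            i = fit.names.index(var)
            row["or_simple"] = fit.odds_ratios[i]
            row["p_simple"] = fit.p_values[i]
        except gstats.StatsError as exc:
            row["or_simple"] = float("nan")
            row["p_simple"] = float("nan")
            notes.append(f"{var}: simple logistic inestimable ({exc})")
        try:
            cfit = gstats.conditional_logistic_fit(x, y, groups)
            i = cfit.names.index(var)
            row["or_conditional"] = cfit.odds_ratios[i]
            row["p_conditional"] = cfit.p_values[i]
        except gstats.StatsError as exc:
            row["or_conditional"] = float("nan")
            row["p_conditional"] = float("nan")
            notes.append(f"{var}: conditional logistic inestimable ({exc})")
        uni_rows.append(row)
    univariable = pd.DataFrame(
        uni_rows, columns=["term", "or_simple", "p_simple", "or_conditional", "p_conditional"]
    )

    always = tuple(v for v in ("age_days", "sex_male") if v in candidates)
    design = pd.DataFrame(index=df.index)
    categorized: dict[str, list[str]] = {}
    pmap = dict(zip(univariable["term"], univariable["p_simple"]))
    for var in candidates:
        x = df[var].astype(float)
        p_uni = pmap.get(var, float("nan"))
        screened_in = (not np.isnan(p_uni) and p_uni < screen_p) or var in always
        if not screened_in:
            design[var] = x  # still offered; stepwise screens again internally
            continue
        is_continuous = x.nunique() > 6 and var != "sex_male"
        if is_continuous and (x >= 0).all():
            try:
                bt = gstats.box_tidwell(x, y)
                if bt.p_value < linearity_alpha:
                    codes, cuts, labels = gstats.quartile_categorize(x)
                    names = []
                    for band in (1, 2, 3):  # band 0 is the reference
                        name = f"{var}_q{band + 1}"
                        design[name] = (codes == band).astype(float)
                        names.append(name)
                    categorized[var] = labels
                    notes.append(
                        f"{var}: non-linear logit (Box-Tidwell p={bt.p_value:.3g}); "
                        f"quartile bands at {np.round(cuts, 3).tolist()}"
                    )
                    continue
            except gstats.StatsError as exc:
                notes.append(f"{var}: Box-Tidwell skipped ({exc})")
        design[var] = x

    selection = gstats.stepwise_aic(
        design, y, direction=direction, screen_p=screen_p, always_candidates=always
    )
    final = selection.fit
    if selection.flagged_empty:
        notes.append("no candidate survived selection; intercept-only model")

    hl = None
    auc = None
    if selection.selected:
        try:
            hl = gstats.hosmer_lemeshow(final, groups=hl_groups)
        except gstats.StatsError as exc:
            notes.append(f"Hosmer-Lemeshow unavailable: {exc}")
        try:
            auc = gstats.roc_auc(final)
        except gstats.StatsError as exc:
            notes.append(f"AUC unavailable: {exc}")
    return CaseControlReport(
        group_label=group_label,
        univariable=univariable,
        selection=selection,
        final_fit=final,
        hosmer_lemeshow=hl,
        auc=auc,
        categorized=categorized,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Outcome (return to racing, earnings) analysis


@dataclass
class GroupOutcome:
    label: str
    returned: int
    total: int
    earnings_positive: int
    earnings_evaluable: int
    days_to_return: list[int] = field(default_factory=list)

    @property
    def pct_returned(self) -> float:
        return 100.0 * self.returned / self.total if self.total else float("nan")

    @property
    def pct_earnings_positive(self) -> float:
        return (
            100.0 * self.earnings_positive / self.earnings_evaluable
            if self.earnings_evaluable
            else float("nan")
        )


@dataclass
class OutcomeReport:
    """Return-to-racing and earnings contrasts between fracture groups."""

    groups: dict[str, GroupOutcome]
    return_test: Optional[gstats.TestResult]
    return_power: Optional[float]
    earnings_test: Optional[gstats.TestResult]
    earnings_power: Optional[float]
    excluded: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out: dict = {"groups": {}, "excluded": self.excluded, "flags": self.flags}
        for label, g in self.groups.items():
            out["groups"][label] = {
                "returned": g.returned,
                "total": g.total,
                "pct_returned": g.pct_returned,
                "earnings_positive": g.earnings_positive,
                "earnings_evaluable": g.earnings_evaluable,
                "pct_earnings_positive": g.pct_earnings_positive,
                "median_days_to_return": (
                    float(np.median(g.days_to_return)) if g.days_to_return else None
                ),
            }
        out["return_test_p"] = self.return_test.p_value if self.return_test else None
        out["return_power"] = self.return_power
        out["earnings_test_p"] = self.earnings_test.p_value if self.earnings_test else None
        out["earnings_power"] = self.earnings_power
        return out


def _earnings_in_window(
    horse: HorseRecord, start: dt.date, end_inclusive: dt.date
) -> float:
    return float(
        sum(
            e.earnings or 0.0
            for e in horse.events
            if e.is_race and start <= e.date <= end_inclusive
        )
    )


def run_outcome_analysis(
    cases: Sequence[CaseRecord],
    horses: Mapping[str, HorseRecord],
    alpha: float = 0.05,
    earnings_anchor: str = "return",
) -> OutcomeReport:
    """Post-repair outcome analysis by fracture group.

    A horse *returned* if it has at least one race after its repair date.
    Earnings are classified positive when race earnings in the 365 days
    following the return race (or following repair, with
    ``earnings_anchor='repair'``) exceed earnings in the 365 days before
    fracture; both windows are closed (day 365 included, day 366 not).
    Groups are contrasted with a plain chi-square test and exact Fisher
    post-hoc power at the observed proportions.  Cases without a repair
    date are excluded and logged.
    """

    if earnings_anchor not in ("return", "repair"):
        raise ValueError("earnings_anchor must be 'return' or 'repair'")
    groups: dict[str, GroupOutcome] = {}
    excluded: list[str] = []
    flags: list[str] = []
    for case in cases:
        horse = horses.get(case.horse_id)
        if horse is None:
            excluded.append(f"{case.horse_id}: not in roster")
            continue
        if case.repair_date is None:
            excluded.append(f"{case.horse_id}: missing repair date")
            continue
        g = groups.setdefault(
            case.location, GroupOutcome(case.location, 0, 0, 0, 0)
        )
        g.total += 1
        post_races = [
            e for e in horse.events if e.is_race and e.date > case.repair_date
        ]
        if not post_races:
            continue
        g.returned += 1
        return_date = post_races[0].date
        g.days_to_return.append((return_date - case.fracture_date).days)
        anchor = return_date if earnings_anchor == "return" else case.repair_date
        after = _earnings_in_window(horse, anchor, anchor + dt.timedelta(days=365))
        before = _earnings_in_window(
            horse, case.fracture_date - dt.timedelta(days=365), case.fracture_date
        )
        g.earnings_evaluable += 1
        if after > before:
            g.earnings_positive += 1

    labels = sorted(groups)
    return_test = return_power = earnings_test = earnings_power = None
    if len(labels) == 2:
        a, b = groups[labels[0]], groups[labels[1]]
        if a.returned + b.returned == 0:
            flags.append("no horse returned to racing; contrasts skipped")
        else:
            table = [[a.returned, a.total - a.returned], [b.returned, b.total - b.returned]]
            try:
                return_test = gstats.chi_square(table, continuity=False)
                return_power = gstats.fisher_power_two_proportions(
                    a.total, b.total, a.returned / a.total, b.returned / b.total, alpha
                )
            except gstats.StatsError as exc:
                flags.append(f"return contrast unavailable: {exc}")
        if a.earnings_evaluable and b.earnings_evaluable and (
            a.earnings_positive + b.earnings_positive > 0
        ):
            table = [
                [a.earnings_positive, a.earnings_evaluable - a.earnings_positive],
                [b.earnings_positive, b.earnings_evaluable - b.earnings_positive],
            ]
            try:
                earnings_test = gstats.chi_square(table, continuity=False)
                earnings_power = gstats.fisher_power_two_proportions(
                    a.earnings_evaluable,
                    b.earnings_evaluable,
                    max(a.earnings_positive / a.earnings_evaluable, 1e-9),
                    max(b.earnings_positive / b.earnings_evaluable, 1e-9),
                    alpha,
                )
            except gstats.StatsError as exc:
                flags.append(f"earnings contrast unavailable: {exc}")
        else:
            flags.append("earnings contrast skipped (insufficient evaluable horses)")
    else:
        flags.append(f"expected two groups, found {labels}; contrasts skipped")
    return OutcomeReport(
        groups=groups,
        return_test=return_test,
        return_power=return_power,
        earnings_test=earnings_test,
        earnings_power=earnings_power,
        excluded=excluded,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Representative careers and plotting


def select_representative_career(panels: Sequence[ExerciseVariables]) -> str:
    """The horse most representative of a cohort's median workload.

    Minimises the sum over {number of races, works, layups} of
    ``|value - cohort median| / IQR`` (IQR of 0 replaced by 1); ties break
    on horse id order.
    """

    if not panels:
        raise ValueError("cohort is empty")
    frame = variables_frame(panels)
    keys = ["n_races", "n_works", "n_layups"]
    med = frame[keys].median()
    iqr = frame[keys].quantile(0.75) - frame[keys].quantile(0.25)
    iqr = iqr.replace(0.0, 1.0)
    score = ((frame[keys] - med).abs() / iqr).sum(axis=1)
    best = score.loc[score == score.min()].index.tolist()
    return sorted(best)[0]


@dataclass
class CareerPlot:
    """Exported plotting data: the cumulative curve and layup spans."""

    horse_id: str
    table: pd.DataFrame  # date, event_type, distance, cumulative_f
    layups: pd.DataFrame  # start, end, duration_days
    index_date: dt.date


def plot_career(
    timeline: CareerTimeline,
    out_png: Optional[str | Path] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CareerPlot:
    """Cumulative-distance career plot with the underlying table.

    Races are filled circles, works open circles, layups shaded spans, and
    the index date a dashed vertical line.  The exported table is the
    single source of truth: its cumulative column equals the cumulative
    distance curve at every event.
    """

    if timeline.is_empty:
        raise ValueError(
            f"timeline {timeline.horse_id}: empty after truncation; nothing to plot"
        )
    curve = cumulative_curve(timeline)
    seg = segment_layups(timeline, config)
    rows = [
        {
            "date": e.date,
            "event_type": e.event_type,
            "distance_f": e.distance,
            "cumulative_f": curve.value(e.date),
        }
        for e in timeline.events
    ]
    table = pd.DataFrame(rows)
    layups = pd.DataFrame(
        [
            {"start": l.start, "end": l.end, "duration_days": l.duration_days}
            for l in seg.layups
        ],
        columns=["start", "end", "duration_days"],
    )
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        for _, l in layups.iterrows():
            ax.axvspan(l["start"], l["end"], color="0.85", zorder=0)
        ax.step(table["date"], table["cumulative_f"], where="post", color="0.3", lw=1)
        races = table[table["event_type"] == "race"]
        works = table[table["event_type"] == "work"]
        ax.plot(works["date"], works["cumulative_f"], "o", mfc="white", mec="k", ms=4,
                label="work")
        ax.plot(races["date"], races["cumulative_f"], "o", color="k", ms=4, label="race")
        ax.axvline(timeline.index_date, ls="--", color="firebrick", label="index date")
        ax.set_xlabel("date")
        ax.set_ylabel("cumulative high-speed furlongs")
        ax.set_title(f"{timeline.horse_id}")
        ax.legend(loc="upper left", frameon=False)
        fig.autofmt_xdate()
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return CareerPlot(
        horse_id=timeline.horse_id, table=table, layups=layups, index_date=timeline.index_date
    )


# ---------------------------------------------------------------------------
# Whole-study convenience runner


def compute_case_panels(
    cases: Sequence[CaseRecord],
    horses: Mapping[str, HorseRecord],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, list[ExerciseVariables]]:
    """Truncate each case at its fracture date and compute panels, grouped
    by fracture location."""

    out: dict[str, list[ExerciseVariables]] = {}
    for case in sorted(cases, key=lambda c: c.horse_id):
        horse = horses[case.horse_id]
        tl = truncate_career(horse, case.fracture_date, config)
        out.setdefault(case.location, []).append(compute_variables(tl, horse, config))
    return out


def run_study(
    bundle,
    out_dir: str | Path,
    master_seed: int = 0,
    k_controls: int = 3,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Run the full analysis on a study bundle and write the report files.

    Writes variables.csv, strata.csv, group_comparison.csv, one
    casecontrol_<group>.json per fracture group, outcome.json and two
    representative-career plots.  Deterministic: a fixed master seed gives
    byte-identical reports.
    """

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(master_seed, ["match_psg", "match_nonpsg"])
    horses, cases = bundle.horses, bundle.cases

    panels = compute_case_panels(cases, horses, config)
    all_panels = [p for group in sorted(panels) for p in panels[group]]
    variables_frame(all_panels).to_csv(out / "variables.csv")

    comparison = run_group_comparison(
        panels.get("nonPSG", []), panels.get("PSG", []), labels=("nonPSG", "PSG")
    )
    comparison.to_csv(out / "group_comparison.csv")

    summary: dict = {"master_seed": master_seed, "stage_seeds": seeds, "groups": {}}
    strata_frames = []
    for group, seed_key in (("PSG", "match_psg"), ("nonPSG", "match_nonpsg")):
        group_cases = [c for c in cases if c.location == group]
        report = build_strata(group_cases, horses, k=k_controls, seed=seeds[seed_key], config=config)
        strata_frames.append(report.frame())
        cc = run_case_control(report.strata, horses, group_label=group)
        hl = cc.hosmer_lemeshow
        summary["groups"][group] = {
            "n_strata": len(report.strata),
            "match_failures": report.failures,
            "selected": list(cc.selection.selected),
            "aic": cc.final_fit.aic,
            "lr_test_p": cc.final_fit.lr_test_p,
            "auc": cc.auc,
            "hosmer_lemeshow_p": hl.p_value if hl else None,
            "notes": cc.notes,
        }
        cc.univariable.to_csv(out / f"univariable_{group}.csv", index=False)
        cc.final_table().to_csv(out / f"final_model_{group}.csv", index=False)
        rep_id = select_representative_career(panels[group])
        rep_case = next(c for c in cases if c.horse_id == rep_id)
        tl = truncate_career(horses[rep_id], rep_case.fracture_date, config)
        plot_career(tl, out / f"career_{group}.png", config)
    pd.concat(strata_frames, ignore_index=True).to_csv(out / "strata.csv", index=False)

    outcome = run_outcome_analysis(cases, horses)
    summary["outcome"] = outcome.as_dict()
    (out / "outcome.json").write_text(json.dumps(summary["outcome"], indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
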