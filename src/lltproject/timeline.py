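"""Per-patient LDL-C timelines from prescription fills and lab results.

Day convention: integer days relative to the index angiography (day 0 is the
procedure date).  A prescription is pharmacologically active from the 14th
day after its release (time to receive it and reach steady state) and stays
active for the days supplied plus 14 days; both window ends are inclusive.

The observed LDL-C trajectory is a right-continuous step function: a value
persists (is carried forward) until either a new measurement arrives or the
active regimen changes, in which case the current value is re-expressed
under the new regimen via :func:`lltproject.regimens.transform_ldl` and
flagged as imputed.  Imputed values are superseded by the next measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regimens import NO_THERAPY, Regimen, RegimenEffectTable, transform_ldl

__all__ = [
    "TherapyInterval",
    "LdlPoint",
    "BaselineLdl",
    "active_window",
    "build_therapy_intervals",
    "regimen_at",
    "baseline_ldl",
    "observed_trajectory",
    "trajectory_value_at",
    "apply_exclusions",
    "PCSK9_AGENTS",
    "ACTIVE_LAG_DAYS",
]

#: Days between prescription release and the start of its active window;
#: also the post-supply grace period appended to the window.
ACTIVE_LAG_DAYS = 14

#: Fill agent names treated as PCSK9 inhibitors (an exclusion criterion).
PCSK9_AGENTS = frozenset({"alirocumab", "evolocumab", "inclisiran", "pcsk9_inhibitor"})

#: Fill agent name for ezetimibe.
EZETIMIBE_AGENT = "ezetimibe"


@dataclass(frozen=True)
class TherapyInterval:
    """A regimen active over a closed range of days."""

    regimen: Regimen
    start_day: int
    end_day: int  # inclusive

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must be <= end_day")

    def covers(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day


@dataclass(frozen=True)
class LdlPoint:
    """A dated LDL-C value on the step-function trajectory."""

    day: int
    value: float
    source: str  # measured | imputed | carried_forward
    regimen: Regimen


@dataclass(frozen=True)
class BaselineLdl:
    value: float
    source: str  # measured | imputed
    lab_day: int


def active_window(
    release_day: int, days_supplied: int, lag: int = ACTIVE_LAG_DAYS
) -> tuple[int, int]:
    """Active span of a fill: ``[release + lag, release + supplied + lag]``.

    Both endpoints inclusive.  The same lag delays onset and extends the
    tail, so back-to-back refills chain without artificial gaps.
    """
    days_supplied = int(days_supplied)
    if days_supplied < 1:
        raise ValueError(f"days_supplied must be >= 1, got {days_supplied}")
    release_day = int(release_day)
    return release_day + lag, release_day + days_supplied + lag


def build_therapy_intervals(
    fills: Iterable[tuple[int, str, float | None, int]],
    lag: int = ACTIVE_LAG_DAYS,
) -> list[TherapyInterval]:
    """Resolve fills into non-overlapping therapy intervals.

    Parameters
    ----------
    fills:
        Iterable of ``(release_day, agent, daily_dose, days_supplied)``.
        Ezetimibe fills run on their own track and combine with whatever
        statin is concurrently active; among overlapping statin fills the
        most recently released wins (a new fill is a switch, not a stack),
        with input order breaking release-day ties.

    Returns
    -------
    list of :class:`TherapyInterval`, sorted, merged where contiguous spans
    carry the same regimen.  Days not covered by any interval are no-therapy
    days.
    """
    statin: list[tuple[int, int, int, int, str, float]] = []  # s, e, release, order, agent, dose
    ez: list[tuple[int, int]] = []
    for order, (release, agent, dose, supplied) in enumerate(fills):
        s, e = active_window(release, supplied, lag)
        if agent == EZETIMIBE_AGENT:
            ez.append((s, e))
        else:
            statin.append((s, e, int(release), order, agent, float(dose)))

    cuts = sorted(
        {s for s, e, *_ in statin}
        | {e + 1 for s, e, *_ in statin}
        | {s for s, e in ez}
        | {e + 1 for s, e in ez}
    )
    intervals: list[TherapyInterval] = []
    for a, b in zip(cuts, cuts[1:]):
        covering = [w for w in statin if w[0] <= a <= w[1]]
        if covering:
            _, _, _, _, agent, dose = max(covering, key=lambda w: (w[2], w[3]))
            reg = Regimen(agent, dose, any(s <= a <= e for s, e in ez))
        else:
            ez_active = any(s <= a <= e for s, e in ez)
            if not ez_active:
                continue
            reg = Regimen(ezetimibe=True)
        if intervals and intervals[-1].end_day + 1 == a and intervals[-1].regimen == reg:
            intervals[-1] = TherapyInterval(reg, intervals[-1].start_day, b - 1)
        else:
            intervals.append(TherapyInterval(reg, a, b - 1))
    return intervals


def regimen_at(intervals: Sequence[TherapyInterval], day: int) -> Regimen:
    """Active regimen on a given day (no-therapy if uncovered)."""
    for iv in intervals:
        if iv.start_day > day:
            break
        if iv.covers(day):
            return iv.regimen
    return NO_THERAPY


def _regimen_change_days(
    intervals: Sequence[TherapyInterval], start: int, end: int
) -> list[int]:
    """Days d in (start, end] where the active regimen differs from day d-1."""
    candidates = set()
    for iv in intervals:
        candidates.add(iv.start_day)
        candidates.add(iv.end_day + 1)
    days = []
    for d in sorted(candidates):
        if start < d <= end and regimen_at(intervals, d) != regimen_at(intervals, d - 1):
            days.append(d)
    return days


def baseline_ldl(
    lab_days: Sequence[int],
    lab_values: Sequence[float],
    intervals: Sequence[TherapyInterval],
    effect_table: RegimenEffectTable,
    pre_window: int = 365,
    post_window: int = 90,
) -> BaselineLdl | None:
    """Baseline LDL-C at the index date.

    The qualifying lab is the one closest to day 0 among those within
    ``pre_window`` days before the index (preferred) or, failing that,
    within ``post_window`` days after.  If the active regimen at the lab
    date matches the regimen at day 0 the value is used as measured;
    otherwise it is back-calculated to the day-0 regimen and flagged
    imputed.  Returns ``None`` when no lab qualifies (the patient is
    excluded downstream for insufficient data, not an error).
    """
    days = np.asarray(lab_days, dtype=int)
    values = np.asarray(lab_values, dtype=float)
    pre = (days >= -pre_window) & (days <= 0)
    if pre.any():
        day = int(days[pre].max())
    else:
        post = (days > 0) & (days <= post_window)
        if not post.any():
            return None
        day = int(days[post].min())
    value = float(values[days == day].mean())  # duplicate same-day labs: average

    reg_lab = regimen_at(intervals, day)
    reg_index = regimen_at(intervals, 0)
    if reg_lab == reg_index:
        return BaselineLdl(value, "measured", day)
    return BaselineLdl(
        transform_ldl(value, reg_lab, reg_index, effect_table), "imputed", day
    )


def observed_trajectory(
    lab_days: Sequence[int],
    lab_values: Sequence[float],
    intervals: Sequence[TherapyInterval],
    effect_table: RegimenEffectTable,
    baseline: BaselineLdl,
    end_day: int,
) -> list[LdlPoint]:
    """Observed LDL-C step function from day 0 through ``end_day``.

    Starts at the baseline value under the day-0 regimen.  A new point is
    emitted at each post-index measurement (source ``measured``) and at each
    regimen-change day (source ``imputed``, via back-calculation from the
    most recent point); a measurement on a regimen-change day wins.  Values
    carry forward between points.
    """
    if end_day < 0:
        raise ValueError("end_day must be >= 0")
    days = np.asarray(lab_days, dtype=int)
    values = np.asarray(lab_values, dtype=float)
    in_fu = (days > 0) & (days <= end_day)
    lab_map: dict[int, float] = {}
    for d in np.unique(days[in_fu]):
        lab_map[int(d)] = float(values[days == d].mean())

    change_days = _regimen_change_days(intervals, 0, end_day)
    reg0 = regimen_at(intervals, 0)
    points = [LdlPoint(0, baseline.value, baseline.source, reg0)]
    cur_value, cur_reg = baseline.value, reg0
    for d in sorted(set(lab_map) | set(change_days)):
        reg = regimen_at(intervals, d)
        if d in lab_map:
            value, source = lab_map[d], "measured"
        else:
            value, source = transform_ldl(cur_value, cur_reg, reg, effect_table), "imputed"
        points.append(LdlPoint(d, value, source, reg))
        cur_value, cur_reg = value, reg
    return points


def trajectory_value_at(points: Sequence[LdlPoint], day: int) -> float:
    """Step-function value at ``day`` (last point at or before it)."""
    if day < points[0].day:
        raise ValueError("day precedes trajectory start")
    value = points[0].value
    for p in points:
        if p.day > day:
            break
        value = p.value
    return value


# ---------------------------------------------------------------------------
# Cohort exclusions
# ---------------------------------------------------------------------------

EXCLUSION_REASONS = (
    "insufficient_baseline_ldl",
    "nonstandard_statin_regimen",
    "pcsk9_inhibitor",
    "dialysis",
    "egfr_below_15",
    "age_below_18",
    "death_within_30_days",
)


def apply_exclusions(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    fills: pd.DataFrame,
    effect_table: RegimenEffectTable,
    *,
    pre_window: int = 365,
    post_window: int = 90,
    egfr_min: float = 15.0,
    min_age: float = 18.0,
    early_death_days: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion filters; reasons are not mutually exclusive.

    Removes patients with: no lab usable for baseline LDL-C (none within the
    pre/post windows around the index); any statin fill whose agent/dose is
    absent from the standard intensity map; any PCSK9-inhibitor fill;
    dialysis dependence; eGFR below 15 mL/min; age below 18; or death within
    30 days of the index angiography.

    Returns
    -------
    (retained patients, report) where the report lists one row per reason
    with its count plus ``total_excluded`` / ``retained`` summary rows.
    Idempotent: re-running on the retained cohort excludes nobody.
    """
    for col in ("patient_id", "age", "egfr", "dialysis"):
        if col not in patients.columns:
            raise KeyError(f"patients table missing required column {col!r}")
    pid = patients["patient_id"]

    flags = pd.DataFrame(index=patients.index)

    lab_ok = labs.loc[
        (labs["day"] >= -pre_window) & (labs["day"] <= post_window), "patient_id"
    ].unique()
    flags["insufficient_baseline_ldl"] = ~pid.isin(lab_ok)

    statin_fills = fills.loc[
        ~fills["agent"].isin(PCSK9_AGENTS | {EZETIMIBE_AGENT})
    ]
    nonstd = statin_fills.loc[
        [
            not effect_table.is_standard(a, d)
            for a, d in zip(statin_fills["agent"], statin_fills["dose"])
        ],
        "patient_id",
    ].unique()
    flags["nonstandard_statin_regimen"] = pid.isin(nonstd)

    pcsk9 = fills.loc[fills["agent"].isin(PCSK9_AGENTS), "patient_id"].unique()
    flags["pcsk9_inhibitor"] = pid.isin(pcsk9)

    flags["dialysis"] = patients["dialysis"].astype(bool)
    flags["egfr_below_15"] = patients["egfr"] < egfr_min
    flags["age_below_18"] = patients["age"] < min_age
    death = patients.get("death_day")
    if death is None:
        flags["death_within_30_days"] = False
    else:
        flags["death_within_30_days"] = death.notna() & (death <= early_death_days)

    excluded = flags.any(axis=1)
    report_rows = [
        {"reason": reason, "n": int(flags[reason].sum())} for reason in EXCLUSION_REASONS
    ]
    report_rows.append({"reason": "total_excluded", "n": int(excluded.sum())})
    report_rows.append({"reason": "retained", "n": int((~excluded).sum())})
    report = pd.DataFrame(report_rows)
    return patients.loc[~excluded].reset_index(drop=True), report
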