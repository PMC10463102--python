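"""End-to-end pipeline: tables in, projected-outcome artifacts out.

Stage order: exclusions -> baseline & observed trajectories -> counterfactual
scenarios -> interval averages & mixed-model curves -> outcome projection
and NNT.  All analysis constants (window lengths, the 14-day rule, the
mg/dL-per-mmol/L conversion, regimen effect sizes, rate-ratio associations,
bootstrap counts) live in :class:`PipelineConfig` with documented defaults
and round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counterfactual import SCENARIOS, assign_tier, project_scenario
from .projection import (
    DEFAULT_CTT_ASSOCIATIONS,
    CttAssociation,
    outcome_survival_data,
    run_projection,
)
from .regimens import RegimenEffectTable
from .simulate import OUTCOMES, DAYS_PER_YEAR
from .timeline import (
    PCSK9_AGENTS,
    apply_exclusions,
    baseline_ldl,
    build_therapy_intervals,
    observed_trajectory,
)
from .trajmodel import (
    fit_trajectory_model,
    interval_averages,
    reduction_summary,
    scenario_reduction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_tables",
    "build_trajectories",
    "ldl_value_matrix",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Analysis configuration with every constant surfaced.

    Durations in days, LDL-C in mg/dL.  ``grid_months`` are the 6-month
    evaluation points for the outcome projection; ``horizon_days`` is the
    administrative censoring horizon (4 years).
    """

    seed: int = 0
    n_bootstrap: int = 1000
    spline_df: int = 6
    horizon_days: int = 1460
    grid_months: tuple[int, ...] = (6, 12, 18, 24, 30, 36, 42, 48)
    bin_days: int = 30
    active_lag_days: int = 14
    baseline_pre_window: int = 365
    baseline_post_window: int = 90
    revasc_min_day: int = 30
    min_followup_days: int = 30
    strata: tuple[str, ...] = ("all",)
    rr_mode: str = "per_bootstrap"
    effect_table: RegimenEffectTable = field(default_factory=RegimenEffectTable)
    associations: dict[str, CttAssociation] = field(
        default_factory=lambda: dict(DEFAULT_CTT_ASSOCIATIONS)
    )

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.spline_df < 3:
            raise ValueError("spline_df must be >= 3")
        if self.horizon_days <= self.min_followup_days:
            raise ValueError("horizon must exceed the minimum follow-up")
        bad = set(self.strata) - {"all", "acs", "non_acs"}
        if bad:
            raise ValueError(f"unknown strata {sorted(bad)}")

    @property
    def grid_days(self) -> np.ndarray:
        days = np.round(np.asarray(self.grid_months) * DAYS_PER_YEAR / 12.0)
        return np.minimum(days, float(self.horizon_days))

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("effect_table", "associations")
        }
        d["grid_months"] = list(self.grid_months)
        d["strata"] = list(self.strata)
        d["effect_table"] = self.effect_table.to_dict()
        d["associations"] = {
            o: {"rr": a.rr, "ci_lower": a.ci_lower, "ci_upper": a.ci_upper}
            for o, a in self.associations.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "effect_table" in d:
            d["effect_table"] = RegimenEffectTable.from_dict(d["effect_table"])
        if "associations" in d:
            d["associations"] = {
                o: CttAssociation(o, a["rr"], a["ci_lower"], a["ci_upper"])
                for o, a in d["associations"].items()
            }
        for key in ("grid_months", "strata"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


def _dates_to_days(df: pd.DataFrame, date_col: str, day_col: str, index_date: pd.Series) -> pd.DataFrame:
    df = df.copy()
    base = pd.to_datetime(index_date.loc[df["patient_id"]].to_numpy())
    df[day_col] = (pd.to_datetime(df.pop(date_col)) - base).dt.days
    return df


def load_tables(
    data_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read patients/labs/fills/events CSVs, converting dates to index-relative days.

    Accepts either ``day`` columns directly or ISO-8601 date columns
    (``date`` / ``release_date`` / ``death_date``) resolved against each
    patient's ``index_date``.
    """
    d = Path(data_dir)
    patients = pd.read_csv(d / "patients.csv")
    labs = pd.read_csv(d / "labs.csv")
    fills = pd.read_csv(d / "fills.csv")
    events = pd.read_csv(d / "events.csv")
    index_date = patients.set_index("patient_id")["index_date"]
    if "death_day" not in patients.columns:
        death = pd.to_datetime(patients["death_date"], errors="coerce")
        patients["death_day"] = (
            death - pd.to_datetime(patients["index_date"])
        ).dt.days
    if "day" not in labs.columns:
        labs = _dates_to_days(labs, "date", "day", index_date)
    if "release_day" not in fills.columns:
        fills = _dates_to_days(fills, "release_date", "release_day", index_date)
    if "day" not in events.columns:
        events = _dates_to_days(events, "date", "day", index_date)
    return patients, labs, fills, events


def build_trajectories(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    fills: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Observed and counterfactual LDL-C step functions for every patient.

    Returns a long table (``patient_id``, ``scenario``, ``day``, ``value``,
    ``source``, ``regimen``) and the per-patient end of observation
    (min of death and the administrative horizon).  Patients without a
    qualifying baseline lab are skipped with a warning (they should already
    have been excluded).
    """
    et = config.effect_table
    lag = config.active_lag_days
    horizon = config.horizon_days
    fills = fills.loc[~fills["agent"].isin(PCSK9_AGENTS)]
    fills_by_pid = {pid: g for pid, g in fills.groupby("patient_id")}
    labs_by_pid = {pid: g for pid, g in labs.groupby("patient_id")}
    empty_labs = labs.iloc[:0]
    empty_fills = fills.iloc[:0]

    rows: list[tuple] = []
    end_days = {}
    n_skipped = 0
    for patient in patients.itertuples(index=False):
        pid = patient.patient_id
        death = getattr(patient, "death_day", np.nan)
        end_day = int(min(death, horizon)) if pd.notna(death) else horizon
        f = fills_by_pid.get(pid, empty_fills)
        intervals = build_therapy_intervals(
            zip(f["release_day"], f["agent"], f["dose"], f["days_supplied"]), lag=lag
        )
        lab = labs_by_pid.get(pid, empty_labs)
        base = baseline_ldl(
            lab["day"].to_numpy(),
            lab["ldl"].to_numpy(),
            intervals,
            et,
            pre_window=config.baseline_pre_window,
            post_window=config.baseline_post_window,
        )
        if base is None:
            n_skipped += 1
            continue
        observed = observed_trajectory(
            lab["day"].to_numpy(), lab["ldl"].to_numpy(), intervals, et, base, end_day
        )
        tier = assign_tier(patient.contraindication)
        trajs = {"observed": observed}
        for sc in ("opt_statin", "opt_statin_ez"):
            trajs[sc] = project_scenario(observed, tier, et, sc).points
        for sc, pts in trajs.items():
            for p in pts:
                rows.append((pid, sc, p.day, p.value, p.source, p.regimen.label()))
        end_days[pid] = end_day
    if n_skipped:
        logger.warning("skipped %d patients without a qualifying baseline lab", n_skipped)
    points = pd.DataFrame(
        rows, columns=["patient_id", "scenario", "day", "value", "source", "regimen"]
    )
    return points, pd.Series(end_days, name="end_day")


def ldl_value_matrix(
    points: pd.DataFrame,
    end_days: pd.Series,
    grid_days: np.ndarray,
) -> dict[str, np.ndarray]:
    """Step-function LDL-C per patient at each grid day, per scenario.

    Entries are NaN past the patient's end of observation.  Patient rows are
    ordered by ``end_days.index`` in every scenario, aligned for use with
    :func:`lltproject.projection.run_projection`.
    """
    grid_days = np.asarray(grid_days, dtype=float)
    pids = end_days.index.to_numpy()
    pos = {pid: i for i, pid in enumerate(pids)}
    big = int(max(points["day"].max(), grid_days.max())) + 2
    out = {}
    for sc, sub in points.groupby("scenario"):
        sub = sub.sort_values(["patient_id", "day"], kind="stable")
        keys = sub["patient_id"].map(pos).to_numpy() * big + sub["day"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        mat = np.full((pids.size, grid_days.size), np.nan)
        for j, g in enumerate(grid_days):
            q = np.arange(pids.size) * big + int(g)
            idx = np.searchsorted(keys, q, side="right") - 1
            mat[:, j] = vals[np.maximum(idx, 0)]
        beyond = grid_days[None, :] > end_days.to_numpy(dtype=float)[:, None]
        mat[beyond] = np.nan
        out[sc] = mat
    return out


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    exclusion_report: pd.DataFrame
    trajectories: pd.DataFrame
    averages: pd.DataFrame
    curves: dict
    reductions: pd.DataFrame
    reduction_summary: pd.DataFrame
    projection: pd.DataFrame
    nnt_table: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            "# days are relative to the index angiography (day 0); "
            "LDL-C in mg/dL; incidences are fractions in [0, 1]\n"
        )

        def dump(df: pd.DataFrame, name: str) -> None:
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

        dump(self.exclusion_report, "exclusions.csv")
        dump(self.trajectories, "trajectories.csv")
        curve_rows = []
        for sc, c in self.curves.items():
            curve_rows.append(
                pd.DataFrame(
                    {"scenario": sc, "day": c.grid, "est": c.mean, "lo": c.lo, "hi": c.hi}
                )
            )
        dump(pd.concat(curve_rows, ignore_index=True), "curves.csv")
        dump(self.reductions, "reductions.csv")
        dump(self.reduction_summary, "reduction_summary.csv")
        dump(self.projection, "projection.csv")
        dump(self.nnt_table, "nnt.csv")
        self.config.to_yaml(out / "config.yaml")


def nnt_table_from_projection(projection: pd.DataFrame) -> pd.DataFrame:
    """NNT summary at yearly time points, one row per scenario x year."""
    sub = projection.loc[
        (projection["stratum"] == "all") & (projection["months"].round().isin([12, 24, 36, 48]))
    ]
    rows = []
    for (sc, months), g in sub.groupby(["scenario", "months"]):
        row = {"scenario": sc, "years": int(round(months / 12))}
        def fmt(v):
            return "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else str(int(v))

        for _, r in g.iterrows():
            if fmt(r["nnt"]) == "NA":
                row[r["outcome"]] = "NA"
            else:
                row[r["outcome"]] = f"{fmt(r['nnt'])} ({fmt(r['nnt_lo'])}-{fmt(r['nnt_hi'])})"
        rows.append(row)
    cols = ["scenario", "years", *OUTCOMES]
    return pd.DataFrame(rows).sort_values(["scenario", "years"]).reset_index(drop=True)[cols]


def run_pipeline(
    config: PipelineConfig,
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    fills: pd.DataFrame,
    events: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on in-memory tables; optionally write artifacts.

    Stages: exclusions -> trajectories & scenarios -> interval averages ->
    mixed-model curves and scenario reductions -> outcome projection and
    NNT.  Deterministic given ``config.seed``.
    """
    logger.info("pipeline start: %d patients, config %s", len(patients), config.config_hash())
    retained, report = apply_exclusions(
        patients,
        labs,
        fills,
        config.effect_table,
        pre_window=config.baseline_pre_window,
        post_window=config.baseline_post_window,
        early_death_days=config.min_followup_days,
    )
    logger.info("exclusions applied: %d retained", len(retained))

    points, end_days = build_trajectories(retained, labs, fills, config)
    retained = retained.loc[retained["patient_id"].isin(end_days.index)].reset_index(
        drop=True
    )

    avgs = []
    for sc in SCENARIOS:
        sub = points.loc[points["scenario"] == sc]
        a = interval_averages(sub, end_days, bin_days=config.bin_days)
        a.insert(1, "scenario", sc)
        avgs.append(a)
    averages = pd.concat(avgs, ignore_index=True)

    curves = fit_trajectory_model(
        averages,
        n_bootstrap=config.n_bootstrap,
        spline_df=config.spline_df,
        seed=config.seed,
        bin_days=config.bin_days,
        boundary=(0.0, float(config.horizon_days)),
    )
    reductions = scenario_reduction(curves)
    summary = reduction_summary(
        reductions,
        {"1y": 365.25, "2y": 730.5, "3y": 1095.75, "4y": float(config.horizon_days)},
    )

    values = ldl_value_matrix(points, end_days, config.grid_days)
    fu = end_days.astype(float)
    survival = {
        o: outcome_survival_data(
            events.loc[events["patient_id"].isin(end_days.index)],
            fu,
            o,
            revasc_min_day=config.revasc_min_day,
        )
        for o in OUTCOMES
    }
    strata_masks = {}
    acs = retained.set_index("patient_id")["acs"].reindex(end_days.index).astype(bool)
    for name in config.strata:
        if name == "all":
            strata_masks[name] = np.ones(len(end_days), dtype=bool)
        elif name == "acs":
            strata_masks[name] = acs.to_numpy()
        else:
            strata_masks[name] = ~acs.to_numpy()

    projection = run_projection(
        values,
        survival,
        config.grid_days,
        associations=config.associations,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        strata=strata_masks,
        rr_mode=config.rr_mode,
    )
    nnt_table = nnt_table_from_projection(projection)

    result = PipelineResult(
        config=config,
        exclusion_report=report,
        trajectories=points,
        averages=averages,
        curves=curves,
        reductions=reductions,
        reduction_summary=summary,
        projection=projection,
        nnt_table=nnt_table,
    )
    if out_dir is not None:
        result.write(out_dir)
        logger.info("artifacts written to %s", out_dir)
    return result
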