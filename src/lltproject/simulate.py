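"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes for a
secondary-prevention angiography cohort: an eligibility mix for optimized
statin therapy, partial baseline statin/ezetimibe coverage, sparse lab
measurement, pharmacy fills realizing each patient's regimen history, and
event hazards that depend on the current true LDL-C through the same
rate-ratio law the outcome projection assumes,

    hazard_i(t) = baseline_hazard_i * rr_i ** ((reference_ldl - LDL(t)) / 38.67),

piecewise constant over the patient's regimen phases.  Because the generator
and the projection share this law, projection parameter recovery is an exact
test of the pipeline.

Each patient has at most two regimen phases: a baseline regimen active from
well before the index date, and (optionally) a switch to a more intensive
regimen.  Under the ``observed`` policy the switch is a random
intensification in the first six months; under the counterfactual policies
(``opt_statin`` / ``opt_statin_ez``) every patient switches at day 0 to
their eligibility tier's optimized regimen.  Patient-level latent draws
(untreated LDL-C, flags, event exponentials) are taken from a dedicated
substream whose consumption depends only on ``n_patients``, so cohorts
simulated under different policies from the same seed are coupled twins of
the same patients — the counterfactual can be simulated directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counterfactual import assign_tier, tier_regimen
from .regimens import (
    DEFAULT_STATIN_REDUCTIONS,
    MGDL_PER_MMOL,
    Regimen,
    RegimenEffectTable,
)

__all__ = ["OUTCOMES", "SimConfig", "SyntheticCohort", "simulate_cohort"]

OUTCOMES = ("death", "mi", "stroke", "revascularization")

DAYS_PER_YEAR = 365.25

# Baseline regimen catalogs: (agent, dose, sampling probability).
_HIGH_CATALOG = (
    ("atorvastatin", 80.0, 0.40),
    ("atorvastatin", 40.0, 0.30),
    ("rosuvastatin", 20.0, 0.18),
    ("rosuvastatin", 40.0, 0.12),
)
_OTHER_CATALOG = (
    ("atorvastatin", 20.0, 0.24),
    ("atorvastatin", 10.0, 0.14),
    ("simvastatin", 40.0, 0.20),
    ("simvastatin", 20.0, 0.14),
    ("rosuvastatin", 10.0, 0.10),
    ("pravastatin", 40.0, 0.08),
    ("simvastatin", 10.0, 0.06),
    ("pravastatin", 20.0, 0.04),
)
# Nonstandard regimens (absent from the intensity map -> excluded upstream),
# with the true fractional LDL-C reduction the generator applies:
# (agent, dose, probability, true reduction).
_NONSTANDARD_CATALOG = (
    ("fluvastatin", 80.0, 0.5, 0.33),
    ("lovastatin", 40.0, 0.3, 0.31),
    ("atorvastatin", 60.0, 0.2, 0.515),
)


def _default_hazards() -> dict[str, float]:
    # events per person-year at the reference LDL-C; scaled to the event
    # counts observed in a comparable angiography cohort over 4 years
    return {"death": 0.055, "mi": 0.014, "stroke": 0.006, "revascularization": 0.045}


def _default_rr() -> dict[str, float]:
    # per-outcome rate ratios per 38.67 mg/dL LDL-C reduction (CTT-style)
    return {"death": 0.90, "mi": 0.74, "stroke": 0.85, "revascularization": 0.76}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Fractions are cohort proportions; hazards are events per person-year at
    ``reference_ldl``; ``rr_per_mmol`` are rate ratios per 38.67 mg/dL
    (1 mmol/L) LDL-C reduction; LDL-C in mg/dL, durations in days.
    """

    n_patients: int
    seed: int = 0
    acs_prevalence: float = 0.268
    # eligible for full-dose / reduced-dose / no statin
    eligibility_mix: tuple[float, float, float] = (0.8389, 0.1534, 0.0077)
    baseline_statin_coverage: float = 0.597
    baseline_high_intensity_fraction: float = 0.349
    baseline_ezetimibe_fraction: float = 0.006
    untreated_ldl_mean: float = 113.0
    untreated_ldl_sd: float = 40.0
    lab_noise_sd: float = 8.0
    # exponential mean for the first post-index lab; 194.8 d puts the
    # median at 135 d
    lab_interval_mean: float = 194.8
    lab_followup_interval: float = 180.0
    lab_followup_jitter: float = 45.0
    pre_index_lab_fraction: float = 0.93
    intensification_prob: float = 0.28
    baseline_hazards: dict[str, float] = field(default_factory=_default_hazards)
    reference_ldl: float = 79.7
    rr_per_mmol: dict[str, float] = field(default_factory=_default_rr)
    admin_censor_days: int = 1460
    fill_days_supplied: int = 90
    nonstandard_fraction: float = 0.098
    pcsk9_fraction: float = 0.0147
    dialysis_fraction: float = 0.032
    underage_fraction: float = 0.00015
    age_mean: float = 68.4
    age_sd: float = 8.8
    male_fraction: float = 0.977
    egfr_mean: float = 75.0
    egfr_sd: float = 22.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        mix = self.eligibility_mix
        if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("eligibility_mix must be 3 fractions summing to 1")
        fractions = dict(
            acs_prevalence=self.acs_prevalence,
            baseline_statin_coverage=self.baseline_statin_coverage,
            baseline_high_intensity_fraction=self.baseline_high_intensity_fraction,
            baseline_ezetimibe_fraction=self.baseline_ezetimibe_fraction,
            pre_index_lab_fraction=self.pre_index_lab_fraction,
            intensification_prob=self.intensification_prob,
            nonstandard_fraction=self.nonstandard_fraction,
            pcsk9_fraction=self.pcsk9_fraction,
            dialysis_fraction=self.dialysis_fraction,
            underage_fraction=self.underage_fraction,
            male_fraction=self.male_fraction,
        )
        fractions.update({f"eligibility_mix[{i}]": v for i, v in enumerate(mix)})
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.baseline_high_intensity_fraction > self.baseline_statin_coverage:
            raise ValueError("high-intensity fraction cannot exceed statin coverage")
        for outcome in OUTCOMES:
            if self.baseline_hazards.get(outcome, 0.0) <= 0.0:
                raise ValueError(f"baseline hazard for {outcome} must be > 0")
            rr = self.rr_per_mmol.get(outcome, 0.0)
            if not 0.0 < rr < 1.5:
                raise ValueError(f"rr_per_mmol for {outcome} must be in (0, 1.5)")
        if self.admin_censor_days <= 30 or self.fill_days_supplied < 1:
            raise ValueError("invalid follow-up or fill duration")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["eligibility_mix"] = list(self.eligibility_mix)
        d["baseline_hazards"] = dict(self.baseline_hazards)
        d["rr_per_mmol"] = dict(self.rr_per_mmol)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "eligibility_mix" in d:
            d["eligibility_mix"] = tuple(d["eligibility_mix"])
        return cls(**d)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """Simulated patients, fills, labs, events and the generating truth.

    All ``day`` columns are integers relative to each patient's index
    angiography.  The truth table records, per patient, the untreated
    LDL-C, the regimen phases actually applied and the day-0 event hazards.
    """

    config: SimConfig
    policy: str
    patients: pd.DataFrame
    fills: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame

    def write_csv(self, out_dir: str | Path) -> None:
        """Write the four input tables plus truth as CSV with ISO dates."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index_date = pd.to_datetime(self.patients.set_index("patient_id")["index_date"])

        patients = self.patients.copy()
        death = pd.to_timedelta(patients.pop("death_day"), unit="D")
        patients["death_date"] = (
            pd.to_datetime(patients["index_date"]) + death
        ).dt.strftime("%Y-%m-%d")
        patients.to_csv(out / "patients.csv", index=False)

        for name, df, day_col, date_col in (
            ("fills", self.fills, "release_day", "release_date"),
            ("labs", self.labs, "day", "date"),
            ("events", self.events, "day", "date"),
        ):
            df = df.copy()
            base = index_date.loc[df["patient_id"]].to_numpy()
            df[date_col] = pd.Series(
                base + pd.to_timedelta(df.pop(day_col), unit="D").to_numpy()
            ).dt.strftime("%Y-%m-%d")
            df.to_csv(out / f"{name}.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _pick(catalog: tuple, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (agent, dose[, truth reduction]) rows of a catalog via uniforms."""
    probs = np.array([row[2] for row in catalog])
    idx = np.searchsorted(np.cumsum(probs) / probs.sum(), u, side="right")
    idx = np.minimum(idx, len(catalog) - 1)
    agents = np.array([row[0] for row in catalog], dtype=object)[idx]
    doses = np.array([row[1] for row in catalog])[idx]
    return agents, doses, idx


def _chain(
    start: np.ndarray, stop_excl: np.ndarray, step: int, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Release days ``start + k*step < stop_excl`` per patient (vectorized).

    Returns (patient row index, release day) flattened over the cohort.
    """
    counts = np.where(
        mask, np.ceil((stop_excl - start) / step).astype(int).clip(min=0), 0
    )
    total = int(counts.sum())
    pid = np.repeat(np.arange(len(counts)), counts)
    cum = np.cumsum(counts)
    offs = np.arange(total) - np.repeat(cum - counts, counts)
    return pid, start[pid] + offs * step


def simulate_cohort(
    config: SimConfig,
    policy: str = "observed",
    effect_table: RegimenEffectTable | None = None,
) -> SyntheticCohort:
    """Simulate a cohort under a therapy policy.

    Parameters
    ----------
    policy:
        ``"observed"`` — baseline regimens with random intensification in
        the first six months; ``"opt_statin"`` / ``"opt_statin_ez"`` — the
        counterfactual twin on tier-optimized therapy from day 0.  Twin
        cohorts simulated from the same config/seed share all patient-level
        latent draws with the observed cohort.

    Deterministic given (config, policy): identical seeds yield identical
    tables.
    """
    if policy not in ("observed", "opt_statin", "opt_statin_ez"):
        raise ValueError(f"unknown policy {policy!r}")
    effect_table = effect_table or RegimenEffectTable()
    cfg = config
    n = cfg.n_patients
    S = int(cfg.fill_days_supplied)
    T = float(cfg.admin_censor_days)

    rng_lat = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 1]))
    rng_lab = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 2]))

    # ----- patient latents (consumption depends only on n) ---------------
    age = np.round(rng_lat.normal(cfg.age_mean, cfg.age_sd, n).clip(25, 100), 1)
    underage = rng_lat.random(n) < cfg.underage_fraction
    age[underage] = 17.0
    male = rng_lat.random(n) < cfg.male_fraction
    acs = rng_lat.random(n) < cfg.acs_prevalence
    contra = np.asarray(
        rng_lat.choice(["none", "relative", "absolute"], n, p=list(cfg.eligibility_mix)),
        dtype=object,
    )
    egfr = np.round(rng_lat.normal(cfg.egfr_mean, cfg.egfr_sd, n).clip(3, 150), 1)
    dialysis = rng_lat.random(n) < cfg.dialysis_fraction
    pcsk9 = rng_lat.random(n) < cfg.pcsk9_fraction
    untreated = rng_lat.normal(cfg.untreated_ldl_mean, cfg.untreated_ldl_sd, n).clip(30)

    # baseline regimen; absolute-contraindication patients take no statin,
    # others at an adjusted rate so the cohort marginal equals the config
    abs_frac = cfg.eligibility_mix[2]
    p_statin = min(cfg.baseline_statin_coverage / max(1.0 - abs_frac, 1e-12), 1.0)
    on_statin = (rng_lat.random(n) < p_statin) & (contra != "absolute")
    p_high = (
        cfg.baseline_high_intensity_fraction / cfg.baseline_statin_coverage
        if cfg.baseline_statin_coverage > 0
        else 0.0
    )
    high = on_statin & (rng_lat.random(n) < p_high)
    u_pick = rng_lat.random(n)
    u_nonstd = rng_lat.random(n)
    u_nonstd_pick = rng_lat.random(n)
    ez0 = rng_lat.random(n) < cfg.baseline_ezetimibe_fraction
    u_int = rng_lat.random(n)
    int_day = rng_lat.integers(14, 181, n)
    u_int_pick = rng_lat.random(n)
    event_exp = rng_lat.exponential(1.0, (len(OUTCOMES), n))
    has_pre_lab = rng_lat.random(n) < cfg.pre_index_lab_fraction
    pre_lab_day = -rng_lat.integers(7, 351, n)
    first_gap = rng_lat.exponential(cfg.lab_interval_mean, n)
    base_offset = rng_lat.integers(0, S, n)
    ez_offset = rng_lat.integers(0, S, n)
    pcsk9_day = rng_lat.integers(-180, 181, n)
    index_date = pd.Timestamp("2015-06-01") + pd.to_timedelta(
        rng_lat.integers(0, 1949, n), unit="D"
    )

    # ----- baseline regimen agents/doses and true reductions --------------
    agent0 = np.full(n, None, dtype=object)
    dose0 = np.full(n, np.nan)
    r_statin0 = np.zeros(n)
    hi_agents, hi_doses, hi_idx = _pick(_HIGH_CATALOG, u_pick)
    ot_agents, ot_doses, ot_idx = _pick(_OTHER_CATALOG, u_pick)
    agent0[high] = hi_agents[high]
    dose0[high] = hi_doses[high]
    mod = on_statin & ~high
    agent0[mod] = ot_agents[mod]
    dose0[mod] = ot_doses[mod]
    for (a, d), r in DEFAULT_STATIN_REDUCTIONS.items():
        r_statin0[(agent0 == a) & (dose0 == d)] = r
    nonstd = on_statin & (
        u_nonstd
        < min(cfg.nonstandard_fraction / max(cfg.baseline_statin_coverage, 1e-12), 1.0)
    )
    ns_agents, ns_doses, ns_idx = _pick(_NONSTANDARD_CATALOG, u_nonstd_pick)
    agent0[nonstd] = ns_agents[nonstd]
    dose0[nonstd] = ns_doses[nonstd]
    r_statin0[nonstd] = np.array([row[3] for row in _NONSTANDARD_CATALOG])[ns_idx][nonstd]

    ez_mult = 1.0 - effect_table.ezetimibe_reduction
    r_pre = 1.0 - (1.0 - r_statin0) * np.where(ez0, ez_mult, 1.0)

    # ----- regimen switch per policy --------------------------------------
    if policy == "observed":
        is_high_std = np.zeros(n, dtype=bool)
        for (a, d), cls in effect_table.intensity_map.items():
            if cls == "high":
                is_high_std |= (agent0 == a) & (dose0 == d)
        switch = (~is_high_std) & (u_int < cfg.intensification_prob) & ~underage
        switch_day = np.where(switch, int_day, 0).astype(float)
        new_agents, new_doses, new_idx = _pick(_HIGH_CATALOG, u_int_pick)
        agent1 = np.where(switch, new_agents, agent0)
        dose1 = np.where(switch, new_doses, dose0)
        r_statin1 = r_statin0.copy()
        for (a, d), r in DEFAULT_STATIN_REDUCTIONS.items():
            r_statin1[switch & (new_agents == a) & (new_doses == d)] = r
        ez1 = ez0
    else:
        tiers = {
            c: tier_regimen(assign_tier(c)) for c in ("none", "relative", "absolute")
        }
        switch = np.ones(n, dtype=bool)
        switch_day = np.zeros(n)
        agent1 = np.array(
            [tiers[c].statin_agent for c in contra], dtype=object
        )
        dose1 = np.array(
            [tiers[c].statin_daily_dose or np.nan for c in contra], dtype=float
        )
        r_statin1 = np.array(
            [
                effect_table.statin_reduction(tiers[c]) if tiers[c].has_statin else 0.0
                for c in contra
            ]
        )
        ez1 = np.full(n, policy == "opt_statin_ez")
    r_post = 1.0 - (1.0 - r_statin1) * np.where(ez1, ez_mult, 1.0)
    r_post = np.where(switch, r_post, r_pre)

    ldl_pre = untreated * (1.0 - r_pre)
    ldl_post = np.where(switch, untreated * (1.0 - r_post), ldl_pre)

    # ----- events: piecewise-exponential by inversion ---------------------
    sw = np.where(switch, switch_day, T).clip(0.0, T)
    event_t = {}
    hazard_day0 = {}
    for i, outcome in enumerate(OUTCOMES):
        h0 = cfg.baseline_hazards[outcome] / DAYS_PER_YEAR
        rr = cfg.rr_per_mmol[outcome]
        lam_pre = h0 * rr ** ((cfg.reference_ldl - ldl_pre) / MGDL_PER_MMOL)
        lam_post = h0 * rr ** ((cfg.reference_ldl - ldl_post) / MGDL_PER_MMOL)
        h_sw = lam_pre * sw
        e = event_exp[i]
        t = np.where(e < h_sw, e / lam_pre, sw + (e - h_sw) / lam_post)
        event_t[outcome] = t
        hazard_day0[outcome] = np.where(sw > 0, lam_pre, lam_post) * DAYS_PER_YEAR

    t_death = event_t["death"]
    death_day = np.where(t_death < T, np.floor(t_death) + 1, np.nan)
    followup_end = np.fmin(death_day, T)

    event_rows = []
    for outcome in OUTCOMES:
        t = event_t[outcome]
        if outcome == "death":
            keep = t < T
        else:
            keep = (t < np.fmin(t_death, T))
        day = (np.floor(t) + 1).astype(int)
        event_rows.append(
            pd.DataFrame(
                {
                    "patient_id": np.flatnonzero(keep),
                    "event": outcome,
                    "day": day[keep],
                }
            )
        )
    events = (
        pd.concat(event_rows, ignore_index=True)
        .sort_values(["patient_id", "day", "event"], kind="stable")
        .reset_index(drop=True)
    )

    # ----- labs ------------------------------------------------------------
    lab_pid, lab_day, lab_true = [], [], []
    pre_ok = has_pre_lab
    lab_pid.append(np.flatnonzero(pre_ok))
    lab_day.append(pre_lab_day[pre_ok])
    lab_true.append(ldl_pre[pre_ok])

    day_next = np.maximum(np.round(first_gap), 1.0)
    active = day_next <= followup_end
    while active.any():
        d = day_next[active].astype(int)
        idx = np.flatnonzero(active)
        true_val = np.where(
            switch[idx] & (d >= switch_day[idx]), ldl_post[idx], ldl_pre[idx]
        )
        lab_pid.append(idx)
        lab_day.append(d)
        lab_true.append(true_val)
        gap = np.maximum(
            rng_lab.normal(cfg.lab_followup_interval, cfg.lab_followup_jitter, n), 30.0
        )
        day_next = day_next + np.round(gap)
        active = day_next <= followup_end

    lab_pid = np.concatenate(lab_pid)
    lab_day = np.concatenate(lab_day).astype(int)
    lab_true = np.concatenate(lab_true)
    noise = rng_lab.normal(0.0, cfg.lab_noise_sd, lab_pid.size) if cfg.lab_noise_sd else 0.0
    labs = pd.DataFrame(
        {
            "patient_id": lab_pid,
            "day": lab_day,
            "ldl": np.round(np.maximum(lab_true + noise, 1.0), 1),
        }
    ).sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    # ----- fills realizing the regimen phases ------------------------------
    fill_frames = []

    def add_chain(pid, release, agents, doses):
        if pid.size:
            fill_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "release_day": release.astype(int),
                        "agent": np.asarray(agents, dtype=object)[pid],
                        "dose": np.asarray(doses, dtype=float)[pid],
                        "days_supplied": S,
                    }
                )
            )

    start_base = (-365 - base_offset).astype(float)
    stop_base = np.where(switch, switch_day - 14.0, followup_end + 1.0)
    pid, rel = _chain(start_base, stop_base, S, on_statin)
    add_chain(pid, rel, agent0, dose0)

    start_post = switch_day - 14.0
    stop_post = followup_end + 1.0
    has_post_statin = switch & pd.notna(pd.Series(agent1, dtype=object)).to_numpy()
    pid, rel = _chain(start_post, stop_post, S, has_post_statin)
    add_chain(pid, rel, agent1, dose1)

    ez_agents = np.full(n, "ezetimibe", dtype=object)
    ez_doses = np.full(n, 10.0)
    start_ez = (-365 - ez_offset).astype(float)
    if policy == "observed":
        pid, rel = _chain(start_ez, followup_end + 1.0, S, ez0)
        add_chain(pid, rel, ez_agents, ez_doses)
    else:
        pid, rel = _chain(start_ez, np.full(n, -14.0), S, ez0)
        add_chain(pid, rel, ez_agents, ez_doses)
        pid, rel = _chain(np.full(n, -14.0), followup_end + 1.0, S, ez1)
        add_chain(pid, rel, ez_agents, ez_doses)

    if pcsk9.any():
        idx = np.flatnonzero(pcsk9)
        fill_frames.append(
            pd.DataFrame(
                {
                    "patient_id": idx,
                    "release_day": pcsk9_day[idx],
                    "agent": "evolocumab",
                    "dose": 140.0,
                    "days_supplied": 28,
                }
            )
        )

    fills = (
        pd.concat(fill_frames, ignore_index=True)
        .sort_values(["patient_id", "release_day", "agent"], kind="stable")
        .reset_index(drop=True)
    )

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "index_date": index_date.strftime("%Y-%m-%d"),
            "age": age,
            "sex": np.where(male, "M", "F"),
            "acs": acs.astype(int),
            "contraindication": contra,
            "egfr": egfr,
            "dialysis": dialysis.astype(int),
            "death_day": death_day,
        }
    )

    def _label(agents, doses, ez_flags):
        out = []
        for a, d, e in zip(agents, doses, ez_flags):
            if a is None or (isinstance(d, float) and np.isnan(d)):
                out.append(Regimen(ezetimibe=bool(e)).label())
            else:
                out.append(Regimen(a, float(d), bool(e)).label())
        return out

    truth = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "untreated_ldl": untreated,
            "r_pre": r_pre,
            "r_post": r_post,
            "switch_day": np.where(switch, switch_day, np.nan),
            "regimen_pre": _label(agent0, dose0, ez0),
            "regimen_post": _label(agent1, dose1, ez1),
            "ldl_day0": np.where(switch & (switch_day <= 0), ldl_post, ldl_pre),
            **{f"hazard_{o}_day0": hazard_day0[o] for o in OUTCOMES},
        }
    )

    return SyntheticCohort(cfg, policy, patients, fills, labs, events, truth)
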