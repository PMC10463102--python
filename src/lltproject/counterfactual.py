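"""Counterfactual LDL-C under optimized lipid-lowering therapy.

Each patient is assigned an eligibility tier from their contraindication
class: no contraindication -> atorvastatin 80 mg (full dose), relative
contraindication -> atorvastatin 20 mg (reduced dose), absolute
contraindication -> no statin.  Ezetimibe is considered an appropriate
addition in every tier.

A scenario trajectory re-expresses each observed LDL-C point under the
tier's optimized regimen (with or without ezetimibe).  Optimization never
raises LDL-C: if the patient's observed regimen is already at least as
effective as the optimized one, the observed value is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .regimens import NO_THERAPY, Regimen, RegimenEffectTable, transform_ldl
from .timeline import LdlPoint

__all__ = [
    "SCENARIOS",
    "EligibilityTier",
    "ScenarioTrajectory",
    "assign_tier",
    "tier_regimen",
    "project_scenario",
]

SCENARIOS = ("observed", "opt_statin", "opt_statin_ez")

TIER_FULL = "full_dose"
TIER_REDUCED = "reduced_dose"
TIER_NONE = "none"

_CONTRAINDICATION_TO_TIER = {
    "none": TIER_FULL,
    "relative": TIER_REDUCED,
    "absolute": TIER_NONE,
}

_TIER_STATIN = {
    TIER_FULL: Regimen("atorvastatin", 80.0),
    TIER_REDUCED: Regimen("atorvastatin", 20.0),
    TIER_NONE: NO_THERAPY,
}


@dataclass(frozen=True)
class EligibilityTier:
    tier: str  # full_dose | reduced_dose | none
    reason: str = ""

    def __post_init__(self) -> None:
        if self.tier not in _TIER_STATIN:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class ScenarioTrajectory:
    scenario: str
    points: tuple[LdlPoint, ...]


def assign_tier(contraindication_class: str) -> EligibilityTier:
    """Map a contraindication class to an optimized-statin eligibility tier.

    ``none`` -> full dose (atorvastatin 80), ``relative`` -> reduced dose
    (atorvastatin 20), ``absolute`` -> no statin.  Deterministic; unknown
    labels raise.
    """
    try:
        tier = _CONTRAINDICATION_TO_TIER[contraindication_class]
    except KeyError:
        raise ValueError(
            f"unknown contraindication class {contraindication_class!r}"
        ) from None
    return EligibilityTier(tier, reason=f"contraindication={contraindication_class}")


def tier_regimen(tier: EligibilityTier, ezetimibe: bool = False) -> Regimen:
    """Optimized regimen for a tier, optionally with ezetimibe added."""
    return _TIER_STATIN[tier.tier].with_ezetimibe(ezetimibe)


def project_scenario(
    observed: Sequence[LdlPoint],
    tier: EligibilityTier,
    effect_table: RegimenEffectTable,
    scenario: str,
) -> ScenarioTrajectory:
    """Project the observed trajectory under an optimized-therapy scenario.

    Each observed point is re-expressed from its concurrent regimen to the
    tier's optimized regimen (plus ezetimibe for ``opt_statin_ez``), then
    clipped at the observed value so switching a patient to the optimized
    regimen never raises their LDL-C (relevant when the observed regimen is
    stronger than the tier's, e.g. rosuvastatin 40 vs atorvastatin 80, or
    already includes ezetimibe).  The day grid and sources are preserved.
    """
    if scenario == "observed":
        return ScenarioTrajectory("observed", tuple(observed))
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    target = tier_regimen(tier, ezetimibe=(scenario == "opt_statin_ez"))
    points = []
    for p in observed:
        projected = min(transform_ldl(p.value, p.regimen, target, effect_table), p.value)
        points.append(LdlPoint(p.day, projected, p.source, target))
    return ScenarioTrajectory(scenario, tuple(points))
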