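"""Lipid-lowering regimens and their expected LDL-C effects.

A regimen is a statin (agent + daily dose) and/or ezetimibe.  The expected
fractional LDL-C reduction of a regimen relative to an untreated baseline is
looked up in a :class:`RegimenEffectTable`; ezetimibe contributes a further
multiplicative reduction on top of the on-statin level, so the total
fractional reduction is ``1 - (1 - r_statin) * (1 - r_ez)``.

The two anchoring constants are atorvastatin 80 mg -> 54% reduction from an
untreated baseline and ezetimibe -> a further 15% reduction from the
on-statin level.  All other agent/dose entries are configurable defaults in
line with published dose-response summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Regimen",
    "NO_THERAPY",
    "RegimenEffectTable",
    "transform_ldl",
    "MGDL_PER_MMOL",
    "INTENSITY_ORDER",
]

#: mg/dL of LDL-C per 1 mmol/L.
MGDL_PER_MMOL = 38.67

#: Statin intensity classes in increasing order of expected LDL-C reduction.
INTENSITY_ORDER = ("none", "low", "moderate", "high")


@dataclass(frozen=True, order=True)
class Regimen:
    """An active lipid-lowering regimen (possibly no therapy at all).

    Parameters
    ----------
    statin_agent:
        Lower-case agent name (e.g. ``"atorvastatin"``) or ``None``.
    statin_daily_dose:
        Daily dose in mg; present iff ``statin_agent`` is present.
    ezetimibe:
        Whether ezetimibe 10 mg is co-administered.
    """

    statin_agent: str | None = None
    statin_daily_dose: float | None = None
    ezetimibe: bool = False

    def __post_init__(self) -> None:
        if (self.statin_agent is None) != (self.statin_daily_dose is None):
            raise ValueError("statin dose must be present iff agent is present")
        if self.statin_daily_dose is not None and self.statin_daily_dose <= 0:
            raise ValueError("statin dose must be positive")

    @property
    def has_statin(self) -> bool:
        return self.statin_agent is not None

    def with_ezetimibe(self, ezetimibe: bool = True) -> "Regimen":
        return Regimen(self.statin_agent, self.statin_daily_dose, ezetimibe)

    def label(self) -> str:
        """Human-readable label, e.g. ``"atorvastatin 80"`` or ``"none"``."""
        parts = []
        if self.has_statin:
            parts.append(f"{self.statin_agent} {self.statin_daily_dose:g}")
        if self.ezetimibe:
            parts.append("ezetimibe")
        return " + ".join(parts) if parts else "none"


NO_THERAPY = Regimen()

# Default expected fractional LDL-C reductions from an untreated baseline,
# keyed by (agent, daily dose in mg).  Atorvastatin 80 -> 0.54 and the
# ezetimibe multiplier 0.15 are the anchoring constants; the rest follow the
# usual statin dose-response orderings and are meant to be overridden from
# config when better estimates are available.
DEFAULT_STATIN_REDUCTIONS: dict[tuple[str, float], float] = {
    ("atorvastatin", 80.0): 0.54,
    ("atorvastatin", 40.0): 0.49,
    ("atorvastatin", 20.0): 0.43,
    ("atorvastatin", 10.0): 0.37,
    ("rosuvastatin", 40.0): 0.55,
    ("rosuvastatin", 20.0): 0.52,
    ("rosuvastatin", 10.0): 0.46,
    ("rosuvastatin", 5.0): 0.41,
    ("simvastatin", 40.0): 0.41,
    ("simvastatin", 20.0): 0.35,
    ("simvastatin", 10.0): 0.30,
    ("pravastatin", 40.0): 0.34,
    ("pravastatin", 20.0): 0.24,
}

# Intensity classification of the standard agent/dose pairs.  Any pair not in
# this map is a "nonstandard" regimen (an exclusion criterion upstream).
DEFAULT_INTENSITY_MAP: dict[tuple[str, float], str] = {
    ("atorvastatin", 80.0): "high",
    ("atorvastatin", 40.0): "high",
    ("atorvastatin", 20.0): "moderate",
    ("atorvastatin", 10.0): "moderate",
    ("rosuvastatin", 40.0): "high",
    ("rosuvastatin", 20.0): "high",
    ("rosuvastatin", 10.0): "moderate",
    ("rosuvastatin", 5.0): "moderate",
    ("simvastatin", 40.0): "moderate",
    ("simvastatin", 20.0): "moderate",
    ("simvastatin", 10.0): "low",
    ("pravastatin", 40.0): "moderate",
    ("pravastatin", 20.0): "low",
}


class RegimenEffectTable:
    """Expected fractional LDL-C reduction per regimen.

    Statin reductions are fractions of the untreated baseline in [0, 0.9];
    ezetimibe applies multiplicatively on the on-statin level.  Reductions
    must be monotone nondecreasing across intensity classes
    none < low < moderate < high.
    """

    def __init__(
        self,
        statin_reductions: Mapping[tuple[str, float], float] | None = None,
        ezetimibe_reduction: float = 0.15,
        intensity_map: Mapping[tuple[str, float], str] | None = None,
    ) -> None:
        self.statin_reductions = dict(
            DEFAULT_STATIN_REDUCTIONS if statin_reductions is None else statin_reductions
        )
        self.ezetimibe_reduction = float(ezetimibe_reduction)
        self.intensity_map = dict(
            DEFAULT_INTENSITY_MAP if intensity_map is None else intensity_map
        )
        self._validate()

    def _validate(self) -> None:
        if not 0.0 <= self.ezetimibe_reduction < 0.9:
            raise ValueError("ezetimibe reduction must be in [0, 0.9)")
        for key, r in self.statin_reductions.items():
            if not 0.0 <= r <= 0.9:
                raise ValueError(f"reduction for {key} outside [0, 0.9]: {r}")
            if key not in self.intensity_map:
                raise ValueError(f"{key} has a reduction but no intensity class")
        # monotone across intensity classes: the weakest member of a class
        # must be at least as strong as the strongest member of the previous
        by_class: dict[str, list[float]] = {c: [] for c in INTENSITY_ORDER}
        by_class["none"] = [0.0]
        for key, cls in self.intensity_map.items():
            if cls not in INTENSITY_ORDER:
                raise ValueError(f"unknown intensity class {cls!r} for {key}")
            if key in self.statin_reductions:
                by_class[cls].append(self.statin_reductions[key])
        prev_max = 0.0
        for cls in INTENSITY_ORDER:
            if not by_class[cls]:
                continue
            if min(by_class[cls]) < prev_max - 1e-12:
                raise ValueError(
                    f"reductions not monotone across intensity classes at {cls!r}"
                )
            prev_max = max(by_class[cls])

    # -- lookups ---------------------------------------------------------

    def is_standard(self, agent: str, dose: float) -> bool:
        """Whether (agent, dose) is a recognized standard statin regimen."""
        return (agent, float(dose)) in self.intensity_map

    def statin_reduction(self, regimen: Regimen) -> float:
        """Fractional reduction from the statin component alone."""
        if not regimen.has_statin:
            return 0.0
        key = (regimen.statin_agent, float(regimen.statin_daily_dose))
        try:
            return self.statin_reductions[key]
        except KeyError:
            raise KeyError(f"regimen {regimen.label()!r} not in effect table") from None

    def reduction(self, regimen: Regimen) -> float:
        """Total fractional reduction from an untreated baseline."""
        r = self.statin_reduction(regimen)
        if regimen.ezetimibe:
            r = 1.0 - (1.0 - r) * (1.0 - self.ezetimibe_reduction)
        return r

    def intensity_class(self, regimen: Regimen) -> str:
        if not regimen.has_statin:
            return "none"
        key = (regimen.statin_agent, float(regimen.statin_daily_dose))
        try:
            return self.intensity_map[key]
        except KeyError:
            raise KeyError(f"regimen {regimen.label()!r} not in intensity map") from None

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ezetimibe_reduction": self.ezetimibe_reduction,
            "statins": [
                {
                    "agent": agent,
                    "dose": dose,
                    "reduction": self.statin_reductions[(agent, dose)],
                    "intensity": self.intensity_map[(agent, dose)],
                }
                for (agent, dose) in sorted(self.statin_reductions)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimenEffectTable":
        reductions = {}
        intensity = {}
        for row in d["statins"]:
            key = (row["agent"], float(row["dose"]))
            reductions[key] = float(row["reduction"])
            intensity[key] = row["intensity"]
        return cls(reductions, float(d.get("ezetimibe_reduction", 0.15)), intensity)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegimenEffectTable):
            return NotImplemented
        return (
            self.statin_reductions == other.statin_reductions
            and self.ezetimibe_reduction == other.ezetimibe_reduction
            and self.intensity_map == other.intensity_map
        )


def transform_ldl(
    value: float,
    from_regimen: Regimen,
    to_regimen: Regimen,
    effect_table: RegimenEffectTable,
) -> float:
    """Re-express an LDL-C value under a different regimen.

    Back-calculates the untreated level ``value / (1 - r_from)`` and applies
    the target regimen's reduction: ``untreated * (1 - r_to)``.  Exact
    algebraic round trip: transforming a->b->a recovers the input.

    Parameters
    ----------
    value:
        LDL-C in mg/dL measured (or imputed) on ``from_regimen``.
    """
    r_from = effect_table.reduction(from_regimen)
    r_to = effect_table.reduction(to_regimen)
    if r_from >= 1.0:
        raise ValueError("source regimen reduction must be < 1")
    return value * (1.0 - r_to) / (1.0 - r_from)
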