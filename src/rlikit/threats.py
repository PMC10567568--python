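"""IUCN threat-classification codes: parsing, grouping and species tallies.

The IUCN threat-classification scheme codes threats hierarchically
("2.1" crop farming under "2" agriculture & aquaculture). For comparison
across species the codes are rolled up into named groups; the two chytrid
fungi (Batrachochytrium dendrobatidis, Bd, and B. salamandrivorans, Bsal)
are split out of the generic invasive/problematic-species codes because of
their outsized role in amphibian declines, which requires the named agent
recorded under codes 8.1.2 and 8.4.2.

Tallies count each species at most once per group, include only ongoing
and future major threats to threatened species, and flag the species for
which a group's threats are exclusively in the future (the emerging-threat
hatching on stacked bar charts).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    AssessmentRecord,
    CategoryState,
    RedListCategory,
    THREATENED_CATEGORIES,
)

__all__ = [
    "ThreatTiming",
    "ThreatRecord",
    "ThreatGroup",
    "ThreatTally",
    "UnmappedThreatCodeError",
    "group_threat",
    "tally_threats",
]


class ThreatTiming(str, enum.Enum):
    PAST = "past"
    ONGOING = "ongoing"
    FUTURE = "future"


@dataclass(frozen=True)
class ThreatRecord:
    """One coded threat to one species.

    ``named_agent`` is the recorded invasive/problematic species name and
    is only meaningful for codes 8.1.2 and 8.4.2. ``major`` is an optional
    importance flag: when absent every ongoing/future threat is treated as
    major.
    """

    code: str
    timing: ThreatTiming = ThreatTiming.ONGOING
    named_agent: Optional[str] = None
    major: Optional[bool] = None


class ThreatGroup(str, enum.Enum):
    AGRICULTURE = "agriculture"
    TIMBER_PLANT_HARVESTING = "timber_plant_harvesting"
    INFRASTRUCTURE = "infrastructure"
    POLLUTION = "pollution"
    MINING_ENERGY = "mining_energy"
    WATER_MANAGEMENT = "water_management"
    HUMAN_DISTURBANCE = "human_disturbance"
    GEOLOGICAL = "geological"
    OVER_EXPLOITATION = "over_exploitation"
    CLIMATE_CHANGE = "climate_change"
    FIRE = "fire"
    BD = "Bd"
    BSAL = "Bsal"
    INVASIVE_SPECIES = "invasive_species"
    NATIVE_SPECIES = "native_species"


class UnmappedThreatCodeError(ValueError):
    """A threat code outside the scheme, or inside a level the grouping
    does not cover (e.g. 7.3)."""


def _agent_matches(agent: Optional[str], genus: str, species: str) -> bool:
    # Tolerates "B. dendrobatidis", full binomials and case differences.
    if not agent:
        return False
    a = agent.lower()
    return species.lower() in a and (genus[0].lower() + "." in a or genus.lower() in a)


# Top-level prefixes with a single group for the whole block.
_TOP_LEVEL = {
    "1": ThreatGroup.INFRASTRUCTURE,
    "2": ThreatGroup.AGRICULTURE,
    "3": ThreatGroup.MINING_ENERGY,
    "4": ThreatGroup.INFRASTRUCTURE,
    "6": ThreatGroup.HUMAN_DISTURBANCE,
    "9": ThreatGroup.POLLUTION,
    "10": ThreatGroup.GEOLOGICAL,
    "11": ThreatGroup.CLIMATE_CHANGE,
}

_LEVEL5 = {
    "5.1": ThreatGroup.OVER_EXPLOITATION,
    "5.2": ThreatGroup.TIMBER_PLANT_HARVESTING,
    "5.3": ThreatGroup.TIMBER_PLANT_HARVESTING,
    "5.4": ThreatGroup.OVER_EXPLOITATION,
}

_LEVEL7 = {
    "7.1": ThreatGroup.FIRE,
    "7.2": ThreatGroup.WATER_MANAGEMENT,
}


def group_threat(rec: ThreatRecord) -> ThreatGroup:
    """Map one threat record to its comparison group.

    The mapping is total over scheme blocks 1–11 except 7.3 (other
    ecosystem modifications), which the grouping does not cover and which
    raises :class:`UnmappedThreatCodeError`, as do codes outside 1–11.
    Codes 8.1.2 / 8.4.2 resolve to Bd or Bsal when the named agent matches
    one of the chytrid fungi, otherwise they fall through to the generic
    invasive-species group; 8.2 is problematic *native* species.
    """
    parts = rec.code.split(".")
    top = parts[0]
    if top in _TOP_LEVEL:
        return _TOP_LEVEL[top]
    if top == "5":
        if len(parts) == 1:
            raise UnmappedThreatCodeError(
                "code 5 must be subcoded (5.1-5.4 split across groups)"
            )
        key = f"5.{parts[1]}"
        if key in _LEVEL5:
            return _LEVEL5[key]
        raise UnmappedThreatCodeError(f"unmapped-code:{rec.code}")
    if top == "7":
        if len(parts) == 1:
            raise UnmappedThreatCodeError("code 7 must be subcoded (7.1 or 7.2)")
        key = f"7.{parts[1]}"
        if key in _LEVEL7:
            return _LEVEL7[key]
        raise UnmappedThreatCodeError(f"unmapped-code:{rec.code}")
    if top == "8":
        sub = ".".join(parts[:2]) if len(parts) >= 2 else None
        if rec.code in ("8.1.2", "8.4.2"):
            if _agent_matches(rec.named_agent, "Batrachochytrium", "dendrobatidis"):
                return ThreatGroup.BD
            if _agent_matches(rec.named_agent, "Batrachochytrium", "salamandrivorans"):
                return ThreatGroup.BSAL
            return ThreatGroup.INVASIVE_SPECIES
        if sub == "8.2":
            return ThreatGroup.NATIVE_SPECIES
        if sub in ("8.1", "8.3", "8.4", "8.5", "8.6"):
            return ThreatGroup.INVASIVE_SPECIES
        raise UnmappedThreatCodeError(f"unmapped-code:{rec.code}")
    raise UnmappedThreatCodeError(f"unmapped-code:{rec.code}")


@dataclass
class ThreatTally:
    """Per-group species counts, split ongoing-or-future vs future-only."""

    counts: dict = field(default_factory=dict)  # ThreatGroup -> dict
    n_threatened: int = 0

    def n_species(self, group: ThreatGroup) -> int:
        return self.counts.get(group, {}).get("n_species_ongoing_or_future", 0)

    def n_future_only(self, group: ThreatGroup) -> int:
        return self.counts.get(group, {}).get("n_species_future_only", 0)


def _is_threatened(state: CategoryState, include_ew: bool) -> bool:
    if state.category in THREATENED_CATEGORIES:
        return True
    return include_ew and state.category is RedListCategory.EW


def tally_threats(
    records: Iterable[AssessmentRecord],
    epoch: int,
    include_ew: bool = False,
) -> ThreatTally:
    """Tally threatened species per threat group at an epoch.

    Threatened means VU/EN/CR (CR(PE) included) at the epoch; EW species
    have no ongoing wild threats and are excluded by default
    (``include_ew`` restores them). Past-only threats never count; threats
    flagged non-major are skipped; within a group each species counts
    once, and it is flagged future-only when *all* of its threats in that
    group have future timing.
    """
    ongoing: dict[ThreatGroup, set[str]] = {}
    has_ongoing_timing: dict[ThreatGroup, set[str]] = {}
    n_threatened = 0
    for rec in records:
        state = rec.state_at(epoch)
        if not _is_threatened(state, include_ew):
            continue
        n_threatened += 1
        for threat in rec.threats:
            if threat.timing is ThreatTiming.PAST:
                continue
            if threat.major is False:
                continue
            group = group_threat(threat)
            ongoing.setdefault(group, set()).add(rec.species_id)
            if threat.timing is ThreatTiming.ONGOING:
                has_ongoing_timing.setdefault(group, set()).add(rec.species_id)
    tally = ThreatTally(n_threatened=n_threatened)
    for group, species in ongoing.items():
        future_only = species - has_ongoing_timing.get(group, set())
        tally.counts[group] = {
            "n_species_ongoing_or_future": len(species),
            "n_species_future_only": len(future_only),
        }
    return tally
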