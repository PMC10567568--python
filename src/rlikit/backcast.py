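"""Backcasted category timelines and genuine-change accounting.

Comparing extinction risk over time is only meaningful if category changes
caused by new information, taxonomic revision or re-application of the
criteria are removed.  Backcasting does this by assigning, with current
knowledge, the category a species would have held at earlier epochs:
absent positive evidence of a *genuine* change (a real improvement or
deterioration driven by changes in the threats), the current category is
copied backward unchanged.  Data Deficient species are Data Deficient at
every epoch.  The genuine changes themselves are an expert-curated input
ledger — one declaration per species and interval, carrying the state at
the interval start, the primary driver and (for improvements) whether
conservation action caused it.

Deriving :class:`ChangeRecord` objects from a backcasted timeline applies
one special rule: CR(PE) and EX share the maximum index weight, so a move
from CR(PE) to EX is *not* a deterioration — it is tracked separately via
the ``became_extinct`` flag — whereas CR to CR(PE) is one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    AssessmentRecord,
    CategoryState,
    DEFAULT_EPOCHS,
    RedListCategory,
    category_rank,
)

__all__ = [
    "PrimaryDriver",
    "DriverGroup",
    "GenuineChangeDeclaration",
    "ChangeRecord",
    "ChangeDirection",
    "ConflictingLedgerError",
    "ResurrectionError",
    "apply_backcast",
    "derive_changes",
    "group_primary_driver",
    "tabulate_changes",
]


class PrimaryDriver(str, enum.Enum):
    """Raw primary-driver vocabulary recorded in the change ledger."""

    AGRICULTURE = "agriculture"
    MINING_ENERGY = "mining/energy production"
    INFRASTRUCTURE = "infrastructure development"
    HUMAN_DISTURBANCE = "human disturbance"
    TIMBER_PLANT_HARVESTING = "timber and plant harvesting"
    ANTHROPOGENIC_FIRE = "anthropogenic fire"
    WATER_MANAGEMENT = "water management"
    NATIVE_SPECIES = "native species"
    INTRODUCED_SPECIES = "introduced species"
    POLLUTION = "pollution"
    GEOLOGICAL_EVENTS = "geological events"
    DISEASE = "disease"
    OVER_EXPLOITATION = "over-exploitation"
    CLIMATE_CHANGE = "climate change effects"
    UNDETERMINED = "undetermined"


class DriverGroup(str, enum.Enum):
    """Grouped primary drivers used in all tabulations."""

    HABITAT_LOSS_DEGRADATION = "habitat_loss_degradation"
    DISEASE = "disease"
    OVER_EXPLOITATION = "over_exploitation"
    CLIMATE_CHANGE = "climate_change"
    UNDETERMINED = "undetermined"
    NUMEROUS = "numerous"


class ChangeDirection(str, enum.Enum):
    DETERIORATION = "deterioration"
    IMPROVEMENT = "improvement"
    NONE = "none"


@dataclass(frozen=True)
class GenuineChangeDeclaration:
    """One declared genuine change for one species over one interval.

    Declarations carry the state at the interval *start* rather than a
    delta, which makes a ledger self-consistent and order-independent.
    """

    species_id: str
    interval: tuple[int, int]
    state_at_from: CategoryState
    primary_driver: PrimaryDriver = PrimaryDriver.UNDETERMINED
    n_codrivers: int = 1
    conservation_driven: bool = False


@dataclass(frozen=True)
class ChangeRecord:
    species_id: str
    interval: tuple[int, int]
    from_state: CategoryState
    to_state: CategoryState
    genuine: bool
    direction: ChangeDirection
    driver_group: Optional[DriverGroup] = None
    conservation_driven: bool = False
    became_extinct: bool = False


class ConflictingLedgerError(ValueError):
    """Two declarations disagree about one species-interval."""


class ResurrectionError(ValueError):
    """A timeline or declaration implies a species left EX."""


# All drivers that act by destroying or degrading habitat.
_HABITAT_DRIVERS = frozenset(
    {
        PrimaryDriver.AGRICULTURE,
        PrimaryDriver.MINING_ENERGY,
        PrimaryDriver.INFRASTRUCTURE,
        PrimaryDriver.HUMAN_DISTURBANCE,
        PrimaryDriver.TIMBER_PLANT_HARVESTING,
        PrimaryDriver.ANTHROPOGENIC_FIRE,
        PrimaryDriver.WATER_MANAGEMENT,
        PrimaryDriver.NATIVE_SPECIES,
        PrimaryDriver.POLLUTION,
        PrimaryDriver.GEOLOGICAL_EVENTS,
    }
)


def group_primary_driver(raw: PrimaryDriver, n_codrivers: int = 1) -> DriverGroup:
    """Roll a raw primary driver up into its tabulation group.

    Several equally contributing co-drivers beat any single attribution
    (``numerous``).  Invasive non-native species other than the chytrid
    fungi drove no status change in amphibians; a ledger declaring
    ``introduced species`` as sole driver is therefore unexpected — it is
    warned about and bucketed as undetermined rather than dropped.
    """
    if n_codrivers > 1:
        return DriverGroup.NUMEROUS
    if raw in _HABITAT_DRIVERS:
        return DriverGroup.HABITAT_LOSS_DEGRADATION
    if raw is PrimaryDriver.DISEASE:
        return DriverGroup.DISEASE
    if raw is PrimaryDriver.OVER_EXPLOITATION:
        return DriverGroup.OVER_EXPLOITATION
    if raw is PrimaryDriver.CLIMATE_CHANGE:
        return DriverGroup.CLIMATE_CHANGE
    if raw is PrimaryDriver.INTRODUCED_SPECIES:
        warnings.warn(
            "unexpected-driver: 'introduced species' as sole primary driver",
            stacklevel=2,
        )
        return DriverGroup.UNDETERMINED
    return DriverGroup.UNDETERMINED


def apply_backcast(
    current: AssessmentRecord,
    declarations: Iterable[GenuineChangeDeclaration],
    epochs: Sequence[int] = DEFAULT_EPOCHS,
) -> dict[int, CategoryState]:
    """Build the full category timeline for one species.

    Rules, applied walking backward from the final epoch:

    * Data Deficient species are DD at every epoch.
    * With no declaration covering an interval, the later epoch's state is
      copied backward unchanged (no evidence of genuine change).
    * A declaration covering an interval sets the state at the interval's
      start epoch.
    * EX is absorbing forward in time; a timeline leaving EX raises
      :class:`ResurrectionError`.
    """
    epochs = tuple(epochs)
    final_epoch = epochs[-1]
    current_state = current.state_at(final_epoch)

    if current_state.category is RedListCategory.DD:
        return {e: CategoryState(RedListCategory.DD) for e in epochs}

    by_interval: dict[tuple[int, int], GenuineChangeDeclaration] = {}
    valid_intervals = set(zip(epochs[:-1], epochs[1:]))
    for decl in declarations:
        if decl.species_id != current.species_id:
            continue
        if decl.interval not in valid_intervals:
            raise ValueError(
                f"declaration interval {decl.interval} is not a pair of "
                f"consecutive configured epochs {epochs}"
            )
        prior = by_interval.get(decl.interval)
        if prior is not None and prior.state_at_from != decl.state_at_from:
            raise ConflictingLedgerError(
                f"conflicting-ledger: {current.species_id} {decl.interval}"
            )
        by_interval[decl.interval] = decl

    timeline = {final_epoch: current_state}
    for earlier, later in reversed(list(zip(epochs[:-1], epochs[1:]))):
        decl = by_interval.get((earlier, later))
        timeline[earlier] = decl.state_at_from if decl else timeline[later]

    # EX absorbing forward: once EX, always EX at later epochs.
    seen_ex = False
    for e in epochs:
        if seen_ex and timeline[e].category is not RedListCategory.EX:
            raise ResurrectionError(
                f"resurrection: {current.species_id} leaves EX after epoch {e}"
            )
        if timeline[e].category is RedListCategory.EX:
            seen_ex = True
    return {e: timeline[e] for e in epochs}


def derive_changes(
    timeline: Mapping[int, CategoryState],
    declarations: Iterable[GenuineChangeDeclaration] = (),
    species_id: str = "",
    epochs: Sequence[int] = DEFAULT_EPOCHS,
    crpe_ex_as_none: bool = True,
) -> list[ChangeRecord]:
    """Emit one :class:`ChangeRecord` per interval where the rank changes.

    Direction follows the severity rank, except that CR(PE) to EX emits
    direction ``none`` (the index weights them identically) while still
    setting ``became_extinct``; the switch ``crpe_ex_as_none`` restores
    ordinary deterioration counting for that transition.  A change is
    genuine iff a declaration covers its interval.
    """
    epochs = tuple(epochs)
    decl_by_interval = {}
    for d in declarations:
        if not species_id or d.species_id == species_id:
            decl_by_interval[d.interval] = d
    out: list[ChangeRecord] = []
    for earlier, later in zip(epochs[:-1], epochs[1:]):
        frm, to = timeline[earlier], timeline[later]
        if frm.category is RedListCategory.DD or to.category is RedListCategory.DD:
            continue
        r0, r1 = category_rank(frm), category_rank(to)
        if r0 == r1:
            continue
        became_extinct = (
            to.category is RedListCategory.EX and frm.category is not RedListCategory.EX
        )
        crpe_to_ex = frm.possibly_extinct and to.category is RedListCategory.EX
        if crpe_to_ex and crpe_ex_as_none:
            direction = ChangeDirection.NONE
        elif r1 > r0:
            direction = ChangeDirection.DETERIORATION
        else:
            direction = ChangeDirection.IMPROVEMENT
        decl = decl_by_interval.get((earlier, later))
        out.append(
            ChangeRecord(
                species_id=species_id,
                interval=(earlier, later),
                from_state=frm,
                to_state=to,
                genuine=decl is not None,
                direction=direction,
                driver_group=(
                    group_primary_driver(decl.primary_driver, decl.n_codrivers)
                    if decl
                    else None
                ),
                conservation_driven=bool(decl and decl.conservation_driven),
                became_extinct=became_extinct,
            )
        )
    return out


def changes_for_records(
    records: Iterable[AssessmentRecord],
    declarations: Iterable[GenuineChangeDeclaration],
    epochs: Sequence[int] = DEFAULT_EPOCHS,
    crpe_ex_as_none: bool = True,
) -> list[ChangeRecord]:
    """Backcast every record and derive all change records in one pass."""
    decls = list(declarations)
    by_species: dict[str, list[GenuineChangeDeclaration]] = {}
    for d in decls:
        by_species.setdefault(d.species_id, []).append(d)
    out: list[ChangeRecord] = []
    for rec in records:
        mine = by_species.get(rec.species_id, [])
        timeline = apply_backcast(rec, mine, epochs)
        out.extend(
            derive_changes(
                timeline,
                mine,
                species_id=rec.species_id,
                epochs=epochs,
                crpe_ex_as_none=crpe_ex_as_none,
            )
        )
    return out


def tabulate_changes(changes: Iterable[ChangeRecord]) -> pd.DataFrame:
    """Count genuine changes by (interval, direction, driver group, to-category).

    Returns a tidy frame with one row per occupied cell and a ``count``
    column; CR and CR(PE) are distinct on the to-category axis.  Marginals
    by interval and direction recover total deteriorations/improvements.
    """
    rows = []
    for c in changes:
        if not c.genuine:
            continue
        rows.append(
            {
                "interval": f"{c.interval[0]}-{c.interval[1]}",
                "direction": c.direction.value,
                "driver_group": c.driver_group.value if c.driver_group else "",
                "to_category": (
                    "CR(PE)" if c.to_state.possibly_extinct else c.to_state.category.value
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["interval", "direction", "driver_group", "to_category", "count"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["interval", "direction", "driver_group", "to_category"])
        .size()
        .rename("count")
        .reset_index()
    )
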