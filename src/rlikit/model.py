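"""Core domain types for IUCN Red List assessment data.

Categories, Possibly Extinct tagging, severity ranks, Red List Index
weights, breeding-strategy classification and record validation. These
types are the vocabulary every other module speaks: an
:class:`AssessmentRecord` holds one species' category per epoch together
with its realms, taxonomic order, breeding-biology codes and threat
records.

Two distinct orderings live here and must not be conflated:

* :func:`category_rank` is the severity ladder used to decide whether a
  category change is a deterioration or an improvement.  On this ladder
  CR(PE) sits strictly above CR and below EW and EX.
* :func:`rli_weight` is the weight used by the Red List Index, where
  CR(PE), EW and EX all share the maximum weight of 5, so a move from
  CR(PE) to EX changes nothing in the index.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "RedListCategory",
    "CategoryState",
    "TriState",
    "BreedingCodes",
    "BreedingStrategy",
    "TaxonomicOrder",
    "Realm",
    "AssessmentRecord",
    "DEFAULT_EPOCHS",
    "MAX_RLI_WEIGHT",
    "UnrankableCategoryError",
    "ExcludedFromRLIError",
    "category_rank",
    "rli_weight",
    "classify_breeding_strategy",
    "validate_record",
    "parse_category",
    "format_category",
]

#: Assessment epochs (years) used throughout unless a caller overrides them.
DEFAULT_EPOCHS: tuple[int, ...] = (1980, 2004, 2022)

#: Weight shared by EX, EW and CR(PE) in the Red List Index.
MAX_RLI_WEIGHT = 5


class RedListCategory(str, enum.Enum):
    """IUCN Red List category codes.

    NE (Not Evaluated) exists only so that input rows carrying it can be
    rejected with a precise message; no analytical operation accepts it.
    """

    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    EW = "EW"
    EX = "EX"
    DD = "DD"
    NE = "NE"


#: Categories counted as "threatened" (the headline percentage additionally
#: counts EW in its numerator; see summary_stats).
THREATENED_CATEGORIES = frozenset(
    {RedListCategory.VU, RedListCategory.EN, RedListCategory.CR}
)


@dataclass(frozen=True)
class CategoryState:
    """A Red List category plus the Possibly Extinct tag.

    The PE tag is only meaningful on CR: a Critically Endangered species
    that is very likely already extinct but does not yet meet the strict
    evidence bar for EX.
    """

    category: RedListCategory
    possibly_extinct: bool = False

    def __post_init__(self) -> None:
        if self.possibly_extinct and self.category is not RedListCategory.CR:
            raise ValueError(
                f"possibly_extinct is only valid on CR, got {self.category.value}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_category(self)


class UnrankableCategoryError(ValueError):
    """Raised when a DD or NE state is passed to an ordering operation."""


class ExcludedFromRLIError(ValueError):
    """Raised when a DD or NE state is passed to an RLI weighting."""


_RANK = {
    (RedListCategory.LC, False): 0,
    (RedListCategory.NT, False): 1,
    (RedListCategory.VU, False): 2,
    (RedListCategory.EN, False): 3,
    (RedListCategory.CR, False): 4,
    (RedListCategory.CR, True): 5,
    (RedListCategory.EW, False): 6,
    (RedListCategory.EX, False): 7,
}


def category_rank(state: CategoryState) -> int:
    """Severity rank for change-direction decisions.

    Total order LC=0 < NT=1 < VU=2 < EN=3 < CR=4 < CR(PE)=5 < EW=6 < EX=7.
    CR(PE) outranks plain CR because a move from CR to CR(PE) is a genuine
    deterioration.  This rank is **not** the RLI weight: above CR the RLI
    weight is capped at 5 while the rank keeps increasing.
    """
    key = (state.category, state.possibly_extinct)
    try:
        return _RANK[key]
    except KeyError:
        raise UnrankableCategoryError(
            f"category {state.category.value} has no severity rank"
        ) from None


def rli_weight(state: CategoryState, ew_weight: int = MAX_RLI_WEIGHT) -> int:
    """Red List Index weight of a category state.

    Equal-step weights LC=0, NT=1, VU=2, EN=3, CR=4 and the shared maximum
    of 5 for CR(PE) and EX.  EW is also weighted 5 by default; the
    published index method never states EW's weight for this dataset, so
    it is exposed as ``ew_weight``.

    DD and NE states raise :class:`ExcludedFromRLIError`; callers filter
    them out (and report the exclusion count) before weighting.
    """
    cat = state.category
    if cat in (RedListCategory.DD, RedListCategory.NE):
        raise ExcludedFromRLIError(f"{cat.value} states carry no RLI weight")
    if cat is RedListCategory.EX:
        return MAX_RLI_WEIGHT
    if cat is RedListCategory.EW:
        return ew_weight
    if cat is RedListCategory.CR:
        return MAX_RLI_WEIGHT if state.possibly_extinct else 4
    return {
        RedListCategory.LC: 0,
        RedListCategory.NT: 1,
        RedListCategory.VU: 2,
        RedListCategory.EN: 3,
    }[cat]


class TriState(str, enum.Enum):
    """Yes / no / unknown coding used for breeding-biology questions."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class BreedingCodes:
    """Per-species answers to the five breeding-biology questions."""

    lays_eggs: TriState = TriState.UNKNOWN
    live_young: TriState = TriState.UNKNOWN
    parthenogenesis: TriState = TriState.UNKNOWN
    free_living_larva: TriState = TriState.UNKNOWN
    water_breeding: TriState = TriState.UNKNOWN


class BreedingStrategy(str, enum.Enum):
    LARVAL = "larval"
    DIRECT = "direct"
    LIVE_BIRTH = "live_birth"
    UNKNOWN = "unknown"


def classify_breeding_strategy(codes: BreedingCodes) -> BreedingStrategy:
    """Four-way breeding-strategy classification.

    Viviparity wins outright: a species giving birth to live young is a
    live-bearer regardless of whether a free-living larval stage is also
    coded.  Otherwise egg-layers split on the larval question — a
    free-living larva makes a larval developer, its absence a direct
    developer (eggs hatch into miniature adults).  Any answer needed for
    the decision being unknown yields ``UNKNOWN``; parthenogenesis and
    water-breeding never enter the decision.
    """
    if codes.live_young is TriState.YES:
        return BreedingStrategy.LIVE_BIRTH
    if codes.live_young is TriState.UNKNOWN:
        return BreedingStrategy.UNKNOWN
    # live_young == no: the egg/larva questions decide
    if codes.lays_eggs is TriState.YES:
        if codes.free_living_larva is TriState.YES:
            return BreedingStrategy.LARVAL
        if codes.free_living_larva is TriState.NO:
            return BreedingStrategy.DIRECT
        return BreedingStrategy.UNKNOWN
    return BreedingStrategy.UNKNOWN


class TaxonomicOrder(str, enum.Enum):
    ANURA = "Anura"
    CAUDATA = "Caudata"
    GYMNOPHIONA = "Gymnophiona"


class Realm(str, enum.Enum):
    """Biogeographical realms used for RLI disaggregation."""

    NEOTROPICAL = "Neotropical"
    NEARCTIC = "Nearctic"
    PALAEARCTIC = "Palaearctic"
    AFROTROPICAL = "Afrotropical"
    INDOMALAYAN = "Indomalayan"
    AUSTRALASIAN = "Australasian"
    OCEANIAN = "Oceanian"
    ANTARCTIC = "Antarctic"


_THREAT_CODE_RE = re.compile(r"^\d{1,2}(\.\d{1,2}){0,2}$")


@dataclass(frozen=True)
class AssessmentRecord:
    """One species' full assessment across the configured epochs."""

    species_id: str
    binomial: str
    order: TaxonomicOrder
    realms: frozenset[Realm]
    states: Mapping[int, CategoryState]
    breeding: BreedingCodes = field(default_factory=BreedingCodes)
    threats: tuple = ()  # tuple[ThreatRecord, ...]; kept loose to avoid a cycle
    unmapped: bool = False

    def state_at(self, epoch: int) -> CategoryState:
        return self.states[epoch]

    def with_states(self, states: Mapping[int, CategoryState]) -> "AssessmentRecord":
        return replace(self, states=dict(states))


def validate_record(
    record: AssessmentRecord, epochs: Sequence[int] = DEFAULT_EPOCHS
) -> list[str]:
    """Return a list of issue descriptors; an empty list means well-formed.

    Checks: every configured epoch present, PE tags only on CR, non-empty
    realm set unless the record is flagged unmapped, well-formed threat
    codes, and no NE states (NE species are not assessed and must not
    reach the analytical pipeline). Never raises and never mutates.
    """
    issues: list[str] = []
    for epoch in epochs:
        if epoch not in record.states:
            issues.append(f"missing-epoch:{epoch}")
    for epoch, state in record.states.items():
        # CategoryState enforces PE-on-CR at construction, but records built
        # from raw mappings may bypass it; re-check defensively.
        pe = getattr(state, "possibly_extinct", False)
        if pe and state.category is not RedListCategory.CR:
            issues.append(f"PE-on-non-CR:{epoch}")
        if state.category is RedListCategory.NE:
            issues.append(f"not-evaluated:{epoch}")
    if not record.realms and not record.unmapped:
        issues.append("empty-realms-not-unmapped")
    for threat in record.threats:
        code = getattr(threat, "code", None)
        if code is not None and not _THREAT_CODE_RE.match(str(code)):
            issues.append(f"malformed-threat-code:{code}")
    return issues


_CATEGORY_TOKEN_RE = re.compile(r"^(?P<cat>[A-Z]{2})(\((?P<tag>PE)\))?$")


def parse_category(token: str) -> CategoryState:
    """Parse a category token such as ``EN`` or ``CR(PE)`` (case-insensitive).

    Only the exact ``CR(PE)`` spelling carries the Possibly Extinct tag;
    a PE tag on any other category is rejected.
    """
    m = _CATEGORY_TOKEN_RE.match(token.strip().upper())
    if not m:
        raise ValueError(f"unrecognised category token {token!r}")
    cat_text, tag = m.group("cat"), m.group("tag")
    try:
        cat = RedListCategory(cat_text)
    except ValueError:
        raise ValueError(f"unrecognised category token {token!r}") from None
    if tag and cat is not RedListCategory.CR:
        raise ValueError(f"PE tag is only valid on CR, got {token!r}")
    return CategoryState(cat, possibly_extinct=bool(tag))


def format_category(state: CategoryState) -> str:
    return "CR(PE)" if state.possibly_extinct else state.category.value


def breeding_strategy_counts(
    records: Iterable[AssessmentRecord],
) -> dict[BreedingStrategy, int]:
    """Count species per breeding strategy (each species in exactly one)."""
    out = {s: 0 for s in BreedingStrategy}
    for rec in records:
        out[classify_breeding_strategy(rec.breeding)] += 1
    return out
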