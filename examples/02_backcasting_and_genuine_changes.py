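"""Backcast one species' category timeline and derive its genuine changes.

A species assessed CR(PE) today, with a declared genuine deterioration
from LC in 1980-2004 driven by disease: the declaration pins the 1980
state, the 2004 state copies the current one backward, and the derived
change record is a genuine disease-driven deterioration.
"""

from rlikit import (
    CategoryState,
    GenuineChangeDeclaration,
    PrimaryDriver,
    RedListCategory,
    apply_backcast,
    derive_changes,
)
from rlikit.model import AssessmentRecord, Realm, TaxonomicOrder, format_category

species = AssessmentRecord(
    species_id="frog001",
    binomial="Atelopus exemplaris",
    order=TaxonomicOrder.ANURA,
    realms=frozenset({Realm.NEOTROPICAL}),
    states={2022: CategoryState(RedListCategory.CR, possibly_extinct=True)},
)
ledger = [
    GenuineChangeDeclaration(
        species_id="frog001",
        interval=(1980, 2004),
        state_at_from=CategoryState(RedListCategory.LC),
        primary_driver=PrimaryDriver.DISEASE,
    )
]

timeline = apply_backcast(species, ledger)
print("backcast timeline:", {e: format_category(s) for e, s in timeline.items()})

for change in derive_changes(timeline, ledger, species_id="frog001"):
    print(
        f"{change.interval}: {format_category(change.from_state)} -> "
        f"{format_category(change.to_state)}  direction={change.direction.value}  "
        f"driver={change.driver_group.value if change.driver_group else '-'}  "
        f"genuine={change.genuine}"
    )
print("\nOnly declared (genuine) changes move the index; with no declaration")
print("the current category would have been copied back to 1980 unchanged.")
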