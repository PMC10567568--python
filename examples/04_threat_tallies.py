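"""Tally coded threats to threatened species, splitting future-only cases.

Three threatened species carry classification-scheme codes: agriculture
(2.x) and pollution (9.x) ongoing, chytrid fungus via a named agent under
8.1.2, and a climate threat that is only projected (timing=future).
"""

from rlikit import (
    CategoryState,
    RedListCategory,
    ThreatRecord,
    ThreatTiming,
    tally_threats,
)
from rlikit.model import AssessmentRecord, Realm, TaxonomicOrder


def species(sid, threats):
    return AssessmentRecord(
        species_id=sid,
        binomial=f"Exemplum {sid}",
        order=TaxonomicOrder.ANURA,
        realms=frozenset({Realm.NEOTROPICAL}),
        states={e: CategoryState(RedListCategory.EN) for e in (1980, 2004, 2022)},
        threats=tuple(threats),
    )


records = [
    species("s1", [ThreatRecord("2.1"), ThreatRecord("9.1")]),
    species("s2", [
        ThreatRecord("8.1.2", named_agent="Batrachochytrium dendrobatidis"),
        ThreatRecord("2.3"),
    ]),
    species("s3", [ThreatRecord("11.1", timing=ThreatTiming.FUTURE)]),
]

tally = tally_threats(records, epoch=2022)
print(f"threatened species considered: {tally.n_threatened}")
for group, vals in sorted(tally.counts.items(), key=lambda kv: kv[0].value):
    print(
        f"{group.value:>12}: {vals['n_species_ongoing_or_future']} species "
        f"({vals['n_species_future_only']} future-only)"
    )
print("\nEach species counts once per group; the climate entry is future-only —")
print("the emerging-threat hatching on stacked threat charts.")
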