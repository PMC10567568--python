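import pytest

from rlikit.model import (
    AssessmentRecord,
    CategoryState,
    Realm,
    RedListCategory,
    TaxonomicOrder,
)

# All weightable states (no DD/NE), used by several suites.
LADDER = [
    CategoryState(RedListCategory.LC),
    CategoryState(RedListCategory.NT),
    CategoryState(RedListCategory.VU),
    CategoryState(RedListCategory.EN),
    CategoryState(RedListCategory.CR),
    CategoryState(RedListCategory.CR, possibly_extinct=True),
    CategoryState(RedListCategory.EW),
    CategoryState(RedListCategory.EX),
]


def make_record(
    species_id="sp00001",
    states=None,
    order=TaxonomicOrder.ANURA,
    realms=frozenset({Realm.NEOTROPICAL}),
    **kwargs,
):
    if states is None:
        states = {e: CategoryState(RedListCategory.LC) for e in (1980, 2004, 2022)}
    return AssessmentRecord(
        species_id=species_id,
        binomial=f"Testus {species_id}",
        order=order,
        realms=realms,
        states=states,
        **kwargs,
    )


@pytest.fixture
def lc_record():
    return make_record()
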