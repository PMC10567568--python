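"""Backcasting rules, change derivation, driver grouping and tabulation.

The backcast operation is checked against an independent rule-by-rule
oracle over exhaustively enumerated three-epoch scenarios.
"""

import itertools

import pytest

from rlikit.backcast import (
    ChangeDirection,
    ConflictingLedgerError,
    DriverGroup,
    GenuineChangeDeclaration,
    PrimaryDriver,
    ResurrectionError,
    apply_backcast,
    changes_for_records,
    derive_changes,
    group_primary_driver,
    tabulate_changes,
)
from rlikit.model import CategoryState, RedListCategory, category_rank

from conftest import LADDER, make_record

EPOCHS = (1980, 2004, 2022)
DD = CategoryState(RedListCategory.DD)


def decl(sid, interval, state, driver=PrimaryDriver.DISEASE, **kw):
    return GenuineChangeDeclaration(
        species_id=sid, interval=interval, state_at_from=state,
        primary_driver=driver, **kw,
    )


def oracle_backcast(current_state, decls_by_interval):
    """Independent restatement of the backcasting rules: DD maps to DD
    everywhere; otherwise walk epochs backward, copying the later state
    unless a declaration pins the interval's start."""
    if current_state.category is RedListCategory.DD:
        return {e: DD for e in EPOCHS}
    timeline = {EPOCHS[2]: current_state}
    timeline[EPOCHS[1]] = decls_by_interval.get(
        (EPOCHS[1], EPOCHS[2]), timeline[EPOCHS[2]]
    )
    timeline[EPOCHS[0]] = decls_by_interval.get(
        (EPOCHS[0], EPOCHS[1]), timeline[EPOCHS[1]]
    )
    return timeline


class TestApplyBackcast:
    def test_no_declarations_copies_current_backward(self):
        rec = make_record(states={2022: CategoryState(RedListCategory.EN)})
        timeline = apply_backcast(rec, [])
        assert all(timeline[e] == CategoryState(RedListCategory.EN) for e in EPOCHS)

    def test_dd_backcasts_to_dd_everywhere(self):
        rec = make_record(states={2022: DD})
        assert apply_backcast(rec, []) == {e: DD for e in EPOCHS}

    def test_declaration_sets_state_at_interval_start(self):
        crpe = CategoryState(RedListCategory.CR, possibly_extinct=True)
        rec = make_record(states={2022: crpe})
        d = decl("sp00001", (1980, 2004), CategoryState(RedListCategory.LC))
        timeline = apply_backcast(rec, [d])
        assert timeline == {1980: CategoryState(RedListCategory.LC), 2004: crpe, 2022: crpe}

    def test_exhaustive_against_rule_oracle(self):
        """Every (current state, per-interval declaration) combination of a
        3-epoch timeline matches the independent oracle."""
        options = [None] + LADDER[:6]  # declared state at interval start, or none
        currents = LADDER + [DD]
        checked = 0
        for current, s1, s2 in itertools.product(currents, options, options):
            decls, by_interval = [], {}
            if s1 is not None:
                decls.append(decl("sp00001", (1980, 2004), s1))
                by_interval[(1980, 2004)] = s1
            if s2 is not None:
                decls.append(decl("sp00001", (2004, 2022), s2))
                by_interval[(2004, 2022)] = s2
            rec = make_record(states={2022: current})
            expected = oracle_backcast(current, by_interval)
            leaves_ex = any(
                expected[a].category is RedListCategory.EX
                and expected[b].category is not RedListCategory.EX
                for a, b in [(1980, 2004), (2004, 2022)]
            )
            if leaves_ex:
                with pytest.raises(ResurrectionError):
                    apply_backcast(rec, decls)
            else:
                assert apply_backcast(rec, decls) == expected
                checked += 1
        assert checked > 200  # the enumeration actually ran

    def test_conflicting_declarations_rejected(self):
        rec = make_record(states={2022: CategoryState(RedListCategory.EN)})
        d1 = decl("sp00001", (1980, 2004), CategoryState(RedListCategory.LC))
        d2 = decl("sp00001", (1980, 2004), CategoryState(RedListCategory.NT))
        with pytest.raises(ConflictingLedgerError):
            apply_backcast(rec, [d1, d2])

    def test_departure_from_ex_rejected(self):
        rec = make_record(states={2022: CategoryState(RedListCategory.EN)})
        d = decl("sp00001", (1980, 2004), CategoryState(RedListCategory.EX))
        with pytest.raises(ResurrectionError):
            apply_backcast(rec, [d])


class TestDeriveChanges:
    def test_deterioration_with_declaration_is_genuine(self):
        timeline = {
            1980: CategoryState(RedListCategory.LC),
            2004: CategoryState(RedListCategory.EN),
            2022: CategoryState(RedListCategory.EN),
        }
        d = decl("s", (1980, 2004), CategoryState(RedListCategory.LC))
        (change,) = derive_changes(timeline, [d], species_id="s")
        assert change.direction is ChangeDirection.DETERIORATION
        assert change.genuine
        assert change.driver_group is DriverGroup.DISEASE

    def test_crpe_to_ex_is_direction_none_but_flagged_extinct(self):
        timeline = {
            1980: CategoryState(RedListCategory.CR, possibly_extinct=True),
            2004: CategoryState(RedListCategory.CR, possibly_extinct=True),
            2022: CategoryState(RedListCategory.EX),
        }
        (change,) = derive_changes(timeline)
        assert change.direction is ChangeDirection.NONE
        assert change.became_extinct

    def test_crpe_to_ex_tally_switch(self):
        timeline = {
            1980: CategoryState(RedListCategory.CR, possibly_extinct=True),
            2004: CategoryState(RedListCategory.EX),
            2022: CategoryState(RedListCategory.EX),
        }
        (change,) = derive_changes(timeline, crpe_ex_as_none=False)
        assert change.direction is ChangeDirection.DETERIORATION

    def test_cr_to_crpe_is_a_deterioration(self):
        timeline = {
            1980: CategoryState(RedListCategory.CR),
            2004: CategoryState(RedListCategory.CR),
            2022: CategoryState(RedListCategory.CR, possibly_extinct=True),
        }
        d = decl("s", (2004, 2022), CategoryState(RedListCategory.CR))
        (change,) = derive_changes(timeline, [d], species_id="s")
        assert change.direction is ChangeDirection.DETERIORATION

    def test_cr_to_ex_is_a_deterioration_and_flagged(self):
        # only the CR(PE) -> EX step is excluded from direction tallies
        timeline = {
            1980: CategoryState(RedListCategory.CR),
            2004: CategoryState(RedListCategory.EX),
            2022: CategoryState(RedListCategory.EX),
        }
        (change,) = derive_changes(timeline)
        assert change.direction is ChangeDirection.DETERIORATION
        assert change.became_extinct

    def test_rederiving_from_backcast_timeline_is_idempotent(self):
        rec = make_record(states={2022: CategoryState(RedListCategory.CR, possibly_extinct=True)})
        decls = [decl("sp00001", (1980, 2004), CategoryState(RedListCategory.LC))]
        timeline = apply_backcast(rec, decls)
        first = derive_changes(timeline, decls, species_id="sp00001")
        again = derive_changes(timeline, decls, species_id="sp00001")
        assert first == again
        # and the emitted timeline re-backcasts to itself
        rec2 = rec.with_states(timeline)
        assert apply_backcast(rec2, decls) == timeline


class TestDriverGrouping:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (PrimaryDriver.AGRICULTURE, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.ANTHROPOGENIC_FIRE, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.NATIVE_SPECIES, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.GEOLOGICAL_EVENTS, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.POLLUTION, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.WATER_MANAGEMENT, DriverGroup.HABITAT_LOSS_DEGRADATION),
            (PrimaryDriver.DISEASE, DriverGroup.DISEASE),
            (PrimaryDriver.OVER_EXPLOITATION, DriverGroup.OVER_EXPLOITATION),
            (PrimaryDriver.CLIMATE_CHANGE, DriverGroup.CLIMATE_CHANGE),
            (PrimaryDriver.UNDETERMINED, DriverGroup.UNDETERMINED),
        ],
    )
    def test_raw_to_group_mapping(self, raw, expected):
        assert group_primary_driver(raw) is expected

    def test_equal_codrivers_group_as_numerous(self):
        assert group_primary_driver(PrimaryDriver.DISEASE, n_codrivers=2) is DriverGroup.NUMEROUS

    def test_sole_introduced_species_warns(self):
        with pytest.warns(UserWarning, match="unexpected-driver"):
            group = group_primary_driver(PrimaryDriver.INTRODUCED_SPECIES)
        assert group is DriverGroup.UNDETERMINED

    def test_every_raw_driver_maps_to_exactly_one_group(self):
        for raw in PrimaryDriver:
            if raw is PrimaryDriver.INTRODUCED_SPECIES:
                continue
            assert group_primary_driver(raw) in DriverGroup


class TestTabulateChanges:
    def test_counts_partition_a_small_fixture(self):
        # 10 deteriorations in one interval: 6 disease, 4 habitat
        from rlikit.synth import scripted_scenario

        ds = scripted_scenario(
            n_species=20,
            deteriorations={
                (1980, 2004): {
                    DriverGroup.DISEASE: 6,
                    DriverGroup.HABITAT_LOSS_DEGRADATION: 4,
                }
            },
        )
        changes = changes_for_records(ds.records, ds.declarations)
        table = tabulate_changes(changes)
        assert table["count"].sum() == 10
        by_driver = table.groupby("driver_group")["count"].sum()
        assert by_driver["disease"] == 6
        assert by_driver["disease"] / table["count"].sum() == pytest.approx(0.6)

    def test_empty_change_list_yields_empty_table(self):
        table = tabulate_changes([])
        assert table.empty
        assert list(table.columns) == [
            "interval", "direction", "driver_group", "to_category", "count",
        ]

    def test_directions_partition_rank_changes(self):
        """deteriorations + improvements + none = all rank-change intervals."""
        from rlikit.synth import ScenarioConfig, generate

        data = generate(ScenarioConfig(n_species=400, seed=7))
        changes = changes_for_records(data.records, data.declarations)
        n_rank_changes = sum(
            1
            for rec in data.records
            for a, b in [(1980, 2004), (2004, 2022)]
            if rec.state_at(a).category is not RedListCategory.DD
            and category_rank(rec.state_at(a)) != category_rank(rec.state_at(b))
        )
        assert len(changes) == n_rank_changes
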