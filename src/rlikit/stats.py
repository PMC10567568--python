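"""Summary statistics: threatened fractions with uncertainty bounds,
extinction accounting, driver shares, improvement breakdowns.

The threatened percentage treats Data Deficient species as the source of
uncertainty.  With T = EW + CR + EN + VU (CR including its Possibly
Extinct subset — EW stays in the numerator because reintroduction to the
wild remains possible):

    lower = T / (total - EX)            all DD assumed not threatened
    best  = T / (total - EX - DD)       DD assumed threatened at the same
                                        rate as assessed species
    upper = (T + DD) / (total - EX)     all DD assumed threatened

Display rounding throughout is half-away-from-zero at the stated decimal
precision (Python's round() rounds half to even, which disagrees at e.g.
40.65).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .backcast import ChangeDirection, ChangeRecord, DriverGroup
from .model import (
    AssessmentRecord,
    DEFAULT_EPOCHS,
    RedListCategory,
)

__all__ = [
    "CategoryCounts",
    "ThreatFraction",
    "DegenerateCountsError",
    "round_half_away",
    "threatened_fraction",
    "extinction_accounting",
    "extinction_accounting_from_counts",
    "driver_shares",
    "improvement_breakdown",
    "dd_proportion",
    "count_categories",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Python's built-in round() is banker's rounding (half to even), which
    disagrees with printed summary tables at exact halves; Decimal with
    ROUND_HALF_UP matches them and dodges binary representation slips.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class CategoryCounts:
    """Species counts per category at one epoch (CR split from CR(PE))."""

    lc: int = 0
    nt: int = 0
    vu: int = 0
    en: int = 0
    cr: int = 0  # non-PE
    cr_pe: int = 0
    ew: int = 0
    ex: int = 0
    dd: int = 0

    @property
    def total(self) -> int:
        return (
            self.lc + self.nt + self.vu + self.en + self.cr + self.cr_pe
            + self.ew + self.ex + self.dd
        )

    @property
    def threatened(self) -> int:
        """Numerator of the threatened-percentage formulas: EW+CR+EN+VU."""
        return self.ew + self.cr + self.cr_pe + self.en + self.vu


@dataclass(frozen=True)
class ThreatFraction:
    lower: float
    best: float
    upper: float

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_away(100 * self.lower, ndigits),
            round_half_away(100 * self.best, ndigits),
            round_half_away(100 * self.upper, ndigits),
        )


class DegenerateCountsError(ValueError):
    """A threatened-fraction denominator is zero."""


def threatened_fraction(counts: CategoryCounts) -> ThreatFraction:
    """Lower/best/upper threatened proportions from one epoch's counts."""
    t = counts.threatened
    denom_known = counts.total - counts.ex
    denom_best = counts.total - counts.ex - counts.dd
    if denom_known <= 0 or denom_best <= 0:
        raise DegenerateCountsError("degenerate-counts: empty denominator")
    return ThreatFraction(
        lower=t / denom_known,
        best=t / denom_best,
        upper=(t + counts.dd) / denom_known,
    )


def dd_proportion(counts: CategoryCounts) -> float:
    """Data Deficient share of all assessed species."""
    if counts.total == 0:
        raise DegenerateCountsError("degenerate-counts: zero total")
    return counts.dd / counts.total


def count_categories(
    records: Iterable[AssessmentRecord], epoch: int
) -> CategoryCounts:
    """Tally records into a :class:`CategoryCounts` at one epoch."""
    c = {k: 0 for k in ("lc", "nt", "vu", "en", "cr", "cr_pe", "ew", "ex", "dd")}
    keymap = {
        RedListCategory.LC: "lc",
        RedListCategory.NT: "nt",
        RedListCategory.VU: "vu",
        RedListCategory.EN: "en",
        RedListCategory.EW: "ew",
        RedListCategory.EX: "ex",
        RedListCategory.DD: "dd",
    }
    for rec in records:
        s = rec.state_at(epoch)
        if s.category is RedListCategory.CR:
            c["cr_pe" if s.possibly_extinct else "cr"] += 1
        else:
            c[keymap[s.category]] += 1
    return CategoryCounts(**c)


def extinction_accounting(
    records: Iterable[AssessmentRecord], epochs: Sequence[int] = DEFAULT_EPOCHS
) -> dict:
    """Cumulative extinctions and the possible-extinction ceiling.

    EX status is absorbing in backcasted timelines, so the per-epoch EX
    count *is* the cumulative number of documented extinctions by that
    epoch.  The ceiling adds the final-epoch CR(PE) count: the number of
    extinctions if every Possibly Extinct species is indeed gone.
    """
    records = list(records)
    counts = {e: count_categories(records, e) for e in epochs}
    cumulative_ex = {e: counts[e].ex for e in epochs}
    cr_pe = {e: counts[e].cr_pe for e in epochs}
    last = epochs[-1]
    return {
        "cumulative_ex": cumulative_ex,
        "cr_pe": cr_pe,
        "possible_total": cumulative_ex[last] + cr_pe[last],
    }


def extinction_accounting_from_counts(
    counts_by_epoch: Mapping[int, CategoryCounts]
) -> dict:
    """Same accounting from pre-tabulated per-epoch counts."""
    epochs = sorted(counts_by_epoch)
    cumulative_ex = {e: counts_by_epoch[e].ex for e in epochs}
    cr_pe = {e: counts_by_epoch[e].cr_pe for e in epochs}
    last = epochs[-1]
    return {
        "cumulative_ex": cumulative_ex,
        "cr_pe": cr_pe,
        "possible_total": cumulative_ex[last] + cr_pe[last],
    }


def driver_shares(
    changes: Iterable[ChangeRecord],
    interval: tuple[int, int],
    direction: ChangeDirection = ChangeDirection.DETERIORATION,
) -> dict[DriverGroup, tuple[int, int]]:
    """Per driver group: (count, integer percent) of genuine changes of one
    direction in one interval. Counts sum to the interval-direction total;
    integer percents may sum to 100±1 through rounding."""
    tallies: dict[DriverGroup, int] = {}
    total = 0
    for c in changes:
        if not c.genuine or c.interval != interval or c.direction is not direction:
            continue
        group = c.driver_group or DriverGroup.UNDETERMINED
        tallies[group] = tallies.get(group, 0) + 1
        total += 1
    return {
        g: (n, int(round_half_away(100 * n / total))) for g, n in sorted(tallies.items(), key=lambda kv: kv[0].value)
    } if total else {}


def improvement_breakdown(changes: Iterable[ChangeRecord]) -> dict[str, int]:
    """Split genuine improvements into conservation-driven vs unaided."""
    conservation = 0
    unaided = 0
    for c in changes:
        if not c.genuine or c.direction is not ChangeDirection.IMPROVEMENT:
            continue
        if c.conservation_driven:
            conservation += 1
        else:
            unaided += 1
    return {"conservation_driven": conservation, "unaided": unaided}
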