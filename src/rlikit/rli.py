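"""The Red List Index (RLI): per-group series across epochs with slopes.

The RLI summarises the aggregate extinction risk of a species set at one
point in time:

    RLI = 1 - sum_s W(s) / (W_EX * N)

where W(s) is the equal-step category weight of species s (LC=0 ... CR=4,
with CR(PE), EW and EX all at the maximum W_EX=5) and N the number of
weighted species.  The index is 1 when every species is Least Concern and
0 when every species is Extinct.  Data Deficient species carry no weight
and are excluded, with the exclusion count reported.  Because timelines
are backcasted, only genuine status changes move the index; its slope
(per year, negative = deteriorating) measures the rate of change in
aggregate risk.

Disaggregation: realm series duplicate multi-realm species into every
realm of occurrence (the global series counts them once); order and
breeding-strategy series partition, with unknown-strategy species left
out of the breeding disaggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .model import (
    AssessmentRecord,
    BreedingStrategy,
    CategoryState,
    DEFAULT_EPOCHS,
    MAX_RLI_WEIGHT,
    RedListCategory,
    classify_breeding_strategy,
    rli_weight,
)

__all__ = ["RLISeries", "EmptyAfterExclusionError", "compute_rli", "rli_series", "rli_slope"]


class EmptyAfterExclusionError(ValueError):
    """Every state in the input was Data Deficient."""


@dataclass
class RLISeries:
    """RLI values for one group across the configured epochs."""

    group_label: str
    epochs: tuple[int, ...]
    values: tuple[float, ...]
    n_included: tuple[int, ...]
    n_dd_excluded: tuple[int, ...]
    slopes: tuple[float, ...] = field(default=())  # per interval, RLI units / year

    def value_at(self, epoch: int) -> float:
        return self.values[self.epochs.index(epoch)]


def compute_rli(
    states: Iterable[CategoryState], ew_weight: int = MAX_RLI_WEIGHT
) -> tuple[float, int, int]:
    """RLI of a snapshot of category states.

    Returns ``(value, n_included, n_dd_excluded)``.  DD states are
    silently excluded but counted; an input that is empty after exclusion
    raises :class:`EmptyAfterExclusionError`.
    """
    total = 0
    n = 0
    n_dd = 0
    for s in states:
        if s.category is RedListCategory.DD:
            n_dd += 1
            continue
        total += rli_weight(s, ew_weight=ew_weight)
        n += 1
    if n == 0:
        raise EmptyAfterExclusionError("empty-after-exclusion: no weightable states")
    return 1.0 - total / (MAX_RLI_WEIGHT * n), n, n_dd


def rli_slope(
    epochs: Sequence[int], values: Sequence[float]
) -> tuple[float, ...]:
    """Per-interval slope in RLI units per year (negative = deteriorating)."""
    return tuple(
        (values[i + 1] - values[i]) / (epochs[i + 1] - epochs[i])
        for i in range(len(epochs) - 1)
    )


Grouping = Literal["global", "realm", "order", "breeding_strategy"]


def _series_for(
    label: str,
    members: list[AssessmentRecord],
    epochs: tuple[int, ...],
    ew_weight: int,
) -> RLISeries:
    values, ns, dds = [], [], []
    for e in epochs:
        v, n, n_dd = compute_rli((r.state_at(e) for r in members), ew_weight=ew_weight)
        values.append(v)
        ns.append(n)
        dds.append(n_dd)
    # DD is epoch-constant under backcasting, so N should not vary.
    if len(set(ns)) > 1:
        warnings.warn(
            f"group {label!r}: included count varies across epochs "
            "(timelines are not DD-consistent)",
            stacklevel=3,
        )
    return RLISeries(
        group_label=label,
        epochs=epochs,
        values=tuple(values),
        n_included=tuple(ns),
        n_dd_excluded=tuple(dds),
        slopes=rli_slope(epochs, values),
    )


def rli_series(
    records: Iterable[AssessmentRecord],
    grouping: Grouping = "global",
    epochs: Sequence[int] = DEFAULT_EPOCHS,
    ew_weight: int = MAX_RLI_WEIGHT,
) -> list[RLISeries]:
    """Compute one :class:`RLISeries` per group under the chosen grouping.

    Groups that are empty after DD exclusion are omitted with a warning.
    """
    epochs = tuple(epochs)
    records = list(records)
    groups: dict[str, list[AssessmentRecord]] = {}
    if grouping == "global":
        groups["global"] = records
    elif grouping == "realm":
        for r in records:
            for realm in r.realms:
                groups.setdefault(realm.value, []).append(r)
    elif grouping == "order":
        for r in records:
            groups.setdefault(r.order.value, []).append(r)
    elif grouping == "breeding_strategy":
        for r in records:
            strategy = classify_breeding_strategy(r.breeding)
            if strategy is BreedingStrategy.UNKNOWN:
                continue
            groups.setdefault(strategy.value, []).append(r)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown grouping {grouping!r}")

    out: list[RLISeries] = []
    for label in sorted(groups):
        try:
            out.append(_series_for(label, groups[label], epochs, ew_weight))
        except EmptyAfterExclusionError:
            warnings.warn(f"group {label!r} empty after DD exclusion; omitted", stacklevel=2)
    return out
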