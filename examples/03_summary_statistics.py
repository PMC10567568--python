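"""Reproduce the headline global amphibian statistics.

Runs the published per-epoch category aggregates through the
threatened-fraction formulas, the extinction-history record set through
extinction accounting, and the scripted change scenario through the
backcast/derive pipeline and driver shares.
"""

from rlikit import (
    ChangeDirection,
    DriverGroup,
    changes_for_records,
    dd_proportion,
    driver_shares,
    extinction_accounting,
    extinction_history_records,
    improvement_breakdown,
    published_counts,
    published_marginals_scenario,
    round_half_away,
    threatened_fraction,
)

counts = published_counts()
for epoch in (1980, 2004, 2022):
    lower, best, upper = threatened_fraction(counts[epoch]).as_percent(1)
    print(f"{epoch}: threatened = {best}% (bounds {lower}-{upper}%)")
print(f"Data Deficient share: {round_half_away(100 * dd_proportion(counts[2022]), 1)}%")

acc = extinction_accounting(extinction_history_records())
print(f"cumulative extinctions: {acc['cumulative_ex']}")
print(f"possible extinctions if all CR(PE) are gone: {acc['possible_total']}")

ds = published_marginals_scenario()
changes = changes_for_records(ds.records, ds.declarations)
det = [c for c in changes if c.direction is ChangeDirection.DETERIORATION]
print(f"\ndeteriorations: {len(det)} "
      f"({sum(c.interval == (1980, 2004) for c in det)} in 1980-2004, "
      f"{sum(c.interval == (2004, 2022) for c in det)} in 2004-2022)")
print(f"improvements: {improvement_breakdown(changes)}")
for interval in [(1980, 2004), (2004, 2022)]:
    shares = driver_shares(changes, interval)
    top = max(shares.items(), key=lambda kv: kv[1][0])
    print(f"{interval}: leading driver {top[0].value} = {top[1][0]} species ({top[1][1]}%)")
print("\nThe lower/best/upper bounds bracket the unknown status of DD species;")
print("the leading deterioration driver shifts from disease to climate change.")
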