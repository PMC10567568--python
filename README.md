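# rlikit

Tools for analysing trends in species extinction risk from IUCN Red List
assessments: backcasted category timelines, genuine-change accounting, the
Red List Index (RLI), threatened-fraction uncertainty bounds,
threat-classification rollups, and equal-area richness/driver grids. The
defaults and packaged reference aggregates follow the second Global
Amphibian Assessment (GAA2), which reassessed 8,011 amphibian species for
the epochs 1980, 2004 and 2022, but every convention (epochs, weights,
tally switches) is configurable.

The intended users are conservation scientists and indicator analysts who
have (or simulate) tabular assessment data — a Red List category per
species per epoch, a curated ledger of *genuine* status changes with
primary drivers, coded threats, and optionally species-by-grid-cell
occurrence — and want reproducible trend statistics from them.

## The model

Comparing categories across assessments is biased by non-genuine changes
(new information, taxonomic revision, criteria re-application).
**Backcasting** removes them: with current knowledge, each species is
assigned the category it would have held at earlier epochs, copying the
current category backward unless an expert-curated ledger declares a
genuine change for an interval; Data Deficient (DD) species are DD at
every epoch. On backcasted timelines the **Red List Index** at epoch *t*
is

```
RLI(t) = 1 − Σ_s W(s,t) / (W_EX · N)
```

with equal-step weights W: LC = 0, NT = 1, VU = 2, EN = 3, CR = 4 and
W_EX = 5 shared by EX, EW and Possibly Extinct CR — so RLI = 1 when all
N weighted species are Least Concern and 0 when all are Extinct, and a
move from CR(PE) to EX is no deterioration while CR to CR(PE) is one. DD
species are excluded (N counts the rest). The **threatened percentage**
brackets DD uncertainty with three ratios (T = EW + CR + EN + VU):

```
lower = T/(total − EX)   best = T/(total − EX − DD)   upper = (T + DD)/(total − EX)
```

Genuine changes carry a **primary driver** (agriculture, disease, climate
change effects, ...) rolled up into habitat loss/degradation, disease,
over-exploitation, climate change, undetermined or numerous; coded
threats roll up by classification-scheme prefix (all codes under 2 →
agriculture, 8.1.2/8.4.2 with a named chytrid agent → Bd/Bsal, ...).
Ranges bin onto a Behrmann equal-area grid for richness quantile classes
and per-cell dominant-driver maps.

## Worked example

```python
from rlikit import (published_counts, threatened_fraction, published_marginals_scenario,
                    changes_for_records, driver_shares)

counts = published_counts()                       # packaged global aggregates
print(threatened_fraction(counts[2022]).as_percent(1))

ds = published_marginals_scenario()               # scripted 8,011-species scenario
changes = changes_for_records(ds.records, ds.declarations)
print(driver_shares(changes, (1980, 2004)))
```

prints `(36.0, 40.7, 47.4)` — 40.7% of species in threatened categories
in 2022, between a 36.0% floor (no DD species threatened) and a 47.4%
ceiling (all DD threatened) — and driver shares whose leading entry is
`disease: (281, 58)`: disease drove 281 of the 482 genuine deteriorations
(58%) in 1980–2004. Running `python examples/03_summary_statistics.py`
extends this to all epochs, extinction accounting (cumulative extinctions
23 → 33 → 37, up to 222 if every Possibly Extinct species is gone) and
the shift of the leading driver to climate change (119 species, 39%) in
2004–2022. The other `examples/` scripts each exercise one capability —
index series, backcasting, threat tallies, grids, the full pipeline — and
print a line on what the numbers mean. A thin CLI wraps the pipeline:
`rlikit simulate`, `rlikit all assessments.csv --ledger ledger.csv ...`.

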