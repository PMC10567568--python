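# Methods

## Category semantics

Two orderings coexist and are deliberately kept apart. The **severity
rank** (LC 0 < NT 1 < VU 2 < EN 3 < CR 4 < CR(PE) 5 < EW 6 < EX 7) decides
whether a category change is a deterioration or an improvement; the
Possibly Extinct tag outranks plain CR because tagging a CR species as
probably gone is itself a genuine deterioration. The **index weight**
(LC 0 … CR 4, then 5 shared by CR(PE), EW and EX) feeds the Red List
Index; capping at 5 makes the CR(PE)→EX step invisible to the index,
which is the published convention. The published method never states EW's
index weight for this dataset; we use 5 — consistent with EW sitting
above CR in the severity ordering and with the index's all-Extinct anchor
— and expose it as `ew_weight` for sensitivity analysis. Similarly, the
severity rank places EW between CR(PE) and EX; only the relative order
EX > EW > CR is externally fixed, and EW transitions are rare enough that
the choice is inconsequential (the generator never emits them by
default).

DD and NE carry neither rank nor weight: NE records are rejected at
validation, DD records flow through backcasting (DD at every epoch) and
are excluded — with reported counts — from the index and from the
best-estimate threatened denominator.

The index formula `RLI = 1 − ΣW/(W_EX·N)` is adopted as the unique linear
form in the per-category weights that satisfies both stated anchors
(1 at all-LC, 0 at all-EX) under equal-step weights; the brute-force
weight-sum oracle in the tests re-derives every value independently.

## Backcasting and genuine changes

Backcasting walks the epoch list backward from the current assessment:
each interval either copies the later state to the interval start (no
evidence of genuine change) or takes the state pinned by a ledger
declaration. Declarations carry the *state at interval start* rather than
a category delta, so a ledger is order-independent and two declarations
for one species-interval can be checked for consistency (conflicts
raise). EX is absorbing forward in time; any timeline leaving EX raises a
resurrection error. Re-deriving changes from an emitted timeline is
idempotent, which the tests assert by exhaustive enumeration of all
three-epoch scenarios against an independent restatement of the rules.

Change direction follows the severity rank with one exception: CR(PE)→EX
is emitted with direction `none` and a `became_extinct` flag, so it is
excluded from deterioration tallies but still visible to extinction
bookkeeping; deteriorations into EX from any other category count
normally. A switch (`crpe_ex_as_none=False`) restores ordinary counting
for users who want the transition in their tallies. Improvements carry a
`conservation_driven` flag (default false) so the conservation/unaided
split is reproducible.

Primary drivers group as: ten habitat-mediated drivers (agriculture,
mining/energy, infrastructure, human disturbance, timber and plant
harvesting, anthropogenic fire, water management, native species,
pollution, geological events) → habitat loss/degradation; disease
(chytridiomycosis), over-exploitation and climate change effects map to
themselves; several equally contributing co-drivers → numerous. A sole
"introduced species" driver is unexpected (no amphibian status change was
attributed to invasive non-natives other than via chytrids, which are
coded as disease): it warns and buckets under undetermined rather than
silently dropping the record.

## Summary arithmetic

Threatened fractions use T = EW + CR + EN + VU (CR including its PE
subset; EW stays in the numerator because reintroduction remains
possible) over denominators that drop EX always and DD only in the best
estimate. Display rounding is half-away-from-zero at the printed
precision, implemented with decimal arithmetic: Python's banker's
rounding disagrees at exact halves, and all reproduced percentages match
under the half-away rule. Because DD status is epoch-constant under
backcasting, the DD count in the 1980/2004 denominators equals the
current one, and the per-epoch EX count in a backcasted dataset *is* the
cumulative number of documented extinctions — extinction accounting reads
it directly and adds the final CR(PE) count for the
possible-extinction ceiling.

Driver shares report integer percents of the interval-direction total;
counts always sum exactly, the rounded percents to 100 ± 1.

## Threat tallies

"Threatened" for threat tallies means VU/EN/CR (PE included) at the
chosen epoch. EW is excluded by default — extinct-in-the-wild species
have no ongoing wild threats — with an `include_ew` switch. Past-only
threats never count; a threat carrying `major=False` is skipped, and
absent the flag every ongoing/future threat is treated as major (no
importance filter is defined beyond the flag itself). Within a group a
species counts once, and is flagged future-only when every one of its
threats in that group has future timing. The code rollup is total over
scheme blocks 1–11 except 7.3 (other ecosystem modifications), which the
grouping does not cover: it raises an unmapped-code error rather than
being silently absorbed into water management. Chytrid agent matching is
case-insensitive and tolerates genus abbreviation ("B. dendrobatidis").

## Grids

Cells are squares in a Behrmann (world cylindrical equal-area,
standard parallel 30°) projection with the authalic Earth radius; any
equal-area grid satisfies the stated cell areas (865 and 7,775 km²
presets), and Behrmann is the simplest closed form. Polygon ranges are
projected and every intersecting cell (boundary touches excluded) records
the species; invalid geometries are skipped, warned about and counted.
Richness classes use the i/k quantiles of the occupied-cell richness
distribution, a cell's class being 1 plus the number of cuts strictly
below its richness — ties share a class and boundary values take the
lower class; fewer distinct richness values than k merge classes with a
warning. Dominant-driver cells take the argmax of deteriorated-species
counts per driver group; exactly two joint winners set the tie flag
(intermediate map colour), three or more — or a winning
undetermined/numerous attribution — set the star flag.

## Synthetic data

The stochastic generator emulates the structure, not the content, of a
global assessment table: per-species categories, genuine changes,
realms, orders, breeding codes, threat codes and clustered grid ranges.
Defaults are sized to the published global aggregates — DD fraction
0.113; a 1980 category mix with ~38% of assessed species threatened;
interval hazards putting the two deterioration waves near the published
482:306 ratio with a disease-led first interval and climate/habitat-led
second; improvement rate 0.008 per interval with a 52.5% conservation
share; a Neotropics-heavy realm mix (48%) with 3.3% multi-realm
species; order weights 88.5/8.9/2.6% for frogs, salamanders and
caecilians; breeding-strategy mix 66.4/30.6/0.8/2.2% (larval, direct,
live-birth, unknown); and threat prevalences among threatened species
following the published bar chart (agriculture 0.77, timber 0.53,
infrastructure 0.40, climate 0.29, Bd 0.29). Deteriorations move one
severity step; species at CR(PE) or beyond are not eligible (keeping
generated ledgers free of direction-`none` records), improvements move
one step down from NT–CR(PE). Ranges are contiguous cell blocks spiralled
around centroids scattered (sd = `clustering` cells) around a handful of
hotspot centres on a 40×40-cell world.

What the generator does **not** emulate: real phylogeny and range
geometry, spatial autocorrelation of drivers, correlated threat
portfolios, assessment error, or taxonomic churn between epochs. Passing
tests therefore demonstrate the correctness of the accounting and index
machinery under controlled conditions, not fidelity to any real dataset.

The scripted mode trades realism for exactness: requested change counts
are realized one-for-one (deteriorations one step from a configurable
start category, improvements likewise), which is what closed-form index
checks and published-marginal reproductions need. The packaged reference
aggregates keep only the published numbers meaningful (totals, threatened
numerator, EX, CR(PE), DD per epoch; per-driver change marginals); the
internal VU/EN/CR split of the threatened block and the 60/60 interval
allocation of the 120 improvements were not published at that granularity
and are arbitrary placeholders no downstream formula reads. The
extinction-history record set realizes the published trajectory with the
four post-2004 extinctions drawn from CR (so the 2022 CR(PE) count is
162 + 23 newly tagged); drawing them from CR(PE) instead would yield the
same accounting.

## Problem sizes and numerics

Tests and the acceptance script run scenarios of 150–2,000 species (the
scripted marginal scenario is 8,011 to match the published totals), which
exercise every code path in seconds. Index values are exact rational
arithmetic in floating point (weights are small integers; the oracle
comparison tolerance of 1e-12 absorbs only division rounding).
Stochastic recovery checks use 3 seeds at n = 2,000 against 3 binomial
standard errors. All randomness flows through `numpy.random.default_rng`
seeded from a single integer; identical config + seed reproduces
byte-identical tables.

## Known limitations

- No confidence intervals on the index (point values only, matching the
  published presentation).
- The ledger is an input: genuineness is expert judgement upstream, never
  inferred from evidence here.
- No severity/scope weighting of threats; tallies are presence counts.
- Polygon rasterization is intersection-based (no minimum-overlap
  fraction) and GeoTIFF export is not provided; the per-cell CSV is the
  grid product.
- Red List criteria themselves (A–E thresholds) are out of scope:
  categories are inputs, not computed.
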