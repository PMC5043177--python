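# Methods

This note documents the models and statistics implemented in `codetect`,
the simulator that stands in for the unavailable field data, the
parameter choices that matter, and the limits of what passing tests
demonstrate.

## Data model

A **detection record** is one reception of a coded tag by a focal
transceiver: (focal id, UTC timestamp, tag code). The **tag registry**
maps each code to an animal (species, sex, fork length), its active
interval, an owner-permission flag and a status flag. All downstream
statistics are computed on two derived structures:

* **Hourly presence** — per (focal, individual) dyad, the sorted set of
  UTC hour bins containing at least one detection. The hour is the unit
  of association throughout; multiple pings within an hour collapse to
  one bin.
* **Monthly communities** — per (focal, UTC calendar month): the unique
  individuals encountered, each individual's *detection-days* (distinct
  calendar days with ≥ 1 detection that month), and per-species
  unique-individual counts divided by the number of active tags of that
  species.

Calendar months are UTC; the convention is documented rather than
configurable per call because every table in the pipeline must agree on
it. An individual detected either side of a month boundary counts in both
months.

## Cleaning rules

Three exclusion rules run in a fixed order — unknown tag code, owner
permission declined, tag suspected dead — and a ledger records
(detections, distinct codes) removed per rule. Ordering matters only for
attribution: a code caught by an earlier rule is not re-counted by a
later one. The rules are idempotent (re-cleaning clean data removes
nothing) and conservative (retained + removed = input, checked in
tests). Unknown-code rows are quarantined for audit, never analysed.

"Active during the study" means the tag's activation-expiry interval
*overlaps* the study span, endpoints inclusive; full containment is not
required. When the active-tag count is used as the coverage denominator,
focal transceiver rows are excluded — a transceiver cannot detect
itself. Coverage is reported as `100 · detected / active`, rounded to
one decimal.

## Association statistics

* **Cumulative hours**: the number of distinct hour bins for a dyad,
  unfiltered. (The alternative reading — summing only event durations —
  is not used; run filtering is a separate, later step.)
* **Consecutive-hour events**: maximal runs of hour bins differing by
  exactly one hour. Runs shorter than `min_event_hours` (default 2, the
  conventional threshold separating a sustained association from an
  isolated pass) are dropped from the event list but still count toward
  cumulative hours.
* **Top fractions**: "top 10% of individuals" ranks dyads by cumulative
  hours; "top 1% of events" ranks *events* by length. The selection
  takes ⌈fraction·N⌉ items and includes all ties at the cut value.
* **Co-encounters**: mutual focal-focal detections, deduplicated per
  (detector, hour) so a ping burst counts once per direction per hour.
  The monthly shared-individual proportion is |A∩B| / |A∪B| over the two
  focals' unique conspecific sets — the union denominator, so the value
  is symmetric in the two focals.

## Community statistics

* **Bray-Curtis similarity** `1 − Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ)` over the union of
  units with zero-fill; undefined (and signalled) when both vectors are
  empty. Emitted both as a full month × month matrix and as a
  consecutive-month series, at two levels: conspecific individuals
  (detection-day abundances) and species (unique-individual counts
  normalised by active tags). Normalising by unique individuals rather
  than raw detection totals is a deliberate choice: raw totals conflate
  abundance with residence time near the focal; a raw-total mode can be
  had by passing different vectors.
* **Shannon diversity** `H = −Σ pᵢ ln pᵢ` (natural log, the
  community-ecology default; base configurable) on detection-days, so H
  mixes individual richness with the evenness of how regularly each
  individual was re-encountered.
* **Rarefaction**: the individual-accumulation curve over random
  permutations of month order; mean ± 1.96·sd bands clipped to [0, total
  uniques]. For M ≤ 8 months the implementation enumerates all M!
  orderings exactly (the mode used in tests); the random mode uses
  `n_perm` draws (default 100).
* **Composition chi-square**: `X² = Σ(Oᵢ−Eᵢ)²/Eᵢ` against tagged-
  population proportions (sex ratio; 25-cm fork-length bins). The
  asymptotic χ²(k−1) p-value is replaced by a Monte Carlo p-value
  whenever any expected count is below 5 — the classical validity
  threshold — using the add-one estimator
  `(1 + #{X²ₛᵢₘ ≥ X²ₒᵦₛ})/(n_sim + 1)` over multinomial null draws
  (default n_sim = 2000), which can never return exactly zero.
* **Size bins**: fork lengths assign to the nearest multiple of 25 cm
  within 75–225, ties at ×.5 rounding up, everything rounding above 225
  pooled into an open "225+" bin and lengths rounding below 75 flagged
  out of range.

## Geolocation

Fix sources (moored receiver lines, satellite pop-ups) yield dated
positions per animal. Each detection event gets the highest-priority
qualifying fix: **primary** (focal's fix, same day), **secondary**
(focal's fix, 1–7 days away), **tertiary** (detected animal's fix, 0–7
days away); otherwise it stays unlocated but is retained, so the output
conserves the input event list. Within a tier the fix minimising the
absolute day offset wins, ties resolved toward the earlier date. "Within
seven days" is inclusive and two-sided. No interpolation between fixes
is attempted — events carry point fixes, not reconstructed tracks.

## The simulator

The generator emulates the study system so that every statistic above
can be checked against ground truth. It is a model of *what the data
look like*, not of shark physiology.

**Movement** is 1-D along-coast (km, negative = south) in hourly steps —
the study's spatial signal is a latitude corridor, and one dimension
suffices to drive encounters. Conspecifics belong to groups, re-drawn at
each behavioral-mode boundary (the simplest mechanism that produces
fission-fusion); each hour an animal moves `cohesion · (centroid − pos)`
plus a Gaussian step of sd `diffusion_km_per_hr`, while group centroids
drift at `drift_km_per_day`. Mode semantics:

* *bottleneck*: all centroids coincide — full fusion;
* *dispersal*: cohesion is forced to zero and positions diffuse —
  fission;
* *south migration*: each conspecific female is flagged offshore (out of
  detection reach) for the phase with probability
  `female_offshore_prob` — sexual segregation on the southward leg.

Heterospecifics hold station around home centres scattered uniformly
along the corridor, so only those near the focals' path are ever heard.

**Detection** is range-limited and memoryless: focal f hears tag g in
hour t iff |pos_f − pos_g| ≤ `range_km` (default 0.4, the reported
transceiver range scale), both tags are active and inshore, and a
Bernoulli draw at `p_detect_per_hour · (1 − collision_loss)^(k−1)`
succeeds, where k is the number of co-located non-focal tags. The
geometric thinning stands in for acoustic code collision, for which no
quantitative model exists; the default loss (0.002 per extra tag) is
small enough that a fully fused group of ~300 animals still yields
detections. Timestamps get a uniform minute-within-hour jitter so
parsing is exercised. There are no false positives by construction.

**Defaults.** The study-scale configuration places two focal
transceiver carriers (mature males, 194 and 198 cm fork length) in a
population matching the regional network's per-species active-tag
counts (325 conspecifics, ~2 000 heterospecific tags across seven
species) over the 24 Aug 2012 – 27 Jul 2013 span, with the five modes
laid out along the annual migration (south drift −10 km/day over
Oct–Nov, bottleneck Dec–Mar, dispersal Apr–May, north drift +11 km/day).
The movement constants (cohesion 0.02–0.1 h⁻¹, diffusion 0.5–1.5 km/h,
90% female offshore probability during south migration) are chosen for
qualitative fidelity and testability — the source study reports no
movement parameters — and are flagged as such: they produce the right
*ordering* of community statistics across modes, not calibrated
magnitudes.

**Randomness.** All stochasticity flows from one integer seed through
spawned child generators (population, tracks, detections, fixes); no
global state. Identical seeds give byte-identical fixtures.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis is meant to
detect: fusion at the bottleneck (high Shannon H, shared-node fraction
near 1, long dyadic associations), fission at dispersal (all three drop),
male-only communities during south migration, and recoverable group
labels per animal-hour. Passing the recovery tests shows the pipeline
detects these signals when present; it does not validate biological
realism. Known gaps versus real data: every tagged conspecific joins the
fused bottleneck group, so simulated coverage of the tagged population
approaches 100% (the real figures were 52.3% and 61.5% — much of a real
tagged pool never enters the corridor); hourly group churn keeps
simulated consecutive-hour events shorter than the longest field runs;
there is no depth, temperature, tag-battery decay, or 2-D space use.

## Validation experiments

* *Calibration*: under a true uniform null (multinomial n = 200, k = 5,
  expected count 40 per cell), the fraction of p ≤ 0.05 over 2 000
  replicates is computed for both the asymptotic and Monte Carlo
  (n_sim = 999) methods; both sit near the nominal 0.05.
* *Structure recovery*: 20 independent reduced-scale simulations (60
  conspecifics, the five modes compressed to one month each,
  `female_offshore_prob = 1` during south migration for the clean
  contrast), comparing bottleneck vs dispersal months per seed by
  Shannon H, conspecific shared-node fraction, and median dyadic
  cumulative hours, plus the Monte Carlo sex-ratio test for the
  south-migration month. The reduced scale keeps repeated-seed
  experiments fast while preserving every mode transition; per-seed
  orderings are evaluated with sign tests.

## Numerical and degenerate-input choices

Bray-Curtis and Shannon raise a typed error on all-zero input rather
than returning NaN silently; the similarity-matrix helper converts that
to NaN so one empty month cannot abort a year. Monte Carlo p-values
compare with a 1e-9 tolerance so exact ties (common with discrete
counts) count as "at least as extreme". Rarefaction clips its normal
bands to the feasible range. The event finder treats bins as integers
(hours since epoch), so daylight-saving artefacts cannot split runs —
all timestamps are UTC end to end. GraphML attributes cannot carry
`None`; missing values are written as empty strings.

## Known limitations

* The 1-D corridor makes re-encounters during dispersal more likely
  than 2-D reality would (recurrent random walks), so dispersal-month
  richness is biased high; the recovery tests therefore compare
  orderings, not levels.
* The exclusion ledger attributes each code to the first rule that
  catches it; a code that is both unknown and dead is counted once.
* Rarefaction confidence bands use a normal approximation, not
  permutation quantiles.
* The pipeline emits no figures; graphs are exported as GraphML and
  tables as CSV for downstream plotting.
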