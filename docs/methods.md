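# Methods

This note documents the models and procedures `momlink` implements, the
decisions taken where the design was genuinely open, and what the synthetic
evaluation does and does not establish about real data.

## The linkage rule set

The algorithm is deterministic and rule-based; it uses only structural
fields (sex, year/month/day of birth, enrollment plan ID, coverage dates,
pregnancy-episode dates and outcomes), never clinical content, so it is
transportable across any claims source mapped to the minimal schema.

**Observation periods.** Raw enrollment spans are unioned and consolidated:
two spans fall in one observation period when the number of *uncovered days
strictly between them* (`next_start − prev_end − 1`) is at most
`max_gap_days` (default 30). A plausible alternative reading — comparing the
raw date difference `next_start − prev_end` — is one configuration switch
away (`gap_rule="date_difference"`); the two differ only when the gap is
exactly at the threshold boundary. All intervals are closed, whole-day,
proleptic Gregorian.

**Candidate mothers.** Age is computed in calendar years
(`episode_start_year − year_of_birth`) because adult birth month/day are
generally absent in de-identified claims; bounds 12–55 inclusive. The
episode must end during coverage: the *end* (delivery) date is the anchor
because delivery is what the linkage keys on. Requiring the full episode
inside one period is available (`episode_anchor="full"`) but rejects women
who enrolled mid-pregnancy — a common and legitimate pattern.

**Candidate infants.** A person qualifies when their year of birth equals
their first observation period's start year (age 0 at database entry) and
their plan is shared with at least one candidate mother. The inferred DOB
takes recorded birth components verbatim when present and fills missing
components from the first observation period start, component-wise; an
impossible combination (e.g. day 31 in a 30-day month) is clamped to the
month end. Candidate-mother persons are excluded from infant candidacy (a
woman cannot be her own infant).

**Steps 2–4.** Candidate links require plan equality and inferred DOB inside
*any* of the mother's observation periods (the containment checks of Steps 1
and 2 are evaluated independently; requiring one and the same period is a
stricter variant deliberately not imposed, since coverage gaps between
delivery and infant enrollment are realistic). The correspondence window is
inclusive: |Δ| ≤ `window_days`. When one infant matches several episodes of
the *same* mother, the episode with the smallest |Δ| wins (ties: earlier
episode end, then lexicographic episode ID) — exclusion is reserved for
multi-*mother* ambiguity, where all links of the contested infant are
removed with no tie-breaking. Ambiguity is assessed after within-mother
resolution by default (fewer spurious ambiguities); the opposite order is
available (`ambiguity_check="before_resolution"`).

**First-births restriction.** Applied at Step 3: probable links are
restricted to each mother's earliest qualifying episode (earliest end date).
This is where the restriction's attrition shows up in the step accounting.

**Attrition accounting.** `probable_links` is counted *after* within-mother
episode resolution, so the identity
`final_links = probable_links − ambiguous_links_removed` is exact;
episode-resolution drops are reported separately as
`within_mother_removed`. One final link row per infant, so
`linked_infants = final_links` always.

## The nine cohorts

Cohorts 7/8/9 hold all candidate mother-episodes (indexed at episode
start/end) and candidate infants (at inferred DOB); 1/2/3 the linked
subsets; 4/5/6 the non-linked complements. Two open choices:

* **Characterization unit.** A mother with several linked episodes
  contributes one row per linked episode (indexes differ); covariates are
  episode-anchored, so rows — not persons — are the unit. Twins do not
  duplicate mother rows.
* **Subtraction level.** Non-linked cohorts subtract by *person*: a mother
  with one linked and one non-linked episode is excluded from cohorts 4/5
  entirely. Under this rule the disjoint-union identities
  (1 ⊎ 4 = 7, 2 ⊎ 5 = 8, 3 ⊎ 6 = 9) are exact at person level on every
  dataset, and exact at row level for infants (one row per infant). Row
  level equality for mothers additionally requires episode-level
  subtraction, available via `subtraction="episode"`.

## Covariates and balance

Windows are inclusive on both ends: mother cohorts look back
(`[index−365, index]`), infant cohorts forward (`[index, index+365]`).
The battery: per-code presence (binary), distinct codes per domain, visit
counts per visit type, age at index, prior/post observation days, pregnancy
episode length (mothers), a Charlson-style comorbidity score (sum of weights
over distinct categories present), and index year/month one-hots.

Two placement details:

* A mother indexed at episode *start* may have that date outside coverage
  (only the episode end is anchored by the algorithm). Such rows are placed
  in the period holding the qualifying anchor, with prior observation
  floored at 0. Rows with no usable period at all raise — that would mean a
  malformed cohort.
* Post-index observation time for *linked* infants runs from the linked
  mother's delivery date (the true birth date) to the end of observation;
  for non-linked infants, from the inferred DOB. Event windows stay anchored
  at the inferred DOB in both cases. The two code paths diverge by exactly
  Δ days and are tested to do so.

**SMD conventions.** Sample SD uses the n−1 denominator (cohorts of size 1
report SD 0 with a warning). Binary covariates use the Bernoulli variance
p(1−p). The default denominators — halved pooling for binary, root-sum of
variances for continuous — reproduce the output of the large
claims-characterization stacks used in observational research (verified by
recomputing several published table rows under both conventions); the
textbook halved pooling is available for continuous covariates via
`continuous_convention="pooled_half"`. Sign is (non-linked − linked). Equal
means with zero variance give SMD 0; unequal means with zero variance are
reported as ±∞ with an explicit flag and warning rather than NaN. Covariates
absent from one cohort are kept at prevalence 0, not dropped, so one-sided
covariates appear in the prevalence scatter.

The Charlson map is deliberately a *synthetic* fixture: 17 categories with
the classic weights, keyed to the generator's token condition codes.
Official code lists are vocabulary-version-dependent; real-vocabulary maps
are supplied by the user as a `concept_code,category,weight` CSV.

## The synthetic generator

The generator emulates the structures that drive linkage behavior in
family-plan commercial claims, not clinical semantics (codes are synthetic
tokens; no pregnancy-marker hierarchy is simulated — pregnancy episodes are
consumed as given, matching the package's scope).

Per family: one plan ID; one woman (two with probability
`p_multi_mother_household = 0.05`, creating genuine Step-4 ambiguity
opportunities); 1–3 pregnancy episodes spaced 330–900 days; outcomes drawn
from `outcome_mix` (live birth 0.70, abortion 0.25, ectopic 0.035,
stillbirth 0.015 — the approximate clinical mix of recognized pregnancy
outcomes); episode lengths from a truncated normal (mean 273 d, SD 18 d,
bounds 150–310 d, matching the ~39-week mean and the dispersion reported in
large claims characterizations). Maternal age at first episode start is
18–40 (uniform), with a 2% outlier rate outside 12–55 to exercise the age
filter.

Noise mechanisms, each independently switchable:

* `p_infant_on_other_plan = 0.10` — infant enrolled under a different plan;
  structurally unlinkable.
* `p_mother_churn = 0.08` — maternal coverage ends 10–120 days before the
  last delivery; the episode fails the coverage criterion.
* `p_enrollment_gap = 0.20` — one 1–45-day coverage gap cut into a span;
  gaps ≤ 30 days are re-bridged by observation-period merging, longer ones
  split observation history.
* `p_twin = 0.032` — a second infant sharing the episode (≈ the US multiple
  birth rate).
* `p_extra_infant = 0.25` — an age-0 entrant on the plan whose birth episode
  is *not* captured (born ≥150 days from any episode end): a candidate
  infant that can never link, populating the non-linked infant cohorts the
  way real databases do. These are not ground-truth pairs of any recorded
  episode.
* `enrollment_delay` — infant enrollment starts on the first of the month
  after birth by default (the de-identification pattern that makes most
  inferred birth days a 1st); `same_day` emulates sources with accurate
  birth-date enrollment; December births therefore roll into the next
  calendar year and break infant candidacy, which is the main driver of
  non-linked mothers clustering at ~March episode starts.

Ground truth records *every* live-birth pair, including unlinkable ones;
evaluation reports sensitivity against both "all" and "recoverable"
denominators, where recoverable pairs are those satisfying the Step-1..3
preconditions on the realized data (so Step-4 exclusions are the only
recoverable-pair loss mechanism).

Determinism: each family draws from its own `SeedSequence(seed,
spawn_key=(family,))` substream, so outputs are byte-identical across runs
and growing `n_families` extends the population without reshuffling earlier
families. All output files are written in canonical sort order.

**What passing does and does not show.** The generator reproduces the
*structural* failure modes (plan mismatch, churn, redaction, year rollover,
multi-mother households) and the evaluation shows the algorithm is exact on
recoverable pairs and robust to these mechanisms. It does not reproduce
real-world linkage proportions or covariate prevalences — code semantics,
family-size distributions, plan-switching dynamics and coding error are not
modeled — so measured sensitivity/PPV characterize the algorithm, not any
particular database.

## Numerical and testing choices

Dates are pandas `datetime64[ns]` at day resolution; day offsets are exact
integer arithmetic — no floating-point tolerances exist anywhere in the
linkage path. SMD assertions at machine precision (1e-12) are made against
hand-computed closed forms on 4-person cohorts. Brute-force oracles (a
day-resolution coverage bitmap for merging; nested loops over persons,
events and pairs for candidates, links and covariates) are implemented
separately from the library and compared exactly on hundreds of randomized
small datasets. Problem sizes in the test suite and acceptance script
(25–3000 families, 200 oracle cases, ~2000-row null-balance cohorts) were
chosen to keep the full run in the low minutes on a single CPU while leaving
every statistical check at its stated strength.

## Known limitations

* Cross-plan linkage is out of scope by design: an infant on a different
  plan is invisible to the algorithm, and the evaluation quantifies (rather
  than mitigates) that loss.
* The candidate-infant year-match rule systematically misses December
  births under first-of-next-month enrollment; this is a property of the
  rule set being evaluated, faithfully reproduced.
* Step-4 exclusion discards both competing links even when one is clearly
  nearer; alternatives (nearest-wins) exist in the literature but are
  intentionally not the default semantics here.
* The measurement domain carries occurrence only, never result values;
  propensity modeling and multiplicity adjustment are out of scope.
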