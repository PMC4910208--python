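# Methods

This note documents the models, rules and numerical choices behind
`linkcohort`, and what the synthetic-data tests do and do not demonstrate
about real linked data.

## The privacy-preserving temporal model

Linked extracts about sensitive subpopulations typically withhold event
dates; each event instead carries the subject's age in days and the
calendar year. The package honours this end to end: no table column is a
date, and all temporal reasoning happens on the age-in-days scale, which is
exact *within* a person. Calendar placement of an event is only partially
identified: an event at age *a* in year *y* constrains the person's
birthdate to a window of up to a year, and intersecting the windows from
all of a person's events (`_temporal.feasible_birthdate_interval`) may
narrow it. Rules that need sub-year calendar resolution (below) act only on
what is provable from that interval and otherwise fall back conservatively.

## Identity resolution

The crosswalk between project person numbers (PPN) and the incarceration
source's person numbers (UPN) is treated as a bipartite graph; each
connected component is assumed to be one person and re-keyed to a single
person id (the smallest PPN in the component). This generalises the
pairwise multiple-match picture transitively; validation of the
single-person assumption is deliberately deferred to the quality rules,
where a false merge surfaces as overlapping episodes or an impossible
maternity history. Identifier normalisation is whitespace trimming and
case folding only — linkage itself happened upstream. Both multiplicity
histograms (PPN→UPN and UPN→PPN) are reported so either reading of a
multiple match is auditable.

## Reshaping

Births collapse to maternities on the key (person, age at birth in days):
distinct baby references at one age are a multiple birth (plurality = the
number of distinct references); a repeated reference is a duplicate record
— one copy is kept and the woman flagged. Same-age births with conflicting
recorded gestations are collapsed on age and flagged with a warning rather
than split, since no dedup key finer than age is available under the
privacy model. Incarceration episodes pivot to wide prisoner records with
slots ordered by start age (ties by end age; exact ties are duplicates and
left for the quality rules); the slot count N is computed from the data,
not fixed.

Estimated conception age is `age_at_birth − 7·gestation_weeks + 17` days.
Missing gestation leaves conception undefined and routes the woman to
missing-data censoring instead of imputing a 40-week term, because the
exposure windows are time-critical.

## Quality rules and censoring

All maternities of a woman are censored when any rule fires, because a
record error cannot be distinguished from a false-positive link and either
corrupts temporal relationships. Choices the rule prose leaves open:

- **Episode intervals are half-open `[start, end)`**: release and same-day
  re-entry (transfers) do not count as overlap.
- **Completed years** = `floor(age_days / 365.25)`; over a 6.5-year window
  this divisor keeps drift below one day.
- **Maternity plausibility.** More than one maternity in the Jun–Dec 2000
  window, or a cumulative 3rd/5th/7th/9th/11th/13th maternity by the end
  of 2001…2006 (counting maternities from 2000 onward), flags the woman.
  The Jun–Dec window needs sub-year resolution: a year-2000 maternity
  counts against it only when its feasible date interval lies wholly
  inside the window, and is dropped from the cumulative count only when
  provably before June 2000. This under-flags rather than over-flags
  ambiguous year-2000 births.
- **Concurrency boundary**: the next conception exactly 30 days after the
  previous birth is allowed; 29 days flags.
- Reasons are independent; a woman may carry several, so per-reason audit
  counts can exceed censored-women counts. Audit margins (validated +
  censored = total, per stratum) are asserted at run time and raise on
  mismatch.

Serious mental health morbidity (MHM), used to stratify the audit, is an
admission with ICD-10 codes in the psychiatric (F00–F09, F20–F99),
self-harm (X60–X84, Y10–Y19, Y87.0, Z91.5), drug (F11–F19, T40, T42, T43)
or alcohol (E24.4, F10, G31.2, G62.1, G72.1, I42.6, K29.2, K70, K86.0,
O35.4, R78.0, T51, X45, X65, Y15, Y57.3, Y90, Y91, Z50.2, Z71.4, Z72.1)
sets — matched by category prefix after dot-stripping, so F20 covers
F20.x — or a psychiatric-ward admission flag, or an opiate-substitution
authority.

## Exposure classification

The five temporal categories are made a provable partition by fixing the
boundary inequalities: category 1 iff `end ≤ conception`; else 2 iff
`start > birth`; else 3/4 iff `start ≥ conception − tolerance` (3 when
`end ≤ birth`, else 4); else 5. The **tolerance** (default 14 days,
configurable, recorded in output metadata) absorbs inaccurate pregnancy
dating from late or absent antenatal presentation: completed-week
truncation contributes up to 6 days and LMP-vs-conception variation most
of the rest. Raising it can only reclassify category-5 boundary cases
toward 3/4; it never demotes an exposed maternity (a property test).

Maternity status: any category-5 count censors; else categories 3/4 define
a prison pregnancy (4 ⇒ birth in prison); else any 1/2 count defines a
prisoner-control maternity. Timing patterns extend the
during/before/after row scheme to control maternities (before_only,
after_only, before_and_after), which the source scheme leaves ambiguous
for controls; the cross-tabulation we publish restricts timing rows to
prison maternities for that reason. Mother status: pregnant prisoner iff
≥1 prison-pregnancy maternity, own control when both types are present,
prisoner control otherwise. The index maternity is the first prison
maternity for pregnant prisoners, else the first maternity in the study
period (1 Jul 2000 – 31 Dec 2006); a year-2000 birth is in-period unless
its feasible interval proves it before 1 July.

## Controls, weighting and risk ratios

The community control set is every mother with no linked record (already a
random sample by the extract design) plus a seeded simple random sample,
without replacement, of non-prisoner MHM mothers at the sampling fraction.
The whole-population estimate is `weight × validated unlinked + validated
linked`, with weight defaulting to the inverse sampling fraction rather
than a hard-coded 10 (10 follows from the 10 % design). A Bernoulli
retention model makes the estimator unbiased; this is verified over 200
seeded replicates.

Censoring risk ratios use the Katz log-normal interval on person-level
counts. Note the point estimates reproduce published values at one
decimal, but Katz intervals computed from the stratum person counts are
wider than the published intervals (≈6.9–14.2 vs 8.2–11.9 for the prisoner
ratio); the interval method is configurable and the discrepancy is
documented rather than chased.

## The synthetic generator

The generator emulates the study conditions, not any real extract:
prisoner prevalence 0.8 %, MHM prevalence 7 % overall and 68 % among
prisoners (the non-prisoner rate is solved from the mixture), a mean of
2.9 episodes per prisoner (zero-truncated geometric, capped at a
configurable maximum, 30 by default), gestation Normal(39, 2) truncated to
[20, 43] completed weeks, mean 1.4 maternities per woman (shifted
Poisson, capped at 8), a 1.5 % twin rate, 20 % of prisoner mothers with a
pregnancy-exposed maternity of which 21 % give birth in custody, and a
10 % retention sample of unlinked women. A latent birthdate per woman
exists only inside the generator to keep (age, year) pairs consistent.

Clean records are constructed to pass every rule: inter-birth gaps are at
least `max(gestation_days + 43, 370)` days. The 370-day floor is what the
privacy-degraded maternity-plausibility rule requires — with only calendar
years observable, three births with ~300-day gaps could land inside a
two-calendar-year counting window and trip the cumulative threshold — and
the gestation-linked term keeps the next conception ≥ 60 days after the
previous birth, clear of the 30-day concurrency boundary. Non-exposure
episodes are placed outside every pregnancy's guarded window
`[conception − 30 d, birth]`, so classification is unambiguous for any
tolerance below the guard. Injected errors are deterministic rule
violations (e.g. the conception-in-prison injection starts an episode 25
days before the estimated conception and ends it 20 days after), so
detection sensitivity 1.0 is the correct expectation, not an optimistic
one.

What passing these tests shows: the pipeline's rules, classifications and
accounting are internally correct and recover known structure exactly when
the data generating process matches the stated record model. What they do
not show: robustness to error modes the generator does not emulate —
gradual dating errors smaller than the tolerance, correlated errors across
sources, non-random linkage failure, or missingness mechanisms beyond
absent episode bounds. Real-data rates of censoring are reproduced only at
the level of printed-table arithmetic, not re-derived from source records.

## Problem sizes

The default test and acceptance runs use populations of 4,000–30,000
simulated women, 10,000 random episode–pregnancy pairs for the partition
property, 200 replicates for estimator bias, and a 5 × 5 × 20 × 20 grid of
small 2×2 tables for risk-ratio equivalence; these sizes give Monte-Carlo
standard errors comfortably inside the asserted 3-SE bounds while keeping
the full suite under a minute.
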