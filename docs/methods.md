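# Methods

## Setting and design

The pipeline implements a new-user (incident-user) cohort design on
community-pharmacy dispensing data. Dispensings, not consumption, are
observed; treatment exposure is reconstructed from refill patterns. The
population of interest is persistent new users of acetylcholinesterase
inhibitors (AChEIs, ATC N06DA), followed over a fixed six-window frame —
four 365-day windows before the index date and two after — and compared,
window by window, with the general population via direct age standardization
with calendar-year/age shifting.

All date arithmetic is in days; the index date is day 0. Age is everywhere
calendar year minus birth year: the registry schema carries only birth year,
so exact ages are unknowable by design and an "age" can be off by up to one
year relative to a birthday-based age.

## Exposure episodes and persistence

**Supply.** Each dispensing supplies `ceil(n_units / rate)` days from its own
date, with `rate` = 2 units/day for rivastigmine (N06DA03; capsules are taken
twice daily — the same rate is applied to all N06DA03 formulations, patches
included, for want of formulation-resolved dose information) and 1 unit/day
otherwise. The ceiling means a partial final day counts as a treatment day
("supposed to be consumed" through that day).

**Use periods.** AChEI dispensings sorted by date are cut whenever the gap to
the previous dispensing exceeds `gap_days` (default 365; a gap of exactly 365
does *not* cut). A period's end date is the last dispensing's date plus its
days of supply minus 1; earlier dispensings' supply does not extend the
period past that (no stockpiling in the period bound).

**Index period.** The period with the largest number of dispensings; ties are
broken by longer duration (start through end of supply), then earlier start.
The rationale for this ordering: a refill count captures sustained engagement
with therapy better than raw span, and span disambiguates equal counts. Both
orderings of the two criteria are defensible; this one is fixed here and
exercised by tests.

**Persistence** at `horizon_days` = 240 with `rule_day` = 210: rule 1, a
dispensing dated in the closed interval [210, 240]; rule 2, total fractional
supply (`Σ n_units/rate`) of dispensings dated in [0, 210) at least 210
days; rule 3, the latest dispensing dated before day 210 supplies through
day 210. A dispensing dated exactly day 210 therefore counts toward rule 1
and not rule 2 — this avoids the same dispensing both "filling the first 210
days" and "renewing after them". Rules 1 and 3 are per-prescription (no
carry-over between dispensings); rule 2 is cumulative. `coverage_oracle`
exposes both the no-carry and the stockpiling per-day supply arrays so the
convention is testable against a brute force.

A consequence of the "last prescription before day 210" wording of rule 3 is
worth stating: persistence is *not* monotone in adding dispensings. A small
dispensing added late (but before day 210) can displace a larger one as "the
last prescription" and undo rule 3 without triggering rules 1-2. The
property tests assert monotonicity only where it genuinely holds (adding
dispensings strictly before the latest pre-210 one) and pin the non-monotone
edge case as intended behavior.

## Cohort selection

Candidates are all patients with ≥ 1 AChEI dispensing. The cascade, applied
in order with the first failing check logged:

1. `not_incident` — index date earlier than data start + 365 days (the
   washout cannot be verified); with data from 2004 the earliest verifiable
   index date is 2005-01-01;
2. `index_outside_window` — index date outside [2008-01-01, 2013-12-31],
   chosen so 4 pre-index years and 2 post-index years of data exist;
3. `over_age_cap` — age at index > 88 (the general-population table has
   1-year age resolution only to 89, and the oldest window shifts ages +1);
4. `died_within_2y` — death year ≤ index year + 2. The rule is calendar-year
   based (month ignored) because death is recorded at year+month resolution
   and the criterion is phrased against the year of initiation; a
   730-day reading would be a defensible alternative and the window is
   configurable;
5. `absent_from_registry_y2` — no dispensing of any ATC code in days
   [365, 729] after index, the operational proxy for having left
   community-pharmacy coverage (typically nursing-home admission);
6. `not_persistent` — the three rules all fail.

The censoring checks (4, 5) deliberately precede the persistence check: a
stream truncated by death or institutionalization cannot be classified by
refill rules, and labelling such patients non-persistent would conflate
censoring with discontinuation.

No lower age bound is enforced; the "37–80" label on the younger stratum
reflects the observed minimum in the motivating setting, not a criterion.
The age strata split at 80 (≤ 80 vs 81–88). Patients with earlier AChEI use
2–4 years before the index date are retained — the 1-year washout is the
incident-use definition, not a lifetime-naive requirement.

## Prevalence

Windows are fixed 365-day day-offsets from the index date, ignoring leap
days: [−1460, −1096], [−1095, −731], [−730, −366], [−365, −1], [0, 364],
[365, 729]. The "second year after" is read as [365, 729], consistent with a
follow-up that ends 729 days after initiation. The cohort is a closed
persistent-survivor population, so the denominator of every window is the
full stratum size.

A member is a user of a drug group in a window if ≥ 1 dispensing matching
any of the group's ATC prefixes is dated inside the window. Concomitant use
of two groups means ≥ 1 dispensing of each within the *same* window; no
supply-overlap requirement is imposed, because the unit of analysis
throughout is "filled at least one prescription" per window.

Wilson score intervals (default 95%) accompany every proportion; the bounds
are exact 0/1 at x = 0 / x = n. Cells with fewer than 5 users carry a
`suppressed` flag applied at reporting; computation (and standardization
inputs) keep the unsuppressed counts.

## Standardization and prevalence ratios

The general population cannot be followed as a closed cohort, so the
comparison for a window X years away from initiation shifts both the
dispensing year and the age in the general population by X: windows −4…−1
shift by −4…−1; window +1 (days 0–364, i.e. the initiation year itself)
shifts by 0; window +2 by +1. For initiators aged 81–88 in 2008–2013 this
yields GP comparison cells at ages 77–84 in 2004–2009 for window −4 and ages
82–89 in 2009–2014 for window +2. The +1/+2 mapping is pinned by the
81–88/second-year example; the first-year shift of 0 follows from the window
being the initiation year.

For each initiation year y, GP rates at the shifted (year, age) cells are
weighted by the age distribution (as counts, per sex and age stratum) of
that year's initiators — "the actual year as reference":
u_y = Σ_a w_a · rate(y+shift, a+shift), N_y = Σ_a w_a, pooled as
Σ_y u_y / Σ_y N_y over 2008–2013. Reference ages shifting outside [0, 89]
are dropped from both sums (renormalization) with a logged warning; under
the 88-year age cap and the shift convention the affected mass is zero.
No CIs are attached to GP quantities (at national denominators they are
negligibly narrow), and no variance is propagated into prevalence ratios.

PR = cohort proportion / adjusted GP proportion, undefined (reported
missing) when the denominator is 0.

The aggregate GP table carries per-group user counts, from which a two-group
joint prevalence is not derivable; GP comparison values for the concomitant
pairs therefore exist only if the population table carries the pair as its
own `drug_group` row. The synthetic generator emits such rows with target =
product of the component targets, consistent with its independence
assumption.

## Synthetic registry generator

`SimulationConfig` defaults *are* the study conditions: calendar span
2004–2016, initiation 2008–2013, 63% women, initiation ages ≈ N(80, 8)
(discretized over birth years, with mass above the 88 cap so the exclusion
is exercised), per-window use probabilities betablockers 0.30,
citalopram/escitalopram 0.15, digitalis 0.03, verapamil 0.015, haloperidol
0.01 (the order of magnitude of elderly-population prevalence in the
motivating setting), persistent fraction 0.85, prior-use fraction 0.04,
institutionalization fraction 0.05, refill intervals U{75..100} days,
90–100 units per dispensation, age-banded annual death hazards (0.002 below
70, 0.02 at 70+, 0.06 at 80+, 0.15 at 90+), GP cell population 1,000.

Design choices:

- **Every simulated patient initiates AChEI once** — the real extract covers
  exactly the people with ≥ 1 AChEI dispensing.
- **Refill streams are renewal processes**: next dispensing = previous date +
  a draw from `refill_interval_days`. Persistent initiators receive refills
  over a random treatment duration (400–1,100 days), verified against the
  persistence rules and repaired with a day-220 refill in the rare
  constructions that fail all three; non-persistent initiators receive a
  single dispensing capped at 150 days of supply, which violates all three
  rules by construction. AChEI unit counts are scaled by the drug's daily
  rate so supply durations are comparable across drugs (donepezil 74%,
  rivastigmine 16%, galantamine 10%).
- **Drug-group use is drawn independently per patient per window** with the
  configured probability, then realized as a dispensing at a uniform day in
  the window. This makes the configured value the exact Bernoulli parameter
  of the quantity the pipeline estimates, and makes combination prevalence
  follow the product law — both used as parameter-recovery checks.
- **A background pantoprazole stream** (every 90 days, not in any studied
  group) keeps non-censored patients registry-visible, so the year-2
  presence exclusion is independent of studied-drug use and does not bias
  prevalence estimates.
- **Death** truncates all dispensings at the end of the death month;
  **institutionalization** (a configurable fraction) truncates them at a
  uniform date in the first post-index year, which triggers the
  `absent_from_registry_y2` exclusion.
- **Digitalis codes switch** from digitoxin (C01AA04) to digoxin (C01AA05)
  at calendar year 2011, mirroring the Norwegian market switch, so prefix
  matching on C01A is exercised across codes.
- The GP table is generated with `users = round(population × target)` per
  (year, age, sex, group) cell; targets may be flat or age/sex-banded.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: dose trajectories and DDD dynamics, switching
between AChEIs as clinically distinct episodes, correlation between drug
groups (real comorbidity clusters), calendar trends in prescribing, age- or
sex-dependent use probabilities within the study population,
population-size age structure in the GP table, and mortality that depends on
drug exposure. Parameter-recovery results demonstrate the estimators are
correct under the stated sampling model, not that the model matches any
specific real registry.

## Numerical choices and problem sizes

- Wilson CI computed from the closed form with z = Φ⁻¹(0.975) ≈ 1.959964;
  bounds clipped to [0, 1], exact at degenerate x.
- Standardization identities (self-standardization, constant-rate
  invariance, brute-force double-sum agreement) hold to 1e−12 and are
  asserted at that tolerance.
- Determinism: a single `numpy` Generator seeded from `SimulationConfig.seed`
  drives all simulation draws; analysis stages are deterministic; CSV output
  uses a fixed float format so reruns are byte-identical.
- Test and acceptance problem sizes: 2,000 random streams for the
  persistence brute-force check, 3,000 patients for structural-invariant
  runs, 10,000 for the end-to-end CLI check, 20,000 for parameter recovery —
  large enough that 3-standard-error bands around configured parameters are
  a few tenths of a percentage point.

## Known limitations

- Prescribed ≠ consumed: supply-based persistence overestimates intake when
  dispensed drugs are discarded.
- The year-granular death rule can exclude someone who died 2 years + 11
  months after initiation and include someone who died 2 years + 1 day
  after the index date, depending on calendar alignment.
- Prefix-based group matching cannot separate indications sharing a code.
- PRs carry no uncertainty interval; treat small-cell ratios with caution
  (the suppression flag marks cells under 5 users).
- The "last prescription" persistence rule 3 is non-monotone in added
  dispensings (see above); this is faithful to the rule's definition, not a
  numerical artifact.
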