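# Methods

This note documents the model implemented in `asthma_cea`: its structure,
the conversions and accounting rules, the reference parameter set, the
uncertainty machinery, numerical choices, and known limitations.

## Cohort model

**States.** `NO_CSE` (stable severe asthma on maintenance therapy), three
exacerbation tunnel states `CSE_OCS` / `CSE_HOSP_ED` / `CSE_HOSP`
(clinically significant exacerbation managed with an oral-corticosteroid
burst, needing an ED visit, needing inpatient admission), and absorbing
`DEATH`.  Exacerbation states are entered only from `NO_CSE` and exited
within one cycle, reflecting that a typical exacerbation resolves within
about two weeks — which is also why the cycle length is 2 weeks (26
cycles/year).

**Transitions.** From `NO_CSE` at age *a*: death first (per-cycle asthma
mortality of the stable state at *a*), then, conditional on survival, an
exacerbation with per-cycle probability `annual_rate / 26`, split across
severity substates by a fixed event-type distribution.  From each
exacerbation state: death at the (higher) exacerbation-state mortality,
otherwise return to `NO_CSE`.  The exacerbation rate is held constant over
the whole horizon (constant-rate extrapolation of the 52-week trial
efficacy).

**Two conversions, fixed per parameter class.** Exacerbation *rates*
(events/person-year) divide by the cycles per year — the only conversion
consistent with the published per-cycle values 0.01731 = 0.45/26 and
0.05038 = 1.31/26 — and the quotient is used as the per-cycle probability
of an exacerbation cycle (clamped at 1 with a warning; the clamp can only
fire under extreme sensitivity ranges).  Mortality *probabilities* use the
compound form `1 − (1 − p)^(1/26)`, so compounding over a year recovers the
annual probability exactly.  Both are exposed in
`asthma_cea.conversions`.

**Horizon and termination.** The cohort starts wholly in `NO_CSE` at age
52.2 and runs until age 100 (remaining survivors censored, no further
accrual) or until living occupancy falls below 1e-9.  With asthma-specific
mortality alone the cohort would never numerically die out, so a terminal
age is required; 100 is the conventional cap.  Background all-cause
mortality is deliberately not added: the model's mortality channel is
asthma-specific by construction, and adding a second channel would change
the meaning of the state-specific tables.  Age advances continuously
(52.2 + k/26); mortality and employment lookups use the containing
half-open integer-age band, the last band open-ended.

**Rewards, discounting, half-cycle correction.** Per cycle, state-wise cost
and utility vectors are assembled (below), weighted by the trapezoidal
average of entry and exit occupancy (the half-cycle correction; switchable
off), and discounted by `(1.05)^(−k/26)`.  With constant rewards and no
deaths the trapezoid is a no-op, which the suite asserts.

**Microsimulation oracle.** `markov.microsim_oracle` simulates individual
trajectories with the same per-cycle probabilities and the same
trapezoidal, discounted reward accounting.  The cohort trace is the exact
expectation of these trajectories, so the sample means must agree with the
cohort totals within Monte-Carlo error — the suite checks agreement within
3 standard errors at 50,000 individuals across random parameter sets.  The
oracle shares no code path with the cohort accumulation loop beyond the
transition-matrix builder.

## Costs and utilities (societal perspective)

Per 2-week cycle and living state:

- **Drug acquisition**: unit price ($682.02 per 100 mg) × dose/100 mg,
  amortised over the dosing interval (a dose every 4 weeks = half a dose
  cost per cycle).  Amortisation rather than pulsing on alternate cycles:
  with half-cycle correction the two differ negligibly and the amortised
  form keeps rewards Markovian in the state.
- **Monitoring**: flat per-cycle cost while alive.
- **Adverse events (AEs)**: 52-week trial incidences are treated as annual
  frequencies, divided by 26 and multiplied by per-event costs
  (frequency-weighted sum); identically for utility decrements.  AE burden
  attaches to *all* living states, because it follows the treatment arm,
  not the exacerbation state.
- **Exacerbation management**: severity-tier cost on exacerbation cycles
  only.
- **Productivity loss** (human-capital approach): (missed workdays +
  presenteeism days) × daily wage × age-band employment rate, on
  exacerbation cycles only; 1 missed day for the outpatient tier, 6.4 for
  both hospital tiers (whether the ED-only fraction should instead use 1
  day is unknowable from the source; the hospital-tier default is the more
  conservative choice).  Employment is 0 beyond the last band.

Utilities: `NO_CSE` gets (0.84 − AE decrement) × (1/26) QALY per cycle;
exacerbation states additionally subtract the substate decrement; the
per-cycle utility is floored at 0 because extreme probabilistic draws could
otherwise push it negative.  Death accrues nothing.

**Treatment and AE accrual windows.** `ModelSettings.treatment_duration_years`
bounds the drug-dosing window and `ae_window_years` the AE accrual window;
both default to `None` (lifetime).  The reference parameter set bounds
dosing at 1 year — the efficacy-trial duration — while retaining the
exacerbation-rate benefit and AE burden for life.  Rationale: a lifetime of
4-weekly dosing at the list price alone (~$143k discounted) is far larger
than any plausible lifetime societal total for this population, so a
bounded dosing window is the only internally consistent reading of models
of this design; making it an explicit, switchable setting surfaces the
assumption instead of burying it.

**Comparison statistics.** ΔC and ΔE between intervention and comparator
traces; ICER = ΔC/ΔE; *dominant* when ΔC < 0 and ΔE > 0, *dominated* when
ΔC > 0 and ΔE < 0; ΔE = 0 leaves the ICER undefined and classifies by the
sign of ΔC with an explicit flag.  Incremental net monetary benefit is
`WTP·ΔE − ΔC`.  Cost totals are decomposed into per-component ledgers
(drug / monitoring / AE / exacerbation management / indirect) that must sum
to the arm totals to 1e-6; the decomposition is exported by the base-case
driver.

## Mortality derivation

Stable-state asthma mortality is derived from three tables (asthma deaths,
asthma incidence rates, population counts, each by age band and gender):
per gender, deaths over estimated asthma cases (incidence × population);
per band, the population-weighted gender average; results clamped to [0,1]
with a warning.  The operation is agnostic about whether the supplied rate
table is an incidence or a prevalence survey — it consumes whatever rate is
given, because the upstream sources conflate the two and the arithmetic is
identical.  Exacerbation-state mortality comes from its own age-indexed
table and must be ≥ the stable-state value per band.  The derivation is
exact arithmetic: on constructed inputs with known rates it recovers them
to machine precision (asserted), and it is invariant to uniform scaling of
the population counts.

## Uncertainty analyses

**Subgroups.** The placebo-arm exacerbation rate is shared across
subgroups (no subgroup-specific control data); the intervention rate is
placebo rate × subgroup rate ratio.  A subgroup whose RR equals the
base-case ratio reproduces the base case exactly (asserted to 1e-9).

**Deterministic (tornado).** One parameter at a time to the ends of its
range: ±20% defaults, the 95% CI for the rate ratio, a literature range
(0.76–0.90) for the baseline utility.  Ranges straddling an invalid domain
(e.g. utility > 1) are clamped with a warning.  Each perturbation runs on a
copy; after the sweep the base case is re-run and compared, guaranteeing
restoration.  Entries are ordered by absolute ICER spread; dominant
outcomes enter the ordering through their (negative) cost-saving-per-QALY
ratio and are flagged.  Exacerbation-rate perturbations vary the *annual*
rates, which are then re-converted — parameters stay on their reported
scale.

**Probabilistic.** Distribution families follow standard practice: beta
for probabilities/proportions/utilities, gamma for costs and disutility
magnitudes, lognormal for rate ratios (moment-matching and CI-matching
constructors provided); `normal` and `fixed` exist for symmetric
perturbation studies and degenerate checks.  At load time every
distribution's analytic mean must sit within 5% of the point estimate it
wraps.  Each uncertain parameter gets its own random stream derived from
the master seed and a stable hash of its path, so adding or removing a
parameter never reshuffles the others' draws, and any prefix of a run is
bitwise reproducible.  Invalid draws (outside the parameter's domain) are
re-drawn up to 100 times, then error.  The placebo rate and the rate ratio
are sampled independently and the intervention rate re-derived (path
`derived.cse_rr`), keeping the two arms' rates consistent within a draw.
The CEAC reports, per WTP grid point (default 0–45,000 by 500), the
fraction of draws with positive incremental net monetary benefit.

## Reference parameter set and provenance

`synthetic.reference_fixture()` pins every value available in the main
published text (rates 0.45/1.31, utility 0.84, price $682.02, missed days
1/6.4, exchange rate 7.0467, start age 52.2, 5% discount, WTP band) and
fills the rest with assumed, clearly tagged stand-ins: severity split
0.78/0.14/0.08; monitoring $25/cycle; exacerbation management $80/$500/$2,000
by tier; a 14-event AE table at DRG-like per-event costs ($60–$1,600) with
the intervention arm carrying the lower incidences; exacerbation utility
decrements 0.27/0.39/0.51 (episode utilities ≈ 0.57/0.45/0.33 against the
0.84 baseline, in line with the asthma-exacerbation utility literature);
daily wage $47 with employment 0.82/0.68/0.30/0.08 by age band; presenteeism
1.5 days; a five-band mortality table rising from 0.0008 to 0.04 (stable)
and 0.002 to 0.085 (exacerbation) annually; and eight subgroups with rate
ratios 0.27–0.45.  These were chosen once for realism; they are *not*
calibrated to reproduce the published outputs, and the provenance map
(`paper_text` / `assumed` per path) makes the distinction auditable.  Under
these inputs the base case lands at ΔC ≈ $773, ΔE ≈ 0.219 QALYs, ICER ≈
$3,528/QALY.

What the fixture consequently does and does not show: passing tests
demonstrate the *machinery* — conservation, oracle agreement, restoration,
reproducibility, correct conversions and accounting — on a realistic
parameter landscape.  They do not validate the published study's exact
totals, which depend on supplementary parameter tables (severity split,
state costs, AE table, disutilities, mortality tables, wages, subgroup
ratios) not reproduced here; `synthetic.apply_overlay` exists precisely to
inject those tables, path-addressed, when a user has them.

`random_parameters(seed)` draws structurally valid sets from wide legal
ranges (utilities to [0.3, 1] neighbourhoods, rates up to 4/year, costs to
$10⁴, rate ratios 0.1–1.5) for property tests; `toy_mortality_inputs`
fabricates derivation inputs with known true rates.

## Numerical choices and scale

- Tolerances: occupancy/row sums 1e-9; probability round trips 1e-12; cost
  ledger closure 1e-6; death-row absorption exact.
- The engine caches transition matrices per integer age and reward vectors
  per (integer age, dosing-window, AE-window) key; band edges are assumed
  to fall on integer ages, which the generators guarantee.
- Problem sizes used by the shipped analyses and suite: lifetime horizon ≈
  1,243 cycles; microsimulation checks at 50,000 individuals; the driver
  and suite run the probabilistic analysis at 1,000 iterations (a
  full-scale analysis would use 10,000 — the machinery is identical, only
  `--iterations` changes).
- Config dialect: YAML mapping with inline or CSV tabular blocks; money in
  USD, with `{cny: x}` accepted and divided by the fixed exchange rate
  (7.0467); no inflation indexing.

## Limitations

- Constant exacerbation rate for life, no effect of exacerbation history,
  no treatment waning or discontinuation other than the hard dosing window.
- Asthma-specific mortality only; no competing background mortality (see
  above), so undiscounted life expectancy is overstated — ICERs are less
  affected because both arms share the bias.
- The severity split, AE-to-arm attachment and one-cycle tunnel are
  structural simplifications; exacerbations longer than one cycle are not
  represented.
- Human-capital costing only (no friction-cost alternative).
- Two-arm frontier only; no EVPI.
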