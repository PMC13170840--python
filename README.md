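# asthma-cea

A Markov cohort cost-effectiveness model for add-on mepolizumab (anti-IL-5,
100 mg every 4 weeks) versus placebo on top of standard of care in severe
eosinophilic asthma, evaluated from a societal perspective in the Chinese
setting.  The package is aimed at health-economics analysts who want a fully
scripted, testable version of this class of decision model: every stage —
parameter handling, the cohort engine, costing, mortality derivation, and
the uncertainty analyses — is an importable, unit-tested function.

## The model

Patients start in a stable state (*No-CSE*, no clinically significant
exacerbation) at mean age 52.2 and move in 2-week cycles (26 per year) over
a lifetime horizon among five states: No-CSE; three one-cycle exacerbation
tunnel states split by severity (managed with oral corticosteroids,
requiring an ED visit, requiring hospitalisation); and absorbing death.
Per cycle, from No-CSE:

- P(death) = state-specific asthma mortality at the current age, converted
  from annual probability *p* by `1 − (1 − p)^(1/26)`;
- P(exacerbation substate *x*) = `(1 − P(death)) · (r/26) · s_x`, where *r*
  is the arm's annual exacerbation rate (0.45 mepolizumab, 1.31 placebo —
  hence per-cycle rates 0.01731 and 0.05038) and *s_x* the severity split.

Exacerbation survivors return to No-CSE after one cycle.  Costs (drug,
monitoring, adverse-event management, exacerbation management, and
human-capital productivity loss = missed workdays × daily wage × employment
rate) and utilities (baseline 0.84 minus frequency-weighted adverse-event
and exacerbation decrements) accrue per cycle with half-cycle correction
and 5% annual discounting.  The primary output is the incremental
cost-effectiveness ratio ΔC/ΔE in $/QALY against a willingness-to-pay band
of $15,217–$38,042 per QALY, with subgroup (rate-ratio) analyses, one-way
deterministic sensitivity analysis, and probabilistic sensitivity analysis
with an acceptability curve.

A full account of assumptions, parameter choices and limitations is in
[docs/methods.md](docs/methods.md).

## Worked example

The analysis chain lives in `analysis/` and runs off a single generated
parameter file:

```bash
python analysis/01_build_parameters.py   # writes results/parameters.yaml
python analysis/02_base_case.py
```

which prints (reference parameter set):

```
mepolizumab arm: $30,692.08 (¥216,278), 13.90642 QALYs
placebo arm:     $29,919.47 (¥210,834), 13.68742 QALYs
increments: dC $772.61, dE 0.21900 QALYs
ICER: $3,527.83 per QALY (icer); WTP band $15,217-$38,042
```

i.e. adding the biologic costs an extra $772.61 per patient over a
discounted lifetime, buys 0.219 quality-adjusted life-years, and the cost
per QALY gained ($3,528) is well below the lower willingness-to-pay limit —
cost-effective under these inputs.  `03_subgroups.py`, `04_dsa_tornado.py`,
`05_psa_ceac.py` and `06_mortality_derivation.py` continue the chain
(subgroup ICERs, tornado ranking, Monte-Carlo acceptability curve, and a
check that the stepwise mortality derivation recovers known rates).

Note the reference parameter set mixes values printed in the published
analysis with clearly tagged assumed stand-ins (see
`results/provenance.csv` after step 01), so its outputs characterise the
model, not the published study; `asthma_cea.synthetic.apply_overlay` can
inject the original supplementary tables where available.

The same analyses are exposed as a CLI:

```bash
asthma-cea base-case --out results/
asthma-cea psa --iterations 1000 --seed 1 --out results/
```

## Layout

```
src/asthma_cea/      parameters, conversions, mortality, economics,
                     markov (cohort engine + microsimulation oracle),
                     analyses, synthetic (reference fixture & generators), cli
analysis/            numbered narrative drivers writing to results/
tests/               unit + property suite, incl. end-to-end acceptance checks
scripts/acceptance.py
```
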