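# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices that matter for reproducing results.

## Intake distributions and the fortification shift

Usual-intake distributions are two-parameter log-normal or gamma, stored
internally as (mean, CV); the family-native parameters are derived
(log-normal: σ² = ln(1+CV²), μ = ln(mean) − σ²/2; gamma: shape = 1/CV²,
scale = mean·CV²). Both construction from a (mean, CV) pair and the
fortification shift are mean/CV-natural, which is why that
parameterisation is primary.

Fortification shifts a distribution right by the fortificant contribution
δ: the family is retained and the mean becomes mean + δ exactly.
"Retaining the shape" is ambiguous between keeping the SD and keeping the
CV; the default preserves CV, consistent with parameterising skewed
intake families by mean and CV, and a `shift_convention="sd"` switch
supports constant-SD shifting for sensitivity checks. Under the CV
convention shifts compose additively in the mean and CV is preserved to
machine precision.

Spreads with CV ≤ 1e-6 are treated as a point mass for cdf/quantile/
prevalence purposes: the analytic formulas become numerically fragile
there, and the point-mass limit is exact.

## Prevalence of inadequate and excess intakes

The probability approach treats individual requirements as a random
variable independent of intake: prevalence of inadequacy is
E[r(intake)] = ∫ f(x)·r(x) dx, with r(x) = P(requirement > x). The
integral is evaluated by adaptive quadrature (absolute and relative
tolerance 1e-8) on the bounded interval (0, q_intake(1−1e-9)); bounding
the support avoids infinite-interval fragility for gamma intakes. The
integrand uses closed-form scalar density and risk expressions rather
than frozen distribution objects; this is numerically identical and makes
whole-world runs take seconds. A quadrature failure raises an error
naming the stratum.

Requirement distributions default to normal with CV 0.10 — the
conventional probability-approach default — overridable per
nutrient×stratum via the requirements table. Iron requirements for
menstruating-age women are right-skewed: the generator (and any input
table) can declare a log-normal requirement family, parameterised so the
stated average requirement is the distribution mean. This is precisely
the case where the cut-point shortcut is invalid, so the pipeline always
integrates the full risk curve. The normal family is used untruncated in
the analytic risk curve and truncated at zero only in sampling oracles;
for CV ≤ 0.25 the truncation mass is below 1e-15. Requirement CVs ≤ 1e-6
short-circuit to the cut-point form F_intake(AR), which is the analytic
limit.

Excess intake is 1 − F_intake(UL). Only nutrients with a harmonised UL
are assessed (seven in the bundled reference tables); all others return a
"not assessed" sentinel rather than zero, because the absence of a UL is
not evidence of zero risk. UL availability is data, not code: strata
absent from the UL table are simply not assessed.

## Programmes, imputation and scenarios

Programme indicators mirror the fortification-data-exchange schema:
status, per-capita vehicle intake, industrially processed fraction (IP),
compliant fraction (FC), and a nutrient→(level, compound) standard.
Missing IP/FC values are imputed as the median of observed values for the
same vehicle within the country's region, falling back to the global
vehicle median; imputed values carry a provenance flag so the compliance
sensitivity analysis can substitute alternatives. Imputation is
idempotent. For inactive programmes a missing FC is structural (no
standard to comply with) and is set to zero without flagging.

Contribution terms are F·IP·FC·D/1000 in mg/day, converted to each
nutrient's registry unit (µg/day for iodine, vitamin A, folate, B12 and
selenium; mg/day otherwise). Age–sex intakes scale the population
per-capita figure by the group's calorie ratio, whose population-weighted
mean is 1 within each country, so group intakes average back to the
per-capita value.

Scenario rules:

* `improved_compliance` applies FC := max(FC, 0.9) to every active
  programme, voluntary as well as mandatory — a country already above 90%
  is not degraded.
* Standards alignment defaults to `max_with_guideline`: levels are raised
  to the guideline where below it, never lowered, and guideline nutrients
  missing from a standard are added (this is how calcium enters wheat
  standards that lack it). `replace_with_guideline` is available where a
  strict-harmonisation reading is wanted. The max rule was chosen because
  many existing standards already exceed guidelines and alignment is
  reported as a pure gain; a replacement rule would force some levels
  down.
* Expansion establishes new mandatory programmes (guideline standards,
  FC = 0.9, flagged `is_new` for planning costs) for inactive
  country×vehicle pairs where some guideline nutrient has baseline
  (no-fortification) country-level inadequacy ≥ 0.2 and the vehicle is
  eaten above a per-vehicle threshold (50 g/day; 5 g/day for salt,
  10 g/day for oil) with IP ≥ 0.5. Only nutrients passing the prevalence
  screen enter the new standard. The thresholds are configurable model
  choices: the qualitative criterion is "identified need and appropriate
  food vehicle", and these defaults encode it at values a fortification
  planner would recognise.

## Costs

Premix cost per tonne: Σ_m level_m (mg/kg ≡ g/tonne) ÷ activity_m ÷ 1000
× price_m, then multiplied by (1+shipping)(1+taxes)(1+logistics) — the
markups compound in supply-chain order. Annual premix cost multiplies by
fortified tonnage = vehicle supply × IP × FC. Industry costs are
per-facility (annualised fortification and QA–QC equipment plus recurrent
supplies, labour, training, management/overhead) times the facility
count, which is input data. Government costs are per active programme
(annualised monitoring equipment plus recurrent items), with annualised
planning/launch added only for programmes a scenario newly establishes.
Capital is annualised as an annuity, capital·r/(1−(1+r)^−life), with
straight-line capital/life at r = 0; defaults r = 0.03/yr, life = 10 yr
(planning/launch amortised on the same schedule), all configurable. No
overage term is applied by default; an overage multiplier on levels
exists for sensitivity use. All monetary amounts are 2021 USD/yr.

The global per-person summary is the mean and sample SD of the five
vehicle-level global per-person costs (global vehicle cost ÷ global
population). Premix costs are linear in compound prices, so scaling all
prices by k scales the premix component by exactly k and changes total
cost by (k−1)×(premix share) — the identity the price sensitivity
reports and the tests verify.

## Synthetic worlds

The generator emulates the structure of the real inputs, not geography.
Defaults: 10 countries in 2 regions, 34 age–sex groups (17 five-year age
bands × 2 sexes), 13 micronutrients, the 5 canonical vehicles. Intake
means are drawn per country×nutrient on a log scale around the stratum's
average requirement (country factor SD 0.6, group noise SD 0.15) so
baseline inadequacy spans (0, 1); CVs are uniform on [0.2, 0.8]; the
family alternates by nutrient so both are exercised. Programme status
frequencies by vehicle follow the observed global pattern (salt most
legislated, rice least); IP ∈ [0.2, 1.0] and FC ∈ [0.1, 0.95]; standards
cover a random 80% subset of each vehicle's guideline nutrients at
0.5–1.6× the guideline level, so alignment both raises and keeps levels.
Per-vehicle IP/FC missingness rates default to the shares imputed in the
source compilation (e.g. most salt IP values missing, few wheat values),
except that at least one observed value per vehicle is always retained
because the median imputation hierarchy needs a donor. Vehicle supply is
derived from per-capita intake × population × 365, keeping the cost and
intake sides mutually consistent. Reference requirement/UL/guideline/
compound tables are fixed, field-plausible values; they are synthetic
stand-ins, not harmonised reference data.

One named generator is seeded from the config; equal seeds give
byte-identical worlds. A `--full-size` flag generates 185 countries for
scaling checks.

What passing tests on these worlds shows: the estimators, scenario
transformations, accounting identities and cost arithmetic are correct
and deterministic on inputs with the assumed structure. What they do not
show: agreement with any real country's intakes, programme data or costs —
real-world headline numbers require the proprietary upstream extracts.

`generate_known_truth` builds a degenerate world (point-mass intakes at,
below and above the AR; vanishing requirement CVs; one single-vehicle,
single-nutrient programme with hand-pickable indicators) plus an answer
sheet of closed-form values computed independently of the pipeline's
quadrature (error-function forms); the test suite requires the full
pipeline to reproduce every entry within 1e-4.

## Aggregation and reporting

Counts are real-valued throughout (prevalence × persons) and rounded only
at report-writing time, so totals over thousands of strata accumulate no
rounding error. Prevented counts are defined as baseline − remaining on
an identical strata universe; a universe mismatch is an error rather than
a silent bias. The decomposition is exact by construction; re-adding
prevented + remaining reproduces the baseline to the last ulp (floating-
point addition is verified at 1e-12 relative). Scenario runs on the
default world complete in well under a minute on one CPU; the problem
sizes used throughout (10-country worlds, 4-country worlds for
orchestration tests, 10⁶-draw Monte-Carlo oracles) keep the full suite in
the low minutes while leaving every estimator grid well covered.

## Known limitations

* No uncertainty propagation: the pipeline is deterministic by design.
* No fortificant losses (storage/cooking), bioavailability adjustment or
  overage in the intake calculation; the contribution equation has no
  such terms.
* Spike-at-zero (zero-consumer) intake strata are not modelled; intakes
  are strictly positive continuous.
* The imputation hierarchy and expansion thresholds are reasonable
  defaults exposed in configuration, not estimates from data.
* Health-burden (DALY) extensions, biofortification and supplementation
  are out of scope.
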