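# Methods

## Model structure and assumptions

The engine is a static cohort decision tree evaluated in expectation over
one influenza season. A hypothetical cohort (the ≥65 population times the
vaccination coverage) is fully vaccinated with one of two strategies,
HD-QIV or aQIV. Within the season each member may become an influenza
case; cases may use GP and emergency-room services (treated as
independent, not mutually exclusive, with constant conditional
probabilities across strategies); hospitalization and death follow the
rules below. All within-season quantities are undiscounted; only the
life-years and QALYs forfeited by premature death extend beyond the
horizon and are discounted. Herd effects, waning, within-season dynamics
and societal (productivity) costs are out of scope by design: the model
is a payer-perspective static comparison.

**Efficacy bridging.** No head-to-head trial compares the two enhanced
vaccines, so their relative efficacy is derived through the shared
standard-dose comparator on risk ratios:
rVE(A vs B) = 1 − (1 − rVE_A)/(1 − rVE_B). This is standard
vaccine-efficacy algebra (a ratio of relative risks) and the only reading
under which a "relative efficacy vs a common comparator" composes. The
comparator rVE must be < 1; a negative bridged rVE is legitimate and
propagates (risk clamped to [0, 1]). Each rVE can be attenuated by a
`preventable_fraction` in [0, 1] before scaling a population risk,
defaulting to 1 (full applicability); this keeps the mapping from
trial-measured efficacy to population-level reductions explicit and
configurable rather than hard-coded.

**Hospitalization definitions.** Two mutually exclusive accounting views:
(1) *influenza-coded* — admissions with an influenza discharge code,
modelled conditional on being a case (so vaccine efficacy acts through
the case channel); (2) *cardiorespiratory* — admissions possibly related
to influenza (respiratory/circulatory codes), modelled as a cohort-level
seasonal rate scaled directly by the hospitalization rVE. The second
captures the hidden burden: coded admissions understate the true
influenza-attributable load by roughly a factor of four (4,407 coded vs
15,206 additional attributable admissions per year on average in the
source setting; `attributable_admissions` documents the sum, 19,613).

**Deaths.** Influenza mortality enters as an excess-mortality rate per
100,000 cohort members, not as a transition from hospitalization. The
per-arm death risk is scaled by 1 − f_deaths × rVE_cases, i.e. deaths
move in proportion to the cases each vaccine avoids. The published
population tables imply a death reduction larger than the case reduction;
the mechanism behind that extra reduction is not recoverable from public
material, so this package does not attempt to reproduce it — f_deaths is
exposed instead of guessed.

## Valuation

Discounted remaining life expectancy from age *a* uses annual cycles with
end-of-cycle discounting and no half-cycle correction:
LY(a) = Σ_{t≥1} S(a,t)(1+r)^{−t}, with S the cumulative product of
life-table survival probabilities and r = 3%/yr. QALE weights each term
by the population norm utility at the attained age. The age grid is
closed at 100. Acute decrements are (u_base − u_event) × duration/365
with durations 6 days (influenza episode) and 5.2 days
(hospitalization); the hospitalization decrement *adds to* the episode
decrement for the same person rather than replacing it — a simple,
auditable convention that slightly overstates losses for the
hospitalized sliver of cases. Deaths are valued at the rounded mean of
the cohort age distribution, since excess mortality carries no age
split; the Monte-Carlo oracle uses the same convention so the two
engines are comparable beyond event counts.

## Parameters

Printed anchors, fixed in the default set and never jittered: rVE 24.2%
(cases) and 18.2% (cardiorespiratory hospitalization) for HD vs SD; aQIV
scenarios 0/6/12% (the scenario value is applied to both outcomes unless
the hospitalization rVE is overridden in the config); episode durations
6 and 5.2 days; admission cost €4,035.32; dose prices €15.45 (aQIV) and
€32.27 (HD-QIV); administration cost defaulting to €0 (never priced
separately in the source); discount 3.0%; WTP €30,000/QALY.

The remaining fields of `default_italy_like()` are **fixtures**, chosen
once as plausible for the Italian ≥65 setting, not estimates of the
original (non-public) input table: cohort 7,367,000 (≈13.9 M aged ≥65 ×
53% coverage), seasonal attack rate 6%, P(GP visit | case) 0.386,
P(ER visit | case) 0.0082, P(coded admission | case) 0.006,
cardiorespiratory admission rate 6.45%/season, excess mortality
83/100,000, GP visit €20.66, ER visit €241.70, OTC €5 per case, utilities
0.50 (episode) and 0.20 (hospitalized), population norms declining from
0.89 at 65 toward a 0.72 floor, a Gompertz-like life table (q(65) ≈
1.1%, doubling ≈ every 7 years, closed at 100) and a geometric age
distribution with mean ≈ 73–74. On these fixtures the per-person
discounted totals (≈10.1 LY, ≈8.4 QALY) and the qualitative results
(cost-effective under the coded view, dominant under the hidden-burden
view, ICER increasing in assumed aQIV efficacy) match the published
pattern; the exact published ICERs depend on the non-public input table
and are deliberately not tuning targets.

`sample_parameter_set(seed, jitter)` perturbs only the fixture fields,
multiplicatively and log-uniformly within ±jitter, clamped to type
invariants (probabilities and utilities to [0, 1], the episode-utility
ordering re-imposed after clamping). `calibrate_baseline` inverts the
tree — which is linear in its baseline rates — in closed form so a chosen
arm reproduces target population counts exactly; infeasible targets
(implied probability outside [0, 1]) raise a named error.

## Sensitivity analysis

One-way DSA reruns the entire pipeline at each parameter's low/high
bound (95% CI when supplied, else mean ± 15%), clamped to hard
invariants. The tornado is ranked by the span of incremental net
monetary benefit at the base WTP for *every* entry, not only when an
endpoint is dominant: the ICER changes sign and meaning across
cost-effectiveness-plane quadrants, so a raw-ICER span is not a total
order, while NMB is linear, monotone in each delta, and defined
everywhere. The per-endpoint ICERs and dominance flags are still
recorded in the table.

PSA samples parameters by moment matching: beta for probabilities and
utilities (shape ν = m(1−m)/s² − 1), gamma for costs (k = m²/s²,
θ = s²/m), normal for relative efficacies, point mass when se = 0. The
default specs set se = 0.15·mean/1.96 so that ±15% spans ≈ a 95%
interval, mirroring the DSA convention; the distribution-family
assignment is a convention of this package (the source defers its
distribution table to prior work). Draws are clamped to hard bounds with
per-parameter clamp counts reported; per-draw engine failures are
recorded, never aborting the run, and count as "not cost-effective" in
the CEAC denominator. The CEAC uses strict NMB > 0 (ties are not
cost-effective), so a degenerate one-draw PSA steps from 0 to 1 exactly
at its deterministic ICER. Default grid: €0–100,000 in €1,000 steps;
default 1,000 draws.

## Verification design

- Closed-form oracles: annuity formula for discounted QALE, direct
  arithmetic for bridging and tree expectations, frozen into unit tests.
- An independent per-individual Bernoulli simulator (200,000 walks in the
  acceptance battery) must agree with the expectation engine within 3
  binomial standard errors on every event count.
- Exactness checks: calibration roundtrips (1e−6 relative), degenerate
  PSA equal to the deterministic run, byte-identical CSV output across
  repeated seeded runs.
- The published per-strategy result columns are bundled as *inputs*
  (`flucea.reference`) and pushed through the incremental module, which
  must reproduce the printed differentials and cost deltas exactly.

What passing tests do **not** show: agreement of the synthetic fixture's
absolute ICERs with the published ones (those require the original input
table), and realism of within-season dynamics the static tree does not
model.

## Known limitations

- Single death age and a single mean baseline utility for episode
  decrements (no age-stratified event risks or costs).
- Acute hospitalization and episode decrements are additive for the same
  person-days.
- The cardiorespiratory admission rate is a free cohort-level parameter;
  the package does not derive it from admission statistics beyond
  documenting the coded/attributable split.
- DSA/PSA address scalar leaves only; the utility-by-age map and life
  table are held fixed in sensitivity analyses.
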