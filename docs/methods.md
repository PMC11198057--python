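# Methods

This note records the model conventions, default parameters, numerical
choices and known limitations of the package. It is written for a reader
who wants to audit or extend the analysis.

## 1. Cohort state-transition model

A closed cohort starts entirely in the *angina* state and evolves through
three states — angina, spontaneous myocardial infarction (MI), death —
over annual cycles. From angina, MI and death are simultaneous competing
transitions with the marginal annual probabilities `p_mi` and `p_death`
(the remainder stays in angina); from the post-MI state, death occurs with
probability `p_death_post_mi` per year; death is absorbing. Unplanned
revascularization does **not** change state: it is a recurring cost event
applied to the angina occupancy at the arm's annual revascularization
probability, with a separate (higher) lump cost attached to the incident
MI flow for revascularizations performed with MI.

**Valuation convention.** End-of-cycle: the cycle-`t` reward uses the
state occupancy *after* the cycle's transitions, discounted by
`(1+r)^−t`, `t = 1..T`. No half-cycle correction. The one-time FFR add-on
cost is charged at cycle 0, undiscounted. This combination of conventions
reproduces the published Korean base case to the printed precision
(angiography arm: 4.60 discounted QALYs, 46.4% 10-year mortality, 11.7%
cumulative incident MI), which is why it was adopted; the convention is
otherwise a genuine modeling choice and is concentrated in
`markov.accrue_qalys` / `markov.accrue_costs` if a half-cycle variant is
ever needed.

**Cost attachment.** Annual angina and post-MI costs on the respective
occupancies; revascularization-without-MI cost on angina occupancy ×
annual revascularization probability; revascularization-with-MI cost on
the incident-MI flow; death-related cost once, in the cycle of death,
discounted at that cycle.

**FFR-arm derivation.** The input tables carry both an observed FFR-arm
probability row and adjusted hazard ratios (HRs) against the angiography
arm, and the two are mutually inconsistent (e.g. Korean annual death
0.039 observed vs 0.056 × 0.80 = 0.0448 HR-scaled). The base case derives
the FFR arm by scaling the angiography-arm probabilities with the HR
point estimates on the probability scale (`p·hr`); this is the
`hr_scaled_probability` mode and is what reproduces the published FFR-arm
outputs (4.89 ≈ 4.90 QALYs, 9.4% MI). `observed` and `hr_scaled_rate`
(`1−(1−p)^hr`, exact under proportional hazards within a cycle) remain
selectable per config. The two HR modes agree to first order for small
probabilities (property-tested at p ≤ 0.05).

**Known tension (costs).** The published per-state cost inputs do not
reconcile with the published total discounted costs (the gap is roughly a
factor of two for Korea; an index-admission cost component appears to be
implicit in the totals). The package therefore makes no attempt to
reproduce printed cost totals: the cost side is validated structurally
(component decomposition, discounting monotonicity, null-effect
invariance, antisymmetry under arm swap) and the computed ΔC for Korea is
about +$375, with the cost-effectiveness conclusion carried by the QALY
gain. Likewise the FFR-arm 10-year mortality computes to ≈39.2% under
every derivation mode versus the printed 38.5%.

**Horizon and discounting defaults.** 10 annual cycles; 4.5%/year
(Korea) and 3.5%/year (US, UK); willingness-to-pay λ = $30,000 (Korea),
$60,000 (US), $40,000 (UK) per QALY. All per the respective national
conventions the source inputs follow. The UK/US transition inputs are
used as given even though some look like multi-year cumulative values
from their source trials; they are labeled annual in the input table.

**Disutilities.** The comorbidity utility decrements (atrial
fibrillation, heart failure, diabetes) shipped with the Korean config are
scenario modifiers (`UtilityInputs.with_disutility`), not part of the
base case — the base-case QALYs reproduce without them.

## 2. Probabilistic sensitivity analysis

Distribution families: lognormal for transition probabilities and hazard
ratios, beta for utilities, gamma for costs. None of the sources report
dispersion for probabilities, utilities or costs, so the default standard
error is **10% of the mean** (`se_frac=0.10`), a common convention for
unreported uncertainty; HR lognormals use `meanlog = ln(HR)`,
`sdlog = (ln U − ln L)/(2·1.96)` from the published 95% CIs.

Two sampling schemes:

- `sampling="probabilities"` (default): each arm's annual probabilities
  and the MI-to-death probability are drawn from independent
  mean-preserving lognormals (`sdlog = sqrt(ln(1+cv²))`,
  `meanlog = ln(mean) − sdlog²/2`). This is the scheme whose Korea
  acceptability at λ = $30,000 (≈0.955 over 25,000 draws) is consistent
  with the reported ≈93.5%.
- `sampling="hazard_ratios"`: angiography-arm probabilities fixed,
  comparative uncertainty only through the CI-derived HR lognormals.
  Because the Korean death-HR CI (0.70–0.91) excludes 1, this scheme is
  far more certain (probability ≈0.9998) and is retained for comparison,
  not as the default.

Utilities and costs are shared between arms within a draw. Each parameter
has a named random substream derived from `(seed, crc32(name))`, so the
draw sequence of one parameter is invariant to adding or removing others.
Draws violating `p_mi + p_death < 1` (or any `p ≥ 1`) are rejected and
redrawn from the same substreams; the count is reported (zero under the
defaults). With `se_frac=0` every draw equals the deterministic base case
(tested to 1e−9), and a fixed seed gives bitwise-reproducible output.

The 25,000-draw PSA is evaluated by an array-vectorized replica of the
cycle loop, verified draw-by-draw against the scalar engine in the test
suite; it runs in well under a second.

## 3. Patient-level cost-effectiveness (4-year horizon)

Per-patient QALYs follow observed person-time, undiscounted (the 4-year
observational window is short and the source analysis describes summing
years lived in each state; discounting is a one-line change if wanted):
`u_angina ×` (entry → first of MI/death/censor/horizon) `+ u_MI ×` (MI →
first of death/censor/horizon). Death truncates all accrual; an MI
recorded after death is rejected as a data error. Per-patient cost
evaluates the cumulative yearly claims stream, linearly interpolated
within years, at the first of death / spontaneous MI / unplanned
revascularization / censoring / horizon.

Kaplan–Meier cumulative incidence (1 − product-limit survival) treats
death as censoring for non-fatal events, matching the source's
event-specific analyses (not a competing-risks estimator). Cox
proportional-hazards fits use lifelines (`CoxPHFitter`, Breslow ties,
Newton precision tightened to 1e−9); the test suite cross-checks the
coefficient against brute-force maximization of a hand-written partial
likelihood on a 4-subject worked example. Age enters as the binary ≥70
flag (continuous age is not generated).

Bootstrap: whole patients are resampled with replacement from the pooled
cohort — keeping each patient's cost and QALY paired and letting arm
sizes vary binomially — ΔC and ΔE are recomputed per replicate, and
2.5/97.5 percentiles are reported (percentile method; default 1,000
replicates in the CLI, configurable). Replicates that leave an arm empty
are redrawn. No multiplicity adjustment is applied to subgroup analyses,
which report raw estimates.

## 4. Synthetic claims cohort

The generator emulates the *structure* of a nationwide PCI claims cohort
so the patient-level stage is fully testable without access to the real
(non-downloadable) claims database:

- arm assignment Bernoulli(`p_ffr = 0.038`), the observed FFR penetration;
- twelve independent Bernoulli comorbidity/demographic flags at the
  cohort's reported prevalences (e.g. hypertension 0.717, diabetes 0.493,
  stable presentation 0.516, female 0.341; `age_ge_70 = 0.38` from a
  normal approximation to the reported age distribution, 66.8 ± 10.3 y);
- event times for death, spontaneous MI and unplanned revascularization
  as independent exponentials with hazard
  `baseline × exp(arm effect + covariate effects)`; baselines calibrated
  from the angiography arm's 4-year cumulative incidences (7.7% death,
  2.2% MI, 15.2% revascularization) via `r = −ln(1−P₄)/4`; arm log-HRs
  `ln(0.798)`, `ln(0.751)`, `ln(0.996)`; covariate effects default to 0
  so regression-adjustment tests can inject known confounding;
- uniform accrual over 7 years with an administrative end at year 8
  (censor time = 8 − entry), the study's enrollment/follow-up window;
- costs: constant accrual of $1,483/year over observed follow-up, lump
  sums at observed events ($1,483 MI, $1,473 revascularization, $6,441
  death) and the $194 FFR add-on at time zero in the FFR arm, discretized
  to cumulative yearly buckets. Only observed events are recorded (no MI
  after death or censoring), as in real claims.

Default size is 20,000 patients — large enough for stable arm contrasts
at the default allocation while keeping test runtimes in seconds; the
estimator-recovery checks use larger, balanced-arm cohorts (up to 300,000
per arm in the acceptance script) to shrink product-limit Monte-Carlo
error below 0.1 percentage points.

**What passing tests show, and what they don't.** The recovery loop
(generator → Kaplan–Meier / Cox → configured values) validates the
estimators and the pipeline plumbing, not the clinical findings: real
claims have correlated comorbidities, non-constant hazards, informative
censoring and loss to follow-up, accrual that is not uniform (the real
median follow-up was 3.0 years; the uniform-accrual synthetic design
gives ≈4.2), and cost dynamics far richer than constant accrual plus
lumps. In particular, the real cohort's *negative* incremental cost for
FFR-guided PCI is not reproduced by the synthetic cost process — longer
FFR-arm survival accrues more annual cost than the (small, Korean-scale)
event lumps save — so patient-level tests assert the effect direction
(ΔE > 0) and interval behavior, not the cost sign. Note also that the
FFR arm's implied 4-year incidences under the calibrated HRs (6.2% death,
1.66% MI) differ slightly from the observed 5.8%/1.6%, because the
published HRs are covariate-adjusted while the observed incidences are
crude.

## 5. Numerical choices and degenerate inputs

- State-occupancy conservation and row-stochasticity are asserted at
  1e−12; the cohort iteration is property-tested against matrix-power
  evolution on random valid matrices.
- Probability↔rate conversions use `log1p`/`expm1` and round-trip to
  1e−12 over p ∈ [0, 0.99].
- `ICER` is `None` (undefined) when ΔE = 0; decisions use NMB, which is
  well-defined everywhere. Negative ICERs are reported as computed but
  always alongside the dominance class.
- A beta distribution cannot match `se² ≥ mean(1−mean)`; such requests
  raise rather than clip.
- Seeds: every stochastic routine takes an explicit integer seed;
  PSA substreams are name-keyed as described above.

## 6. Problem sizes used in the shipped checks

Markov stages are exact and instantaneous. The default test suite uses
25,000 PSA draws, a 200,000-patient balanced cohort for product-limit
recovery, 100 seeded 20,000-patient cohorts for Cox coverage, and
1,000-replicate bootstraps; the full suite runs in about a minute on one
core, and `scripts/acceptance.py` (600,000 patients) in a few seconds.
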