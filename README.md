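# ffrcea

Cost-effectiveness analysis of **fractional flow reserve (FFR)-guided
percutaneous coronary intervention (PCI)** versus angiography-guided PCI
in patients with stable or unstable angina.

FFR is a pressure-wire index measured during invasive angiography that
identifies whether a coronary stenosis actually causes ischemia; guiding
stenting by FFR improves lesion selection but adds procedural cost. This
package provides a tested, reusable implementation of the standard
health-economic toolchain for that question, aimed at health-economics and
clinical-epidemiology researchers:

1. **Markov cohort model** (`ffrcea.markov`) — a 3-state
   (angina / spontaneous MI / death) annual-cycle state-transition model
   that accrues discounted costs and quality-adjusted life-years (QALYs)
   over a 10-year horizon, parameterized for the Korean, US, and UK health
   systems (`ffrcea.model_inputs`, bundled JSON configs).
2. **Probabilistic sensitivity analysis** (`ffrcea.psa`) — Monte-Carlo
   propagation of parameter uncertainty (lognormal transition
   probabilities / hazard ratios, beta utilities, gamma costs) with
   cost-effectiveness acceptability curves (`ffrcea.economics`).
3. **Patient-level CEA** (`ffrcea.patient_level`) — per-patient QALY and
   cumulative-cost computation on claims-style cohorts over a 4-year
   horizon, Kaplan–Meier cumulative incidence, multivariable Cox
   regression, and percentile-bootstrap incremental cost-effectiveness —
   exercised on synthetic claims cohorts from `ffrcea.synthetic`, which
   emulates a nationwide PCI claims cohort (exponential event times under
   proportional hazards, administrative censoring from an accrual window,
   yearly cost streams).

## The economics in brief

For two strategies, with per-patient mean cost `C` and effectiveness `E`
(QALYs), the comparison reports

- incremental cost and effect: `ΔC = C_FFR − C_angio`, `ΔE = E_FFR − E_angio`;
- the incremental cost-effectiveness ratio `ICER = ΔC / ΔE`;
- net monetary benefit at a willingness-to-pay threshold λ:
  `NMB = λ·ΔE − ΔC` (cost-effective when `NMB > 0`);
- a dominance class (*dominant* = cheaper and more effective).

QALYs accumulate utility-weighted person-time: `Σ_t d(t) · (a_t·u_angina +
m_t·u_MI)` where `a_t, m_t` are state occupancies and `d(t) = (1+r)^−t`
discounts at annual rate `r`.

## Worked example

```bash
ffrcea run-markov --config korea --out out/markov
```

prints (and writes to `out/markov/comparison.json`):

```json
{
  "delta_cost": 374.92325627842365,
  "delta_qaly": 0.2853463881955731,
  "icer": 1313.923258847964,
  "dominance": "tradeoff_more_costly_more_effective",
  "cost_effective_at_wtp": true,
  "nmb": 8185.46838958877,
  "wtp": 30000
}
```

Under the Korean parameterization, FFR-guided PCI gains 0.29 discounted
QALYs over 10 years (4.89 vs 4.60 per patient, driven by roughly 7
percentage points lower 10-year mortality and 2.3 points fewer incident
MIs). With the bundled per-state cost inputs it costs $375 more per
patient, giving an ICER of about $1,314 per QALY — far below the $30,000
threshold, so the strategy is cost-effective (NMB ≈ $8,185). Note the cost
side depends strongly on which cost components the input set carries; see
`docs/methods.md`.

The same comparison under parameter uncertainty:

```bash
ffrcea run-psa --config korea --n-iterations 25000 --seed 1 --out out/psa
```

reports `"probability_cost_effective": 0.95568` at λ = $30,000 together
with 95% percentile intervals for ΔC, ΔE and NMB, and writes the CE-plane
cloud (`ce_plane.csv`) and acceptability curve (`ceac.csv`).

A full synthetic patient-level run (cohort generation → bootstrap CEA →
subgroup tables):

```bash
ffrcea simulate-cea --n-patients 20000 --n-boot 1000 --seed 7 --out out/sim
```

## Library use

```python
import ffrcea

korea = ffrcea.load_bundled_config("korea")
angio, ffr, comparison = ffrcea.compare_arms(korea)

cohort = ffrcea.generate_cohort(ffrcea.default_config(seed=1))
result = ffrcea.bootstrap_icer(cohort, korea.utilities, horizon=4.0,
                               n_boot=1000, seed=2)
```

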