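# Methods

## Model structure

The aggregate model tracks three stocks in continuous time (unit: months):

| stock | symbol | range | meaning |
|---|---|---|---|
| trained staff | *T* | [0, N] | people involved in discharges who are trained on the score |
| perceived evidence | *E* | ≥ 0 | smoothed avoided-readmission rate staff have had time to notice (persons/month) |
| individual interest | *i* | [0, 1] | fraction of discharges at which a trained person actually looks at the score |

Auxiliaries, evaluated instantaneously from the state:

```
L  = (T/N) · i                                   likelihood of red-alert use
V  = L · min(f_flag, f_readmit) · D · e          readmission avoidance rate
R  = f_readmit · D − V                           residual readmission rate
P  = max(0, (R/D − g) / g)                       simplified CMS penalty
I  = min(1, P / P0) / A                          institutional interest
S  = min(1, E / E_req)                           perceived success
u  = clamp(I + w_team · L · S, 0, 1)             training drive
```

and the state equations

```
dT/dt = u · (N − T) / τ_train  −  k · T
dE/dt = (V − E) / τ_evidence
di/dt = (clamp(w_ext · I + w_int · S, 0, 1) − i) / τ_interest
```

`P0` is the penalty at the cold start, so baseline runs begin at full
institutional interest diluted only by the attention-to-conflicting-
priorities divisor `A ≥ 1`. Headcount is constant: departures (rate `k·T`)
are replaced immediately by untrained hires, which is why training never
quite closes the gap while `k > 0`.

Only true-positive alerts can avert a readmission, hence the
`min(f_flag, f_readmit)` factor: over-flagging adds alerts but no avoidable
readmissions, and the avoidance rate can never exceed the normal
readmission rate. In the best case (`L = 1`, `f_flag = f_readmit` with no
false positives, `e = 1`) residual readmissions are exactly zero.

Modeling choices where the design was genuinely open:

* the attention fraction inside `L` is identified with the individual
  interest stock — the two are conceptually distinct but move together,
  and a single stock keeps the model minimal;
* institutional interest is normalized by the initial penalty, the only
  scale available inside the model, so a high initial readmission rate
  relative to the goal yields full initial interest;
* the Team Use loop enters as one interpretable knob: an additive
  `w_team · L · S` term buoying the training drive;
* perceived evidence is first-order smoothing of the avoidance rate
  because staff rarely see immediately which readmissions they prevented;
* the penalty is the fractional excess of the readmission fraction over
  the goal — a deliberate simplification of the DRG-based, risk-adjusted
  HRRP formula, which is out of scope.

## Parameters

| name | default | units | why |
|---|---|---|---|
| `n_staff` | 100 | persons | order of a large service's discharge workforce; round number |
| `discharge_rate` | 300 | persons/month | ~10 discharges/day for one service line of a large hospital |
| `normal_readmission_fraction` | 0.15 | — | typical unplanned-readmission fraction for high-acuity medicine |
| `cms_goal_fraction` | 0.10 | — | benchmark below baseline, giving initial penalty `P0 = 0.5` |
| `turnover_fraction` | 0.01 | 1/month | low turnover condition |
| `training_time` | 1 | months | quick training condition |
| `attention_conflicting_priorities` | 1 | — | baseline: no competing demands; raised to 5 in scenarios 2–3 |
| `required_evidence` | 100 | persons/month | weak-reinforcement baseline; lowered to 3.5 in scenario 3 |
| `fraction_flagged` | 0.15 | — | alerts match the normal readmission rate, no false positives |
| `effectiveness` | 1 | — | interventions fully effective in the favorable baseline |
| `evidence_smoothing_time` | 3 | months | perception delay: a quarter to notice a trend |
| `interest_adjustment_time` | 3 | months | attitudes adjust over a quarter |
| `team_pressure_weight` | 0.5 | — | internal pressure buoys but does not dominate training |
| `external_interest_weight`, `internal_interest_weight` | 1, 1 | — | external and internal drivers weighted equally |
| `dt` | 1/128 | months | see numerics |
| `horizon` | 60 | months | long enough for every scenario to be near steady state |

The scenario presets change exactly one parameter at a time:
`conflicting-priorities` raises `A` from 1 to 5; `reinforced` additionally
lowers `required_evidence` from 100 to 3.5 persons/month (it builds on the
previous run, so `A = 5` is carried over).

## Numerics

Integration is fixed-step forward Euler, the convention of desktop
system-dynamics tools, with stocks clamped to their physical ranges after
each step; any excursion beyond 1e-9 of a variable's scale raises instead
of being silently clamped. The default step is `dt = 1/128` month: the
first month of a cold-start run is a steep transient (the training drive
starts saturated), and coarser conventional steps (1/16 month) leave a
~2.4% dt-halving drift in the readmission fraction, while 1/128 brings the
worst-case drift to ~0.26% of each variable's range, comfortably inside
the 0.5% tolerance the test suite enforces. A 120-month run settles to a
fixed point that matches an independent root solve of the derivative field
to ~1e-11 relative; the test tolerance is 1%.

Ties and degenerate inputs: `cms_goal_fraction = 0`, `required_evidence =
0` and `n_staff = 0` are rejected rather than special-cased;
`turnover_fraction = 0` is legal (training then converges to full staff
and stays). The behavior-mode classifier uses a noise band of 0.1% of a
series' range, making labels invariant to uniform rescaling; series are
labeled from the sign pattern of first differences, with a flat final
tenth distinguishing settling from ongoing motion.

## The stochastic micro-simulator

`microsim.simulate_cohort` emulates monthly hospital event streams with
exactly the statistical structure the aggregate equations assume:
discharges ~ Poisson(D); would-be readmissions ~ Binomial(discharges,
f_readmit); true-positive flags a Binomial thinning (all of them under
perfect flagging); attention ~ Binomial(true positives, L); avoidance ~
Binomial(attended, e). Training and turnover are Binomial over the
untrained/trained pools with per-month probabilities `1 − exp(−u/τ_train)`
and `1 − exp(−k)`, the survival-probability conversion appropriate for a
1-month step. Evidence and interest update monthly from the realized
counts with the aggregate formulas.

Two deliberate choices:

* **The institutional penalty responds to the systematic readmission rate**
  (the state-implied expectation `f_readmit·(1 − p_tp·L·e)`), not to the
  single-month realized fraction. CMS penalties are computed over
  multi-year windows, so month-to-month sampling noise should not move
  institutional interest; feeding the noisy monthly fraction through the
  kinked `min(1, P/P0)` would also bias the mean drive well below the
  aggregate model's (a Jensen effect at the clamp).
* **Cross-validation compares replicate means to the month-grid
  expectation map** (`expected_cohort`): the identical monthly update
  applied to expected counts. This isolates Monte-Carlo error from time
  discretization; the month grid's agreement with the continuous model is
  covered separately by the dt-halving and fixed-point tests.

The agreement statistic is the maximum over months of
`|mean − expected| / SE` per tracked variable (readmissions, avoidance,
trained headcount), with 200 replicates in the acceptance test. Note this
is a max over ~60 near-independent month statistics, so even a perfectly
unbiased simulator exceeds 3 for a minority of seeds by multiple-comparison
chance; the test fixes its seed for reproducibility.

What the generator does *not* emulate: patient covariates and risk-score
distributions, length-of-stay dynamics, seasonal census variation,
non-stationary staffing, or correlated attention across discharges.
Passing tests therefore show the aggregate equations are internally
consistent with their own probabilistic assumptions — not that the model
is calibrated to any real hospital.

## Known limitations

* The causal-loop fixture is a reconstruction: the minimal link set
  consistent with the four named loops; additional minor arrows in the
  original whiteboard diagram may be missing.
* All parameter defaults marked "why: realistic order" above are scenario
  conditions, not estimates; the model is a logic probe, not a forecast.
* Loop-dominance-over-time analysis, calibration to hospital data and
  optimization over intervention levers are out of scope.
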