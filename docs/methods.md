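# Methods

## Patient-flow model

The simulator is a terminating discrete-event model of one working day
of an emergency department, opened empty.  Entities are patients;
resources are five pools — community health workers (CHW), receptionists,
nurses, cardiologists, beds — with integer capacities, the decision
vector X₁..X₅.

**Arrivals.** Homogeneous Poisson over the working day: with
`arrival_rate` R patients/day and `day_length` T minutes, interarrival
times are Exp(T/R).  Time-of-day variation is deliberately out of scope.

**Triage and routing.** Each arrival draws an ESI level from the
configured mix and follows a fixed path:

| ESI | path (stage → pools seized) |
|-----|------------------------------|
| 1 | resuscitation (cardiologist + bed; service = ECG + CPR draws) → on success chest-pain unit (bed); on failure the journey ends (`died_cpr`, default success 0.7) |
| 2 | nurse assessment (nurse) → registration (receptionist + CHW) → chest-pain unit (bed + cardiologist) |
| 3–4 | registration (receptionist + CHW) → ICU handoff (bed + nurse) |
| 5 | registration (receptionist + CHW) → GP visit (no pooled resource) → discharge |

Beds are held for the whole chest-pain-unit / ICU-handoff stay;
clinicians are released at service end.  The ECG has no station of its
own: it is part of the resuscitation stage's service time.  Cardiac
status is sampled per patient (default 40 %) and recorded on the event
log; routing is driven by ESI alone.

**Queue discipline.** Non-preemptive priority: lower ESI first, FIFO
within a level, ties by arrival time then patient id.  A stage starts
only when *all* its pools have a free unit.  Allocation is greedy in
priority order: when the highest-priority request is blocked on one
pool, a lower-priority request whose pools are all free may start.  The
alternative (strict head-of-line blocking) idles resources a real
charge nurse would use; greediness is the behaviour we want to emulate.

**Close-out.** Arrivals stop at T.  By default the day is *flushed*:
patients already admitted are served out, and the response is the mean
total queueing delay (service time excluded) over the entire cohort.  A
`censor` mode instead stops the clock at T and excludes unfinished
journeys from the mean.  Flushing is the default because the censored
estimator is selection-biased under heavy load: adding capacity lets
long-waiting patients finish before close and thereby *enter* the mean,
which can push the censored mean the wrong way even when every
individual waits less.  We verified this on the bed factor at the lower
staffing bounds: with synchronized streams the accumulated waiting time
fell in 30 of 30 paired days when beds went from 5 to 10, while the
censored mean rose slightly.  Utilization is busy-server time divided by
capacity × horizon (horizon = last event time under flushing).

**Randomness.** One root seed; the arrival stream and each patient
(ESI, cardiac flag, every service draw, CPR outcome) get private
substreams keyed by patient index.  Identical seeds therefore give
bit-identical runs, and two configurations sharing a seed see the same
patients with the same demands — full common-random-number
synchronization, used by the experiment runner's CRN mode and by the
paired monotonicity tests.

## Default study conditions

The generator's defaults are the study workload: 145 patients/day
(~52,000/year), ESI mix (0.05, 0.15, 0.30, 0.30, 0.20), 40 % cardiac,
24 h day.  Real per-activity service distributions for such departments
are rarely published; the defaults are exponential with means (minutes)

| activity | mean | | activity | mean |
|---|---|---|---|---|
| registration | 13 | | GP visit | 12 |
| nurse assessment | 10 | | chest-pain-unit stay | 90 |
| ECG | 6 | | ICU handoff | 14 |
| CPR | 15 | | | |

chosen by load arithmetic so that the *current* staffing (1, 2, 3, 1, 7)
is congested: registration demand ≈ 0.096/min gives the single CHW an
offered load ≈ 1.24, and 90-minute unit stays give the single
cardiologist ≈ 1.4 — mean waits on the order of hours, the regime the
method is meant for.  All of this lives in the YAML configuration, not
in code.

What the generator does *not* emulate: time-varying arrivals, balking or
reneging, ambulance diversion, shift schedules, and correlated or
heavy-tailed service times.  Passing tests show the pipeline recovers
the structure of *this* stochastic model; they do not certify any real
department's parameters.

## Experiment design and metamodel

The 2⁵ full factorial (standard Yates order, first factor alternating
fastest) codes each factor to ±1 via x = (X − (L+U)/2)/((U−L)/2) with
the study bounds L = (1,1,1,1,5), U = (2,3,6,3,10).  Per-cell seeds are
a pure function of (master seed, row, replicate); default 10 replicates
per design point, cell response = replicate mean.  The analysis uses one
response per run (the cell mean), the classical factorial layout with
n = 32.

The surface is multilinear with interactions up to order three
(quadratics are not estimable in a two-level design without center
points, and none are included).  Least squares on the coded design; on a
balanced orthogonal design the implementation additionally verifies the
contrast-average identity bⱼ = (1/n) Σ xᵢⱼ yᵢ and refuses to continue if
it fails.  Diagnostics follow standard response-surface practice:

- per-term SS = n bⱼ², F = SS/MS_res with MS_res = SS_res/(n − p′),
  p from F(1, n − p′); shared SE = √(MS_res/n);
- adjusted R² = 1 − (1 − R²)(n − 1)/(n − p′);
- PRESS by the leverage identity Σ (eᵢ/(1 − hᵢᵢ))², which on a balanced
  orthogonal design collapses to SS_res/(1 − p′/n)² — both paths are
  computed and must agree;
- adequate precision = (max ŷ − min ŷ)/√(p′·MS_res/n).  Published
  variants of this statistic differ; this standard signal-to-noise form
  is the one implemented and the one reproduced by
  `summary_reconstruction`.

With zero residual degrees of freedom the diagnostics are reported as
undefined, never fabricated.  In the exact-fit limit (MS_res = 0) a term
counts as active only if its SS exceeds 10⁻²⁰ × total SS, so numerical
noise in a perfectly interpolated surface cannot masquerade as
significance.

**Reduction.** Retained set = {terms with p < α} ∪ forced terms ∪
intercept, refit on the coded design (orthogonality leaves the retained
coefficients unchanged; the residual pools the dropped SS).  The frozen
reference panel in `edsimopt.reference` reduces, at α = 0.05 with the
X₂, X₃, X₄ mains forced, to exactly the nine-term reference surface.
One discrepancy in the source material is preserved deliberately: the
reference ANOVA panel lists the X₃X₅ estimate as +0.081 while the
reduced equation carries −0.081; the frozen model follows the equation,
since that is the surface the optimization used.  An order-selection
helper fits orders 1–3 and picks the lowest whose whole-model F has
p < α.

## Optimization

min Ŷ(x) over integer Lᵢ ≤ Xᵢ ≤ Uᵢ with Σ CᵢXᵢ ≤ B, solved by
exhaustive enumeration of the lattice (648 points at the study bounds) —
a multilinear surface is affine in each coordinate, so the
unconstrained minimum sits at a vertex, but enumeration also handles
budget-truncated lattices exactly.  Ties on predicted value break by
lower cost, then lexicographic order; equal-value configurations are
reported (tolerance 10⁻⁹ on the response scale).  The default budget is
the cost of the current staffing.  Unit costs are relative; the
reference dollar totals are not derivable from them under any single
scale factor, so dollar figures are a separate configurable table and no
result depends on them.

## Pipeline and reproducibility

`run_pipeline` chains the stages, derives all seeds from one master
seed, and writes every artifact (CSV/JSON/JSON-lines) plus a seed
manifest; identical configurations reproduce the artifact set byte for
byte.  Wall-clock stage timings go to `timings.json`, kept outside the
deterministic set on purpose.  The validation stage re-simulates the
recommended staffing with fresh seeds and reports the simulated-minus-
predicted gap; the surface is a surrogate and is only trusted where the
simulator confirms it.

Problem sizes used by the test suite and the reproduction script: 2⁵
designs with 10 replicates (2–3 for the fast pipeline tests), 200
Monte-Carlo repeats for coefficient-recovery checks, 50 randomized
problems for the optimizer-vs-brute-force oracle, and 50,000 arrivals
for the Erlang-C (M/M/c) single-station agreement check at utilization
0.83, where the simulated mean delay matches the closed form to well
under 5 %.

## Known limitations

- Exponential service defaults understate variability in some real
  activities (boarding, imaging); the config accepts uniform and
  deterministic families, but not yet lognormal/gamma.
- The censored close-out is kept for comparability but its mean is
  biased under overload (see above); prefer the default flush mode.
- The metamodel is first-order in each factor; strong curvature inside
  the box (as opposed to at its corners) needs center points or a
  higher-order design, which the two-level factorial cannot detect.
- The optimizer treats the fitted surface as exact; it propagates no
  simulation uncertainty into the argmin.
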