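# Methods

## The multi-state model

The analysis treats the course of aplastic anaemia after first-line IST
as a time-inhomogeneous Markov multi-state process on a single clock,
time since IST start, measured in days (fractional days are allowed;
months are a reporting unit only, 1 month = 365.25/12 days). The default
structure has eight states and 18 transitions; it is fully configuration
driven (`build_transition_structure`), so an alternative reading of the
state diagram — e.g. removing the direct relapse arrow out of the
therapy-free state or the post-transplant relapse arrow — is a config
change, not a code change. Absorbing states (death after alloSCT,
AML/MDS treatment, death without alloSCT/AML/MDS) have out-degree zero by
validation.

### State derivation from raw events

`derive_state_path` is deterministic and uses only the event log:

* entry into "transfusion-independent with therapy" at
  (last transfusion before a ≥28-day transfusion-free run) + 28 days;
  the qualification window is credited at its end, never back-dated;
* entry into "free of transfusion and therapy" at (therapy stop) + 14
  days, provided neither a transfusion nor a therapy restart falls in
  that window;
* a transfusion while transfusion-independent returns the patient to the
  dependent state on the transfusion day; a therapy restart returns a
  therapy-free patient to the on-therapy state on the restart day;
* alloSCT, AML/MDS treatment and death override any pending window-based
  promotion (strict comparison: an event on the exact promotion day
  cancels the promotion);
* same-day events resolve with priority death > AML/MDS > alloSCT >
  transfusion > therapy change;
* after alloSCT the 28-day transfusion rule applies between the
  post-transplant states; therapy status is not tracked post-transplant.

Two situations the endpoint rules do not determine are resolved by
convention and flagged in the run log when they occur: a patient whose
therapy stopped before the transfusion-free window completed enters the
on-therapy state at the transfusion-rule time and the therapy-free state
one day later (the model has no direct arrow from transfusion-dependent
to therapy-free, and zero-length sojourns are disallowed); a
transfusion-independent patient with no recorded therapy at all is
fast-tracked the same way. A relapse out of the therapy-free state is
interpreted as simultaneous therapy restart, since the only arrow out of
the transfusion-dependent state towards recovery leads to the on-therapy
state.

### Long-format expansion

Each sojourn in a non-absorbing state g on (t0, t1] emits one
counting-process row per arrow g→h with `status = 1` on the arrow taken
(all zero on a censored final sojourn), visits numbered per patient.
Intervals are half-open, (Tstart, Tstop]: events at Tstop belong to the
row, and an event tied with a censoring time counts first. All rows stay
on the since-IST clock (clock-forward), including post-transplant ones,
matching a single time-inhomogeneous model.

## Estimation

**Nelson–Aalen / Aalen–Johansen.** Per-transition increments
dA = dN/Y with Aalen (Poisson-type) increment variance dN/Y² — standard
in the multi-state literature and simpler to propagate than Greenwood.
The product integral P(s,t) = ∏(I + dA(u)) is accumulated over the union
of event times; tied increments of different transitions share one
factor. The occupation-vector covariance follows the delta-method
recursion Σ(t) = F'Σ(t−)F + D(t), F = I + dA(t), where D(t) collects the
increment variances weighted by the squared pre-update occupation
probabilities (independent increments across source states; within a
source state, cov(dA_gh, dA_gg) = −dN_gh/Y²). Confidence intervals for
occupation probabilities and their sums are Wald on the probability
scale, truncated to [0,1]: log-type transforms do not add across states,
and combined-state intervals need the plain-scale covariance block.
Kaplan–Meier (overall survival; log(−log) intervals via lifelines) and
the reverse Kaplan–Meier follow-up distribution are thin front-ends.
Competing-risks cumulative incidences are computed as absorbing-state
occupations of a star-shaped structure through the same product
integral, which makes Σ_k CIF_k + KM = 1 hold identically.

**Transition-specific Cox models.** Breslow partial likelihood on the
counting-process rows, maximised by Newton–Raphson with step-halving;
ties are handled by Breslow for consistency with the Breslow baseline
A₀(t) = Σ d(t)/Σ_risk exp(β'Z), which reduces exactly to Nelson–Aalen for
the null model. The gradient is a sum over events, so the convergence
tolerance scales with the event count (sup-norm < 1e-8 · max(1, events);
an absolute 1e-8 is below the floating-point noise floor of risk-set
sums on 10⁵-row cohorts). Monotone likelihood (no events, perfect
separation) and non-convergence within 50 iterations raise explicit
errors. Three presets mirror the registry analysis: M1 (response
transition; PNH ≥1%, age 40–59/60+ vs 18–39, SAA/VSAA vs NSAA), M2
(therapy-stop transition; same covariates), M3 (the three death
transitions pooled with a *common* baseline and no from-state effect;
age 60+ vs 18–59). Complete-case exclusion is per model: records with
missing PNH status drop from M1/M2 but stay in M3. All other transitions
carry no covariate model and enter predictions non-parametrically,
shared across profiles.

**Reference-patient prognosis.** For a covariate profile Z, modelled
transitions use A₀(t)·exp(β'Z) and unmodelled ones their Nelson–Aalen
hazards; the product integral of these profile hazards gives the
model-based occupation trajectory (18 profiles: 3 ages × 3 severities ×
2 PNH levels). In sparse tails a scaled baseline increment can push a
row's total exit mass above 1; the row is then renormalised to exit mass
1 (this clamp applies only to model-based prediction — for data-based
hazards the condition is impossible and treated as a data anomaly).
Uncertainty comes from a nonparametric bootstrap over patients (default
B = 500): resample, re-expand, refit all models, recompute the profile
trajectory; percentile 2.5/97.5 bands at the horizon; non-convergent
resamples are redrawn and counted, with an error above a 20% failure
rate. Bootstrap was chosen over asymptotic formulas because its coverage
is directly verifiable by simulation.

## The synthetic registry generator

The generator reproduces the statistical structure the estimators
assume: covariates drawn from the registry marginals (age bands
28/30/42%; severity NSAA/SAA/VSAA 33/43/24%; PNH ≥1% 45% with 15/127
missing completely at random; 64% male); a clock-forward multi-state
process with piecewise-constant baseline intensities; multiplicative
covariate effects — by default the registry-estimated hazard ratios
(2.19 for PNH ≥1%, 0.41/0.43 for age, 0.42/0.46 for severity on the
response transition; 7.28 for age 60+ on the pooled death transitions,
zero elsewhere); and administrative censoring from uniform accrual over
9 years with a 10-year cutoff. Default baseline rates are chosen to give
registry-like dynamics — most responses within the first year, therapy
stops mainly from the second year on, non-negligible relapse/restart
flows, low but age-sensitive mortality, a post-transplant pathway with
realistic early mortality — with no claim of quantitative calibration to
the non-public registry timing. 144 patients are generated with exactly
17 flagged as Eltrombopag-containing first-line treatment; the cohort
filter removes them.

One deliberate deviation from a pure Markov process: promotion hazards
carry a refractory window after state entry (28 days for the two
transfusion-independence transitions, 14 days for therapy freedom),
during which they are zero. A pure clock-forward process could place a
re-response 10 days after a relapse, which no event log can represent —
transfusion independence is *defined* by 28 transfusion-free days. The
windows are the registry's own logical constraint; they affect only
short intervals after (re-)entry, and measured hazard-ratio recovery on
gated cohorts stays within a few percent of the generator values. The
back-filled event logs (a transfusion 28 days before each independence
entry plus routine transfusions every 10 days while dependent, a therapy
stop 14 days before each therapy-free entry, transfusions/restarts on
relapse days, failure events at their transition days) reproduce the
latent paths exactly — a round-trip property tested on every simulated
cohort. A `clock_reset` switch turns the baselines semi-Markov (sojourn
clock) for robustness experiments; it is off by default. `apply_gates=False`
gives the exact ungated Markov process for oracle comparisons (its paths
cannot be back-filled).

`true_occupation_probabilities` provides the exact solution of the
ungated process by chaining matrix exponentials of the profile-specific
intensity matrix over its constant pieces; it is validated against an
independent ODE integration of the forward equations to 1e-8.

## Validation design and problem sizes

* Exact identities (machine precision): two-state Aalen–Johansen =
  Kaplan–Meier; null-model Breslow baseline = Nelson–Aalen; CIFs +
  survival = 1; occupation rows sum to 1.
* Cross-checks: coefficients vs lifelines' time-varying Cox fit (agree
  to ~1e-9 on tie-free data) and vs a Nelder–Mead maximisation of the
  same partial likelihood on a ≤20-row fixture (1e-4).
* Consistency: Aalen–Johansen vs matrix-exponential truth on an ungated
  constant-hazard cohort of n = 10,000, sup-norm ≤ 0.01. The sup-norm of
  a nonparametric curve has Monte-Carlo scale ≈ 1.36/√n when a curve
  crosses mid-range probabilities, so the comparison uses a
  low-intensity configuration (all 18 arrows active, occupation curves
  bounded away from 0.5) for which that scale sits well below the
  tolerance; error decrease is additionally checked over n ∈ {250,
  1000, 4000}.
* Parameter recovery: n = 20,000 gated cohort with default effects, no
  censoring before 120 months; M1 hazard ratios within 10% and the M3
  ratio within 15% of the generator values.
* Round-trip: event-log derivation reproduces all latent paths at
  n = 10,000.
* Bootstrap coverage: 25 simulated registries (n = 500, B = 100); the
  95% band for the reference patient's 5-year TT-DFS must cover the
  truth (a 150,000-path simulation of a profile-degenerate cohort) in
  ≥ 85% of runs. Sizes are scaled to keep the default suite around two
  minutes; delta-method standard errors are separately checked against a
  200-resample bootstrap (ratio within [0.7, 1.4]).

## What the synthetic data do and do not show

Passing tests demonstrate that the estimators are correct for the
process class they assume (Markov on the study clock, independent
administrative censoring, proportional covariate effects, missingness
completely at random). Real registry data can violate each assumption:
sojourn-time dependence (semi-Markov effects), event-dependent
censoring, non-proportional hazards, informative missingness of PNH
status, and calendar-time drift in treatment practice. Parameter
recovery on synthetic cohorts therefore validates the software, not the
clinical conclusions; analyses of real data should add
proportional-hazards diagnostics, which are out of scope here.

## Known limitations

* The AML/MDS-treatment state is absorbing, so deaths after it are
  outside the model; the model-internal "alive" curve can overstate
  mortality-adjusted survival, and Kaplan–Meier OS is reported as the
  headline survival estimate.
* Left truncation beyond the long-format Tstart handling, interval
  censoring, time-dependent covariates other than the state process,
  frailty terms and Fine–Gray regression are not implemented.
* The delta-method occupation covariance assumes independent increments;
  for very small risk sets the Wald intervals can be anti-conservative —
  the bootstrap path is the recommended alternative there.
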