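# Methods

`predinc` quantifies how much a candidate marker improves a risk-prediction
model, and — more importantly — how far the usual confidence intervals for
those improvement measures can be trusted. This note records the models,
estimators, numerical choices and their limitations.

## Measures of prediction increment

Let the *standard* model predict the event from an established marker x1 and
the *expanded* model add one candidate marker, with per-subject predicted
event probabilities p_old and p_new.

**Binary framework** (logistic regression, full follow-up):

- **ΔAUC** — difference of Mann–Whitney C-statistics,
  C = (1/n0 n1) Σ [1{risk_ne < risk_ev} + ½·1{tie}]. The standard error is
  DeLong's structural-component estimate: per-subject placement values
  V10 (events) and V01 (nonevents) for each model, with
  Var(ΔAUC) = Var(V10,new − V10,old)/n1 + Var(V01,new − V01,old)/n0
  (sample variances, n−1 divisor). Placements are computed via midranks in
  O(n log n); a brute-force enumeration oracle pins both value and SE in
  the tests.
- **Categorical NRI** — events and nonevents are cross-tabulated by risk
  category under the old and new model (half-open bands [low, high)):
  NRI = (p̂_up,1 − p̂_down,1) + (p̂_down,0 − p̂_up,0) = eNRI + neNRI, with
  SE(eNRI)² = (p̂_up,1 + p̂_down,1)/n1 − (p̂_up,1 − p̂_down,1)²/n1 and the
  class components combined in quadrature. Both components are always
  reported alongside the sum: a favourable NRI can hide a harmful move in
  one class. Default bands: the event rate as the single 2-category cutoff;
  (0.05, 0.20) and (0.40, 0.60) as the 3-category bands for 10% and 50%
  event rates.
- **Continuous NRI (NRI > 0)** — same algebra on strict increases and
  decreases of p_new vs p_old; exact ties count as neither direction.
- **IDI** — difference of discrimination slopes,
  (mean p_new − mean p_old | events) − (mean p_new − mean p_old | nonevents);
  SE from the within-class paired differences (sample variance, n−1
  divisor — the divisor is a package choice, not prescribed).

**Survival framework** (Cox regression at a fixed horizon τ = 10 years):

- **ΔC** — difference of Harrell's overall C over *usable pairs*: the two
  observed times must differ and the smaller one must be an event (a pair
  censored before the other subject's event cannot be ordered); the pair is
  concordant when the shorter-lived subject carries the higher predicted
  risk, with ½ credit for prediction ties. The tie conventions matter only
  on sets of measure zero under the continuous generator. The estimator is
  an O(n log n) Fenwick-tree count over subjects processed in decreasing
  observed-time order; a brute-force pair enumeration and an independent
  library implementation serve as oracles.
- **NRI(t)** — subjects are classified by risk movement under the expanded
  model; the event probabilities P(Y(t)=1 | up), P(Y(t)=1 | down) and the
  marginal p are Kaplan–Meier estimates within each movement subgroup, and
  NRI(t) = [(P(Y(t)=1|up) − p)·P(up) − (P(Y(t)=1|down) − p)·P(down)] / (p(1−p)),
  i.e. the equal-weight (w = 0.5) event/nonevent average doubled back onto
  the binary scale. With administrative censoring only at τ this reduces
  *exactly* to the binary NRI on event indicators (asserted in tests). A
  count-based estimator (raw indicator proportions) is provided as an
  alternative; the Kaplan–Meier form is the default. An empty movement
  subgroup contributes zero through its P(up)/P(down) weight. The weight w
  is exposed for cost-weighted variants.
- **IDI(t)** — difference of explained-variance ratios
  R²(t) = Var[S(t|Z)] / (Ŝ(t)(1 − Ŝ(t))) with Ŝ from Kaplan–Meier and the
  n−1 variance divisor. R²(t) is theoretically bounded by [0, 1]; small
  samples can exceed 1 through the n/(n−1) factor, and the value is then
  reported as computed, never silently clipped.

## Risk models

Logistic fits use Newton–Raphson on the full likelihood; Cox fits maximise
the Breslow-ties partial likelihood with the Breslow cumulative-hazard
estimator for the baseline survival at τ (ties have probability zero under
the generator; the convention is documented for user data). Convergence is
declared when the score's max-norm falls below 1e-8·n — the score is a sum
of n bounded terms, so an n-free threshold is unattainable in float64 for
mega-cohorts — with at most 100 iterations. Diverging coefficients
(|β| > 40) or a singular information matrix raise a separation error; the
bootstrap layer treats such resamples as skipped replicates rather than
redrawing them. Both fitters accept warm starts (used by the bootstrap
engine; the optimum is unchanged). They are validated coefficient-for-
coefficient against statsmodels (`Logit`, `PHReg` with Breslow ties) and
lifelines in the test suite.

Cox predicted event probabilities are 1 − S0(τ)^exp(β'x), strictly
increasing in the risk score, so measures based on ranks are identical
whether computed on probabilities or linear predictors.

## Synthetic cohorts

The binary generator draws Y ~ Bernoulli(rate) per subject (the event count
is random, not a quota) and X | Y from N(µ_Y, Σ) with µ0 = 0,
µ1 = (0.7, 0, 0.2, 0.5, 0.8), Σ = I5: x1 is the standard marker
(single-marker AUC Φ(0.7/√2) ≈ 0.690) and the candidates range from null
(x2) to strong (x5). The survival generator draws five N(0,1) covariates
with hazard ratios (2, 1, 1.2, 1.5, 2) and Weibull(shape 2) failure times
via inverse transform, U = λ(−log u / e^{β'x})^{1/2}. Censoring is either
administrative at τ = 10 (type I) or C ~ Uniform(0, c_max) followed by the
administrative cut; the uniform bound defaults to c_max = 2τ (light
censoring) because no value is prescribed — it is a configuration knob
reported in outputs, not a calibrated quantity.

The baseline scale λ solves marginal P(failure by τ) = target incidence.
Because β'X ~ N(0, ‖β‖²), the marginal incidence is a one-dimensional
Gaussian integral; it is evaluated by 80-node Gauss–Hermite quadrature and
inverted with Brent's method (closed form λ = τ/(−log(1−r))^{1/2} when all
HRs are 1). This is deterministic and accurate to the quadrature error,
which Monte-Carlo checks in the tests confirm at the 10⁵-draw scale.

Proportional hazards holds by construction in the generator, so no PH
diagnostic step is run in the simulation pipeline.

What the generator does **not** emulate: correlated predictors (Σ accepts
general PD matrices but the study grid never uses them), competing risks,
informative censoring, covariate measurement error, model miscalibration.
Passing tests therefore speak to estimator and interval behaviour under a
correctly specified model, not to robustness against those violations.

## Confidence intervals

Asymptotic intervals are θ̂ ± z_{1−α}·SE with the formulas above; they exist
only in the binary framework (no SE formulas are implemented for the
survival measures, matching their absence from the literature the measures
come from). Bootstrap intervals resample whole subjects with replacement
(unstratified by default; a stratified option guards very low event
counts), refit *both* nested models per replicate, and recompute the
measure. Replicates where a fit or measure is undefined are skipped and
logged — never redrawn, which would bias the bootstrap distribution — and a
distribution with under 95% valid replicates refuses to produce intervals.
Replicate b draws its generator from a child seed keyed by (seed, b), so
any single replicate is reproducible in isolation and results do not depend
on execution order.

Constructions, all using linear interpolation between order statistics
(Hyndman–Fan type 7; percentile/BC/BCa endpoints depend on this choice):

- **percentile** — (q_α, q_{1−α});
- **BC** — z0 = Φ⁻¹(fraction of replicates strictly below θ̂), endpoints at
  levels Φ(2z0 + z_α), Φ(2z0 + z_{1−α});
- **BCa** — adds acceleration a from the jackknife skewness formula
  (leave-one-out values supplied by the caller);
- **bootstrap-t** — pivots (θ̂*_b − θ̂)/se*_b; the inner SE is the measure's
  asymptotic formula where one exists, otherwise a grouped delete-d
  jackknife with 25 groups inside each resample (a deliberate design
  choice: the inner studentisation for measures without SE formulas is
  nowhere prescribed, and this is the largest judgment call in the package);
- **hybrid** — percentile endpoints reflected about θ̂,
  (2θ̂ − q_{1−α}, 2θ̂ − q_α).

## The coverage study

A scenario is framework × event rate (10%, 50%) × marker strength × n
(300, 2000) × censoring. Each repeat generates a fresh cohort, computes
all measures, builds the requested intervals (B = 2000 bootstrap replicates
at full scale), and scores whether each interval contains the reference
value. Coverage carries its binomial Monte-Carlo SE; the acceptable band is
the closed interval [94.0%, 96.0%].

The **reference ("true") value** is the plug-in estimate on a mega-cohort
of 10⁶ subjects drawn with a fixed internal seed — a deliberately defined
estimand, cross-checked against the binormal closed form
AUC = Φ(‖δ‖/√2) for the binary ΔAUC to five Monte-Carlo SEs. Null-marker
scenarios are the exception: there the population value of every increment
measure is exactly 0 (the expanded population model coincides with the
standard one), and the exact zero is used. The distinction matters: the
in-sample plug-in value of, e.g., IDI for a null marker is positive with
O(1/n) bias, and null-marker interval endpoints live on exactly that
scale, so the two truth conventions differ by roughly ten coverage points
in the worst cell. Each result's provenance records which convention
produced its reference value.

Repeats are independent work units keyed by spawned seeds
(master → repeat → bootstrap replicate), so results are bit-identical under
re-execution and invariant to joblib worker count.

**Problem sizes.** Full-scale runs (K = 1000 repeats, B = 2000) are cluster
work. The packaged acceptance checks run the study at desk scale —
K = 1000 for asymptotic-only cells (no bootstrap), K = 300 / B = 400 for
binary bootstrap cells, K = 200 / B = 300 for survival bootstrap cells, and
n = 10⁴ with 300 iterations for the sampling-distribution shapes — and
compare coverage within three combined Monte-Carlo standard errors of the
full-scale values. At these scales the Monte-Carlo SE of a ~95% coverage
estimate is 1.3–1.6 percentage points (2.6–2.9 points near 72%).

## Known limitations

- The survival bootstrap-t inner jackknife makes that interval ~25× the
  cost of a percentile interval on survival measures.
- BCa requires caller-supplied leave-one-out estimates (O(n) refits); it is
  practical for n = 300, expensive for n = 2000.
- Coverage conclusions are conditional on the mega-sample truth definition;
  a different estimand convention (e.g. averaging large-sample estimates)
  would shift null-marker coverage by small systematic amounts.
- The category-based NRIs are extremely discrete at n = 300 and a 10% event
  rate (≈30 events); their interval behaviour there is dominated by that
  discreteness, not by bootstrap failure.
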