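# Methods

## Model

One school is a system of n actors with a directed friendship network
x (at most 10 nominations per actor: best friend plus up to nine others)
and three ordinal behaviours z: drinking frequency (1 never … 4 weekly or
more), parental control and secrecy (tertiles 1–3).  Between consecutive
annual observations the system evolves as a continuous-time Markov chain
of microsteps.  Each actor receives change opportunities for each
dimension d ∈ {network, alcohol, control, secrecy} at rate λ_d; the total
event rate is n·Σλ_d and the period horizon is fixed at 1.0, so the rates
carry the timescale.  At a network opportunity the actor chooses among
"toggle one outgoing tie" (additions barred at the cap) and "no change";
at a behaviour opportunity among {−1, 0, +1} clipped to the scale.
Choice probabilities are a multinomial logit over the objective
f_i = Σ_k θ_k s_ik evaluated at each candidate state, computed with
log-sum-exp stabilisation (the compiled path uses cached multiplicative
weights, clamped at e^±50, which is equivalent up to float association).

Network statistics: outdegree; reciprocity; transitive triplets with the
fixed orientation x_ij x_jh x_ih; indegree popularity Σ_j x_ij √indeg_j;
same-gender ties; FSM similarity; and per behaviour the alter, ego and
similarity statistics with sim_ij = 1 − |z_i − z_j|/range; plus the
control-ego × alcohol-similarity interaction.  Behaviour statistics:
linear and quadratic shape; for alcohol total similarity and its
interactions with control and secrecy; for secrecy average similarity
(isolates contribute 0 via the max(1, outdegree) denominator) and the
alters' average drinking; for control the effect-from-alcohol term;
gender and FSM main effects on each behaviour.  Behaviour means z̄,
mean similarities s̄ and the FSM mean similarity are computed per school
over all observed actor-waves; ranges are theoretical (3 for alcohol,
2 for tertiles, 1 for FSM).  In single-sex schools all gender effects are
structurally zero-variance and are fixed at 0.

## Estimation

Unconditional method of moments: evaluation parameters and the
per-period rates are free, and θ solves E_θ[S] = s_obs.  Targets are
**cross-lagged**: a network effect's statistic pairs the period-end
network with period-start behaviours, a behaviour effect's statistic
pairs the period-end behaviour with the period-start network (and other
behaviours).  Evaluated instead on a common end state, the network
similarity statistic and the total-similarity influence statistic are
the same number and selection cannot be told from influence — the
cross-lagging is what identifies the two processes.  Rate targets are
the observed change amounts per period (network Hamming distance;
Σ|Δz| per behaviour) restricted to jointly observed rows/values, so
imputed entries never enter rate targets.  Each period's simulations
start from the (imputed) observed earlier wave.

Missing data: last observation carried forward; wave-1 missing
behaviour → school-wave mode; wave-1 missing out-row → zeros.  This is a
deliberate, simple approximation; its imputed entries feed simulations
but are excluded from the rate targets.

The solver is a three-phase stochastic approximation:

1. **Derivative.**  D̂ = dE[S]/dθ by forward finite differences with
   common random numbers (n1 paired replications per column; default
   probe 0.3, widened ×3 for weakly identified effects — averaged
   similarities and interactions — ×2 for quadratic shapes, relative for
   rates).  D̂ is solved through a truncated SVD (relative cut 10⁻⁶):
   directions whose columns are simulation noise are left un-updated;
   exactly duplicated strong columns (a structurally collinear effect
   set) raise an error naming the effects.
2. **Travel + polish.**  Damped-Newton updates θ ← θ − a·D̂⁻¹(S̄ − s_obs)
   with the derivative refreshed along the way, the largest component of
   a step capped, and the best iterate (by a standardised-deviation
   loss) retained; then a long Polyak-averaged polishing phase at a
   fixed, freshly estimated D̂.
3. **Diagnostics.**  N independent simulations at θ̂ give the statistic
   covariance Σ̂, per-parameter t-ratios (threshold .1), the overall
   ratio √((S̄−s)ᵀΣ̂⁻¹(S̄−s)) (threshold .25) and the parameter
   covariance D̂⁻¹Σ̂D̂⁻ᵀ.  Note the overall ratio has a pure-noise floor
   of √(p/N): N must exceed ~16p for the .25 threshold to be reachable
   even at a perfect root.  Up to `max_restarts` automatic restarts from
   the last iterate; non-convergence returns a flagged result, never an
   exception.

Initial values are data-driven: outdegree at the observed-density
log-odds, reciprocity at the excess log-odds of reciprocation, behaviour
shapes at a two-parameter Gibbs fit (exp(θ_L c + θ_Q c²)) moment-matched
to the observed marginal, rates at 1.5× the observed per-capita change
plus a floor.  Zero starts leave weakly identified directions stuck at
zero and bias replicate means; the data-driven starts remove most of
that.

## Pooling and tables

Per-school estimates are combined per effect under
θ_s ~ N(x_sᵀβ, se_s² + τ²) with Paule–Mandel τ² (weighted residual sum
of squares equated to its degrees of freedom, solved by bracketing and
Brent to 10⁻⁸, floored at 0).  Moderators: intercept, boys, girls
(coeducational reference) and school prevalence centred on the sample
mean, so the intercept is the expected value for an average
coeducational school.  Inference is Wald/normal.  Schools whose fit did
not converge are excluded from pooled stages of the pipeline (count
logged); the reduced-scale validation experiments instead include every
fit with finite standard errors, because the strict thresholds are
calibrated for production phase-3 sizes and at reduced scale would drop
schools on Monte-carlo noise and unbalance the school-type design.

Selection tables: cell (e, a) is the tie log-odds of an ego at category
v_e toward an alter at v_a relative to a dyad at the school mean,
β_ego(v_e−v̄) + β_alt(v_a−v̄) + β_sim(sim(v_e,v_a) − 1); the delta-method
variance uses the fitted covariance of (β_ego, β_alt, β_sim).  Against
this reference the similarity terms cancel on the diagonal, so β_sim
moves only dissimilar-pair cells (downward when positive).  Cells are
pooled across schools on the log scale by the same random-effects
machinery, exponentiated into odds ratios, and flagged when the 95% CI
of the pooled log-odds excludes 0.  Asymmetry contrasts
cell(e,a) − cell(a,e) are available pooled (treating cells as
independent — a documented approximation) and exactly per school, where
the similarity terms cancel and the variance uses the full covariance.

## Synthetic studies

The generator emulates the target cohort: 22 schools (9 coeducational,
8 girls, 5 boys), 60–210 pupils, five annual waves, outdegree-4
homophilous random wave-1 networks, wave-1 drinking (.55, .30, .10, .05)
over the four categories (≈5% weekly), uniform tertiles for control and
secrecy, FSM prevalence drawn per school from U(.05, .45), and 12%
wave-level absence (wave-1 absence capped at 20%).  Default true
parameters: outdegree −2.2, reciprocity 1.5, transitive triplets 0.3,
indegree popularity 0.2, same-gender 0.5 (coeducational), FSM similarity
0.2, alcohol similarity 0.35, alcohol total similarity 0.46, control
similarity 0.12, secrecy average similarity 1.2, alcohol→control −0.25.
Behaviour drifts were calibrated once so the default configuration
reproduces the documented prevalence trajectory (weekly share
.05/.12/.20/.34/.43 across waves on trial runs): alcohol linear 1.1,
quadratic −0.05, control linear −0.15, secrecy linear +0.10, with rates
(5.0, 1.2, 0.6, 0.6).  School-context ground truth defaults to a
+0.4 boys-school offset on the secrecy-alter selection effect.
Sub-seeds derive deterministically from (master seed, school index).

What the generator does *not* emulate: item-level questionnaires,
school recruitment/attrition, informative (non-random) absence,
time-varying effects, or pupils switching schools.  Passing tests
therefore demonstrate internal consistency of the method under its own
assumptions, not robustness to the missingness and measurement quirks of
real cohorts.

## Validation experiments and problem sizes

* **Statistic oracles** — every kernel statistic against a brute-force
  enumeration written from the definitions, on 100 random 4–6 actor
  fixtures (tolerance 10⁻¹⁰); triad census against per-triple
  classification and networkx.
* **Analytic limits** — the pure-outdegree chain at n = 2, where the
  binary choice set makes the logistic stationary law exact.  For n > 2
  the multinomial-logit chain is *not* reversible with respect to
  exp(θ·#ties) (the softmax normalisation is state-dependent) and the
  density genuinely deviates from the logistic value; the exact law
  follows from the outdegree birth–death chain and is checked at n = 10.
  A single-actor behaviour chain is checked against the stationary
  eigenvector of its explicit 4-state transition matrix (TV < 0.02).
* **Parameter recovery** — 100 replicate coeducational schools of 40
  pupils over 3 waves simulated at the default θ*, fully observed,
  refitted with the full 42-parameter model at reduced solver settings.
* **Moderator recovery** — 50 replicate 22-school studies at reduced
  scale (30–40 pupils, two waves, network + secrecy co-evolution with a
  compact effect set) with the +0.4 boys offset, run through per-school
  fits and the school-context meta-regression.
* **GOF calibration** — 50 replicates of a 30-actor structural-only
  model: simulate, refit, simulate the reference cloud at θ̂, and
  compare observed degree distributions and triad census by Mahalanobis
  distance with a Monte-Carlo p-value.  Reference distances are computed
  leave-one-out; in-sample distances would be biased low and skew
  p-values toward zero.

## Known limitations

* Method-of-moments estimates of weakly identified parameters
  (quadratic shapes, averaged similarities, interactions) carry
  finite-sample biases of a few tenths at n = 40 that are insensitive
  to solver effort; their standard errors are honest about the weak
  identification (95% coverage ≈ .98 in the recovery experiment).
* The convergence flag follows strict thresholds (.1 / .25) whose noise
  floors depend on the phase-3 size; at reduced settings many perfectly
  usable fits are flagged non-converged.
* Score-type tests for time heterogeneity of effects are out of scope.
* GOF auxiliaries are degree distributions and the triad census only.
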