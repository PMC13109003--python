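# Methods

## Setting and notation

One binary event of interest Y and one binary competing event D observed
by end of follow-up, with D temporally preceding Y (a record with D=1 has
Y=0 deterministically).  A is a randomized binary treatment, L a measured
binary baseline covariate, U an unmeasured binary common cause of the two
event processes.  The point-treatment law is parameterized by two
seven-coefficient logistic models,

    mu0(a,l,u; th) = Pr(Y=1 | A=a, L=l, U=u, D=0)
                   = expit(th0 + th1 a + th2 l + th3 al + th4 u + th5 au + th6 lu)
    pi0(a,l,u; b)  = Pr(D=1 | A=a, L=l, U=u)
                   = expit(b0 + b1 a + b2 l + b3 al + b4 u + b5 au + b6 lu)

with U, L, A mutually independent Bernoulli draws (pU, pL, pA).  The
independence of L and U is a modeling choice: only the marginals are
specified, and the underlying causal diagram has no L–U edge.

## Targets

All targets are computed **exactly** by enumeration over the 2×2 (L,U)
support; no simulation enters the target calculations.

True causal targets:

    psi0_cde(a)      = sum_{l,u} mu0(a,l,u) P(l) P(u)
    psi0_sde(aY,aD)  = sum_{l,u} mu0(aY,l,u) (1 - pi0(aD,l,u)) P(l) P(u)
    CDE0             = psi0_cde(1) - psi0_cde(0)
    SDE0^{aD}        = psi0_sde(1,aD) - psi0_sde(0,aD)

Observed-data statistical targets (what the weighted estimators converge
to), with pi~(a,l) = sum_u pi0(a,l,u) P(u):

    psi~(a,d=0)   = sum_l Pr(Y=1|A=a,D=0,L=l) P(l)
    psi~(aY,aD)   = sum_l Pr(Y=1|A=aY,D=0,L=l) (1 - pi~(aD,l)) P(l)

where Pr(Y=1|A=a,D=0,L=l) marginalizes U within the survivor stratum,
which is exactly where non-identification error originates: conditioning
on D=0 opens a path through U unless U is absent from one of the two
models.  When th4=th5=th6=0 or b4=b5=b6=0 the observed functionals equal
the causal targets identically (verified to machine precision in tests).

### Positivity

Strong condition (controlled direct effect): every reachable (a,l)
stratum has 1 − pi~(a,l) > 0.  Weak condition (separable direct effect,
per aD): strata only need survivors if they carry weight, i.e. if
1 − pi~(aD,l) > 0.  The strong condition implies the weak one; the
package checks both and reports the margin min(1 − pi~).  A functional
whose required survivor stratum has probability zero is represented by an
`UndefinedFunctional` sentinel whose arithmetic raises — never NaN, so
undefinedness cannot silently propagate.  With finite coefficients the
conditions only fail in floating point (expit saturates to 1.0 near a
linear predictor of 37); this is deliberate — it is exactly how a
violation manifests numerically, and the near-violation diagnostic
(threshold eps, default 0.05, configurable; no canonical cutoff exists)
covers the practically relevant regime.

Sign-discordance between CDE0 and SDE0^{aD} treats zero as concordant
with everything (a point on an axis belongs to no quadrant).

## Estimators

Both estimators use a fitted model pi~(A,L; b~) for the competing-event
probability — saturated by default (cell proportions, matching a
correctly specified nuisance), or logistic with user-chosen terms for
misspecification experiments.  Estimation is the plain sample-average
(Horvitz–Thompson) form with no weight normalization and no truncation;
records with D=1 contribute zero to numerators but stay in the arm
denominators.

    IPCW:  (1/n_a) sum_{i: A=a} Y_i I(D_i=0) / (1 - pi~(a, L_i)),  contrast a=1 vs 0
    SDE:   (1/n_a) sum_{i: A=a} Y_i (1 - pi~(aD, L_i)) / (1 - pi~(a, L_i))

An optional truncation flag is deliberately absent: raw maximum weights
are themselves a reported diagnostic.  A populated cell with fitted
pi~ = 1 raises a positivity error naming the cell; a cell needed for the
SDE reference arm but empty in the data raises an inestimable-cell error.

## Error decomposition

Premising that the actual causal target is SDE0^{aD}, the bias of an
estimator with expectation m decomposes exactly as

    m - SDE0^{aD} = (ostensible - actual)       estimand error
                  + (statistical - ostensible)  non-identification error
                  + (m - statistical)           statistical error

with (ostensible, statistical) = (CDE0, CDE_obs) for IPCW and
(SDE0^{aD}, SDE_obs^{aD}) for the separable-effect estimator — whose
estimand error is identically zero.  MSE = (total bias)² + variance.
The identity is algebraic and is property-tested to 1e-12.

## Simulation engine

Replicate r draws n i.i.d. records with seed base_seed + r (one named
generator per dataset; nothing touches global state), fits the nuisance
once, and evaluates all requested estimators on the shared fit.  Variances
use the unbiased (reps−1) denominator; the reported MC standard error of
a variance estimate is var·sqrt(2/(reps−1)).  Replicates where an
estimator is incomputable (empty cell, fitted survivor probability zero)
are excluded from that estimator's moments with the count reported; at
n = 100,000 under the preset scenarios such failures essentially never
occur.  More than 50% failures aborts the run.

### Preset scenarios

Six scenarios span the factorial: near positivity violation × dependence
on U × marginally rare competing events (Pr(D=1) < 10%).  In all six,
(pL, pU, th0..th3) = (0.1, 0.5, −1, −2, 1, 3).  The remaining
coefficients live in a packaged YAML (`sepeffects/data/scenarios.yaml`)
and are stand-ins chosen to satisfy each row's flags; any same-schema
file can override them.  Design choice for the near-violation rows: the
high competing-event hazard sits in the (rare, pL = 0.1) L=1 stratum for
*both* arms, with survivor probability ≈ 0.003 — "positive yet close to
zero."  This is the structurally interesting regime: IPCW weights reach
the hundreds and its variance inflates to ~3×10⁻⁴ at n = 100,000, while
the separable-effect ratio weights stay near 1 and its variance stays
~4×10⁻⁶ — a 60–80× gap.  Had the violation been driven by treatment
(large b1), the ratio weights would blow up too and the comparison would
understate the separable-effect estimator's advantage.

Desk-scale defaults: 2,000 replicates of n = 100,000 (about five minutes
for all six scenarios on one CPU).  The engine accepts any reps for
tighter Monte Carlo error.

### Grid scans

The analytic scans over coefficient grids (slots th1..th6, b1..b6 each in
{−1, −0.5, 0.5, 1}; th0 = −1; b0 controlling rarity; Pr(L=1) = 0.5 for
grids vs 0.1 in the simulation presets) use a seeded random subsample —
the full 4¹² factorial is combinatorially infeasible — with the drawn
parameter values recorded in the output table.  Undefined rows are
emitted with None markers, never dropped.

## Discrete-time longitudinal extension

Person-period tables carry one row per person-month at risk; the
competing event is evaluated before the event of interest within a month,
so a D_k=1 row terminates follow-up with Y_k=0.  Only the competing-event
process is modeled parametrically — a pooled logistic discrete hazard
with a second-degree polynomial in month, treatment, baseline covariates,
and a treatment × cardiovascular-history interaction by default — while
event-of-interest increments enter nonparametrically as weighted
indicator sums.  The two curve estimators use cumulative-product weights:

    IPCW:  risk_a(t) = (1/n_a) sum_{i in a} sum_{k<=t} I(Y_ik=1) prod_{j<=k} 1/(1 - h_D(j,a,L_i))
    SDE:   risk_aY(t) = (1/n_aY) sum sum I(Y_ik=1) prod_{j<=k} (1 - h_D(j,aD,L_i))/(1 - h_D(j,aY,L_i))

These collapse exactly to the point-treatment estimators at K=1 (a unit
test guards this reduction, since the published time-varying expressions
are only available in supplementary material).  Percentile bootstrap CIs
(2.5th/97.5th of B resamples) resample persons, not person-months, and
refit the hazard model within every resample; failed refits are skipped
and counted.  No loss-to-follow-up weights are implemented: the intended
use restricts follow-up to a window with complete ascertainment.

### Synthetic trial generator

`generate_synthetic_trial` is a synthetic stand-in for the historical
estrogen-therapy trial data (which must be obtained externally): two arms
defaulting to 125/127 persons, 50 monthly intervals, four baseline
covariates (dichotomized hemoglobin, three-level age group, bed-bound
activity level, cardiovascular history).  Default hazard coefficients
give a baseline monthly other-cause-death hazard near 1%, rising with
age/frailty, with treatment raising cardiovascular mortality more in men
with prior cardiovascular disease, and a treatment benefit on the event
of interest.  It emulates the *structure* of such a trial — discrete
hazards, administrative censoring at K, covariate mix — but not
loss to follow-up, time-varying covariates, or any calendar-time
artifacts; tests passing on it demonstrate correctness of the estimators
under the assumed discrete-hazard law, not fidelity to the historical
dataset.

## Numerical choices and limitations

- Saturated nuisance fits are exact cell proportions; logistic fits go
  through IRLS (statsmodels GLM) and equal the saturated fit to ~1e-8
  when fully interacted, which is the tolerance used where the two paths
  are compared.
- A dataset with no modeled events yields an exact all-zero hazard fit
  rather than a separation failure.
- Monte Carlo tolerances in tests follow the 4-standard-error convention
  for binomial/empirical checks.
- Scope is deliberately limited to IP-weighted estimators; g-computation
  and efficient-influence-function estimators, partial-isolation
  variants, continuous covariates, and time-varying treatments are out of
  scope.
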