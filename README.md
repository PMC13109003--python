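# sepeffects

Tools for biostatisticians analyzing **competing-events data** when the
question of interest is a **direct treatment effect** on the event of
interest — e.g., the effect of estrogen therapy on prostate-cancer death
when many men die first of cardiovascular causes.

The default practice of "censoring by competing events" targets, at best,
a **controlled direct effect**,

CDE₀ = Pr(Y^{a=1, d=0} = 1) − Pr(Y^{a=0, d=0} = 1),

the effect under an impossible intervention eliminating all competing
events.  When what the investigator actually wants is a **separable direct
effect** of the treatment component acting on the event of interest,

SDE₀^{a_D} = Pr(Y^{a_Y=1, a_D} = 1) − Pr(Y^{a_Y=0, a_D} = 1),  a_D ∈ {0, 1},

the analysis accumulates three distinct, compounding errors, which this
package computes and separates exactly:

1. **estimand error** — CDE₀ − SDE₀^{a_D}, a purely interpretational gap;
2. **non-identification error** — the gap between a causal target and the
   observed-data functional the estimator converges to, driven by an
   unmeasured common cause U of the two event processes;
3. **statistical error** — bias and variance of the estimator relative to
   its observed-data functional only.

Two inverse-probability weighted estimators are implemented, both built on
a model for π̃(A, L) = Pr(D=1 | A, L):

- the classical **IPCW estimator** (competing events treated as censoring),
  weights 1 / (1 − π̃(A, L));
- the **separable-effect weighted estimator**, weights
  (1 − π̃(a_D, L)) / (1 − π̃(A, L)).

The ratio form of the second estimator's weights is why it tolerates
(near-)positivity violations that inflate the IPCW variance by orders of
magnitude: strata where nearly everyone has the competing event *under
both arms* largely cancel out of the ratio.

## What's in the box

| module | contents |
| --- | --- |
| `sepeffects.dgp` | point-treatment data-generating process (binary U, L, randomized A, logistic models for D and Y, Y≡0 when D=1), six preset scenarios |
| `sepeffects.estimands` | exact analytic causal targets, observed-data functionals, positivity diagnostics — all by enumeration over the discrete covariate support |
| `sepeffects.estimators` | saturated / logistic nuisance fits, the two weighted estimators, weight diagnostics |
| `sepeffects.decomposition` | the three-way error decomposition, MSE, analytic grid scans |
| `sepeffects.simulation` | seeded Monte Carlo engine and the six-scenario variance comparison table |
| `sepeffects.longitudinal` | discrete-time generalization: pooled logistic competing-event hazards, IPCW and separable-effect cumulative-incidence curves, person-level percentile bootstrap CIs, a synthetic two-arm trial generator |

## Worked example

The `row6` preset is the hardest scenario: a near positivity violation
(survivor probability ≈ 0.003 in one covariate stratum), U influencing
both event processes, non-rare competing events.

```python
import sepeffects as se
from sepeffects.simulation import SimulationConfig, run_simulation

sc = [s for s in se.scenario_presets() if s.name == "row6_viol_U_nonrare"][0]
tv = se.all_targets(sc.params)         # exact, no simulation
cfg = SimulationConfig(scenario=sc, n=100_000, reps=200, base_seed=1,
                       aD_values=(0,))
res = run_simulation(cfg)
```

Output (printed by the snippet above with simple formatting):

```
SDE0(aD=0) = -0.2246   (actual causal target)
CDE0       = -0.2758   (ostensible target of a censoring analysis)
CDE_obs    = -0.2704   SDE_obs(aD=0) = -0.2247

IPCW-CDE: MC mean -0.2704, variance 3.12e-04, max weight 1019.0
  estimand error -0.0512, non-identification error +0.0055, statistical error +0.0000
  total bias -0.0457, MSE 2.40e-03

IPW-SDE,aD=0: MC mean -0.2246, variance 4.65e-06, max weight 3.4
  estimand error +0.0000, non-identification error -0.0001, statistical error +0.0001
  total bias +0.0000, MSE 4.66e-06
```

Reading: the censoring analysis is unbiased *for its own statistical
target* but answers the wrong question (estimand error −0.051), picks up
extra confounding through U (+0.006), and its weights reach 1000, giving
it ~67× the variance of the separable-effect estimator — whose total bias
for the actual causal target is zero to Monte Carlo precision.

The same comparison at trial scale:

```bash
sepeffects synth-trial --n1 125 --n0 127 --months 50 --seed 3 --out trial.csv
sepeffects reanalyze --data trial.csv --estimator ipcw --bootstrap 1000 --seed 1
sepeffects reanalyze --data trial.csv --estimator sde --aD 0 --bootstrap 1000 --seed 1
```

emits per-month cumulative-incidence contrasts with 95% percentile
bootstrap CIs; the IPCW max weight is several times the separable-effect
max weight, and its intervals correspondingly wider.

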