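# mixshift

Discovery and semiparametric estimation of **interaction between continuous
exposures** under **stochastic shift interventions**, with targeted maximum
likelihood (TMLE) inference.

## The problem

Environmental-health studies routinely measure a *mixture* of correlated,
continuous exposures (metals, POPs, phthalates, ...) together with
confounders and a health outcome. Two questions follow naturally:

1. *Which* pairs of exposures act synergistically (super-additively) or
   antagonistically (sub-additively) on the outcome?
2. *How large* is that departure from additivity, with honest confidence
   intervals, when the candidate pair was itself chosen from the data?

Classical additive-interaction measures assume binary treatments; for
continuous exposures a more natural intervention is a **stochastic shift**:
replace each subject's exposure `A` by `A + δ`, i.e. replace the exposure
density `g₀(a|w)` by `g₀(a − δ|w)`. For a pair `(Aᵢ, Aⱼ)` with shifts
`(δᵢ, δⱼ)` the interaction target is the departure from additivity

    Ψ_int = E_{δᵢ,δⱼ}[Y] − E_{δᵢ}[Y] − E_{δⱼ}[Y] + E[Y],

where `E_δ[Y]` is the mean outcome had the shifted exposure law applied and
`E[Y]` the unshifted baseline. `Ψ_int > 0` is synergy, `Ψ_int < 0`
antagonism, with no parametric model for the exposure–outcome surface.

## The estimator

Each shifted mean is estimated by TMLE. The efficient influence function of
`E_δ[Y]` is

    D(O) = H_δ(A,W) · (Y − Q̄(A,W)) + Q̄(A+δ, W) − E_δ[Y],
    H_δ(A,W) = g₀(A−δ|W) / g₀(A|W),

so two nuisances are learned by cross-validated (discrete super-learner)
selection: the outcome regression `Q̄ = E[Y|A,W]` and the density ratio
`H_δ` (either by probabilistic classification on an augmented
observed-vs-shifted dataset, or by direct conditional-density modelling).
A one-dimensional fluctuation (logistic on the outcome rescaled to [0,1],
or linear) makes the empirical mean of the EIF zero; standard errors come
from the EIF's sample variance. Two routes to `Ψ_int` are provided: the
**Delta-Method** combination of four targeted shift means, and a **direct
single-step TMLE** with the combined clever covariate
`H* = H_joint − H_i − H_j + 1`.

Because "the top synergistic pair" is a data-adaptive target, the engine
uses **K-fold discovery–estimation**: training folds rank all exposure
pairs by fast g-computation contrasts, validation folds estimate the
discovered parameters (CV-TMLE), shifts are shrunk adaptively when the
density ratio exceeds a positivity ceiling `λ` (default 50), and fold
estimates are pooled by rank through a single targeting step over the
stacked validation folds, reported with the average feasible shift `δ̄`.

## Worked example

```python
from mixshift import ShiftInteractionModel, make_niehs_like_fixture

data = make_niehs_like_fixture(seed=4, n=500)   # synthetic 7-exposure mixture
model = ShiftInteractionModel(
    data, k_folds=3, delta=1.0, seed=7,
    q_roster=("mean", "glm", "poly2"), ratio_roster=("logit2",),
)
results = model.fit()
print(results.summary())
```

```
Stochastic-shift interaction analysis
========================================================================
n = 500, exposures = 7, K = 3 folds, approach = delta, delta = 1.0
------------------------------------------------------------------------
Condition                               Psi      SE             95% CI      P
Rank 1 Antagonism Var 1 (A5)          3.981   0.196  (  3.597,   4.365)   0.00
Rank 1 Antagonism Var 2 (A7)          5.237   0.195  (  4.856,   5.619)   0.00
Rank 1 Antagonism Joint               4.471   0.293  (  3.896,   5.046)   0.00
Rank 1 Antagonism Interaction        -0.123   0.148  ( -0.413,   0.167)   0.41
Rank 1 Negative Marginal Marginal     3.741   0.319  (  3.115,   4.367)   0.00
Rank 1 Positive Marginal Marginal     6.386   0.313  (  5.773,   6.999)   0.00
Rank 1 Synergy Var 1 (A1)             6.278   0.238  (  5.812,   6.744)   0.00
Rank 1 Synergy Var 2 (A7)             5.659   0.253  (  5.164,   6.154)   0.00
Rank 1 Synergy Joint                  7.595   0.225  (  7.154,   8.036)   0.00
Rank 1 Synergy Interaction            0.283   0.222  ( -0.153,   0.718)   0.20
------------------------------------------------------------------------
top positive marginal: A1 (in 3/3 folds, mean rank 1.0, robust)
top negative marginal: A5 (in 3/3 folds, mean rank 1.0, robust)
top synergy: A1+A7 (in 2/3 folds, mean rank 1.0, robust)
top antagonism: A5+A7 (in 2/3 folds, mean rank 1.0, robust)
```

Reading the output: the fixture builds in positive effects for A1/A2/A7
with supra-additive A1×A7 and A2×A7 terms and an antagonistic A5×A7 term.
Discovery correctly and stably ranks A1 (top positive marginal), A5 (top
negative), A1+A7 (top synergy) and A5+A7 (top antagonism). The marginal
and joint rows are counterfactual means `E_δ[Y]` under a one-unit shift;
the `Interaction` rows are the pooled departure-from-additivity estimates
with their EIF-based 95% CIs — positive for the synergy pair, negative for
the antagonism pair, both with intervals that reflect the modest n=500.

The same analysis runs from the shell on any CSV:

```bash
mixshift analyze data.csv --config config.yaml --seed 3 --out-dir out/
mixshift simulate --config grid.yaml --seed 1 --out-dir sim/
```

`analyze` writes a tidy results table (`Condition | Psi | Variance | SE |
Lower CI | Upper CI | P-value | Fold | N | Delta`) plus a JSON run
manifest; `simulate` writes replicate logs, a metrics CSV and a
five-panel summary (bias, MSE, coverage, discovery rate, scaled bias).

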