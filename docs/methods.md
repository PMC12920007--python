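# Methods

## Target parameters

Data are i.i.d. triples `O = (W, A, Y)`: confounders `W ∈ ℝ^q`, continuous
exposures `A = (A₁, …, A_p)`, and a continuous or binary outcome `Y`. The
observed exposure law is `g₀(a|w)`; a stochastic shift intervention with
signed magnitude δ replaces it by `g_δ(a|w) = g₀(a − δ|w)`, i.e. every
subject's exposure moves to `A + δ` (a regulatory *reduction* of one unit
is δ = −1). The shift mean is

    E_δ[Y] = ∫∫ Q̄₀(a, w) g₀(a − δ|w) p₀(w) da dw = E[ Q̄₀(A + δ, W) ],

with `Q̄₀(a,w) = E[Y|A=a, W=w]`. For an exposure pair `(Aᵢ, Aⱼ)` the
additive-scale interaction is

    Ψ_int = E_{δᵢ,δⱼ}[Y] − E_{δᵢ}[Y] − E_{δⱼ}[Y] + E[Y],

positive under super-additivity (synergy), negative under sub-additivity
(antagonism). A causal reading requires ignorability and positivity
(`g_δ/g₀` bounded on the support); absent those, Ψ remains a well-defined
variable-importance contrast. A sign convention note: the package pairs
the density ratio `g₀(A−δ|W)/g₀(A|W)` with outcome-regression substitution
at `A + δ`; this is the unique pairing under which the substitution term
and the shifted density agree by change of variables, and it is verified
against Monte-Carlo truth in the test suite. The three-way generalization
is provided as the standard third-order finite difference (triple shift
minus pairwise shifts plus single shifts minus baseline), as an
untargeted g-computation contrast only — with high-dimensional exposures
its positivity and sample-size demands rarely justify full inference.

## Estimation

**Nuisances.** `Q̄` is fitted by discrete cross-validated selection over a
learner roster (the member with the smallest V-fold CV squared error, or
log loss for binary `Y`, refit on all training rows). The default roster
is intercept-only, main-terms GLM, random forest and gradient boosting;
a "fast" roster replaces the tree ensembles by a degree-2 polynomial
ridge whose penalty is chosen by an internal cross-validated path
(alphas 10⁻³…10³). The clever covariate `H_δ = g₀(A−δ|W)/g₀(A|W)` is
estimated either by

* *classification*: each observation contributes two rows — observed
  exposures labelled 0 and post-intervention exposures `A+δ` labelled 1 —
  and a probabilistic classifier's odds `p/(1−p)` estimate the ratio
  (balanced copies make the odds equal the density ratio with no prior
  correction); joint shifts use a single classifier on jointly shifted
  copies so exposure dependence is respected; or
* *direct density*: a homoscedastic location model per target exposure
  (linear regression of `A` on `W`; Gaussian KDE with Silverman bandwidth
  on the residuals), multi-target ratios evaluated as products.

Classifier probabilities are bounded into (10⁻⁶, 1−10⁻⁶) before odds;
ratios are truncated into [10⁻⁶, λ] with ceiling λ = 50 by default. No
symmetric lower bound is imposed: ratios below 1 move observations into
denser regions and pose no positivity risk.

**Targeting.** Continuous `Y` is rescaled to [0,1] using
`(min Y − 0.1·range, max Y + 0.1·range)`; binary `Y` uses (0, 1). The
default fluctuation is logistic: scaled `Y` regressed on `H_δ` with
offset `logit Q̄`, no intercept; the maximum-likelihood ε solves the score
`mean(H_δ (Y − Q̄*)) = 0`, found by bracketed root-finding (the score is
monotone in ε) to 10⁻¹⁴; |ε| > 10 is flagged as non-convergent. A linear
fluctuation (`Q̄* = Q̄ + εH`, least-squares ε) is available. The estimate
is `ψ̂ = mean Q̄*(A+δ, W)` on the natural scale, where the updated
regression — a function of `(a, w)` — is evaluated at the shifted
exposures with the clever covariate also evaluated there. Inference uses
`SE = sqrt(Var̂(D)/n)` with the n−1 variance denominator and 1.96-SE Wald
intervals; a printed variance formula that would divide by an extra √n is
treated as a typo. The estimator is doubly robust: consistent if either
`Q̄` or `g` is consistently estimated, efficient if both are.

**Interaction.** Route 1 (*Delta-Method*) targets the joint and the two
marginal shift means separately, takes the baseline as the sample mean,
and combines; the variance comes from the combined influence function
`D = D_joint − D_i − D_j + D_base`, which accounts for all covariances.
Route 2 (*direct targeting*) runs one fluctuation with the combined
covariate `H* = H_joint − H_i − H_j + 1` and evaluates the updated
regression at the four exposure configurations; the baseline's influence
is carried by the `+1` term, so the interaction EIF includes the
`(Y − E[Y])` contribution and the variance is correct for the full
contrast. The two routes agree within sampling error at moderate n; the
Delta route also yields the marginal estimates analysts usually want,
and is the default.

## Discovery–estimation cross-validation

Estimating a data-adaptively chosen target ("the top synergy pair") on
the rows that chose it gives anti-conservative intervals. The engine
splits the n rows into K validation folds (default K = 3, sizes within
one of each other, seeded). Per fold:

1. fit `Q̄` on the training rows;
2. rank all p(p−1)/2 pairs by the untargeted g-computation contrast
   `mean[Q̄(joint) − Q̄(i) − Q̄(j) + Q̄(obs)]` (row-wise, so additive
   surfaces cancel exactly; values within numerical dust of zero are
   unsigned); the top-s positive values form the synergy set, the top-s
   negative the antagonism set — a pair only enters with the right sign.
   Single exposures are ranked the same way for the top positive /
   negative marginal blocks;
3. shrink the requested δ geometrically (factor 0.9) on the training
   fold until `max_i H_δ < λ`, erroring below 1% of the request
   ("positivity" failure, reported per fold, never silently dropped);
4. estimate the discovered parameters on the validation rows by TMLE
   using the training-fold nuisances (CV-TMLE).

**Pooling** is *by rank*, not pair identity: the rank-1 synergy slot may
hold different pairs in different folds (provenance is kept in the fold
rows). The pooled estimate stacks the validation folds — each row keeping
its own fold's nuisance predictions and clever covariates — and runs a
single global fluctuation on the stacked arrays with scaling constants
from the full outcome range, then takes the stacked plug-in mean; the SE
uses the stacked EIF over all n. The pooled row is paired with the
average feasible shift `δ̄ = mean_k δ_k`. A fold whose pairing slot is
empty (no correctly-signed candidate) simply contributes nothing to that
slot. Rank stability is summarized per pair as (folds present in top-s,
mean rank), with a "robust" flag when a pair appears in more than half
the folds.

Marginal and joint table rows report the counterfactual mean `E_δ[Y]`
itself (not its difference from the baseline mean); the interaction row
is identical under either convention.

## Benchmark simulation

The generator draws `W ~ N₄(0, Σ)` with exchangeable correlation ρ = 0.3
(from the plausible 0.2–0.4 band), exposures

    A₁ ~ Gamma(2, exp(0.2 W₁)),  A₂ ~ Gamma(2, exp(0.2 W₂)),
    A₃ = 4·Beta(2,2) + 0.1 W₃,
    A₄, A₅ ~ TruncNormal(2 + 0.2 W₃, 1) on [0,6],
    A₆ ~ TruncNormal(2 + 0.2 W₄, 1) on [0,6],

and outcome

    Y = 1 + 0.3 W₁ + 0.2 W₂ + 0.3 A₁ + 0.2 A₂ − 0.3 A₃
        + synergy·A₁A₂ + antagonism·A₅A₆ + 0.2 A₄² + ε,  ε ~ N(0,1),

with synergy ∈ {0.25, 0.40, 0.60} and antagonism ∈ {−0.20, −0.45, −0.70}
(paired small-with-small in the study grid). The exposure-family
parameters and W-links are package defaults chosen to keep exposures
positive, right-skewed or bounded, and confounded by W; the published
form of this mechanism names only the families. Because `Y` is linear in
the `A₁A₂` product and every other term cancels in the double difference,
the true interaction under shifts (δ₁, δ₂) = (0.5, 0.5) is exactly
`synergy·0.25`; a 100,000-draw Monte-Carlo evaluation of the four shifted
means confirms this to float precision (the double difference is
deterministic for this mechanism). The antagonism arm is generated but
headline metrics focus on synergy detection.

Replicate metrics: bias (mean estimate minus truth), MSE (satisfying
`MSE = Bias² + Var` exactly, with the n-denominator variance across
replicates), 95% CI coverage of the truth, discovery rate (fraction of
replicates in which (A₁, A₂) is the rank-1 synergy pair in more than half
the folds — the same majority rule used for the robustness flag), and
scaled bias `|Bias|·√n`. A replicate that fails (e.g. no correctly-signed
candidate in any fold) is recorded; a scenario aborts if more than 20%
fail.

**What the generator does and does not emulate.** It reproduces
confounded, correlated, non-Gaussian continuous exposures with known
product-form interactions and homoscedastic Gaussian noise. It does not
emulate measurement error, limits of detection, missing data (rejected at
validation — no imputation), heteroscedastic or heavy-tailed outcome
noise, or interactions that are not bilinear. Passing the simulation
suite therefore certifies the estimator under known-truth conditions of
this family, not performance on arbitrary real mixtures.

The NIEHS-like fixture is a separate synthetic 7-exposure generator (one
binary confounder, two correlated exposure clusters, null-but-correlated
members, supra-additive A₁×A₇ / A₂×A₇ and antagonistic A₅×A₇ terms) used
for integration tests; its coefficients are invented test constants, not
any external dataset's answer key.

## Problem sizes and numerical choices

The simulation study and acceptance runs use desk-scale settings chosen
as this package's own defaults: K = 3 folds, the fast learner roster
(mean / main-terms GLM / degree-2 ridge path for `Q̄`; degree-2 logistic
classifier for the ratio), 30–50 replicates per condition, and n up to
2000. The degree-2 roster members span the benchmark's outcome surface,
so they play the role of the correctly-specified parametric candidate a
discrete super learner would select; the tree-ensemble default roster is
appropriate for real data where no such form is known.

Other numerical choices: outcome-scale probability bounds (10⁻⁴,
1−10⁻⁴) before the logit; ranking tie-breaks lexicographic by pair name
(recorded); adaptive-δ shrink factor 0.9 with a 1% floor; one global
seed fans out to per-fold and per-replicate child seeds through a
counter-based `SeedSequence` scheme recorded in the run manifest, making
reruns bit-identical. δ = 0 degenerates gracefully: ratios are exactly 1
(direct density), the shift mean equals the sample mean, and `H* ≡ 0`
forces a zero interaction with ε = 0.

## Known limitations

* Only additive shifts `A ↦ A + δ` are implemented; multiplicative or
  covariate-dependent shifts require Jacobian machinery that is out of
  scope.
* The three-way contrast is g-computation only, with no targeted
  inference.
* The direct conditional-density estimator assumes a homoscedastic
  location family; strongly heteroscedastic exposures are better served
  by the classification route (the default).
* Pointwise kernel density-ratio evaluations carry sampling noise of a
  few percent at n = 5000; positivity diagnostics use the raw maximum
  ratio, which is itself an estimate.
* Pooling by rank answers "how large is the rank-1 interaction",
  averaging over whichever pairs occupy the slot; when folds disagree,
  interpret the pooled row together with the rank-frequency table.
* All-pairs FDR-corrected testing is intentionally not provided; the
  discovery–estimation split is the inferential strategy.
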