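# Methods

`msrlearner` estimates conditional average treatment effects (CATEs) by pooling K
studies. This note records the model, the estimation and inference choices, what the
synthetic generators do and do not emulate, and the package's known limitations.

## Model and estimand

Each patient contributes a tuple (Y, A, S, X): outcome, binary treatment, study label
in {1..K}, covariates in R^p. Study membership follows p\*(k|x) = pr(S=k | X=x), and
within study k the structural pieces are the CATE τ\*_k(x), the control mean
μ_k⁽⁰⁾(x), and the propensity e\*_k(x). The patient-level estimand is the
membership-weighted CATE

    τ*(x) = Σ_k τ*_k(x) p*(k|x),

the effect expected for a new patient whose covariates could plausibly have arisen
from any of the K studies. Identification requires consistency, within-study mean
unconfoundedness, and within-study positivity.

Writing m\*(x) = E[Y|X=x] = Σ_k {μ_k⁽⁰⁾(x) + e\*_k(x) τ\*_k(x)} p\*(k|x), the
multi-study residual-on-residual (Robinson-type) decomposition is

    Y − m*(X) = Σ_k {A − e*_k(X)} p*(k|X) τ*_k(X) + ε.

Estimation minimizes the plug-in squared-error loss of this regression over
series-approximated CATEs τ_k(x) = v_k(x)'β_k, with an optional ridge penalty:

    (U'U/n + λP) β = U'ỹ/n,

where row i of U stacks the blocks {A_i − ê_k(X_i)} p̂(k|X_i) v_k(X_i) and
ỹ_i = Y_i − m̂(X_i). With K=1 and p ≡ 1 this is exactly the single-study R-learner.

### Validity condition for the moment equation

The error ε above satisfies E[ε | A, X] = 0 — and hence the population minimizer of
the loss is τ\* — only when S ⊥ A | X, i.e. when the treatment-assignment mechanisms
coincide across studies (as in a set of 1:1 RCTs), or when the outcome functions
(μ_k, τ_k) are homogeneous. With heterogeneous propensities *and* heterogeneous
outcome functions, P(S=k | A, X) ≠ p\*(k|X) and the estimand acquires an O(1) tilt
(a two-study counterexample: p = 1/2 each, e = (0.9, 0.1), μ⁰ = (10, 0), τ = 0 gives
E[ε·A] = 2). For this reason the default simulated design uses a common constant
propensity of 0.5 (RCT-style), and the heterogeneous-propensity efficiency analysis
below holds the outcome functions common across studies. Users combining
observational studies with very different treatment protocols and very different
outcome models should treat pointwise intervals with caution.

## Three-step procedure and cross-fitting

1. Study-specific nuisances m̂_k, ê_k by separate per-study fits.
2. Membership probabilities p̂(k|·) by a pooled multinomial fit.
3. CATE coefficients by the closed-form penalized solve.

All nuisances are cross-fitted with Q = 5 folds by default (Q between 5 and 10 is
reasonable): pooled, study-stratified folds q(i) for membership and within-study
folds q_k(i) for m̂_k, ê_k. For a sample outside study k the full study-k fit is
used — that sample never entered study k's training data, so no fold exclusion is
needed. The pooled mean is composed as m̂ = Σ_k m̂_k p̂(k|·) rather than fit
directly, keeping every cross-study prediction explicit.

Default learners mirror a penalized-regression workflow: conditional means by
elastic net (internally cross-validated penalty) on cubic-spline expanded
covariates (3 interior knots at quantiles, linear extrapolation); propensities by
logistic regression with **cross-validated** regularization strength on the same
expansion; membership by unpenalized multinomial logistic regression on a
configurable basis (default: intercept + linear). The cross-validated propensity
penalty matters in practice: with a rich spline expansion and a fixed penalty, the
pointwise noise in ê enters the CATE coefficients through a term proportional to
Var(ê)·β and produced visible undercoverage in our calibration studies; letting the
internal CV shrink spurious propensity signal removed most of that gap. Probability
estimates are clipped to [0.01, 0.99] (propensities) and [0.001, 0.999] with row
renormalization (memberships) to keep the study-specific comparator stable.

## Inference

The stacked parameter θ = (β, γ) collects the series coefficients and the
membership model's reference-category-K multinomial coefficients. Each block has
its own estimating equation: the gradient of the (penalized) R-loss in β, and the
multinomial log-likelihood score in γ — the equation the membership MLE actually
solves. (The literal derivative of the squared-error criterion with respect to γ is
exposed behind `convention="loss"` for sensitivity checks; the multinomial MLE does
not zero it in finite samples.) With A = ∂(mean ψ)/∂θ and B = mean(ψψ'), the
delta-method variance of τ̂(x) = Σ_k p(k|x; γ̂) v_k(x)'β̂_k is

    Var{τ̂(x)} = Dg A⁻¹ B A⁻ᵀ Dg' / n,

using the general (non-symmetric A) sandwich since the γ score does not involve β.
B carries an HC1-style n/(n − dim θ) degrees-of-freedom factor by default. The
β-β block of A is analytic; γ-involved blocks use central finite differences with
step 1e-5·max(1, |θ_j|). Wald intervals use normal quantiles. A zero-average-effect
test averages Dg over an evaluation set and forms the corresponding z-statistic.

Two deliberate approximations: (i) m̂ and ê_k are treated as known in the variance
(justified asymptotically by the orthogonality of the loss in those nuisances;
finite-sample nuisance error is not propagated); (ii) for exact self-consistency of
the estimating equations, inference re-solves β on the design built from the
parametric membership model p(k|x; γ̂) rather than the cross-fitted probabilities —
the two designs estimate the same truth and the difference vanishes with n. A
within-study nonparametric bootstrap (nuisance values held fixed, membership and β
refit per resample) is available as an alternative variance.

### Efficiency

For two studies with equal membership, a common basis, and propensity variances
related by e₁(1−e₁) = c·e₂(1−e₂), the pooled fit has smaller asymptotic variance
than the ensemble of per-study fits whenever the error variance exceeds
(1+c)/(2√c). `efficiency_threshold` computes the transition point;
`efficiency_study` reproduces the ordering empirically with oracle nuisances and
common outcome functions (isolating the design effect).

### Regret

`regret` implements the overlap-weighted excess-risk functional
E[Σ_k e_k(1−e_k) p_k² (τ\*_k − τ_k)²]. This diagonal form equals the population
loss difference L(τ) − L(τ\*) exactly when memberships partition the covariate
space (p(k|x) ∈ {0,1}); with overlapping memberships the loss difference contains
additional cross-study covariance terms, so the functional should be read as an
overlap-weighted MSE summary rather than an exact excess risk.

## Comparators

The study-specific comparator fits a plain R-learner inside each study (the 1/p̂
rescaling of the multi-study design cancels analytically, so no division by small
memberships occurs) and ensembles predictions with membership weights. The pooled
comparator ignores study labels entirely. Both share the serialization schema with
a method tag.

## Synthetic data

Covariates are Gaussian per study with a shared compound-symmetry covariance
(correlation 0.2) and study mean shifts of configurable magnitude (default 1.0)
along random directions — partially overlapping supports. Because equal-covariance
Gaussian classes imply an exactly multinomial-logistic posterior, the Scenario A
membership truth is derived analytically (LDA coefficients) from the means,
covariance and mixture weights: p\* is the *true* conditional law of S given X, not
an arbitrary model, which is what makes coverage of τ\*(x) well defined.

Scenario A draws one shared fixed-effect vector β ~ MVN(0, I_p) per replicate and
study-level random effects η_k ~ MVN(0, σ_τ² I_q) on the first q covariates
(default q = 5 of p = 10): τ\*_k(x) = x'β + z_k'η_k. Scenario B uses the non-linear
form sin(2x₁+2η_k1) + log|x₂+η_k2| + cos(x₃+η_k3)(x₄+η_k4)² with q = 4 and a
tree-ensemble membership truth frozen from a large provisional draw. Baselines are
linear with random study intercepts (μ_k⁽⁰⁾ = x'α + a_k, α ~ N(0, I_p/p),
a_k ~ N(0,1)); errors are Gaussian with σ = 1 per study; treatment is assigned per
patient with constant propensity 0.5 in every study (see the validity condition
above; per-study constants or functions are configurable). Replicates split
patients by Mahalanobis distance from the pooled centroid — closest 85% train,
farthest 10% test, middle 5% discarded — so evaluation happens on a covariate
region disjoint from training.

What the generators do not emulate: real gene-expression marginals (heavy tails,
skewness, block correlation), covariate-dependent treatment assignment,
non-Gaussian or heteroscedastic errors, within-study clustering, and missingness.
Passing calibration here demonstrates correctness of the machinery under the stated
design, not robustness to those features.

Problem sizes in the shipped calibration studies (three studies of 300, 200–500
replicates, scaled-down two-study designs for size/normality checks) were chosen to
exercise the asymptotic claims at moderate samples while keeping the full suite
quick to re-run.

## Numerical choices

- Closed-form solves use the symmetric normal equations with a pseudo-inverse
  minimum-norm fallback (warned) when the system is singular at λ = 0.
- The ridge penalty applies to each coefficient block including intercepts;
  per-block weights are possible through the penalty matrix P. Penalty selection
  minimizes the cross-validated plug-in loss over a grid, ties toward the larger
  penalty.
- The reparameterized fit (τ_k = τ + δ_k, common basis required) penalizes only
  the δ blocks; at λ_δ = 0 the solution is the minimum-norm one and reproduces the
  unpenalized fit's predictions exactly.
- Spline knots are frozen at training quantiles and serialized; evaluation beyond
  the boundary knots extrapolates linearly and logs a warning.
- Binary outcomes are handled on the identity scale inside the loss;
  `scale_to_effect_range` (2·expit(τ)−1) maps effects to [−1, 1] for reporting.
- All randomness flows from one master seed through spawned generator streams;
  repeated runs are bit-identical.

## Known limitations

- Pointwise (not simultaneous) intervals; no honest/tree-based CATE learners.
- Nuisance uncertainty is not propagated into the variance; at small n with rich
  nuisance models this can produce mild undercoverage.
- The estimand tilts away from τ\* when propensity heterogeneity meets outcome
  heterogeneity (see the validity condition).
- Survival/censored outcomes, continuous or multi-level treatments, and
  cluster-randomized designs are out of scope.
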