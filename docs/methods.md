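# Methods

## Model

The package approximates GP regression with additive Gaussian noise,
y = f(x) + ε, ε ~ N(0, σ_n²), f ~ GP(0, k_θ). The data are divided into J
ordered experts of target size B; expert j carries L_j = ⌊γ B_j⌋ local
inducing points A_j (a random subset of its own inputs) and is linked to the
C − 1 closest preceding experts by the predecessor set π_C(j). The joint
density factorizes over the directed expert graph,

    q(a, f, y) = ∏_j p(y_j | f_j) p(f_j | a_ψ(j)) p(a_j | a_π(j)),

with ψ_C(j) = π_C(j) ∪ {j} for j > C and ψ_C(j) = {1, …, C} otherwise, so
that the first C experts are treated exactly and the model collapses onto
FITC (C = J, γ < 1) and the full GP (C = J, γ = 1). Both conditionals are
the *true* GP conditionals restricted to the sets above (projection
H_j = K_{X_j A_ψ}K_{A_ψ A_ψ}⁻¹ with diagonalized residual V̄_j; transition
F_j = K_{A_j A_π}K_{A_π A_π}⁻¹ with Schur complement Q_j). The assumptions
are therefore: (i) conditional independence of experts given their
predecessors, (ii) a diagonalized projection residual, and (iii) noise
homoscedasticity. The prior precision S = FᵀQ⁻¹F and posterior precision
Λ = S + HᵀV⁻¹H are sparse; all inference is done through sparse
factorizations of Λ (and the closed-form log|S| = −Σ log|Q_j|).

Predictions are per-expert Gaussian projections through ψ(j) fused by
covariance intersection, which is conservative by construction: the fused
variance is a β-weighted harmonic mean of expert variances and never leaves
their range. Weights are entropy differences β̄*_j = ½ log(v*₀/v*_j) raised
to Z = log(N)·C and normalized; Z is exposed because the independent-experts
limit (C = 1, γ = 1) equals the generalized product of experts only under
Z = 1, and the package's equality test fixes Z = 1 on both sides.

## Parameters that matter

| parameter | meaning | default | rationale |
| --- | --- | --- | --- |
| B | expert/batch size (points) | 128 (CLI) | trades expert cost B³ against the number of experts |
| C | correlation degree | 2 | smallest value that models inter-expert correlation; C = J is exact |
| γ | inducing sparsity | 1.0 | fraction of each expert's inputs kept as inducing points |
| mode | predecessor choice | nearest | `consecutive` gives a block-banded precision (bandwidth 2C − 1) |
| σ_n | noise sd (response units) | data-driven 0.1·sd(y) | standard moment initialization |
| lengthscales | SE-ARD per dimension (input units) | sd of each input | standard moment initialization |
| Z | weight exponent | log(N)·C | emphasizes informative experts more strongly at larger N, C |

Distance ties anywhere in the graph construction resolve to the smallest
expert index, and nearest-mode predecessor ranks are computed once per
expert, which makes π_{C+1}(j) ⊇ π_C(j) automatic. Whether "nearest" is
measured from expert j's center (used here) or from the most recent
predecessor is genuinely open; the flag `mode` plus the center convention is
the package's choice and is exercised by the determinism tests.

## Hyperparameter estimation

The analytic log marginal likelihood log N(y | 0, HS⁻¹Hᵀ + V) is evaluated
through log|P| = log|Λ| − log|S| + log|V| and yᵀP⁻¹y = yᵀV⁻¹y − ηᵀμ, i.e.
without forming the dense N×N covariance. Optimization runs on log
parameters (positivity by construction) with L-BFGS-B and finite-difference
gradients, box-bounded to e^±12, with optional restarts jittered by
N(0, 0.3²) in log space; MAP adds independent log-normal log-priors. The
expert graph is built once from the initial inputs and held fixed across
objective evaluations, so the objective is smooth in θ. The trace records
(evaluation, objective, best-so-far).

## Numerical choices

- **Jitter.** Every kernel-matrix Cholesky adds ε·(mean diagonal)·I with
  ε = 10⁻¹² by default, escalating ×10 up to 10⁻⁴ before raising. The tiny
  default keeps the limiting-case equalities (full GP, FITC) tight to ~10⁻⁹
  relative — the collapse error grows linearly in ε. For Schur complements
  Q_j the jitter is scaled by the *parent* matrix's diagonal, because the
  complement's own diagonal underestimates its roundoff when lengthscales
  are large relative to the expert span.
- **Training jitter.** During LML optimization the model uses ε = 10⁻⁶
  (FitConfig.jitter): near-singular K_{A_ψ A_ψ} solves make the objective
  chaotically sensitive at tiny ε, while a moderate fixed ε gives
  finite-difference gradients that agree across step sizes. The fitted
  model keeps that ε so predictions are consistent with the objective.
- **Sparse factorization.** Λ (SPD) is factorized with SuperLU
  (`scipy.sparse.linalg.splu`); its log-determinant is Σ log|U_ii|, valid
  because the determinant is positive. The natural block order is used; any
  column permutation the backend chooses leaves the determinant unchanged.
- **Posterior sub-blocks.** The marginal covariance of a correlation region
  is obtained by solving Λ against the region's unit columns —
  correctness-first; a banded selected-inverse would be a performance
  optimization, not a behavioural change.
- **Weight clipping.** β̄ < 10⁻¹² (theoretically anomalous negative entropy
  differences) is clipped before the power Z, computed in log space via a
  softmax to avoid overflow at large Z; if every expert clips at a query
  point the weights fall back to uniform.
- **V̄ with γ = 1.** The projection is then deterministic and V̄ vanishes up
  to roundoff; entries below 10⁻⁸ in *both* models are treated as exact
  zeros inside the closed-form KL difference.

## Synthetic data

`make_two_se_benchmark` draws exactly (dense Cholesky) from the sum of two
SE kernels with lengthscales 5.0 and 0.5 (ratio 10), unit signal variances
and σ_n = 0.1 on inputs uniform in [0, 10]^D — a surface with a smooth
global trend plus fine local structure, the regime where neither a purely
global nor a purely local approximation is adequate. Default study sizes
are N = 1024, D = 2. `make_fig8_toy` builds five well-separated planar
clusters of four points (J = 5, B = 4, γ = 0.75 hence L = 3) for the graph
combinatorics; its coordinates are synthetic — only the combinatorial
structure is meaningful. For calibration studies,
`sample_gp_conditional` draws held-out responses from the *univariate*
conditionals given the training latents, independently across test points:
pointwise quantities (coverage, RMSE) are exact in distribution, joint
statements across test points are not supported by these draws.

What the generator does **not** emulate: non-Gaussian or heteroscedastic
noise, input distributions beyond uniform boxes/grids, model misspecification
(the fitted kernel family always contains the truth), and covariate shift
between training and test regions. Passing tests therefore demonstrate
correctness of the inference machinery and calibration *under the model*,
not robustness to the violations real surveillance or exposure data exhibit.

## Scope and problem sizes

The package targets desk-scale verification: dense baselines are guarded at
N ≤ 4000 (full GP / FITC) and the exact sampler at N ≤ 8192. The test suite
and the acceptance script run at N between 100 and 1024 for distributional
checks, N = 10⁴ only for interval-coverage counting and the sizing example —
sizes at which every sparse result can be compared against a dense oracle.
Stochastic mini-batch optimization, selected-inverse prediction shortcuts
and streaming state-space updates are out of scope.

## Known limitations

- Training cost is dominated by J Cholesky factorizations of LC × LC
  matrices per objective evaluation; finite-difference gradients multiply
  that by the parameter count. Analytic gradients are the natural extension.
- Prediction cost retains the O(N·Bα²) per-query term (column solves per
  correlation region); no prediction-time scaling trick is applied.
- The marginal likelihood is a biased (approximate-model) objective for
  C < J; hyperparameter estimates inherit that bias, which shrinks as C
  grows.
- Covariance intersection guarantees consistency, not efficiency: fused
  variances are conservative when experts are strongly redundant.
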