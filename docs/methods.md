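# Methods

## Model

The package infers latent pathway structure from two paired binary
matrices over the same S tumour samples: an event matrix `Mut` (S × M,
1 = gene carries a non-silent somatic alteration in that sample) and a
differential-expression matrix `Expr` (S × G, 1 = the gene's expression
Z score exceeds ±1.96 in that sample). Between them sit P latent
pathways. Two probabilistic relation matrices parameterize the model:

- `U` ((M+1) × P): probability that an alteration of gene m suffices to
  dysregulate pathway p;
- `Z` ((P+1) × G): probability that dysregulation of pathway p suffices
  to flip gene g's expression.

Each layer combines its causes with a probabilistic OR-gate,

    OR(x, δ) = 1 − ∏_i (1 − x_i δ_i),

the combination rule for independent, individually sufficient causes. The
forward model is

    Path[s, p]    = OR(Mut[s, ·], U[·, p])          (pathway abnormality status)
    ExprHat[s, g] = OR(Path[s, ·], Z[·, g])         (predicted DEG probability)

The "+1" rows are leak terms: an always-active pseudo-cause per layer
that absorbs effects of unmodeled causes (methylation, germline variants,
technical noise). A leak is implemented exactly as an all-ones column
appended to the cause matrix; either layer's leak can be disabled
(`FitConfig.leak_sga` / `leak_deg`, both on by default; the simulator
generates with both off, i.e. zero leak).

Because a single sufficiently-linked cause saturates an OR-gate, the
model is consistent with the mutual exclusivity of driver mutations: once
one member of a module is mutated, additional members add no likelihood
benefit, so co-occurring same-module mutations are not needed to explain
the data.

## Estimation

Parameters are estimated by maximum a posteriori. Probabilities are
reparameterized through an element-wise sigmoid, `U = σ(μ)`,
`Z = σ(ζ)`, so the optimizer works on unconstrained matrices. The
objective is the Bernoulli log-likelihood of `Expr` under `ExprHat` plus
a Beta(α, β) log-prior on every entry of `U` and `Z` (α = β = 0.95 by
default, a weakly bimodal prior that pushes entries away from 0.5;
`prior_on="z"` restricts it to `Z`). On the raw scale the prior's
gradient contribution is (α−1)(1−v) − (β−1)v for v = σ(r); a legacy
sign variant is available as `prior_gradient="printed"`.

Gradients are analytic chain rules through the OR-gates and sigmoids. For
the expression layer,

    ∂LL/∂ζ_pg = Z_pg (1 − Z_pg) Σ_s E_sg · Path_sp · Q_sg / (1 − Path_sp Z_pg)

with `E = Expr/ExprHat − (1−Expr)/(1−ExprHat)` and `Q = ∏_p (1 −
Path·Z)` the survivor product; the mutation layer is symmetric, with the
extra factor `∂Path_sp/∂U_mp = Mut_sm (1 − Path_sp)/(1 − Mut_sm U_mp)`.
The test suite verifies both gradients against central finite differences
of the penalized objective at 1e-5 relative tolerance on randomized small
instances — this is the load-bearing correctness check of the package.

Optimization is full-batch iRprop−: per-parameter step sizes grow by
η+ = 1.2 while the gradient sign is stable and shrink by η− = 0.5 when it
flips (the flipped gradient is zeroed before the next comparison), with
steps clamped to [1e-6, 1.0]. The initial step is 0.01: on logit-scale
parameters the conventional 0.1 proved too aggressive, frequently driving
the optimization into merged-pathway local optima before the latent
columns could differentiate. Iteration stops at `max_iter` (500) or when
the penalized log-likelihood changes by less than `tol` (1e-6, relative)
over a 10-iteration window; typical fits at the scales below converge in
70–120 iterations.

### Initialization and restarts

Raw parameters start at Normal(logit(0.1), 0.5): small initial
probabilities keep the OR-gates far from saturation, where gradients
vanish. The penalized likelihood is multimodal — two latent pathways can
merge onto one true module while another true module is orphaned — and a
single run ends in such an optimum roughly half the time at the standard
simulation scale. `fit` therefore runs `n_restarts = 5` independently
seeded optimizations and returns the one with the highest final penalized
log-likelihood. Selection uses only the model's own objective; failed
runs are separated from successful ones by large likelihood margins, so
the selection is sharp. Fits are bit-reproducible given a config: all
randomness flows from `FitConfig.seed` through per-restart derived seeds.

Raw parameters are clipped to ±15 after each update, keeping sigmoid
values strictly inside (0, 1) in double precision; predicted
probabilities are additionally clipped to [1e-10, 1 − 1e-10] before logs.
Neither clip is active in any test's gradient-check region.

## Synthetic data

The simulator emulates the generative process the model assumes:
`Mut ~ Bernoulli(0.02)` i.i.d., binary truth matrices
`U* ~ Bernoulli(0.01)` and `Z* ~ Bernoulli(0.05)`, deterministic OR-gate
propagation with zero leak (binary in, binary out), and a
mutual-exclusivity post-pruning pass: pathways are visited in ascending
index order and, per sample, among the still-active mutations belonging
to the pathway one uniformly drawn survivor is kept. A gene removed for
an earlier pathway is gone for later pathways too. Expression is
propagated from the *pruned* mutation matrix, so the generative
invariants hold exactly on every emitted dataset. `prune=False` gives
the unpruned variant; `prune_order="before"` is a sensitivity variant
that propagates first and prunes afterwards, leaving the emitted
expression consistent with the pre-pruning mutations instead.

At the standard scale (S = M = G = 1000, P = 5) the default densities
give ≈20 candidate mutations per sample, ≈10 SGAs per pathway module,
≈50 genes per regulon, and a DEG density of ≈4–5% — a sparse but
non-degenerate regime chosen to resemble gene-level alteration and DEG
rates in real tumour cohorts. What the simulator deliberately omits:
measurement noise on either matrix, leak effects, correlated mutations,
copy-number segment structure, and expression count distributions.
Passing recovery tests therefore demonstrates correctness of inference
under the model's own assumptions, not robustness to the full messiness
of real cohorts.

## Evaluation

Recovery is measured by the Jaccard score: for each true pathway, the
best-match Jaccard similarity of its U column against all fitted columns
and of its Z row against all fitted rows; the score is the mean over true
pathways of the product of the two. The max over fitted indices makes the
score invariant to pathway relabeling. Fitted matrices are binarized at
0.5 before scoring (truth is binary; the soft variant, and cosine in
place of Jaccard, are available). Leak rows are dropped before scoring.
Reconstruction error is the mean absolute difference between `Expr` and
`ExprHat`.

The neural-network baseline is a one-hidden-layer perceptron with sigmoid
activations in both layers, trained on the same Bernoulli likelihood with
the same iRprop− optimizer and iteration budget — a controlled comparison
in which only the combination rule (weighted sum vs OR) differs. Its
weight matrices are min-max normalized per hidden unit into [0, 1] so
they can be scored like relation matrices.

## Problem sizes used by the test and acceptance harnesses

Gradient checks run on instances with S ≤ 10, M ≤ 6, P ≤ 4, G ≤ 8.
Recovery checks use the standard scale with 5 replicate seeds, the
S = 500 and M = 3000 regimes with 10 seeds each, and the G = 500 regime
with 5 seeds; the NN comparison uses 3 standard-scale replicates. These
replicate counts keep a full desk run in the tens of minutes on one CPU
while leaving the medians stable.

## Known limitations

- P is fixed by the user; the package offers no automatic selection.
- Inference is MAP, not Bayesian: no uncertainty on U, Z, or Path.
- The likelihood treats genes and samples as conditionally independent
  given pathway status; co-occurrence structure that an AND-gate would
  capture is out of scope.
- With restart selection the fit is robust at the simulated scales, but
  multimodality grows with P; for large P more restarts may be needed.
- Survival analysis and gene-set enrichment on extracted modules are
  deliberately external: the package exports binarized PAS groups and
  GMT gene sets for those tools rather than reimplementing them.
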