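# Methods

## Model

We consider a generalized linear model `f(E(y_i | x_i)) = β₀ + x_iᵀβ`
with `p ≫ n` covariates organised on three levels: disjoint clusters
`A_1, …, A_C` of genes, each gene `h` of cluster `c` holding the `n0`
omics columns `A_ch`, and `H_c` genes per cluster (`G = Σ H_c`,
`p = n0·G`).  Only the binomial family with the logit link is
implemented; the likelihood plumbing is written against a family tag so
that other exponential-family outcomes could be added behind the same
interface.  The coefficient vector is assumed sparse at the gene level:
a handful of genes carry all the signal.

## Joint screening

The screening estimator maximises `l(β)` subject to at most `q₁` active
clusters and at most `q₂c` active genes inside cluster `c`.  Because the
constrained MLE is intractable for `p ≫ n`, each sweep maximises the
quadratic minorant

    g(ω | β) = l(β) + (ω − β)ᵀ l′(β) − (u/2)(ω − β)ᵀ W(β) (ω − β)

with `W(β)` block diagonal by gene: block `(c, h)` is the sub-block of
`−l″(β)` on the gene's columns, multiplied by the cluster constant
`q₂c·n0`.  Block diagonality yields the unconstrained maximiser
`ω̂ = β + (1/u)·W(β)⁻¹ l′(β)` blockwise, and the constrained maximiser
exactly — keep the top `q₂c` genes per cluster by `r_ch = ω̂ᵀW_ch ω̂`
(unscaled gene block; the cluster constant cannot reorder genes within a
cluster), zero the rest, recompute `R_c = ω̂ᵀW_c ω̂` on the masked vector
and keep the top `q₁` clusters.  The test suite verifies this optimality
claim against exhaustive support enumeration on tiny instances.  The
survivors are refit by Newton/IRLS maximum likelihood (intercept always
unpenalised and never counted against the constraints) and the sweep
repeats from `β⁽⁰⁾ = 0` until `‖β⁽ᵏ⁺¹⁾ − β⁽ᵏ⁾‖ / ‖β⁽ᵏ⁾‖ < tol`.

Whenever `u` dominates the largest generalised eigenvalue τ(k) of
`−l″` against `W(β⁽ᵏ⁾)`, `g` is a global minorant of `l` and the sweep
cannot decrease the log-likelihood.  We do not compute τ(k) inside the
algorithm; with the default `u = 10⁵` the observed τ is orders of
magnitude smaller (a dense generalised-eigenvalue diagnostic,
`track_tau`, is available on small instances).  A practical consequence
of a large `u` is that `ω̂ − β` is tiny, so after the first sweep the
refitted coefficients dominate the scores, the selected support
reproduces itself, and the refit is its own fixed point: the algorithm
typically converges in two sweeps, with the support decided by the
score-test-like statistic `l′ᵀ W⁻¹ l′` at `β = 0`.  If the support ever
cycles without converging, the best-log-likelihood iterate is returned
with `converged=False`.

Numerical choices:

* relative-change convergence switches to the absolute norm when
  `‖β⁽ᵏ⁾‖ < 10⁻¹²` (the criterion is undefined at the zero start);
* a gene block whose condition number exceeds `10¹²` receives the ridge
  `10⁻⁸·trace/n0` before inversion (degenerate omics must not abort a
  screen);
* refits cap Newton at 50 steps with step-halving and stop (flagged
  `separated`) once the linear predictor exceeds 30 in absolute value —
  low-dimensional logistic refits frequently separate at small `n`, and
  the bounded iterate is returned instead of a divergent one;
* all rankings break ties by ascending index, so every screen is a
  deterministic function of its inputs;
* the cluster constant `q₂c·n0` in `W_c` is implemented exactly as the
  method defines it; a `scale_blocks=False` switch removes it for
  sensitivity analysis (it changes cluster ranking from a sum-like to a
  mean-like aggregate of the per-gene scores, and made no measurable
  difference in the retention studies).

**Competitors.**  JSD replaces every gene block by its diagonal
(identical to JSBD when `n0 = 1`).  OMS fits one single-covariate
logistic model per omics and ranks Wald p-values; GMS fits one
`n0`-covariate model per gene and ranks likelihood-ratio omnibus
p-values (a Wald alternative was considered but the LRT is the natural
single p-value per gene).  Both are vectorised Newton iterations;
non-convergent fits are flagged and assigned p-value 1.  When OMS
retains omics rather than genes, a gene counts as retained as soon as
one of its omics is retained (`rule="any"`; `rule="all"` is available).

## Group bridge

On the retained design (`d < n` columns) with clusters as groups, the
objective `−l(β) + λ Σ_c |Ã_c|^{1/2} (Σ_{j∈Ã_c} |β_j|)^{1/2}` is
minimised by the variational reformulation of the bridge penalty:
`√s = min_{θ>0} (s/θ + θ)/2` gives alternating updates — closed-form
group scales `θ_c = √(Σ|β_j|)` and a weighted-ℓ₁ logistic step solved by
IRLS with cyclic coordinate descent.  The objective is monitored and is
non-increasing across alternations; a group whose ℓ₁ norm hits zero is
frozen (its effective weight is infinite), the usual behaviour for
concave bridge exponents.  The fixed initialiser is a ridge-stabilised
MLE (ridge 10⁻²), which makes every fit deterministic; the exponent is
fixed at 1/2.  λ is selected by BIC `−2l + df·log n` with
`df = #non-zero coefficients (+1 for the intercept)` over 50 log-spaced
values from `λ_max` (smallest null-model λ, located by
doubling/bisection) down to `10⁻³·λ_max`; ties go to the larger λ.
Cross-validation and GCV tuning are not implemented.

## Gene clustering

Association between genes `i` and `j` is the first canonical correlation
of their column-centred `n × n0` blocks, computed from whitened blocks
with a `10⁻⁸` ridge on the within-block covariances (collinear omics).
The association matrix is soft-thresholded to an adjacency `a^τ`
(default power τ = 6, the weighted-network convention), converted to the
dissimilarity `1 − a^τ` and clustered by average-linkage agglomeration.
The tree is cut at the largest gap between consecutive merge heights —
under separated within/between-cluster association levels the
cross-cluster merges concentrate near dissimilarity 1 and the gap is
unambiguous — or at a user-forced number of clusters.  These defaults
are an approximation of the multi-omics gene-clustering tools in this
family, whose exact linkage and cut rules vary; the screening pipeline
therefore accepts externally supplied labels and treats clustering as
optional.  Partition agreement is measured by the Hubert–Arabie adjusted
Rand index (scikit-learn implementation).

## Synthetic data

The generator emulates the validation design: mean-zero unit-variance
Gaussian covariates whose correlation depends only on the tri-level
relation of a pair — π₁ within gene, π₂ (same omics type) and π₃
(different type) across genes within a cluster, π₄ across clusters —
and a logistic outcome.  The correlation matrix decomposes as
`π₄·J + blockdiag(J_{H_c} ⊗ A + I_{H_c} ⊗ D)` with `n0 × n0` components
`A` and `D`; this gives an O(p) sampler (one global factor, one factor
per cluster, one per gene) and a closed-form spectrum used to verify
positive definiteness exactly before any sampling.  The dense matrix is
retained as a small-instance oracle, and a dense-Cholesky fallback
covers valid correlation settings outside the factorable family.

Canonical design points: scenario 1 uses π = (0.8, 0.6, 0.6, 0.1),
scenario 2 swaps π₁ and π₂; dimensions grow with `n` (10/5/4/3 clusters
of sizes 5/10/20/40 at n=200, 20/10/6/6 at n=400, 40/20/10/10 at n=800,
`n0 = 3`).  Five non-zero genes carry the coefficient vectors
(1.5, 1.5, 1.5), (0, 0, 3), (−1.2, −1.4, −1.3), (−2, 0, 0) and
(0, −2.8, 0), hosted by the first cluster of sizes 5, 10, 20 and 40 (the
last hosting two), at the leading gene positions — under exchangeable
correlation the placement is distributionally irrelevant, and both the
host clusters and positions are configurable.  The intercept defaults to
β₀ = 0, which balances the outcome classes; the design description does
not fix it, and it is a plain configuration field.  Each replicate
splits one master seed into independent streams for covariates and
outcome, so `y | X` depends only on the linear predictor.

The imperfect-clustering arm corrupts 16% of gene labels before
screening.  Two mechanisms are provided: the default shuffles the labels
of the sampled genes among themselves (preserving every cluster size and
realising an adjusted Rand index of ≈ 0.71–0.72 against the truth at the
canonical dimensions, matching the reported realized ARIs), and a
uniform-reassignment alternative gives each sampled gene a different
label drawn uniformly.

What the generator does **not** emulate: non-Gaussian marginals, heavy
tails, heterogeneous block sizes within a gene, missing omics, and the
preprocessing artefacts of real multi-omics matrices (normalisation,
probe-to-gene mapping, duplicated samples).  Passing retention checks on
these data therefore demonstrates correctness of the algorithms under
the stated correlation model, not performance on raw TCGA-like input,
which must be preprocessed upstream.

## Monte-Carlo harness

For each replicate the harness simulates a dataset, optionally corrupts
the labels, screens with JSBD, and size-matches the competitors — GMS
keeps exactly as many genes as JSBD retained; OMS keeps `n0` times as
many omics.  Reported quantities are the proportion of replicates in
which all non-zero genes survived and the mean/SD of the retained
fraction.  Replicates are independent, per-replicate-seeded tasks
(joblib-parallelisable; results are invariant to scheduling).  The
acceptance script runs 200 replicates per design point; the test suite
uses 200 at n=200 and 100 at n=400/800 to keep the default run short.
The repeated 5-fold AUC utility refits the entire pipeline inside every
training fold (stratified splits; degenerate folds are skipped with a
warning) and scores held-out probabilities by the rank-based AUC.

## Known limitations

* Only the logistic family is implemented end to end.
* Group-bridge solutions are local minimisers — guaranteed only to
  satisfy the variational fixed-point conditions from the fixed
  initialiser; concave penalties admit multiple local optima.
* The dynamic dendrogram cut assumes a clear within/between association
  gap; heavily overlapping clusters need an explicit cluster count or
  external labels.
* Conditional screening given a set of protected prior variables is not
  implemented.
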