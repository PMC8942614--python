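# Methods

## The model

For `n_p` subjects there are `n = C(n_p, 2)` unordered pairs, ordered
lexicographically (`(i, j)`, `i < j`, 0-based) everywhere in the package.
The response for pair `(i, j)` is a distance (or similarity) between the two
subjects' nodal network features; the design row holds pairwise covariate
contrasts: `|x_i − x_j|` for continuous covariates, `1{x_i ≠ x_j}` for
categorical ones (a multi-level category collapses to a single
different-membership indicator; no dummy expansion). The covariate of
interest is always the last column, and the null hypothesis is that its
coefficient is zero. Coefficients are left unstandardized so that each one
reads as the change in the distance metric per one-unit covariate
difference.

Design rows are invariant to pair orientation, and the distance vector,
design matrix and residual covariance all share the single canonical pair
ordering (`PairIndex`), which removes a whole class of silent misalignment
bugs.

## Features and metrics

A connection matrix must be symmetric (absolute tolerance 1e-8, then
symmetrized as `(C + Cᵀ)/2`), have a zero diagonal and entries in [0, 1].
The weighted degree vector is its row sums. The key-node (hub) vector marks
the top fraction of nodes by degree: exactly `k = round(fraction · n_n)`
nodes (round half to even, so 268 nodes at fraction 0.2 give k = 54), ranked
by degree descending with ties broken by ascending node index. The tie rule
is arbitrary but deterministic; ties have probability zero under the
continuous generators, so the choice cannot affect the simulation results.

Metric conventions:

* **KS**: `sup` of the ECDF gap over the pooled sample points. The scalar
  uses searchsorted on pooled points; the all-pairs kernel is a merge walk
  over pre-sorted rows (numba-JIT when available, pure numpy otherwise),
  with ties consumed per pooled value so tied inputs are exact. Both paths
  are tested against an O(n²) brute-force oracle and `scipy.stats.ks_2samp`.
* **log-KS**: natural log. The KS statistic is the only metric used on the
  log scale (it is the only one whose inference improves under the
  transform); requesting `log=True` for any other metric raises. Since two
  identical empirical distributions give KS = 0, the statistic is floored at
  1e-12 before the log; floored values are counted in the log output.
* **Jaccard**: mismatch proportion over the union of hub sets. The 0/0 case
  (both sets empty) is defined as distance 0 with a warning — unreachable
  under the top-fraction rule, defined for safety. `JD + JI = 1` holds
  exactly.
* **Canberra**: 0/0 terms contribute 0 (the scipy convention, matched
  exactly).

## Inference procedures

**Standard F.** Partial F comparing the full model with the model without
the covariate of interest, referenced to F(1, n − p). Not valid under dyadic
dependence (it over-rejects for continuous covariates); kept as the
baseline.

**F with individual-level effects (ILE).** One indicator column per subject
(the row for pair `(i, j)` has ones at `i` and `j`). The ILE columns sum to
twice the intercept, so the intercept is dropped whenever the block is
present; inference on the covariates is invariant to which redundancy is
removed. The partial F for the covariate of interest equals the
Frisch–Waugh–Lovell residualized F (asserted against that oracle in tests).
Denominator degrees of freedom: `n − (n_p + #covariates)`.

**Dyadic FGLS.** Errors are assumed to satisfy `Var(ε) = σ²`,
`Cov(ε_a, ε_b) = γ` when observations a and b share exactly one subject,
and 0 otherwise: `Σ = σ²I + γS`. This is the natural restriction for
C(n_p, 2) dyadic observations and the only exchangeable-by-subject
structure with two parameters. Estimation is one non-iterated feasible
step:

1. OLS; `σ̂² = RSS/(n − p)`;
2. `γ̂ = (‖Bᵀe‖² − 2‖e‖²) / (n_p(n_p−1)(n_p−2))` where B is the pair-subject
   incidence matrix — the mean residual product over all observation pairs
   sharing one subject, computed in O(n) via the incidence identity;
3. GLS with Σ̂ and a Wald F on the covariate of interest against
   F(1, n − p).

S is the adjacency of the triangular (Johnson J(n_p, 2)) graph with
spectrum {2(n_p−2), n_p−4, −2}, so Σ̂ is positive definite iff
`−σ̂²/(2(n_p−2)) < γ̂ < σ̂²/2`; γ̂ is clipped to 0.999 of the violated bound
(with a logged warning) if the moment estimate falls outside. Solves use
the Woodbury identity with `BᵀB = (n_p−2)I + J`, giving O(n·n_p) cost per
right-hand side; a dense-inverse oracle verifies the solve in tests. With
γ = 0 the procedure reproduces the OLS partial F exactly (σ̂² uses the same
n − p divisor for that reason).

**Freedman–Lane permutation.** The reduced model (all columns except the
covariate of interest) is fitted once; its fitted values stay fixed and its
residuals are permuted to build the null of the partial F. Residuals are
permuted by relabeling subjects — pair `(i, j)` receives the residual of
pair `(π(i), π(j))` — because rows of the pair design are exchangeable only
under relabeling of subjects, not under arbitrary row shuffles. Row
shuffling is available behind a `permute_rows` flag for demonstration and is
not valid for dyadic data. The p-value uses the (b + 1)/(B + 1) convention,
so `p ∈ [1/(B+1), 1]` always; at least 99 permutations are required.
Permutations are generated in vectorized batches (argsort of uniforms), and
each permuted statistic is computed from residualized inner products rather
than refits.

**MDMR (permutation).** The comparator consumes the square distance matrix:
`A = −½ D∘D`, `G = HAH` with `H = I − J/n_p` (for Euclidean D, G is the
centered Gram matrix; its rows sum to zero exactly). The pseudo-F for a
covariate is `[tr(H_full G) − tr(H_red G)] / [tr((I−H_full) G)/(n_p −
p_full)]` using participant-level (not pairwise) designs, with significance
from jointly permuting participant rows/columns of D. MDMR consumes raw
distances — the log transform of KS is a regression-side device — and only
the permutation variant is implemented; analytic MDMR p-values are out of
scope.

## The synthetic-data generators

The generators emulate the validation conditions, not realistic
connectomes: block-Beta stubs are exactly what is needed to plant a
covariate-dependent signal of controllable strength in an otherwise
exchangeable network population.

* Covariates (defaults: 100 subjects): SEX iid fair coin; TRT a uniformly
  random exact half split (n_p must be even); AGE, IQ ~ round(Normal(100,
  15²)). AGE and SEX never enter the generators, so they are true nulls.
* Scenario 1: 268 nodes; one 15×15 high-connectivity block Beta(4, 6)
  shared by all subjects (node range 0–14), one 15×15 covariate-dependent
  signal block (15–29) with entries Beta(s_p·a_i + (1−s_p)·4/3, 6),
  `a_i = max(4/3, 4 + 0.2(IQ_i − 100) + 6·1{treatment})`, everything else
  Beta(4/3, 6). At s_p = 0 the signal block is distributionally identical
  to the background, so the whole generator ignores covariates.
* Scenario 2: the signal moves to the border of a combined 21×21 region:
  high block centered at nodes 3–17, signal = pairs inside 0–20 not inside
  3–17 (105 node pairs, same count as scenario 1).
* Scenario 3: scenario 1 plus two extra high blocks at 30–44 and 45–59.
* Scenario 4: no matrices; degree vectors of length 268 drawn iid
  Normal(100 + s_p·a_i, 1) per subject. Binarizing iid entries makes the
  hub sets uniform regardless of covariates, so every Jaccard test faces a
  true null at every s_p — the built-in specificity check.

Blocks act on node pairs (both endpoints inside the block's node range);
the diagonal stays zero. Block placement uses fixed node indices: all
metrics here are permutation-invariant in node labels, so placement is
immaterial, and fixed indices make outputs reproducible. The border
geometry of scenario 2 (a centered inner block) is one concrete reading of
"expand the border to 21×21"; any border variant with the same pair count
is statistically equivalent for these metrics.

What the generators do *not* emulate: graph topology (small-worldness,
community structure), spatial autocorrelation, measurement artifacts, or
any preprocessing pipeline. Passing the operating-characteristic tests
therefore shows the inference machinery is calibrated and powered under
controlled dyadic dependence — not that any particular real dataset meets
the model's assumptions.

## The rejection-rate study

`run_study` crosses scenario × metric × method × covariate × signal percent.
Every replicate draws fresh covariates and data from a substream keyed by
(master seed, scenario, signal percent, replicate), computes the features,
distances, and designs once, and runs every configured test; rejection
rates are tallied at α = 0.05 with binomial Monte-Carlo standard errors.
Permutation substreams are keyed additionally by (method, covariate) but
deliberately *not* by metric, so the exact JD/JI p-value equivalence holds
replicate-by-replicate inside a study. A failed replicate is logged with
its seed and excluded, and the exclusion count is reported per cell — never
silently dropped. For scenarios 1–3 the replicate path generates edge
weights and accumulates degrees directly (identical random stream to the
matrix generator, asserted in tests) instead of materializing 268×268
matrices.

The 80%-power signal threshold is the *first* grid point whose rejection
rate reaches the level; Jaccard power is known to be non-monotone in signal
percent, and a later dip does not revoke a crossing. Monotonicity is
spot-checked (non-strictly) only for the Euclidean/ILE cells.

Default problem sizes are desk scale: 100–500 replicates per cell and 500
permutations, against 10,000/10,000 in the motivating study; thresholds at
these sizes carry ±1 grid-step uncertainty, which is why the
operating-characteristic tests use three-Monte-Carlo-SE tolerances. All
sizes are plain `StudyConfig` fields.

## Numerical choices and edge cases

* Rank checks are QR-based (tolerance 1e-10 relative to the largest
  diagonal) and name the dependent columns.
* Near-perfect fits (RSS below 1e-12 of the response scale) short-circuit
  the partial F to 0 or ∞ instead of forming a 0/0 ratio.
* A constant pairwise covariate column is an error (the covariate is
  untestable), as are missing covariate values (reported with subject and
  column), duplicate subject ids, and mixed matrix dimensions.
* Subject order is lexicographic by id everywhere; node and subject indices
  are 0-based internally.
* All stochastic entry points take either an integer seed or a
  `numpy.random.Generator`; CLI commands require a seed and echo the
  resolved configuration next to their outputs, and reruns are
  bit-reproducible for a fixed (seed, configuration).

## Known limitations

* A mixed model with random subject intercepts is deliberately not
  implemented (prohibitively slow at replicate scale for this design); the
  dyadic FGLS is the parametric alternative.
* The dyadic covariance restriction is a two-parameter reconstruction; it
  cannot capture heteroscedasticity across subjects.
* Analytic MDMR p-values, directed networks, centrality- or module-based
  key-node criteria, and neuroimaging-native file formats are out of scope;
  inputs begin at the connectivity-matrix stage.
* No multiple-testing adjustment is applied across covariates.
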