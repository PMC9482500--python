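# Methods

This note documents the models and procedures `batsel` implements, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not show.

## Data model and normalisation

Expression is held genes-in-rows, samples-in-columns throughout.  The
raw input is either such a matrix or a long-format two-channel spot
table (one row per sample × spot) with per-spot intensity summaries for
the Cy5 (CH1) and Cy3 (CH2) channels.  Normalised expression is
log2(CH1/CH2) per spot, using either the mean or the median intensity
summary (default median), followed by per-array median centring so each
sample's median log-ratio is exactly 0.  Background columns are carried
but **not** subtracted by default — no particular correction is assumed;
an opt-in flag subtracts CHx_BG with a floor at a small positive epsilon
(1e-3) to keep ratios defined.  Intensities must be strictly positive;
zero or negative values raise an error naming the spot rather than
propagating silently.

Missing cells are imputed with the mean of the gene's observed values
over *comparable* samples, interpreted as samples sharing the class
label when labels exist (all samples otherwise) — the only grouping the
data model provides.  A gene observed in one label group but not the
other falls back to its overall mean.  Imputation is idempotent and a
gene with no observations at all is an error.

## Fuzzy C-means

Gene profiles g_j are partitioned into c clusters by minimising
J_m = Σ_i Σ_j μ_ij^m ‖g_j − p_i‖²_A with the standard alternating
updates (memberships from prototypes, prototypes as μ^m-weighted
means).  A is the identity (plain Euclidean norm); Mahalanobis norms
are out of scope.  Defaults: m = 2, tol = 1e-5 on |ΔJ|, max 300
iterations.  Initialisation is a seeded uniform-random membership
matrix with columns normalised to 1 — the procedure is silent on
initialisation, and a seed is the minimum needed for reproducibility.

Numerical choices: memberships are computed in the log domain
(softmax-style max-subtraction), which keeps the update finite for
fuzzifiers near 1 where d^(−2/(m−1)) overflows; a gene coinciding with
one or more prototypes gets membership split equally among the
coincident prototypes.  The recorded J trace is evaluated after each
full (prototype, membership) sweep, so it is non-increasing by the
usual alternating-minimisation argument, and the test suite asserts it.
Downstream, the hard partition (argmax membership) groups genes; the
imputed log-ratio matrix itself passes unchanged to the network stage.

## Coexpression and differential networks

Pearson correlation over the (sub)set of samples of one state, with at
least 3 samples required; zero-variance genes yield NaN rows that are
flagged, never silently zeroed.  An edge links a pair when |r| > τ
(absolute mode, default — coexpression modules are sign-agnostic in
common practice) or r > τ (signed mode); the inequality is strict, so
r = τ exactly is not an edge.  τ defaults to 0.8.  The differential
network of two states is the symmetric difference of their edge sets —
pairs coexpressed in exactly one state — with each edge tagged by its
source state.  This is the minimal faithful reading of "differential
coexpression"; soft-threshold (power-adjacency) networks and
topological-overlap measures are deliberately not implemented.

## Module detection (fixed-height cut + PAM)

Dissimilarity is d = 1 − |r| (absolute mode) or 1 − r (signed).
Agglomerative clustering (scipy; average linkage by default) gives a
dendrogram which is cut at a predefined height h; the default is
h = 0.99 × root height, which separates only the loosest top-level
structure.  Each resulting cluster is re-dendrogramed; while its own
fixed-height cut at h still separates it, PAM with k = 2 (configurable)
splits it, and the loop repeats until an iteration creates no new
cluster.  Clusters smaller than `min_module_size` (default 5) are
merged into the module whose medoid is nearest (set to 1 to disable).
Finally one PAM pass seeded with the surviving medoids polishes the
assignment, which guarantees the nearest-medoid property exactly.

PAM itself is the classical swap algorithm: random seeded medoids,
then repeatedly evaluate the switching cost S(m, x) = (total assignment
cost after swapping medoid m with non-medoid x) − (current cost),
perform the most negative swap, stop when no swap has S < 0.  Every
executed swap strictly decreases the cost, so termination is
guaranteed; ties break on the lexicographically lowest (medoid,
candidate) gene-id pair, and all assignment ties break to the lowest
medoid gene id, making results order-independent.

The default cut height is deliberately conservative.  When block
structure is strong and well separated (within-block d ≈ 0.1–0.3,
between-block d ≈ 0.9–1.0), an explicit mid-range cut height — the
examples and tests use 0.5 — recovers planted blocks exactly; any value
comfortably between the two distance regimes behaves identically.

## HSIC gene selection with the bat swarm

The fitness of a candidate subset is the empirical HSIC between the
subset's sample-level kernel and a label kernel:
HSIC(K, B) = tr(HKHB)/(n−1)², H = I − (1/n)11ᵀ.  The 1/(n−1)²
normalisation is the standard empirical estimator; the bare trace grows
arbitrarily with n, and at fixed n the normalisation cancels in subset
comparisons.  Defaults: delta label kernel (B_ij = 1 iff y_i = y_j) and
linear gene kernel K = SᵀS for the masked submatrix S; an RBF kernel
with median-heuristic bandwidth is optional.  For the linear kernel the
trace is additive over genes, so per-gene contributions g^T(HBH)g are
precomputed once and subset fitness is a sum — algebraically identical
to forming K, and the tests assert the equivalence.

The optimizer is a swarm of `n_bats` = 30 bats over one continuous
coordinate per candidate gene, run for `n_iter` = 100 iterations.  Per
bat and iteration: a frequency Fr ~ U(Fr_min, Fr_max) = U(0, 2) is
drawn; velocity and position update as v ← v + (x − Gbest)·Fr,
x' ← x + v; with probability 1 − r_i the move is replaced by a local
walk around the best solution found, x' = Gbest + ε·Ā with
ε ~ U(−1, 1) per coordinate and Ā the mean loudness.  The position is
binarised by keeping the k largest coordinates (ties to the lowest
gene id), which enforces fixed cardinality and the unit-length weight
vector u = mask/√k without inventing a transfer-function threshold.  A
candidate is accepted into the bat's state when it improves that bat's
fitness and a U(0,1) draw falls below its loudness A_i, whereupon
A_i ← αA_i and r_i ← r₀(1 − e^(−γt)) (α = γ = 0.9, A₀ = 1, r₀ = 0.5).
Gbest is elitist — it records the best mask ever evaluated — so the
best-fitness trajectory is non-decreasing by construction.  All
randomness flows from one seeded generator and bats update in fixed
order, making runs exactly reproducible.

**Positions are clamped to the unit box** after every move (bounds
configurable; `None` disables).  This is load-bearing, not cosmetic:
accepted local-walk steps otherwise push the incumbent mask's
coordinates ever further above every other coordinate, and because the
walk noise has bounded support, a point is reached where no outside
gene can enter the top k — the search freezes at whatever it found
early.  With clamping, coordinates saturate at the box faces, the walk
amplitude anneals through the mean loudness, and the swarm behaves as a
proper stochastic local search.  On the synthetic benchmark below this
is the difference between median recovery of 3.5/10 and 9/10 planted
genes at identical budgets.

## Classification and evaluation

SVM classification delegates to scikit-learn's SVC (RBF kernel, C = 1
by default) behind a genes×samples interface; tumor (label 1) is the
positive class.  From pooled confusion counts (tpv, fpv, fnv, tnv):
precision tpv/(tpv+fpv), recall tpv/(tpv+fnv), F = 2·Pr·Re/(Pr+Re),
specificity tnv/(tnv+fpv), accuracy (tpv+tnv)/total.  Zero denominators
flag the metric as undefined instead of reporting 0.  ROC tables
tabulate (FPR, TPR) per threshold with "positive" meaning score
strictly above the threshold; the mean tabulated TPR summarises a ROC
table as the arithmetic mean of its TPR column (this is the reading
consistent with published per-operating-point tables), and a
trapezoidal AUC is also reported.  Method comparisons are per-metric
differences (reference − other) in percentage points, two decimals.

Validation is stratified k-fold (default 5) with gene selection
re-run inside every training fold, so the held-out samples never
influence the panel.  No external validation scheme is assumed; nesting
is what makes the reported numbers honest.

## Synthetic benchmark

The generator emulates the structure of two-channel tumor/normal
microarray experiments: balanced labels; i.i.d. Gaussian log-ratios of
SD `noise_sd` (default 1.0); correlated gene blocks built from one
shared latent factor per block, value = √ρ·factor + √(1−ρ)·noise, so
the within-block correlation is ρ in expectation; informative genes
shifted by `effect_size` log2 units in tumor samples (with the default
unit noise SD this is an SD-unit effect, and with zero noise the
construction separates classes exactly); missing cells planted
uniformly at `missing_rate`.  `to_two_channel` inverts normalisation
into a spot table with the 54-feature-column layout of scanner exports
(six channel/background columns plus deterministic filler transforms of
them), round-tripping through `log_ratio_normalize` up to median
centring.

What it does not emulate: dye bias and dye-swap designs, spatial and
probe-level artifacts, heavy-tailed intensity noise, many-to-one
probe-to-gene maps, unbalanced classes, and correlation between the
informative genes and the module blocks (informative genes are drawn
outside the blocks).  Passing the benchmark therefore shows the
pipeline's machinery is correct and well-calibrated on clean planted
structure, not that it is robust to real-array artifacts.

Benchmark scale: the recovery study uses 200 genes × 60 samples with 10
informative genes at 1.5 SD, 10 seeds; oracle comparisons use 10–20
item instances where exhaustive enumeration is exact.  These sizes make
the full suite and the acceptance script run in seconds while leaving
the statistics (binomial bounds, permutation nulls, medians over seeds)
meaningful.

## Known limitations

- Candidate sets for selection (all genes, module medoids, differential-
  network genes) are computed once on the full data in the pipeline;
  only the subset search itself is re-run inside CV folds.
- The fixed-cut/PAM loop is a deliberate simplification of adaptive
  dendrogram-cut algorithms; it has no per-branch adaptive height.
- Probe-to-gene collapsing is first-match only; GEO SOFT parsing and
  dye-swap normalisation are out of scope.
- The swarm optimises a fixed cardinality k; k itself is a user choice,
  not searched.
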