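# Methods

## Data model and preprocessing

A cohort is a samples x CpG-loci matrix of beta values in [0, 1] with
`NaN` marking failed probes, plus per-sample labels (cancer type,
malignant flag).  Beta values derive from probe intensities as
`max(M,0) / (max(M,0) + max(U,0) + alpha)` with `alpha > 0` (default
100, the Illumina-recommended offset), so a value is 0 exactly when no
methylated signal was detected and always strictly below 1.

Preprocessing has two steps, in a fixed order:

1. **Sample rejection** on *raw* missingness: a sample is dropped when
   its missing fraction strictly exceeds the platform threshold — 10%
   for 27k arrays, 20% for 450k arrays, explicit for custom platforms.
   Samples at exactly the threshold are retained.  Rejection precedes
   imputation because a sample rejected from training should not first
   be partially reconstructed.
2. **Imputation** by per-sample linear regression of beta on locus
   index.  Interior gaps reduce to linear interpolation between the
   flanking observed loci; runs of missing values at either edge are
   extrapolated from the least-squares line through the k = 4 nearest
   observed loci.  Imputed values are clamped to [0, 1].  The scheme is
   deterministic and borrows no information across samples, so the
   result is independent of cohort composition and processing order.
   (Whether cross-sample borrowing would be preferable is an open
   modelling question; the per-sample reading is the simplest one
   consistent with a row-wise "linear regression" imputation.)

CSV formats: beta matrices have locus ids as the header row, sample ids
in the first column, empty cells for missing values; label files carry
`sample_id, cancer_type, malignant`.

## Synthetic cohorts

Real Infinium beta values are bimodal: probes concentrate near an
unmethylated and a methylated mode.  The generator emulates this with
Beta-distributed draws.  Each *informative* locus assigns every class
either the hypomethylated mode `0.5 - s/2` or the hypermethylated mode
`0.5 + s/2` (never the same mode for all classes), where
`s = informative_separation`; each *noise* locus has one randomly chosen
mode shared by all classes.  Draws use a Beta distribution with mean at
the mode and concentration `noise_concentration` (default 30, giving
within-class standard deviations of roughly 0.07–0.09, comparable to
well-measured array probes).  Missingness is injected cell-wise,
independently, at a configurable rate.

Defaults describe the desk-scale study condition used throughout the
tests: a custom 500-probe platform, 50 informative + 450 noise loci,
three cancer types of 20 samples each, separation 0.6.  What the
generator deliberately does **not** model: probe chemistry and type I/II
bias, batch effects, chromosomal correlation between neighbouring CpGs,
and cell-type composition.  Passing recovery tests therefore show that
the selector finds class-informative signal under realistic marginal
distributions — not that it is robust to the structured artefacts of
production array data.

## Inner layer: grouping GA over sample partitions

The chromosome is a permutation of sample indices cut into contiguous
logical clusters; cluster count and sizes are free.  Initial individuals
draw a uniform random permutation and a cluster count uniform in
`2..ceil(sqrt(n))`.

**Fitness.**  With squared Euclidean distance over the currently
selected loci, `alpha_c` is the size-weighted dispersion of cluster
centroids about the overall centroid and `gamma_c` the pairwise
within-cluster dispersion `sum_h (1/(2 S_h)) sum_{i,j in C_h} d(i,j)^2`
(identically the sum of squared distances to cluster centroids).  The
fitness is the Calinski–Harabasz index
`F_CH = (alpha_c/gamma_c) * (n - k)/(k - 1)`, higher better.  A
partition with `gamma_c = 0` (e.g. all singletons) is flagged degenerate,
carries a sentinel fitness, and is excluded from elitism and given no
selection advantage — otherwise the objective's known fragmentation bias
would collapse the population into singletons.

**Operators.**
*MPX crossover* (applied with probability 0.30): the target is the
cluster whose centroid lies nearest the overall centroid — the least
distinctive one.  A substring of random offset and length within that
cluster is removed from the first parent; the removed items re-enter in
the second parent's relative order, appended sequentially into the first
parent's final surviving cluster.  Both directions are built and the
fitter offspring kept.  Appending into the final cluster (rather than
opening new clusters) makes the operator a strong merger; the split
mutation can always carve the items off again.  This choice was made
because the alternative — re-inserting transplanted items as their own
clusters — left the population stuck in fragmented pure subclusters far
below the optimum on clearly separated data.
*Split/merge mutation*: with probability ramping linearly from 0 to the
10% cap over the configured generations, either one cluster splits at a
random interior point or two neighbouring clusters merge; the move type
is uniform over whichever of the two is feasible.
*Selection* is roulette-wheel on min-shifted fitness
(`f' = f - min(f)`, uniform fallback when all equal); *elitism* copies
the best individuals unchanged, so the best-fitness trajectory is
non-decreasing.

**Canonical arrangement.**  After initialisation and after every child
is produced, the arrangement is put in canonical order: items sorted
within each cluster by their score on the data's first principal axis,
clusters sorted by mean score.  This changes neither the grouping nor
the fitness (asserted by test), but it aligns the contiguous encoding
with the data's dominant axis of variation, so split points and
neighbour merges act on spatially coherent segments.  Without it the
split/merge moves cut arbitrary subsets and the GA needs an order of
magnitude more generations to approach the optimum.

**Evaluation fast path.**  `run_ilga` precomputes the full pairwise
squared-distance matrix once per masked dataset; each partition is then
scored in O(n^2) index arithmetic using the total-variance decomposition
`alpha_c = total SSD - gamma_c`.  The public `ch_fitness` computes both
terms literally from the data; tests assert the two paths agree to 1e-9
and match an independent reference Calinski–Harabasz implementation.

## Outer layer: binary GA over locus masks

Chromosomes are boolean vectors over the platform's loci, initialised
with independent 0.5 bits (re-seeded to at least 2 set bits, the minimum
evaluable mask).  A mask's fitness is obtained by restricting the cohort
to its selected loci — the mask multiplies the feature space — and
running the inner GA to convergence; the converged best `F_CH` is the
mask's fitness.  The alternative reading of coupling fitness to the
*number* of selected features was rejected: it would monotonically
reward larger masks and make dimensionality reduction impossible.

Operators: single-point crossover (tails swapped after one uniform cut),
roulette selection, elitism, and adaptive bit-flip mutation with per-bit
probability `p_max * f_avg/f_best` (shifted fitnesses of the latest
generation, `p_max = 5%`): mutation pressure rises as the population
converges.  Elite masks carry their fitness records unchanged into the
next generation — the inner GA is not re-run for an unchanged
chromosome — which both saves the dominant cost and guarantees a
monotone elite trajectory despite the stochastic inner evaluation.

Each chromosome's evaluation is independent and seeded by hashing
(master seed, generation, chromosome index) through
`numpy.random.SeedSequence`, so concurrent evaluation (joblib threads,
`n_jobs > 1`) reproduces the sequential result bit for bit.

Per-cancer masks are intersected bitwise into the common pan-cancer
locus set consumed by the classifiers.  Population sizes default to 30
(outer and inner); generations default to 100 (outer) and 200 (inner)
and are scaled down in tests (20 x 20 outer, 50 x 20 inner on the
500-locus cohort) to keep the suite desk-scale.

## Classification

Fully connected ReLU networks with a softmax head, trained on
cross-entropy with mini-batch Adam.  Adam follows the standard
formulation: first/second moment averages with decay 0.9/0.999,
bias-corrected (`m_hat = m/(1-b1^t)`, `v_hat = v/(1-b2^t)`), update
`-lr * m_hat/(sqrt(v_hat) + eps)` with `eps = 1e-8`.  Loss, batch size
(32), epoch budget (100) and early stopping (patience 10 on a validation
split, best parameters restored) are implementation choices; the
gradient computation is verified against finite differences.

Feature masking zeroes unselected inputs before the first layer —
numerically equivalent to zeroing the corresponding first-layer weight
rows, and easy to verify: perturbing any unselected coordinate never
changes the output.

Hyperparameter search is an exhaustive grid over learning rates (0.1,
0.01, 0.001), base hidden sizes (512, 256, 128, 64) and hidden-layer
counts (1, 2, 4); multi-layer stacks halve the width per layer (e.g.
base 256 with 2 layers gives 256, 128).  Ties break toward fewer
parameters, then lower learning rate.  The binary model defaults to one
512-unit layer and the pan-cancer model to (256, 128), both at learning
rate 0.001 — the optima this grid typically selects.

The 70/30 train/test split is stratified by the malignant flag within
each cohort, with a fixed derived seed.

## Evaluation metrics

Confusion matrices are rows-true/columns-predicted.  Per class,
one-vs-rest accuracy, precision (`TP/(TP+FP)`, reported as 0 with a flag
when no positive predictions exist), recall and F1.  Because per-class
"accuracy" of a binary model is ambiguous, the one-vs-rest per-class
accuracy and the overall accuracy (trace/total) are both reported,
labelled explicitly.  MCC uses the generalized multi-category
coefficient, which reduces exactly to the familiar binary formula at
K = 2; a zero denominator yields 0 by convention.  ROC curves are
one-vs-rest with thresholds at distinct scores and trapezoidal AUC;
macro AUC is the unweighted mean over classes (classes lacking either
positives or negatives are skipped and flagged), micro AUC pools the
(sample, class) indicator stream.  Heat-map matrices are row-normalized;
zero rows stay zero with a flag.

## Pipeline, seeding, determinism

`run-all` executes preprocess -> per-cancer selection -> intersection ->
training -> evaluation, writing every artifact plus a manifest with the
config hash and all derived seeds.  The seed chain is
`SeedSequence(master, spawn_key=(stage, cohort))`, then
`(master, generation, chromosome)` inside the outer GA; all derived
seeds stay below 2^31.  Two sequential runs with the same config and
master seed produce byte-identical masks and reports (asserted by
test).  Each CLI stage (`simulate`, `preprocess`, `select`,
`intersect`, `train`, `evaluate`) also runs standalone from files, so
any stage can be reproduced in isolation from cached upstream artifacts.

Replicate stability of the selector is summarised as the mean selected
count with a textbook 95% t-interval, normalized by the mean (the form
in which selector stability is usually quoted).

## Known limitations

- The selector's fitness signal degrades with class-separation and
  sample-size; at the desk-scale test condition (60 samples, separation
  0.6) enrichment of truth loci is strong but the selected set is far
  from exactly the informative set.
- The canonical-arrangement heuristic keys on the first principal axis;
  data whose cluster structure is orthogonal to the dominant variance
  direction would lose most of its benefit (the GA remains correct, just
  slower).
- The numpy MLP targets desk-scale inputs; no GPU path, no sparse
  input handling for full 450k-width matrices.
- The multi-host distributed evaluation of the original software design
  is out of scope; concurrency is single-host (threads) under an
  order-independent reduction contract.
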