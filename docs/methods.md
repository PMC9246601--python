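# Methods

`swarmnas` implements two swarm-intelligence searches over a constrained
space of sequential convolutional networks for severity grading of retinal
fundus images, together with the search-space calculus, the evaluation
metrics, a synthetic data generator, and an experiment pipeline. This note
records the model choices, the defaults and why, and what the tests do and
do not establish.

## The search problem

A candidate model is an ordered sequence of layers over the vocabulary
{C2D, BN, DO, MP, AP, DE, F}. With `t_l` layer kinds and lengths bounded by
`B_l..B_u`, the unconstrained space has exactly

    t_s = sum_{b=B_l}^{B_u} t_l^b

sequences; for four kinds and lengths 3–20 that is 1,466,015,503,680. All
counting is exact integer arithmetic (`count_search_space`,
`count_parameterized_space`); no floating point is used anywhere in the
calculus.

`count_parameterized_space` offers two modes for the per-layer parameter
permutation counts `P_i` with layer multiplicities `n_i`: a literal
sum-of-powers `sum P_i^{n_i}` and the combinatorial product
`prod P_i^{n_i}` (the number of distinct parameterizations of a fixed
sequence). For `P = [9, 2, 1, 4]` and `n = [12, 1, 15, 3]` the sum form
gives 282,429,536,548; we are aware of a published figure of
282,429,569,261 for this configuration that neither mode reproduces, so
both interpretations are provided and the computed values stand as-is.

Three structural rules keep candidates trainable as image classifiers: at
least one dense (DE) layer; a flatten (F) before the first dense layer; no
convolution after the flatten. `validate_architecture` reports violations
as values; `repair_architecture` deterministically restores validity by
appending a dense layer if none exists, re-inserting a single flatten
immediately before the first dense layer, and dropping spatial layers
(conv *and* pooling — pooling cannot be applied to a flat tensor) stranded
after the flatten. Repair is idempotent: already-valid architectures pass
through unchanged, which makes a full block-copy of the global best a
fixed point of the particle update.

## Ant-colony-system search

The graph starts as an input-only root. When an ant reaches an unexpanded
node, every concrete layer choice (kind × parameter permutation) is added
once as a child with initial pheromone `tau0`. Selection follows the
ant-colony-system pseudo-random proportional rule: with probability `q0`
the maximum-pheromone child (ties to the lowest index), otherwise
pheromone-proportional sampling. Each traversed edge receives the local
update `tau' = (1-rho) tau + rho tau0`; after all ants of a depth round
are evaluated, the round's best ant reinforces its path with
`tau' = (1-rho) tau + rho f` where `f` is its fitness. Both updates are
convex combinations, so local updates contract pheromone geometrically
toward `tau0` and the global update contracts on-path pheromone toward the
best fitness — properties asserted directly in the tests.

Defaults `q0 = 0.5`, `rho = 0.1`, `tau0 = 1.0` are the canonical
ant-colony-system settings; the literature this search descends from names
the rules without printing constants, so these are deliberate,
configurable choices. No heuristic desirability term is used — selection
is pheromone-only. The round best (not the all-time best) triggers the
global update, matching the "all ants reach the same depth, then the best
is chosen" schedule. Identical candidates are deliberately re-evaluated
rather than cached so the trained-model count is exactly `ants × depth`.

The ant vocabulary is [C2D, MP, BN, DE] with permutation counts
(9, 2, 1, 4), realized as conv filters {32, 64, 128} × kernels {1, 3, 5},
max-pool sizes {2, 3}, parameterless batch norm, and dense units
{64, 128, 256, 512}. Only the counts are fixed by the search design; the
grids are conventional values chosen to reproduce them exactly.

## Particle-swarm search

Particles are whole architectures. The classical continuous update
(`X += V` with inertia `w` and coefficients `c1 r_t1`, `c1 r_t2`) does not
apply to a discrete layer sequence; those symbols are retained in
`PSOConfig` as documented, unused fields, and the executed move is a
block-copy plan: per aligned slot, the source is the global best with
probability `Cg` (default 0.5) and the personal best otherwise, copying
only where the particle differs from that source. When a source is longer
than the particle, trailing slots may be appended from it under the same
`Cg` rule, truncated at `B_u` — this is how architectures grow or shrink
toward the best performers; the alignment anchors at the input end. Merged
sequences keep only the first flatten, and every move ends with the repair
pass, so each intermediate architecture in the history is valid.

Random initialization draws a trunk of length uniform in `[B_l, B_u]`
i.i.d. over conv/pooling/dense kinds with probabilities 0.7 / 0.15 / 0.15,
then stably partitions it so dense layers come last (the sampled kind
multiset — and hence the empirical kind frequencies — is preserved; a
pooling draw is a fair coin between max and average pooling). Batch norm
is attached after conv/dense layers with probability 0.5 and dropout
(rate 0.5) with probability 0.3, under a decoration budget that keeps the
pre-repair length within `B_u`; repair can add at most a flatten and one
dense layer beyond it. Initialization ranges follow the search design:
conv outputs 3–256, kernels 3/5/7, dense units 1–300, lengths 3–20.

Runs are independent (`r` restarts, each with its own generator derived
from the global seed), the per-run gbest trace is non-decreasing, and the
cross-run winner is chosen by fitness, then smaller trainable-parameter
count, then earlier discovery — favouring lightweight models.

## Candidate evaluation

Fitness is validation accuracy on a fixed stratified 80/20 split after
brief training (1 epoch per particle evaluation by default; the final best
is retrained longer). The trainer backend is a compact numpy CNN:
same-padding stride-1 convolutions via im2col, batch norm (2 trainable
terms per channel, running statistics with momentum 0.9), inverted
dropout, max/average pooling with stride = pool size, dense layers, leaky
ReLU activations (slope 0.1 — plain ReLU proved prone to whole-network
death under short aggressive training of randomly searched stacks), a
softmax classification head appended to every candidate, and Adam. Inputs
are standardized per channel with training-split statistics inside
`train_and_score`, so every training path — fitness evaluation, final
retrain, cross-validation — sees well-conditioned data. All randomness
flows from one seed, so training is bit-reproducible on a fixed
single-threaded BLAS. Default optimizer settings (learning rate 3e-3,
batch size 16) were selected on a panel of random desk-space
architectures for the small-sample regime the searches operate in
(hundreds of images, a few epochs). `fit` restores the
weights of the best-validation epoch by default, which guards candidate
scoring against late-epoch instability in deeper stacks; early stopping
monitors validation accuracy with configurable patience (minimum one
epoch). Divergence (non-finite loss) scores fitness 0 with a warning, and
an evaluator failure inside a search logs the candidate at fitness 0 and
continues, keeping the evaluation count exact.

Parameter counting uses the stated conventions (conv `k·k·c_in·f + f`,
dense `d·u + u`, batch norm `2c`, nothing for pooling/flatten/dropout) and
counts the listed layers only — the softmax head that instantiation
appends is excluded, so the count describes the architecture, not one
task-specific realization of it.

Metrics: accuracy is `trace/total` of the confusion matrix; per-class
one-vs-rest AUC is the Mann–Whitney rank statistic with tied scores
counting 0.5 (classes lacking positives or negatives are skipped with a
warning and excluded from the macro average); Cohen's kappa is
`(po - pe)/(1 - pe)` from the confusion-matrix marginals, with a
quadratic-weighted option because ordinal severity grading is commonly
scored that way. The tests verify all three against independent
brute-force oracles (pair counting for AUC, direct po/pe for kappa) to
1e-12 and cross-check against scikit-learn. Stratified k-fold splitting
wraps scikit-learn's `StratifiedKFold` and adds a hard error naming any
class with fewer members than folds.

## Synthetic data

The generator emulates the monotone lesion structure that drives real
severity grading: a class-`k` image is a reddish retinal disc with a
radial falloff, one off-centre yellow optic-disc ellipse, and exactly `k`
small bright near-white blobs (hard-exudate-like; the blue channel
separates them from the optic disc) at rejection-sampled non-overlapping
positions inside the disc, plus additive Gaussian noise clipped to [0, 1].
Class proportions default to the 5-class APTOS-style skew
1805 : 370 : 999 : 193 : 295 via largest-remainder rounding (which
conserves the total exactly); the "easy profile" used for search-quality
tests is 600 images, 32 px, noise 0.02, uniform classes. Because the label
*is* the blob count, a ground-truth oracle classifies perfectly at zero
noise, and increasing noise monotonically degrades intensity-based
classifiers — difficulty is a single dial.

What passing tests show: that the searches optimize a real training
signal, respect their budgets, and return architectures that train to high
accuracy on a separable task. What they do not show: performance on real
fundus photographs, which vary in illumination, orientation, lesion
morphology and label noise far beyond this generator; no photorealism,
vessel trees or segmentation masks are attempted.

## Experiment pipeline

`run_experiment` wires generator (or an image directory with an
`id_code,diagnosis` CSV) → search → final retrain → metrics, writes
best-architecture JSON (with the canonical notation embedded), history
CSV, metrics CSV, a log, and an experiment record containing the seed and
full settings — sufficient to replay bit-identically with the
deterministic trainer. A success flag records whether each metric + its
tolerance reaches its goal; the defaults (accuracy 74.8% with 1.5-point
tolerance, AUC 0.91 with 0.2, kappa 0.776 with 0.02) encode "beat the
best pretrained baseline" for each metric.

## Problem sizes

Desk-scale settings used throughout the test suite and the acceptance
script, chosen as this package's single-CPU study conditions: search space
with conv filters {8, 16, 32} × kernels {3, 5}, pooling size 2, dense
units {16, 32, 64}, lengths 3–10 (`desk_space`); ant runs of 4 ants ×
depth 6 and particle runs of 1–2 runs × 3 iterations × 4–5 particles;
training on 600 32-px images with 1-epoch fitness evaluations and a
5-epoch final retrain. The full-scale budgets (16 × 32 = 512 ant models,
5 × 12 × 20 = 1200 particle models, 10-fold cross-validation at up to
128 px) are exercised arithmetically and by the same code paths.

## Known limitations

- The numpy backend is single-threaded and unsuitable beyond small images
  and datasets; it exists to make the searches executable and
  deterministic, not to compete with GPU frameworks.
- One-epoch fitness is a noisy ranking signal; the searches tolerate this
  (the retrained best is much stronger than its search-time fitness), but
  desk-scale gbest choices can be suboptimal.
- Only sequential (chain) architectures are representable — no branches,
  no skip connections.
- The quadratic-weighted kappa option and per-class AUC lists are reported
  but not used as search fitness.
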