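# Methods

## The model

`enggnn` implements a dual-graph neural classifier for high-dimensional
omics matrices (n samples × p features, binary outcome). Two feature graphs
over the same p features drive the architecture:

* an **external graph** Ge — undirected, from curated biological networks
  (protein–protein interactions, tissue-specific functional networks), given
  by the user as an edge list over feature names;
* a **generated graph** Gg — directed, extracted from a gradient-boosted
  tree ensemble fitted to the training data: within each tree, every internal
  node splitting on feature f whose child also splits on f′ contributes the
  edge f → f′; per-tree graphs are unioned across the ensemble.

Each graph masks the first layer of one *graph-embedded deep feedforward
network* (GEDFN): with Ã = A + I the self-loop-augmented adjacency,

    H1 = σ( X (W ⊙ Ã) + b ),

so hidden unit u aggregates only feature u itself and its graph neighbours
(rows of Ã index input features, columns hidden units). The mask is applied
multiplicatively at every forward pass, so weights outside the graph support
have exactly zero effect and exactly zero gradient — a property the test
suite verifies directly rather than assumes. Both branches continue with
fully-connected layers of widths 64 and 16 (ReLU); the two 16-wide
embeddings are concatenated and passed through one 16-unit hidden layer to a
2-class softmax. Branches and head are trained jointly under a single
categorical cross-entropy loss; nothing is pre-trained stage-wise, since the
procedure is a single pipeline with one output loss.

Single-branch ablations (external graph only; boosted-tree graph only;
random-forest graph only) use one masked branch with a 16 → 2 head, and the
graph-free DFN baseline is the identical stack with an all-ones mask, so the
effect of masking is isolated from everything else. Raw boosted-tree and
random-forest classifiers complete the baseline set.

The networks are implemented directly in NumPy (forward passes, hand-derived
backpropagation, Adam). The architectures are small and fixed, the masked
layer is the scientific core of the package, and an explicit implementation
makes the mask-opacity and oracle-equivalence guarantees exactly testable.

## Training

Defaults (all exposed in `TrainingConfig`): Adam with learning rate 1e-4,
50 epochs, batch size 16, ReLU activations, dropout 0.2 on the
fully-connected hidden layers. Dropout is never applied to the masked layer
or the raw inputs: dropping inputs would corrupt the graph-aggregation
semantics of H1. Early stopping monitors the loss on a stratified 10%
validation split carved from the training data, with patience 5, and
restores the best-epoch weights; monitoring the training loss instead is a
config option. Weight initialization is variance-scaled (He) over the full
unmasked shapes — masked entries are inert regardless. All randomness
(initialization, shuffling, dropout, validation split) flows from one seeded
generator, so fits are bit-reproducible on fixed thread settings.

Z-score normalization is computed on the training split only (population sd,
floored at 1e-8 so constant features map to zero) and the stored statistics
are reapplied to held-out rows, avoiding information leakage. For the same
reason the graph-generating ensemble is always fitted on the training split
only: Gg is part of the learned model. The ensemble size defaults to
max(1, round(0.2 p)), scaling complexity with dimensionality; remaining
boosting hyperparameters (depth 6, learning rate 0.3, L2 = 1, binary
logistic objective, exact split finding) are the ecosystem defaults of the
sparsity-aware boosting implementation and are config-exposed.

## Feature importance

Per branch, feature j scores the masked row-sum plus masked column-sum of
the first-layer weight matrix; the model's score is the sum over branches
(the absent branch contributes zero for single-branch models; the DFN uses
its all-ones mask). By default the **magnitudes** of the weights are summed.
The signed variant (summing raw weights) is available, but signed sums over
many masked connections cancel toward zero, collapsing the ranking toward
chance, whereas the magnitude ranking recovers the simulator's informative
features well above chance (the toy-scale benchmark in the test suite checks
exactly this), so magnitudes are the scientifically defensible default. Scores are taken from the effective masked weights at the
early-stopping checkpoint and converted to pseudo-probabilities by the
percentile-rank (empirical CDF) transform, with ties sharing the maximal
rank — deterministic, order-preserving, and comparable across models. Tree
baselines contribute their native importances (boosting gain; random-forest
Gini mean-decrease-in-impurity), percentile-ranked the same way.

## The simulator

The generator emulates expression data coupled to a biological network:

1. **Graph** — Barabási–Albert preferential attachment on p nodes
   (attachment m = 1 by default, the sparsest scale-free graph; the
   heavy-tailed degree distribution is verified empirically in tests).
2. **Covariance** — every edge gets a Uniform[0.1, 10] weight in a weighted
   adjacency A*, and Σ_X = (I − A*)⁻¹ Σ_ε (I − A*)⁻ᵀ with Σ_ε = I and error
   mean 0. By default A* is **symmetric** (the weighted version of the
   undirected adjacency). A strictly-upper-triangular orientation is also
   provided; it guarantees invertibility algebraically, but its unit-
   triangular inverse compounds edge weights multiplicatively along graph
   chains, so one or two features end up carrying ~98% of the outcome
   variance and every classifier — including plain boosted trees — becomes
   trivially perfect. The symmetric form spreads signal over many correlated
   features and yields baseline difficulty consistent with the published
   benchmark, so it is the default.
3. **Features** — X ~ MVN(μ_X, Σ_X), μ_X ~ Uniform[7, 13] per feature.
   Sampling uses the SEM factor B = (I − A*)⁻¹ directly (Σ_X = BBᵀ), which
   is numerically safer than factorising Σ_X itself.
4. **Informative set** — round(pt·p) seed features drawn 80% from the top
   half of the closeness-centrality ranking and 20% from the bottom half
   (hubs are more likely disease-relevant), then expanded by all one-hop
   neighbours; centrality ties break by node index.
5. **Outcome** — η = β0 + x_imp·β with β ~ Uniform[−5, 5] and
   β0 ~ N(−5, 5²); φ min-max rescales η to [0, 1]; g = exp(φ) + φ². Since g
   maps [0, 1] into [1, e + 1], comparing g with a sub-1 threshold directly
   would label every sample positive. The default rule treats s = 0.6 as a
   quantile level: y = 1 iff g exceeds its empirical 60th percentile, fixing
   the positive fraction at 0.4 — mild class imbalance, consistent with the
   benchmark's accuracy/F1 relationship. An alternative that min-max
   rescales g before thresholding is available (`threshold_mode="rescaled"`);
   it labels only the extreme upper tail (~5%) positive. Both rules are
   monotone in η, so the min-max-invariance and boundary properties hold for
   either. β0 is annihilated by the min-max transform; it is drawn and
   recorded for provenance only.

What the simulator does *not* emulate: measurement noise floors, batch
effects, non-Gaussian marginals (real expression data are typically
log-skewed counts), graph misspecification (the external graph handed to
the model is exactly the generating graph), and label noise. Passing
benchmarks here therefore demonstrate correct mechanics and relative model
ordering under a favourable prior, not expected real-data performance.

## Benchmark protocol

Nine scenarios cross sample-to-feature ratio pn ∈ {0.05, 0.1, 0.2} (so
p ∈ {250, 500, 1000} at n = 5000) with true-feature proportion
pt ∈ {0.05, 0.1, 0.2}. Per replicate: simulate with seed base_seed + r,
split 80/20 stratified by class, fit each model on the training split,
score classification on the test split and feature selection against the
simulator's ground truth (ROC-AUC; PR-AUC via the average-precision step
estimator — trapezoidal PR interpolation is biased). Predicted labels are
the softmax argmax. Tables report mean (SD) over replicates; model pairs are
compared with Welch's unequal-variance t-test on the per-replicate vectors.
Failures are logged and marked as failed cells, never silently dropped.

The published protocol uses 20 replicates per scenario; the package's
acceptance run and test suite use 5 replicates of the p = 250 scenario and a
reduced-n toy scenario for the directional checks, sizes chosen so the whole
suite runs on a single CPU in minutes. The full 20-replicate, 9-scenario,
7-model grid is available through `ScenarioSpec`/`run_scenario` (or the
`benchmark` CLI) and simply takes hours.

## Known limitations

* Binary outcomes only (K = 2 softmax); no multi-class or multi-omics.
* External graphs are binarized; edge confidences are not used beyond an
  optional pre-filtering by the user.
* The tree-graph construction ignores split gain/cover; edges are unweighted
  and multiplicity is discarded, matching the downstream masking which is
  itself binary.
* NumPy execution is CPU-only; at p ≫ 1000 the p × p masked layer dominates
  cost and a GPU implementation would be preferable.
* With the symmetric SEM orientation, I − A* is invertible only generically;
  a singular draw (probability zero for continuous weights) raises a clear
  error rather than being silently regularised.
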