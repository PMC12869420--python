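# enggnn

Dual-graph neural networks for disease classification and feature selection
on high-dimensional omics data.

## The problem

Expression matrices are wide (p features ≫ n samples), features are not
independent — they sit on biological networks — and practitioners need both
a good classifier and an interpretable ranking of the features driving it.
Graph-informed neural networks address this by restricting connectivity to a
feature graph, but any single graph is a partial view: curated networks are
incomplete or misannotated, and data-driven graphs encode task noise.

`enggnn` implements a dual-graph model that uses both. An **external
undirected graph** Ge (e.g. a protein–protein interaction or tissue-specific
functional network) masks one network branch; a **generated directed graph**
Gg, extracted from a gradient-boosted tree ensemble fitted to the same
training data (parent-split → child-split edges, unioned over trees), masks
a second branch. Each branch is a graph-embedded deep feedforward network
whose first layer is

    H₁ = σ( X (W ⊙ Ã) + b ),        Ã = A + I,

so a hidden unit aggregates only a feature and its graph neighbours. The two
16-wide branch embeddings are concatenated and classified by a small fusion
network with a softmax output; everything is trained jointly under one
cross-entropy loss. Feature j is scored by connection weights,

    IF_j = IF_j^{Ge} + IF_j^{Gg},

the masked row- plus column-sums of each branch's first-layer weights,
converted to percentile-rank pseudo-probabilities for comparison across
models. The package also ships every ablation and baseline used in its
benchmark protocol (single-graph networks, graph-free DFN, raw boosted
trees and random forest), a scale-free-network simulator with
centrality-stratified informative features and a nonlinear thresholded
outcome, the replicated benchmark harness, and Welch-test model comparison.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
python examples/02_train_and_rank_features.py
```

simulates a dataset (p=100, n=1000, 20% seed features), fits the dual-graph
model and prints:

```
training stopped after 28 epochs (best validation loss 0.1762)
generated graph: 178 directed edges from the tree ensemble
test accuracy 0.955, ROC-AUC 0.992, F1 0.944
feature-selection ROC-AUC 0.742, PR-AUC 0.776 (ranking scored against the simulator's ground truth)

top 5 features by connection-weight importance:
feature    if_ge    if_gg  if_total  percentile_rank  rank_order
     f1 4.630317 2.081834  6.712151             1.00           1
    f85 0.455029 3.502838  3.957867             0.99           2
...
```

Accuracy/ROC-AUC/F1 score the classifier on the held-out 20% split; the
feature-selection ROC-AUC of 0.742 says the importance ranking places the
truly informative features (known here because the data are simulated) well
above the rest. `examples/01_simulate_dataset.py` dissects the generator and
`examples/03_benchmark_models.py` runs a small replicated comparison against
the graph-free network and boosted trees.

The same workflow is available from the shell for user-supplied files
(TSV expression matrix + two-column edge list over feature names):

```bash
enggnn simulate --p 100 --n 1000 --pt 0.2 --seed 1 --out-prefix sim
enggnn train --matrix sim.expression.tsv --labels sim.labels.txt \
             --graph sim.edges.tsv --model enggnn --out model.pkl
enggnn importance --model model.pkl --out ranked_features.tsv
enggnn benchmark --pn 0.05 --pt 0.1 --replicates 5 --out-prefix bench
```

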