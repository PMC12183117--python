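# Methods

This note documents the modelling assumptions, the defaults that matter,
the synthetic-data generator, and the numerical and design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The prediction problem

Given a protein and a GO sub-ontology (BP, MF or CC), predict a score in
[0, 1] for every term of a fixed vocabulary. The vocabulary is built from
the ancestor-propagated training annotations: every term annotated at
least `min_count` times (default 1), namespace roots excluded. Ground
truth obeys the true-path rule (a term implies its ancestors), so label
sets are closed under ancestors before training and evaluation, and
prediction scores are made monotone along `is_a` edges (each term's score
becomes the max over itself and its descendants) before metrics are
computed. Only `is_a` edges are used by default; `part_of` can be enabled
via `parse_obo(..., include_part_of=True)` but crosses namespaces and is
therefore pruned to within-namespace edges.

## Architectures

* **MLP head** (sequence and structure-aware modalities): blocks of
  linear → SiLU → dropout over a fixed per-protein embedding, final
  linear to one logit per term. Defaults: one hidden layer of 128, dropout
  0.3.
* **Ego-graph network** (interaction modality): per query protein, the
  subgraph of its top-k interaction partners ranked by (confidence
  descending, partner id ascending), k = 100 by default, including the
  edges among selected partners, with a self-loop on every node so
  isolated proteins remain a valid single-node graph. Node features are
  the partners' (pooled) embeddings. Message passing is GAT by default
  (multi-head additive attention with per-destination softmax), with GCN
  (symmetric degree normalization) and GIN (neighbour sum + two-layer MLP,
  ε = 0) as alternatives; the center node's final representation feeds the
  output layer. Defaults: 2 layers, hidden 64, 4 heads, dropout 0.3.
  Edge confidences select and rank the neighbourhood but are not used as
  message weights; attention learns its own weighting.
* **Label embedder**: the protein's binary label vector through
  linear → SiLU → linear into the predictor's output space, so label
  embeddings M and prediction vectors Z are directly comparable. It exists
  only during training.

One activation (SiLU) is used throughout, including inside the graph
layers, to keep the three architectures directly comparable.

The networks, their gradients and Adam live on a small in-package
reverse-mode autodiff engine over NumPy arrays (`gopredict.nn`); gradient
correctness of every primitive is checked against central finite
differences in the test suite.

## The training objective

    L = L_BCE + α · L_InfoNCE      (training)        α ≥ 0, default 0.1
    L = L_BCE                      (validation/inference)

`L_BCE` is the mean elementwise binary cross-entropy on logits.
`L_InfoNCE` treats the protein's own label embedding as the positive and
the other in-batch label embeddings as negatives, on cosine similarities
scaled by a temperature τ (default 0.5):

    L_InfoNCE = −(1/N) Σ_i log [ exp(cos(Z_i, M_i)/τ) / Σ_j exp(cos(Z_i, M_j)/τ) ]

Choices worth noting:

* **Z is the logit vector**, not a hidden representation; a hidden-space
  variant would change the alignment target but not the objective's form.
* Cosine with a zero-norm vector is defined as 0; such rows contribute a
  zero-gradient direction.
* Two proteins with identical label vectors inside one batch are false
  negatives for each other. The default keeps them (the simplest
  formulation); `LossConfig(mask_duplicate_negatives=True)` excludes them
  from the denominator.
* The loss is directional (Z anchors, M candidates);
  `LossConfig(symmetric=True)` averages both directions.
* α = 0 reproduces plain BCE bit-for-bit — loss values, gradients and
  whole seeded training trajectories (asserted in the tests).
* The contrastive term needs in-batch negatives, hence batch size ≥ 2
  whenever α > 0.

## Training and ensembling

Adam (lr 1e-3, batch 64 by default), seeded shuffling and seeded dropout;
all randomness derives from one top-level seed through named substreams
(`split`, `init`, `shuffle`, `dropout`, ...), so a run is reproducible
from a single integer. Early stopping monitors validation Fmax by default
(validation loss optional) and restores the best epoch's parameters after
`patience` epochs without improvement (default 10). Data splits are
floor-based with the remainder assigned to the first (training) partition:
80/20 for train/validation, 8:1:1 where a test set is carved out.

One model is trained per modality per sub-ontology; the ensemble is the
equal-weight elementwise mean of the three probability matrices
(probabilities, not logits, so the scales are commensurable). The mean is
computed as `ref + mean(deviations)` so averaging identical inputs is
bit-exact.

## Evaluation

* **Fmax** (protein-centric): thresholds {0.01, ..., 1.00}; at each t,
  precision is averaged over proteins with ≥ 1 score ≥ t, recall over all
  benchmark proteins; F = 0 when no protein is covered. The benchmark set
  is the truth file's proteins with a non-empty (propagated, root-free)
  term set; scored proteins absent from the truth are excluded with a
  warning; truth proteins without scores count as all-zero predictions.
  On ties the smallest attaining threshold is reported.
* **AUPR** (function-centric): average precision per term with ≥ 1
  positive, macro-averaged ("term-centric", the default); the micro mode
  pools all protein–term pairs into one ranking. Average precision is the
  step-wise area (no precision-envelope interpolation), delegated to
  scikit-learn and verified against full threshold enumeration in the
  tests.
* **Naive baseline**: every target protein receives each term's relative
  annotation frequency in the training set.

Score serialization is 6-decimal fixed point; the 0.01 threshold grid is
far coarser, so round-tripping scores through TSV cannot move Fmax.

## The synthetic generator

The generator emulates the *structure* of the real inputs, not their
geometry:

* a layered, single-namespace rooted DAG (each non-root term takes 1–2
  parents from the layer above);
* latent functional groups: Dirichlet-distributed prevalences (a
  `function_balance` concentration parameter controls skew), each group
  owning a characteristic set of leaf terms; a protein draws a group, a
  Poisson number of leaves from the group's set, and is annotated with
  their ancestor closure;
* embeddings: `signal_strength · (W_modality · label_vector) + N(0, noise_sd²)`
  with a distinct seeded projection per modality — the same label
  information through complementary coordinates; zero signal is an exact
  null;
* a homophilous PPI network: within-group pair weight h, cross-group
  weight 1−h, scaled to a target mean degree; within-group edges draw
  higher confidences (U(0.6, 1) vs U(0.3, 0.7)).

What this does *not* emulate: sequence evolution, real PLM embedding
geometry (anisotropy, clustering by family), STRING evidence channels,
annotation incompleteness bias. Passing tests on this generator therefore
demonstrate that the pipeline's machinery is correct and that each model
can exploit the kind of signal it is designed for — not that the reported
benchmark numbers of any real dataset would be reproduced.

### Frozen scenarios (the study conditions)

| scenario | condition | intent |
| --- | --- | --- |
| A | 300 proteins, 30 terms, signal 4.0, noise 1.0 | separable; near-perfect recovery expected |
| B | as A with signal 0.0 | null; nothing beyond the Naive baseline is learnable |
| C | signal 1.0, noise 1.5, homophily 0.9, dims 24 | three weak complementary modalities; the ensemble regime |

Two further frozen conditions back the dedicated experiments
(`gopredict.experiments`):

* **interaction-signal** (`HOMOPHILY_CONFIG`): signal 0.5, noise 4.0,
  homophily 1.0, mean degree 16, near-balanced groups
  (`function_balance` 10). The point of this condition is that the label
  signal lives in the *neighbourhood* — an individual node feature is
  too noisy to decode alone, while ~16 same-group neighbours average the
  noise away — so comparing a GAT on the true graph against the same
  model on an edge-shuffled graph isolates exactly the model's ability to
  exploit interaction structure. Balanced groups matter here: under a
  degenerately skewed prevalence the frequency prior saturates Fmax and
  the comparison measures nothing. Evaluation uses the val+test 20%;
  early stopping is inert in this experiment (patience equals the epoch
  budget), so the validation split carries no information into training.
* **contrastive-gain** (`CONTRASTIVE_CONFIG`): scenario A with signal 1.5
  and noise 2.0 — separable but noisy, the regime where a regularizer
  could plausibly help. The experiment reports the per-seed Fmax
  difference α = 0.1 vs α = 0 with a normal-approximation 95% CI; the
  sign is an empirical observation of this synthetic condition, not a
  claim about real data.

Problem sizes (300 proteins, ~30 terms, hidden dims 32–128, ≤ 50 epochs)
are the package's standard desk-scale settings: large enough for the
effects of interest to be measurable, small enough that the full test
suite and the reproduction script each run in minutes on one CPU.

## Numerical choices

* float64 throughout the autodiff engine; embeddings stored as float32.
* BCE on logits via the softplus form `max(z,0) + log1p(exp(−|z|)) − y·z`;
  sigmoids computed branch-wise for stability.
* InfoNCE via log-sum-exp with per-row max subtraction; the per-segment
  max subtracted inside the GAT attention softmax is a value-level shift
  the softmax (and its gradient) is invariant to.
* Neighbour ranking ties break by ascending partner id; split remainders
  go to the training partition; Fmax threshold ties report the smallest
  attaining threshold — all for determinism.
* Degenerate inputs: empty FASTA → empty list; a query absent from the
  interaction table → a single-node self-loop graph (not an error); a
  protein with empty truth after propagation is excluded from evaluation;
  an all-zero score matrix has Fmax 0 by the coverage rule.

## Known limitations

* The GAT does not use edge confidences as attention priors; a
  confidence-aware attention variant is an obvious extension.
* Vocabulary selection (count ≥ min_count on propagated training
  annotations) is one defensible rule among several; published benchmark
  vocabularies are typically fixed term lists and can be passed in
  explicitly via the `vocab` argument.
* The in-package autodiff engine is sized for these models; it has no
  GPU path and no operator fusion, so very large vocabularies or graphs
  would be slow.
* Whether reported AUPRs in the literature are macro or micro varies;
  both modes are provided and must be matched by the user when comparing.
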