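# Methods

## Model

### Featurization

Herb attributes use a fixed, ordered 22-token vocabulary: ten
properties/flavors (cold, hot, warm, cool, neutral, sour, bitter, sweet,
pungent, salty) and twelve meridian tropisms (lung, pericardium, heart,
large intestine, triple energizer, small intestine, stomach, gallbladder,
bladder, spleen, liver, kidney). Each attribute is one-hot; a herb's
vector is the multi-hot union of its attributes. The vocabulary order is
serialized as JSON next to any feature matrix it produced.

A prescription's feature is the elementwise sum of its (de-duplicated)
herbs' vectors, standardized across its own 22 entries with the
population (1/n) standard deviation. A constant sum (σ = 0) yields a zero
vector with a warning rather than an error, so batch pipelines survive
degenerate records.

Metabolites are double-featurized: a sequence embedding of the SMILES
string on the metabolite node itself, and a hashed extended-connectivity
(Morgan) fingerprint — radius 2, 2048 bits, configurable — on a dedicated
virtual node attached by a single edge. One virtual node per metabolite
(rather than one global node) is the only reading that injects
molecule-specific structure into message passing. Fusion of the two
featurizations happens purely through graph propagation; they are never
concatenated.

The sequence-embedding contract is pluggable: deterministic given
(string, seed), fixed output dimension (default 256). The default backend
is a character k-mer hashing projector (k = 3, keyed blake2b hash to a
coordinate and a sign, L2-normalized signed counts). A contrastive
projector (`ContrastiveProjector`) can fine-tune a linear map on top with
the standard in-batch contrastive objective — dropout-perturbed duplicate
encodings as positive pairs, cosine-similarity logits at temperature τ
(default 0.05) — initialized at identity so the untrained projector
equals the base encoder. Training a transformer encoder is out of scope;
the objective itself is implemented and tested.

### Graph

Node types: prescription, herb, metabolite, target, ecfp_virtual.
Forward relations: prescription–herb (from membership lists),
herb–metabolite, metabolite–target, metabolite–ecfp. Every relation gets
an explicit reverse dual with its own name and its own relation
embedding, so information can reach prescription nodes from targets.
Edges carry no attributes; repeated edges and repeated herbs within a
prescription collapse. Cleaning removes metabolites without parsable
SMILES and targets without sequences together with all incident edges,
reporting counts; efficacy classes with a positive share strictly below
15% are dropped (a share exactly at the threshold is retained).

### Relational graph attention

Each layer computes, per node `i` with in-neighborhood `N(i)`:

- node attention, K heads (default 4): per head
  `α_ij = softmax_j((h_i W_q)·(h_j W_k)/√d_head)`,
  message `Σ_j α_ij (h_j W_v)`, heads concatenated. The per-head
  transforms live in column blocks of fused hidden×hidden matrices — an
  equivalent parametrization that runs as single matmuls.
- relation attention, M heads (default 4): each relation type owns a
  learned embedding `r` (dim 32, normal-initialized);
  `g = sigmoid(relu(r W₁ + b₁) W₂ + b₂)` scores every edge by its type,
  `β_ij = softmax_j(g)`, and `Σ_j β_ij (h_j W_m)` is concatenated over
  heads. The outer σ is sigmoid; relation heads have their own value
  transforms, separate from the node-attention heads.

The concatenation `x = h_att ‖ h_rel` passes through
`h' = relu(Wx + b)`. Default depth is exactly two layers, hidden width
512. Self-loops with a dedicated "self" relation are added for every
node so isolated nodes remain defined. Per-type input projections are
linear without bias. Heterogeneous input widths (22 / 256 / 2048) meet at
the common hidden width there.

All attention weights of a forward pass are retained edge-aligned
(`AttentionTrace`) for later analysis; per-destination weights sum to 1
per head and layer by construction (verified to 1e-6 in tests, and
against a dense per-node brute-force implementation to 1e-5 on all graphs
with up to 6 nodes and 2 relation types).

### Prediction and training

Prescription representations pass through layer normalization, a linear
map to two logits, and softmax; the positive-class probability is trained
with binary cross-entropy (probabilities clamped to [1e-7, 1−1e-7]).
Classification is argmax with exact ties resolved to negative. The
positive class is presence of the target efficacy; all other retained
prescriptions are negatives.

Optimization is Adam (default lr 1e-3) with early stopping on validation
AUC (default patience 20), full-batch. Evaluation follows a rotating
stratified 10-fold protocol: test fold t, validation fold (t+1) mod 10,
the remaining eight folds train — the concrete resolution of "10-fold
cross-validation at an 8:1:1 split". Stratification guarantees both
classes in every fold. Metrics: AUC, area under the precision–recall
curve, accuracy, recall, precision, F1 (scikit-learn), reported per fold
with a mean (sd) summary.

### GAN rebalancing

One generator/discriminator pair per (efficacy, label) stratum — the
per-efficacy generation counts in this design make a single conditional
GAN unnecessary. The generator maps noise (default dim 64) through one
hidden relu layer to the concatenation [feature ‖ soft adjacency]; the
adjacency block passes through a sigmoid into [0, 1], while the feature
block keeps a linear head because standardized features are unbounded — a
sigmoid head cannot represent them. The discriminator is a two-layer
perceptron with sigmoid output, so its outputs are strictly inside
(0, 1). The discriminator step maximizes `log D(x) + log(1 − D(G(z)))`;
the generator step uses the standard non-saturating form (maximize
`log D(G(z))`), the conventional stable realization of the min–max value
function.

Soft adjacency rows are binarized by drawing k from the empirical
herbs-per-prescription counts of the real stratum and keeping the k
largest entries (an empty result falls back to the argmax, first index on
ties). A fixed threshold rule (θ = 0.5) is available but is not the
default: weakly trained generators emit rows hovering near 0.5, and
thresholding then yields implausibly large herb sets that the
incompatibility screen rejects wholesale. Generated prescriptions
containing both members of any forbidden herb pair are pruned;
matching is order-insensitive, pairs naming unknown herbs are skipped
with a warning, and pruning shortfalls are accepted and reported rather
than regenerated. Generated labels are fixed per stratum, not emitted by
the generator.

Augmentation is fitted on training folds only; generated nodes are
flagged, never reuse real prescription ids, extend only the training
loss, and never contribute to validation or test metrics.

Default learning rates follow the reference configuration (discriminator
1e-5, generator/discriminator ratio 30, hence generator 3e-4). On the
small synthetic strata of the benchmarks those rates leave the feature
head effectively unconstrained (the discriminator adapts too slowly), so
the benchmark configuration uses discriminator 5e-4, ratio 4, 3000
epochs, batch 64 — sized for strata of roughly a hundred records.

### Ablation variants

- **R** — herb–metabolite and metabolite–target relations (and the
  fingerprint pairs) are excluded from message passing.
- **E** — the sequence encoder backend is swapped (alternate k-mer width
  and hash key) for metabolite and target features.
- **H** — prescription features are the concatenation of herb vectors,
  padded/truncated to a configured maximum herb count, instead of the
  standardized sum.
- **S** — the graph is bypassed: minority oversampling by k-NN
  interpolation of prescription features (the SMOTE construction,
  implemented directly on scikit-learn's NearestNeighbors) plus a
  random-forest classifier under the same fold protocol.

## Synthetic data

The generator emulates the schema and first-moment shape of a classical
prescription corpus joined to a herb–compound–target knowledge base: ids,
"|"-separated herb lists, one binary column per efficacy, SMILES from a
fixed bundled list of 50 valid small molecules (so fingerprints are
deterministic), random peptide sequences for targets, Poisson(10)
herbs-per-prescription truncated at ≥1, and configurable fractions of
unsequenced metabolites/targets (default 5%).

Ground truth is a herb-motif threshold rule: a hidden effective set S
(default 10 of 100 herbs); a prescription is positive iff it contains at
least k (default 2) herbs of S. Efficacy in the source domain is a
function of herb composition, which this rule captures in its simplest
nonlinear form. Labels flip independently with probability p (default
0.05). The requested class balance applies to the observed (post-noise)
labels: quota sampling targets a clean-label fraction of
(f − p)/(1 − 2p) so that after flips the observed positive share is f.

Signal routing decides where the rule is visible:

- `features` (default): S-herbs have a biased attribute profile (six
  signal tokens present with probability 0.95 vs 0.15 for other herbs;
  remaining tokens 0.3 everywhere), so herb and prescription vectors
  carry the signal directly.
- `graph`: herb attributes are drawn from a small shared profile pool
  independent of S; S-herbs connect exclusively to a reserved marker
  pool of metabolites (25% of metabolites, drawing SMILES from the first
  ten bundled molecules) which in turn connect to marker targets. Only
  metabolite/target structure identifies S.
- `both`: both mechanisms.

Two leaks discovered while designing the graph-routed benchmark are worth
recording because they bound what such fixtures can show. First, with
per-herb random attributes the attribute vector is effectively a herb
identifier, so even a model without metabolite edges can memorize which
herbs matter — hence the graph-routed benchmark assigns all herbs one
shared profile. Second, prescription size correlates with the threshold
rule's outcome, and class-balancing quota sampling makes S-herbs more
popular than average, so node degrees alone beat chance; fixing the herb
count per prescription removes the first shortcut, and the residual
popularity signal is available equally to both arms of the ablation.

What passing these benchmarks does **not** show: the generator matches
only first moments of real degree distributions, its herbs are
exchangeable tokens without pharmacology, its SMILES list is tiny, and
label noise is independent — real corpus noise is not. Results on it
validate the machinery (featurization, graph construction, attention,
rebalancing, protocol hygiene), not clinical predictive power.

## Benchmarks (`herbgat.benchmarks`)

Problem sizes are chosen so every benchmark runs in minutes on one CPU;
the model sizing used throughout is hidden 64→32, 2+2 heads, relation dim
16, two layers (`compact_rgat`), which recovers planted signal as well as
larger settings on these corpora.

- **Signal recovery** — balanced corpus at full scale (2,000
  prescriptions, 100 herbs, |S| = 10, k = 2, noise 0.05, dataset seed 7);
  10-fold CV, Adam lr 2e-3, ≤60 epochs, patience 12. Mean test AUC ~0.95
  against the ~0.95 noise ceiling; a label-permutation control lands at
  chance.
- **Augmentation direction** — 1:4-imbalanced corpus built to be hard
  (500 prescriptions, noise 0.10, attribute contrast 0.7/0.25), the
  regime where unaugmented minority recall is poor and rebalancing has
  headroom; five seeds, one 8:1:1 split each, GAN-augmented vs plain
  minority recall medians.
- **Ablation direction** — graph-routed corpus (600 prescriptions, one
  shared attribute profile, fixed 10 herbs per prescription, 8
  metabolites per herb, dataset seed 33); five seeds, full model vs the
  R variant; lr 1e-3 and patience 25 here because the constant-feature
  input makes optimization noisier.
- **End-to-end determinism** — a compact 160-prescription pipeline
  (simulate → assemble → GAN-augment → 10-fold CV → attention
  extraction) whose metrics CSV and attention TSV are compared by digest
  across two invocations.

## Numerical choices

- All computation in float64 on a tape-based numpy autodiff core; segment
  reductions (scatter-add, neighborhood softmax max-shift) use
  sort + `reduceat`. Softmaxes subtract the per-segment maximum as a
  constant, which leaves gradients unchanged.
- BCE clamp ε = 1e-7; layer-norm variance floor 1e-6; early-stopping
  improvement threshold 1e-6 on validation AUC.
- Ties: argmax ties classify negative; binarization fallback picks the
  first maximal index; binned top-edge selection breaks ties by source
  then destination id.
- Checkpoints are npz archives embedding the config as JSON; graphs
  serialize as typed TSV + npz features + JSON manifest, with GraphML
  export for visualization.
- Every random draw flows from an explicit seed: dataset seeds define a
  corpus; training seeds drive folds, initialization and GAN noise; two
  runs with equal seeds are byte-identical.

## Known limitations

- Full-batch training only; corpora beyond ~10⁴ nodes per type would
  need minibatching, which is out of scope.
- The default sequence encoder is a hashing projector, not a pretrained
  language model; the encoder contract accepts a stronger backend but
  none ships with the package.
- GAN training on very small strata (tens of records) is noisy; the
  pruning shortfall is accepted, so requested generation counts are upper
  bounds.
- The attention analysis ranks edges within a trained model; it makes no
  mechanistic claim about high-attention metabolites.
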