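# Methods

## Problem and model

Transfer learning helps molecular property prediction when the target task
has few labeled molecules, but a badly chosen source dataset causes
*negative transfer*. This package estimates, before any target training,
how well pretraining on a source dataset `D_s` will transfer to a target
dataset `D_t`, and validates the estimate with an explicit transfer-learning
harness.

The prediction model factors as `F = g · w`: a graph feature extractor `g`
and a task-specific predictor head `w`. Transferability is treated as a
property of the extractor alone, since the head is retrained per task.

### Principal gradients

For a dataset `D`, the *principal gradient* is the expectation of the
extractor gradient at initialization,

    PG(D) = E[ ∇L(g0) ],

estimated by a restart scheme: initialize the model, shuffle the data, make
one full update-free pass accumulating the gradient of the masked loss with
respect to extractor parameters per batch (unweighted mean over batches),
and repeat for `n_restarts` passes (default 10), averaging across restarts.
No optimizer state ever exists. Two expectation readings are exposed:

- `same_init` (default): every restart reuses the same initial point;
  randomness enters only through batch composition.
- `random_init`: restart `k` draws initialization seed `base_seed + k`,
  identical across datasets so per-restart gradients stay paired; the
  expectation is then genuinely taken over `g0`.

On the synthetic study both modes recover relatedness rankings equally
well (20/20 generator seeds), so the simpler fixed-initial-point reading
is the default.

### The distance

Transferability between datasets `s` and `t` is the normalized distance

    d(s, t) = ‖PG(t) − PG(s)‖₂ / ( ‖PG(s)‖₂ · ‖PG(t)‖₂ ).

Smaller distance = more related tasks. The measure is symmetric with a zero
diagonal but is **not** a metric: the normalizing denominator breaks the
triangle inequality, and scaling both gradients by `c` scales the distance
by `1/c`. A principal gradient with norm below 1e-12 is treated as a hard
error (a broken setup), not clamped. Distances are only defined between
gradients computed under the same model configuration and restart scheme,
enforced by a configuration digest carried on every gradient.

The pairwise distance matrix over a dataset collection is the
*transferability map*; ranking a target's row ascending (ties broken
alphabetically) orders candidate source datasets.

### Encoder

The reference extractor is a GIN-style message-passing network: atom
embeddings (atomic number 1–118 + unknown; chirality tag in
{unspecified, CW, CCW, other}) are summed, then each of 3 layers computes
`h_v ← MLP( h_v + Σ_{u∈N(v)} (h_u + e_uv) )` with per-layer bond-type and
bond-direction embeddings `e_uv`, a one-hidden-layer MLP, and ReLU between
layers. Mean pooling over nodes gives the graph representation; a single
affine layer is the predictor. Batch normalization and dropout are
deliberately absent so that forward passes and gradients are deterministic
and batch-size robust — a requirement for reproducible principal gradients.
A trivial bag-of-atoms encoder (mean of atom embeddings) is provided for
fast tests.

All numerics are NumPy with hand-derived reverse-mode gradients, verified
against central finite differences to 1e-4 relative in the test suite.
Initialization draws each parameter tensor from its own seeded stream in
registration order (fan-in uniform bounds, zero biases), so extractors are
bit-identical across tasks with different numbers of subtasks — the "same
initial point" contract that makes gradients comparable across datasets.

### Losses and metrics

Classification uses per-cell logistic cross-entropy on logits, regression
smooth-L1 (beta = 1); both average over *observed* label cells only
(missing labels are stored as 0 with an observed=False mask, never as NaN).
Evaluation uses ROC-AUC (mean over subtasks, single-class subtasks skipped)
for classification and RMSE over observed cells for regression. Rank
agreement uses tie-adjusted Kendall tau-b, oriented so that perfect
prediction (small distance ↔ good transfer) gives +1; tau on an all-tied
ranking is an error, not 0.

### Transfer harness

Pretraining: Adam (lr 1e-3, batch 32) on the source's scaffold-split train
partition, keeping the best-validation checkpoint.
Fine-tuning: the extractor is copied from the pretrained model and frozen
bit-for-bit (enforced by hashing); the predictor head is re-initialized per
run seed and trained from scratch on the target train partition; the
best-validation head is scored on the scaffold-held-out test partition, and
runs are aggregated to mean ± std. Scaffold splits are Bemis–Murcko-based
8:1:1, assigning scaffold groups (sorted by descending size, then smallest
member SMILES) greedily to train, then validation, then test — groups never
straddle partitions, and the seed only breaks exact ties.

Desk-scale defaults are 30–40 epochs and width 32; `TrainConfig.full_scale()`
restores the full protocol (200 epochs). In validation experiments the
target head trains on a seeded subsample of at most 96 train molecules
("data-poor" regime): with hundreds of target labels a linear head
saturates on any reasonably pretrained extractor and source choice stops
mattering, which is exactly the regime where transferability guidance is
moot. Transfer learning is for scarce targets, and that is where the
harness tests it.

## Synthetic data

No external dataset is required: the generator builds labeled molecule
tables with *known* inter-task relatedness.

**Molecules** are assembled from a fixed fragment grammar (benzene,
pyridine, naphthalene, furan, thiophene, cyclohexane, piperidine,
pyrrolidine, oxolane cores plus acyclic chains; 24 substituents), giving
valid, canonical SMILES with ≥ 5 Bemis–Murcko scaffolds per 100 molecules.

**Labels** are substructure-driven, not random, so a graph encoder's
gradients can carry task signal. Each subtask's score is a standardized
random weighting of z-scored SMARTS match counts over a *base* motif pool
(hydroxyl, amine, aromatic atoms, methyl, ether, alkene). Classification
labels threshold the score at its median (class-balanced) and apply
balance-preserving noise (equal numbers of 0→1 and 1→0 flips, default rate
0.05); regression labels add Gaussian noise.

**Task families** control relatedness: member `i`'s subtask scores are
`r·base + (1−r)·alt`, with the alternative score drawn from a disjoint
motif pool (halogens, carbonyl, sulfur, nitrile, methylene) and
decorrelated from the base score by deterministic re-draws (best of 32).
Two details matter and were found the hard way:

- *Decorrelation*: molecule size correlates all motif counts, so without
  it an "unrelated" task agrees with the base well above chance.
- *Coverage*: the methylene motif keeps the alternative score varying on
  molecules that carry none of the rarer motifs; otherwise those molecules
  tie and inherit the base label even at low relatedness.

Default family datasets are multitask panels (8 binary subtasks over a
shared 400-molecule set), mirroring real multitask property panels. The
multitask design is load-bearing: with a single binary subtask on a shared
molecule set, each task's gradient norm is a quadratic form of its label
vector under the molecule-similarity kernel and fluctuates by 2–3× across
label draws, which scrambles the normalized distances. Averaging over
subtasks suppresses this flip-pattern noise while leaving the relatedness
signal, and the distance ranking then recovers the true ordering with
tau ≥ 0.6 in 20/20 generator seeds. A shared molecule set isolates task
relatedness from data distribution shift; `shared_molecules=False`
resamples molecules per task for the harder mixed case.

What passing synthetic tests does **not** show: real property panels have
unbalanced classes, correlated subtasks, missing labels, and molecules far
more diverse than the grammar produces; absolute distances and AUCs here do
not predict benchmark values.

## Study conditions

Fixed across tests and the acceptance script: 3-layer GIN of width 32;
10 restarts of batch 32, `same_init`, base seed 0. Rank-recovery families:
400 molecules × 8 subtasks, noise 0.05, relatedness levels
(0.9, 0.7, 0.5, 0.3, 0.1). Transfer validation: 600-molecule families,
pretraining 40 epochs, fine-tuning 3 runs with the target head capped at 96
training molecules.

## Numerical choices and degenerate inputs

- Seeds: every stochastic step (init, shuffles, subsampling, label noise)
  derives from explicit seed sequences; batch-shuffle seeds combine
  (base_seed, restart index, CRC32 of the dataset name).
- Batches with zero observed labels are skipped and counted; a restart with
  no usable batch is an error.
- Single-atom molecules (no bonds) are valid inputs throughout.
- Scaffold splitting with fewer than 3 scaffold groups fails loudly; a
  random split is available only by explicit opt-in.
- Distances involving near-zero gradient norms, non-finite gradients, and
  mismatched configuration digests are errors, never silently patched.
- Ties in source ranking break alphabetically; best-checkpoint ties keep
  the earliest epoch.

## Known limitations

- The measure responds to any gradient difference, not only task
  relatedness: label marginals, dataset size, and loss family all move it.
  Mixing classification and regression datasets in one map is allowed but
  flagged, as it compares gradients of different loss families.
- At single-task desk scale the denominator of the distance is noisy (see
  above); trust rankings, not absolute distance values.
- The transfer harness freezes the full extractor; partial unfreezing and
  multi-source pretraining are out of scope.
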