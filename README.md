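# pgm-transfer

Gradient-based transferability estimation for molecular property
prediction: decide **which source dataset to pretrain on** for a given
target task — before doing any training on the target.

Transfer learning is the standard answer to scarce labeled molecules, but
pretraining on an unrelated property can *hurt* the target task (negative
transfer). This package implements an optimization-free measure of task
relatedness for people building property predictors (toxicity, ADME,
physical chemistry, bioactivity panels) who must choose among several
candidate source datasets.

## The measure

A property predictor factors as `F = g · w` — a graph feature extractor
`g` and a task head `w`. For each dataset `D`, the **principal gradient**
is the expected extractor gradient at initialization,

    PG(D) = E[ ∇L(g0) ],

estimated by repeated update-free passes over `D` (re-initialize, shuffle,
accumulate per-batch gradients; no optimizer step ever). It is a cheap
proxy for the direction model optimization would take on `D`.
Transferability between datasets `s` and `t` is the normalized distance

    d(s, t) = ‖PG(t) − PG(s)‖₂ / ( ‖PG(s)‖₂ · ‖PG(t)‖₂ ),

smaller = more related. The matrix of all pairwise distances is a
**transferability map**; sorting a target's row ascending ranks candidate
source datasets. A small transfer harness (pretrain on source, fine-tune
on target with the extractor frozen) validates rankings, and tie-adjusted
Kendall's τ quantifies rank agreement.

The reference encoder is a 3-layer GIN-style network with mean-pooling
readout over RDKit-featurized molecular graphs (atomic number + chirality,
bond type + direction), implemented in deterministic NumPy with
hand-derived gradients. See `docs/methods.md` for the model, its
assumptions, and all numerical choices.

## Worked example

Generate a synthetic task family whose true relatedness to the base task
is known by construction (0.9, 0.5, 0.1), map it, and rank sources:

```bash
pgm-transfer synth --n-molecules 200 --n-subtasks 8 \
    --relatedness 0.9,0.5,0.1 --seed 3 --output-dir family
# wrote 4 datasets to family (true ranking: rel0.90, rel0.50, rel0.10)

pgm-transfer map -c config.yaml
#            base  rel0.90  rel0.50  rel0.10
# base     0.0000  18.1818  27.9858  74.2595
# rel0.90 18.1818   0.0000  31.5252  76.7545
# rel0.50 27.9858  31.5252   0.0000  69.4066
# rel0.10 74.2595  76.7545  69.4066   0.0000

pgm-transfer select -c config.yaml base
# rel0.90       18.181777
# rel0.50       27.985784
# rel0.10       74.259526
```

The distance ranking (rel0.90 < rel0.50 < rel0.10) recovers the generator's
true relatedness ordering exactly: tasks sharing more of the base task's
substructure-label rule sit closer in gradient space. Absolute distances
are unit-free and only comparable within one map. Validating the top pick
by actual transfer learning:

```bash
pgm-transfer transfer -c config.yaml rel0.90 base
# rel0.90 -> base: roc_auc = 0.6863 +/- 0.1023 over 3 runs
```

with `config.yaml`:

```yaml
model: {hidden_width: 32, encoder_depth: 3}
pgm: {n_restarts: 10, base_seed: 0, batch_size: 32}
train: {max_epochs: 40, n_runs: 3, seeds: [0, 1, 2]}
datasets:
  - {name: base, path: family/base.csv}
  - {name: rel0.90, path: family/rel0.90.csv}
  - {name: rel0.50, path: family/rel0.50.csv}
  - {name: rel0.10, path: family/rel0.10.csv}
output_dir: out
```

Any delimited table with a SMILES column and label columns works as a
dataset (MoleculeNet-style CSVs included); blank label cells are treated
as unobserved and masked from every loss.

The same workflow is available as a library through sklearn-style
estimators:

```python
from pgm_transfer import TransferabilityMapper, rank_sources

mapper = TransferabilityMapper(model_config, pgm_config).fit(datasets)
ranking = rank_sources(mapper.map_, target="base")
```

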