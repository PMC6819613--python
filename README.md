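# dfnforest

Cancer-subtype classification from multi-omics data with a **hierarchical
integration deep flexible neural forest**: stacked autoencoders learn a
representation of each omics layer (gene expression, miRNA expression,
DNA methylation), one integrating autoencoder fuses the per-layer codes,
and a cascade forest of flexible neural trees classifies samples from the
fused representation.

The package is aimed at computational-biology practitioners who want a
reproducible, leakage-free implementation of this framework: the
representation learning, the tree-based cascade classifier, the
evaluation protocol (stratified cross-validation, permuted-input
overfitting control), and a synthetic multi-omics generator so every
stage is testable without downloading consortium data.

## The model

**Representation.** Each omics block X_b (samples × features) is
standardised per feature, f̃ = (f − E(f)) / √Var(f), and compressed by a
stacked autoencoder trained greedily by gradient descent on

  J(θ, θ′) = (1/N) Σᵢ ‖x(i) − d_θ′(e_θ(x(i)))‖² + λ‖W‖²₂ ,

with encoder h = tanh(Wx + b_x) and affine decoder. The final per-block
codes are concatenated and passed through one further autoencoder layer,
giving a single integrated representation that reflects both within-block
structure and cross-block correlation.

**Classifier.** A C-class problem is decomposed into ceil(log₂ C) binary
tasks (M-ary output coding). Each *flexible neural tree* (FNT) is a
sparse tree whose leaves are input features and whose internal nodes are
flexible neurons of arity k: net = Σ wᵢ·childᵢ, out = exp(−((net−a)/b)²).
Tree *structures* are evolved by grammar-guided genetic programming
(population 50, crossover 0.4, mutation 0.01); tree *parameters* are
tuned by particle swarm optimisation (c₁ = c₂ = 2, V_max = 2) against
RMSE. A cascade level holds three forests with function sets
{+2,+3,+4}, {+2,+4,+5}, {+3,+4,+5}; each forest holds one FNT per code
bit, and its concatenated outputs form a class vector. Later levels see
the raw features plus the previous level's class vectors, and the number
of levels is chosen adaptively on an internal validation split.
Prediction decodes each forest's class vector to the nearest codeword and
majority-votes across forests.

## Worked example

Simulate a 4-subtype study with three omics blocks, then run 5-fold
cross-validation end to end (roughly half a minute):

```bash
dfnforest simulate --config config.yaml --out demo/data
dfnforest cv --config config.yaml --in demo/data --out demo/cv.json
```

with a config like

```yaml
simulate:
  n_samples: 120
  n_classes: 4
  features_per_omics: [300, 150, 80]
  effect_size: 5.0
  noise_sd: 0.1
  missing_rate: 0.05
pipeline:
  sae_dims: [[50, 12], [50, 12], [50, 12]]
  integrator_dim: 10
  cv_folds: 5
  train: {epochs: 300, learning_rate: 0.02}
  gp: {population_size: 30, generations: 5}
  pso: {swarm_size: 10, iterations: 100}
  cascade: {max_depth: 3, max_levels: 2}
seed: 7
```

The `cv` command prints a JSON report; this run ends with

```json
  "mean": {
    "accuracy": 0.8916666666666666,
    "macro_precision": 0.9013095238095238,
    "macro_recall": 0.8916666666666666,
    "macro_f1": 0.8879620379620381
  }
```

(per-fold accuracies 0.875, 0.792, 0.875, 0.958, 0.958). The mean CV
accuracy of 0.89 on 120 samples says the pipeline recovers the four
planted subtypes from the fused representation far above the 0.25 chance
level; macro precision/recall close to accuracy reflect the balanced
classes. `dfnforest permutation-control` on the same data reports
accuracies near 0.25, the expected behaviour of an unoverfitted model on
label-permuted data.

The same machinery is available as a library:

```python
from dfnforest import SyntheticSpec, generate_multiomics
from dfnforest.pipeline import synthetic_study_config, cross_validate

omics, labels = generate_multiomics(SyntheticSpec(seed=0))
report = cross_validate(omics, labels, synthetic_study_config(1))
print(report.mean.accuracy)
```

## Layout

- `src/dfnforest/synthetic.py` — multi-omics generator and permutation control inputs
- `src/dfnforest/preprocess.py` — missingness filter, KNN imputation, standardisation
- `src/dfnforest/autoencoder.py` — AE cost/gradients, greedy stacking, integration
- `src/dfnforest/fnt.py` — flexible neural trees, GGGP structure search, PSO
- `src/dfnforest/cascade.py` — M-ary coding, forests, cascade growth, decoding
- `src/dfnforest/pipeline.py` — end-to-end fitting, cross-validation, metrics, controls
- `src/dfnforest/io.py`, `src/dfnforest/cli.py` — TSV formats and the `dfnforest` CLI
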