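# Methods

`dfnforest` implements a hierarchical multi-omics integration and
classification framework for cancer-subtype prediction: per-omics stacked
autoencoders (SAEs) learn a low-dimensional code for each molecular layer,
one further autoencoder layer fuses the codes, and a cascade forest of
flexible neural trees (a deep flexible neural forest, DFNForest) classifies
samples from the fused representation. This note records the model, its
assumptions, the package's numerical choices, and what the synthetic study
does and does not demonstrate.

## Preprocessing

Each omics block is a samples × features matrix with an explicit missing
mask. Three steps run in order, per block:

1. **Missingness filter.** A sample missing strictly more than a threshold
   fraction (default 20%) of a block's features is removed. Because the
   framework requires sample alignment across blocks, a sample dropped in
   any block is dropped from all blocks.
2. **KNN imputation.** A missing entry (s, f) is filled with the mean of f
   over the k = 5 nearest samples (Euclidean distance over features
   observed in both samples, no rescaling by the number of shared
   features), restricted to neighbours observing f; if none of the k
   nearest observe f, the feature's global observed mean is used. Distance
   ties break by sample order for determinism. At prediction time new
   samples are imputed against the frozen training pool, never against
   each other.
3. **Standardisation.** Each feature f becomes (f − E(f)) / √Var(f) with
   the *population* variance (divide by N). Contract: post-normalisation
   column means satisfy |mean| < 1e−10 and |var − 1| < 1e−8. Zero-variance
   features are an error unless `drop_constant` removes them.

An optional winsorisation (clip at |z| > 6) is available but off by
default: outlier handling in this setting has no principled criterion, so
the package exposes it as an explicit choice rather than a silent default.

## Autoencoders

A layer encodes h = f(Wx + b_x) and decodes x' = W'h + b_h. The cost is

    J = (1/N) Σᵢ ‖x(i) − d(e(x(i)))‖² + λ‖W‖²₂,

with λ‖W‖²₂ the L2 penalty on encoder weights only. Choices:

- **tanh encoder, affine decoder.** Inputs are z-scored — signed and
  unbounded — so a bounded decoder could not reconstruct them; the affine
  decoder makes perfect reconstruction of centred data attainable in the
  near-linear regime of tanh. A sigmoid encoder is available by config.
- **Plain full-batch gradient descent** with analytic gradients (verified
  against central finite differences to 1e−5 relative error). Defaults:
  learning rate 1e−3, 200 epochs, λ = 1e−4; the synthetic study uses
  2e−2 / 500 epochs, where training is stable and converged for its data
  scale. The parameters returned are the post-epoch snapshot with the
  lowest recorded training loss; the loss trace is retained on the model.
- **Initialisation** is uniform on ±√(6/(n+m)) from a seeded generator;
  biases start at zero. All training is bit-reproducible under a fixed
  seed.
- **Greedy stacking without end-to-end fine-tuning:** layer i trains on
  layer i−1's codes. Hierarchical integration concatenates the per-block
  codes and trains one further layer on the concatenation.

Default structures follow the standard configuration for TCGA-scale data
(500-200-50 for wide expression/methylation blocks, 100-50 for narrow
miRNA blocks, 50-unit integrator). For the bundled synthetic study the
code widths are chosen commensurate with the generator's latent
dimensionality — 50-12 stacks and a 10-unit integrator for eight shared
factors — since a bottleneck far wider than the data's intrinsic dimension
carries noise directions that dilute class structure at small n.

## Flexible neural trees

An FNT is a tree whose leaves are input features and whose internal nodes
are flexible neurons: a node of arity k holds weights w₁..w_k and
activation parameters (a, b), computing net = Σ wᵢ·childᵢ and output
exp(−((net − a)/b)²) — the Gaussian flexible activation customary in the
flexible-neural-tree literature. Outputs of neuron-rooted trees lie in
(0, 1].

**Structure search (GGGP).** Grammar productions: S → N;
N → +_k(A, …, A) for each k in the forest's function set; A → N | T with
T forced at the depth bound (default max depth 4; the synthetic study uses
3 for its 10-dimensional codes). The terminal expansion probability is
0.7: terminal-heavy growth keeps sampled trees sparse — the representation's
point, and its overfitting control — and caps parameter counts relative to
the order-10² sample sizes the model targets. Evolution uses tournament
selection (size 2), grammar-respecting subtree crossover (probability 0.4)
that rejects swaps violating the depth bound, and point mutation
(probability 0.01) that either regrows a subtree or perturbs one
parameter. Population 50. Elitism makes best-so-far fitness non-increasing.

**Parameter search (PSO).** All neuron parameters flatten into one
position vector (preorder; per neuron [w₁..w_k, a, b]). Standard update
v ← ωv + c₁r₁(pbest − x) + c₂r₂(gbest − x) with c₁ = c₂ = 2, velocity
clipping at ±v_max = 2, inertia ω = 0.729 (the conventional constriction
value). With c₁ = c₂ = 2 the
attraction terms alone are at the edge of the stability region, so the
velocity cap is what keeps the swarm bounded — longer runs rather than
larger steps buy quality. b components are clamped to |b| ≥ 0.05 to bound
the Gaussian widths away from zero. Swarm initialisation: particle 0
keeps the incoming parameters, half the swarm perturbs them locally
(±0.25), half restarts globally in the sampling ranges; velocities start
at zero so short runs are purely attraction-driven.

**Interleaving.** During evolution each new candidate's fitness is its
training RMSE after a 10-iteration PSO polish; the original 5-iteration
polish ranked structures too noisily to guide selection (polished RMSEs of
identical structure distributions varied by more than the structure
effect). After the last generation the top 10 candidates each receive a
full PSO run and the lowest post-run RMSE wins — cheap vectorised restarts
over good structures.

## Cascade forest

A C-class problem becomes ceil(log₂ C) binary tasks: class c's codeword is
its binary representation, least-significant bit first. Each forest holds
one FNT per bit; three forests per level use the function sets
{+2,+3,+4}, {+2,+4,+5}, {+3,+4,+5} for diversity. Levels after the first
see the raw features concatenated with the previous level's class vectors
(raw continuous estimates, not thresholded bits). Growth monitors a
stratified 80/20 internal validation split: when validation accuracy fails
to improve by more than 1e−6 for `patience` (default 1) consecutive
levels, or at `max_levels` (default 10), growth stops; the earliest level
attaining the trace maximum is used for prediction. Decoding maps each
forest's class vector to the nearest codeword (Euclidean), then majority
votes across forests; all ties break toward the lowest class index.

Decoding and aggregation details, and the choice to decode only at the
selected level after full propagation, are package decisions;
nearest-codeword decoding with a cross-forest majority vote is the
standard treatment of output codes.

## Pipeline and evaluation

`fit_pipeline` freezes every stage (imputation donors, feature statistics,
all weights, all trees), so held-out samples are transformed with training
statistics only. `cross_validate` is stratified k-fold (default 5) with
every stage — including preprocessing and representation learning —
fitted inside the training folds; this is stricter than fitting the SAEs
once on all data, and the leakage-free choice is deliberate.
`permutation_control` repeats cross-validation on permuted data and
reports the mean accuracy next to the 1/C chance level (0.25 for four
classes) and the empirical majority-class frequency. Both label-shuffle
(default, the standard overfitting control) and row-shuffle (destroying
cross-omics alignment) permutation modes are provided; either destroys
the feature-label association, and the choice is explicit rather than
implied.

The master seed fans out to stage seeds through a spawned
`numpy.random.SeedSequence`, so the full run is bit-reproducible and
stages can be re-run independently.

Metrics: accuracy plus macro precision/recall/F1 with 0/0 defined as 0.

## Synthetic data

Real multi-omics layers on the same patients are dependent: subtype shapes
all layers jointly. The generator draws per-sample latent factors from
class-specific Gaussian means (unit within-class standard deviation;
means on a scaled simplex with pairwise distance `effect_size`) and emits
each block as an independent random linear map of the latents plus
Gaussian noise, with entries masked missing uniformly at random. Defaults
define the bundled study: 200 samples, 4 balanced subtypes, three blocks
of 300/150/80 features (expression-, methylation- and miRNA-like widths
at desk scale), 8 latent factors, effect size 5, noise sd 0.1, 5%
missingness.

What this emulates: differing block dimensionality, small n, class-driven
mean shifts, cross-omics correlation through shared factors, missingness.
What it does not: count or beta-value marginals, heavy tails, batch
effects, block-specific (non-shared) signal, informative missingness.
Passing the study therefore shows the machinery recovers planted
low-dimensional class structure end to end; it says nothing about
performance on real TCGA marginals.

Under these conditions the latent-space Bayes accuracy is ≈ 0.98, but a
practical ceiling near 0.95 applies at n = 200 (estimation error; the
fold-level linear-discriminant ceiling on the learned codes ranges
0.925–1.0). The M-ary decomposition squares per-bit error, which is the
method's structural cost on 4-class problems; the measured integrative
5-fold accuracy at the study seed is 0.90, above every single-omics
baseline (0.865–0.895), with the permuted-label control at chance.

## Problem sizes and budgets

The bundled study uses reduced search budgets — 10 GGGP generations,
10-particle swarms, 150 final PSO iterations — and the compact SAE
structures above; these are the package's desk-scale choices and are what
`scripts/acceptance.py` and the acceptance tests run. The repeated
permuted-label control uses a lighter variant (100 training epochs,
single-level cascade, 2-fold CV, 10 repeats): chance-level behaviour does
not depend on training effort, and the variant keeps ten repeats
affordable. Hot evaluation paths compile each tree to a postorder
instruction list and evaluate all swarm particles in one vectorised pass;
the compiled path is bitwise-identical to the recursive reference
evaluator (property-tested).

## Known limitations

- Plain gradient descent needs per-scale learning-rate choices; there is
  no schedule or momentum, by design fidelity.
- tanh saturation prevents exact reconstruction of large-amplitude data;
  z-scoring keeps the operating range reasonable but reconstruction MSE is
  optimisation-limited, not rank-limited, on wide blocks.
- With c₁ = c₂ = 2 PSO relies on velocity clipping for stability; quality
  comes from restarts and iterations rather than convergence guarantees.
- Accuracy on 4-class problems is bounded by squared per-bit accuracy;
  fold-to-fold variance of the 2-bit decomposition is visible at n = 200.
- The cascade rarely benefits from depth on well-separated synthetic
  codes; its adaptive growth is exercised but usually stops at 2–3 levels.
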