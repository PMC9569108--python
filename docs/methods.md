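# Methods

## Problem and approach

QSAR/QSPR models predict a compound's physicochemical or biological
property from its structure. Labeled property data are scarce, so a
common strategy is transfer learning: pre-train a representation model
on a large unlabeled corpus of molecules, then train a small
downstream model on the frozen representations. `descvae` implements a
descriptor-guided variant of this strategy for SMILES variational
autoencoders: before pre-training, a small set of cheaply computable
molecular descriptors most correlated with the downstream property is
identified, and the VAE is pre-trained *jointly* with a head that
predicts those descriptors from the latent code. The joint objective
pulls the latent space into an arrangement where the chosen
descriptors — and, by proxy, the correlated property — vary smoothly,
which downstream regressors exploit.

## Models

Both VAE variants encode a SMILES string to a diagonal-Gaussian
posterior N(μ, diag(σ²)) over a latent space (196-dimensional by
default; tests and fixtures use 16) and decode it with a GRU that
receives the latent vector at every step alongside the previous
token's embedding. The training loss is

    L = CE(decoder, input) + β · KL(N(μ,σ²) ‖ N(0,I)) + λ · MSE(predictor, z-scored descriptors)

* **CVAE**: convolutional encoder over the one-hot token matrix
  (three same-padded 1-D convolutions, ReLU), GRU decoder, and a
  3-hidden-layer perceptron predictor.
* **PVAE**: GRU encoder and decoder, a single linear predictor, and
  per-character weights on the decoder's output alphabet. For a symbol
  seen n_c times among N total occurrences of V distinct symbols, the
  cross-entropy weight is w_c = N/(V·n_c) (all ones for a uniform
  corpus), so rare SMILES characters are penalized proportionally more.
  A configurable exponent softens the weighting; unseen-but-known
  symbols get the maximum computed weight.

The closed-form KL per molecule is ½ Σᵢ (μᵢ² + e^{logvarᵢ} − logvarᵢ − 1).
Reconstruction cross-entropy is averaged over non-pad target positions.
Descriptor targets are standardized with corpus statistics that are
stored in the trained model, so probes and serving use one convention.

The networks are built on a small NumPy layer library (`descvae.nn`)
with hand-written backward passes (Dense, Embedding, GRU with the
reset-gate-inside-candidate parameterization, same-padded Conv1D) and
an Adam optimizer. Every layer's gradient, and the fully chained
VAE gradient (encoder → reparameterization → decoder/predictor → all
three loss terms), is verified against central finite differences in
the test suite to ~1e-10 relative error.

## Training defaults and why

One integer seed controls weight initialization, batch shuffling and
posterior sampling, so a fixed (config, corpus) pair reproduces its
loss history bit-for-bit. Defaults: hidden 64, embedding 32, batch 8,
learning rate 5e-3 (Adam), KL weight β = 0.02 annealed linearly from 0
over the first 20% of epochs, predictor weight λ = 1. The small batch
and raised learning rate reflect the corpus sizes this package trains
at (tens to hundreds of molecules): with a batch of 32 on a
32-molecule corpus, 300 epochs would yield only 300 optimizer steps
and reconstruction stalls near chance; batch 8 at lr 5e-3 reaches
≥ 0.94 exact-match reconstruction across seeds in the same budget.
β well below 1 is the usual regime for SMILES VAEs — at β ≈ 1 the KL
term collapses the posterior before the decoder can learn, and greedy
decoding from posterior means degenerates. Character weighting is on
by default for the PVAE only; `use_char_weights` overrides.

Reconstruction accuracy is exact string match of greedy decoding from
the posterior mean; per-character prefix accuracy is available as a
softer secondary metric. Embeddings default to posterior means
(deterministic); `mode="sample"` draws one reparameterized sample per
molecule under a seed, which is what the variance-decomposition
experiment uses.

## Descriptor selection

Classical filter selection, applied before any modeling: (1) drop
descriptors with sample variance ≤ 0.5 (strict comparison, computed on
raw unstandardized values); (2) rank the rest by |Pearson r| against
the task label, ties broken alphabetically; constant columns are
excluded with a warning; for classification tasks an optional mask
restricts the correlation to compounds with numeric labels; (3) greedy
pruning in ranking order — a descriptor is kept iff its pairwise |r|
with every already-kept descriptor is ≤ 0.9, so the more
task-correlated member of an intercorrelated pair survives, and each
drop is recorded with the kept partner and the offending r; (4) keep
the top 3 survivors. Pruning uses |r|, not signed r.

**Correlation-matched noisy descriptors.** To study how much of the
joint-pre-training benefit is attributable to the correlation
coefficient alone, a synthetic descriptor with a chosen lower
correlation is built by adding Gaussian noise to a real one. The
attenuation formula corr(d+ε, y) = r_d·sd(d)/√(sd(d)²+s²) gives the
analytic noise scale s = sd(d)·√((r_d/r_t)² − 1); the scale actually
applied to the drawn noise vector is then calibrated in closed form
(a quadratic in the sample moments) so the *realized* sample
correlation matches the requested value, not just its expectation —
at n = 10⁴ the expectation-only construction leaves ~0.01 of sampling
noise in the realized correlation, which defeats the purpose of
matching a real descriptor's printed correlation. Requesting the
current correlation returns the descriptor verbatim; a target larger
in magnitude or of opposite sign raises an error.

## Data curation

CSV in, canonical SMILES out (RDKit canonicalization). Unparseable
rows are dropped and counted. Structures are keyed by InChIKey;
duplicate keys collapse to one record when their labels agree
(regression labels within a configurable absolute tolerance, default
0.01 in label units) and the whole group is discarded when they
conflict. Any SMILES with more than one covalently connected component
(salts, mixtures, hydrates) is removed outright — no largest-fragment
rescue. logBB values binarize at −1 with the boundary in the positive
(BBB+) class. Descriptor rows with non-finite values are dropped and
recorded; rows with any per-column |z| > 6 are flagged but kept unless
an explicit drop flag is set (there is no principled universal outlier
rule for descriptors, so the default is conservative).

## Downstream models and evaluation

Three families run under seeded tenfold cross-validation (stratified
by class for classification; fold sizes differ by at most one; every
prediction comes from the fold where the molecule was held out):
ordinary least squares ("linear"; logistic regression for
classification), scikit-learn's MLP, and a 1-D residual network that
reads the d-dimensional embedding as a length-d single-channel
sequence — stem convolution, 4 pre-activation residual blocks of two
same-padded convolutions (32 channels, kernel 5), global average
pooling, linear head; trained with Adam on z-scored features and
targets, no early stopping or nested tuning. The baseline
representation is the 1024-bit Morgan radius-2 (ECFP4-equivalent)
fingerprint.

Model pairs are compared by within-fold bootstrap: in each of 1000
trials, indices are resampled with replacement inside each CV fold,
the metric (R², RMSE, accuracy or F1) is recomputed per fold for both
candidates and averaged over folds, and the trial is scored for
whichever candidate strictly exceeds the other — ties count for
neither, so identical candidates give proportion 0. A pair is
significantly different when one direction's exceedance proportion
exceeds 0.95. One comparison per pair; no multiple-testing correction.

Latent-space diagnostics: the expected-KL distance of a dataset is the
mean over molecules of the closed-form KL from the encoder posterior
to the prior — a measure of how far the dataset sits from the modeled
chemical space. Linear probes regress a target on frozen embeddings
under tenfold CV and report held-out RMSE mean ± SD; targets are
z-scored by default so probe errors are comparable across descriptors
(an uninformative embedding probes at RMSE ≈ 1), with raw-scale RMSE
available via `standardize_target=False`. Cluster-error analysis runs
seeded K-means (10 restarts, Euclidean metric on raw embedding
coordinates, k = 10 by default) and reports per-cluster size, mean
KL distance and held-out RMSE. PCA projections are centered scores
with explained-variance fractions.

## Synthetic fixtures

The fixture generator replaces download-scale corpora with small,
valid, fully reproducible chemistry: acyclic single-bonded molecules
over C/N/O (implicit hydrogens, valences 4/3/2). Two generators:
exhaustive breadth-first enumeration of the whole space up to a heavy-
atom limit (also the brute-force oracle in tests), and a seeded random
tree walk for larger samples. All outputs are canonical, distinct and
parseable, and span enough token types (atoms, branches) to exercise
the vocabulary and character-weighting logic. Properties are planted
as y = Σ w_d·z(d) + N(0, noise_sd²); with standardized descriptors the
weights are effect sizes, and for independent descriptors
corr(d, y) = w_d/√(Σw² + noise_sd²) in closed form.

What the fixtures do **not** emulate: rings, aromaticity,
stereochemistry, charged species, realistic drug-likeness, and the
scale (10⁵–10⁶ molecules) at which pre-training corpus size effects
appear. Passing tests therefore demonstrate the correctness and the
qualitative behavior of the machinery (joint training retains more
descriptor information; unfamiliar regions of chemical space sit
farther from the prior and predict worse), not performance figures
transferable to real logS/logD/logBB data.

## Problem sizes used in tests and the acceptance script

Overfit check: 32 molecules ≤ 6 heavy atoms, 300 epochs. Selection
recovery: 500 molecules, 8 candidate descriptors, planted weights
(1.0, 0.5), noise sd 0.5. Probe comparison: 300 molecules, 3 seeds,
60 epochs per model, joint (λ=1) vs plain (λ=0). Prior-distance
contrast: train on 150 small molecules, compare against 40 molecules
roughly twice the size. Workflow smoke: 200 molecules end to end, run
twice to confirm bit-identical artifacts. These sizes keep every run
deterministic, seeded and fast on one CPU while leaving each effect
well clear of its decision threshold.

## Known limitations

* The exact hyperparameters of the original large-scale CVAE/PVAE
  systems are not reproduced; all sizes and rates are config fields.
* Greedy decoding only; no sampling-based or validity-constrained
  decoding, and no de novo generation.
* The 1-D ResNet treats the embedding as a sequence, which is one of
  several defensible readings of "1-D ResNet on an embedding"; its
  architecture is a stated assumption, configurable.
* Linear-probe RMSEs depend on whether targets are standardized; both
  conventions are exposed and neither is claimed canonical.
* The NumPy training loop is single-threaded and intended for the
  fixture scale; it is not a route to 250K-molecule pre-training.
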