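# descvae

Descriptor-guided pre-training of SMILES variational autoencoders for
QSAR/QSPR property prediction, with the full downstream evaluation
machinery: filter-based descriptor selection, embedding-based property
models under tenfold cross-validation, bootstrap model comparison and
latent-space diagnostics.

## Who this is for

Cheminformatics practitioners who pre-train molecular representation
models on large unlabeled corpora and fine-tune small property models
(aqueous solubility logS, lipophilicity logD, blood–brain-barrier
penetration logBB, …) on top of the frozen embeddings — and who want
to know whether steering the pre-training with cheap, task-correlated
molecular descriptors buys downstream accuracy.

## The method

1. **Select descriptors.** Compute 2D descriptors for the target
   dataset, drop those with sample variance ≤ 0.5, rank the rest by
   |Pearson r| against the task label, greedily prune pairs with
   pairwise |r| > 0.9 (keeping the more task-correlated member), and
   take the top 3.
2. **Pre-train jointly.** Train a SMILES VAE — either the
   convolutional-encoder **CVAE** (3-hidden-layer MLP predictor) or the
   character-weighted **PVAE** (GRU encoder/decoder, linear predictor)
   — on the source corpus with the loss

   L = CE(decoder) + β·KL(N(μ,σ²) ‖ N(0,I)) + λ·MSE(predictor, z-scored descriptors)

   where the predictor head maps the latent code to the selected
   descriptors. λ = 0 recovers the plain VAE.
3. **Evaluate.** Encode the target dataset to posterior means, train
   linear / MLP / 1D-ResNet models under seeded tenfold CV, and compare
   representations pairwise by within-fold bootstrap (1000 trials,
   significant when one side's exceedance proportion exceeds 95%).
   Diagnose the latent space with expected-KL distances to the prior,
   linear probes of descriptor information, K-means cluster-error
   analysis and 2D PCA.

The neural networks run on a small, fully tested NumPy layer library
with hand-verified gradients; everything is single-CPU and seeded.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Self-contained (no downloads): generate a synthetic corpus of 300
small acyclic C/N/O molecules, plant a property
y = 1.0·z(MolLogP) + 0.5·z(TPSA) + N(0, 0.5²), select descriptors,
pre-train a joint and a plain PVAE, and compare the embeddings.

```python
import numpy as np
from descvae import (FixtureSpec, generate_corpus, make_record, MoleculeDataset,
                     TaskType, compute_descriptors, plant_property,
                     select_descriptors, VAEConfig, train_vae, embed,
                     ModelSpec, run_cv, linear_probe)

corpus = generate_corpus(FixtureSpec(n_molecules=300, max_heavy_atoms=9, seed=21))
dataset = MoleculeDataset([make_record(s) for s in corpus], TaskType.REGRESSION)
table = compute_descriptors(dataset, ["MolLogP", "MolWt", "TPSA", "NumHAcceptors",
                                      "NumHDonors", "NumRotatableBonds",
                                      "HeavyAtomCount", "NumHeteroatoms"])
y = plant_property(table, {"MolLogP": 1.0, "TPSA": 0.5}, noise_sd=0.5, seed=42)

sel = select_descriptors(table, y, k=3)
print("selected descriptors:", sel.selected)

arch = dict(variant="pvae", latent_dim=16, hidden_dim=64, embed_dim=32,
            epochs=60, seed=1)
joint = train_vae(VAEConfig(**arch, lambda_pred=1.0), corpus,
                  table.subset(sel.selected))
plain = train_vae(VAEConfig(**arch, lambda_pred=0.0), corpus)

for tag, model in [("joint", joint), ("plain", plain)]:
    e = embed(model, corpus)
    cv = run_cv(ModelSpec(family="linear"), e.vectors, y, n_folds=10, seed=0)
    rm, rs = linear_probe(e, table.column("MolLogP"), seed=0)
    print(f"{tag}: CV R^2 = {cv.aggregate['r2'][0]:.3f} +/- {cv.aggregate['r2'][1]:.3f}; "
          f"MolLogP probe RMSE = {rm:.3f} +/- {rs:.3f}")
```

Output:

```
selected descriptors: ['MolLogP', 'NumHDonors', 'TPSA']
joint: CV R^2 = 0.522 +/- 0.127; MolLogP probe RMSE = 0.182 +/- 0.024
plain: CV R^2 = 0.318 +/- 0.235; MolLogP probe RMSE = 0.464 +/- 0.051
```

Reading the numbers: the selection pipeline recovers the planted
descriptors (NumHDonors rides along because it correlates with planted
TPSA in this chemistry). Joint pre-training leaves far more MolLogP
information linearly accessible in the latent space (probe RMSE 0.18
vs 0.46 on the z-scored descriptor, where 1.0 would mean none), and
that translates into better downstream property prediction from the
same 16-dimensional embeddings (CV R² 0.52 vs 0.32).

The same workflow runs from the shell:

```sh
descvae make-fixture --n 300 --max-atoms 9 --plant MolLogP:1.0,TPSA:0.5 \
    --noise 0.5 --seed 21 --out fixture/
descvae select-descriptors --table fixture/desc.csv --target y --k 3 \
    --out selection.json          # (join desc.csv with clean.csv's y first)
descvae pretrain --corpus fixture/corpus.smi --variant pvae \
    --descriptors MolLogP --latent 16 --epochs 60 --seed 1 --out model/
descvae embed --model model/ --in fixture/clean.csv --out emb.npz
descvae train-qsar --x emb.npz --data fixture/clean.csv --model linear \
    --task regression --out cv.json
descvae run --config run.yaml     # full pipeline from one config
```

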