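"""Shared fixtures: synthetic corpora, descriptor tables and small
trained VAEs (session-scoped — training is the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

from descvae import (FixtureSpec, MoleculeDataset, TaskType, VAEConfig,
                     compute_descriptors, generate_corpus, make_record,
                     plant_property, train_vae)


def dataset_from_smiles(smiles, task=TaskType.REGRESSION, labels=None):
    labels = labels if labels is not None else [None] * len(smiles)
    return MoleculeDataset(
        [make_record(s, l) for s, l in zip(smiles, labels)], task)


@pytest.fixture(scope="session")
def tiny_corpus():
    """32 distinct acyclic C/N/O molecules, seeded."""
    return generate_corpus(FixtureSpec(n_molecules=32, max_heavy_atoms=6, seed=11))


@pytest.fixture(scope="session")
def medium_corpus():
    """300 molecules for selection/probe experiments."""
    return generate_corpus(FixtureSpec(n_molecules=300, max_heavy_atoms=9, seed=21))


@pytest.fixture(scope="session")
def medium_table(medium_corpus):
    ds = dataset_from_smiles(medium_corpus)
    return compute_descriptors(
        ds, ["MolLogP", "MolWt", "TPSA", "NumHAcceptors", "NumHDonors",
             "NumRotatableBonds", "HeavyAtomCount", "NumHeteroatoms"])


@pytest.fixture(scope="session")
def overfit_pvae(tiny_corpus):
    """PVAE trained to memorize the 32-molecule corpus (hidden 64,
    latent 16, 300 epochs)."""
    config = VAEConfig(variant="pvae", latent_dim=16, hidden_dim=64,
                       embed_dim=32, epochs=300, seed=3, lambda_pred=0.0)
    return train_vae(config, tiny_corpus)


@pytest.fixture(scope="session")
def joint_and_plain_pvae(medium_corpus, medium_table):
    """One jointly-trained and one plain PVAE per seed in (1, 2, 3),
    sharing corpus and architecture."""
    logp = medium_table.subset(["MolLogP"])
    out = {}
    for seed in (1, 2, 3):
        joint = train_vae(
            VAEConfig(variant="pvae", latent_dim=16, hidden_dim=64,
                      embed_dim=32, epochs=60, seed=seed, lambda_pred=1.0),
            medium_corpus, logp)
        plain = train_vae(
            VAEConfig(variant="pvae", latent_dim=16, hidden_dim=64,
                      embed_dim=32, epochs=60, seed=seed, lambda_pred=0.0),
            medium_corpus)
        out[seed] = (joint, plain)
    return out


@pytest.fixture(scope="session")
def planted_regression():
    """200-sample planted linear problem y = Xw in 8 dimensions plus
    mild noise, for model-capacity checks."""
    rng = np.random.default_rng(5)
    X = rng.standard_normal((200, 8))
    w = rng.standard_normal(8)
    y = X @ w + 0.1 * rng.standard_normal(200)
    return X, y
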