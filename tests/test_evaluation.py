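"""Bootstrap comparison, latent-space distances, probes, clustering
and PCA diagnostics."""

import numpy as np
import pytest

from descvae import (EmbeddingMatrix, bootstrap_compare,
                     cluster_error_analysis, dataset_prior_distance, embed,
                     linear_probe, make_folds, pca_project)
from descvae.vae_core import _kl_rows


def make_embedding(vectors, kl_scale=0.0):
    """EmbeddingMatrix with posterior means equal to the vectors and
    unit variances (logvar 0) unless kl_scale shifts the means."""
    v = np.asarray(vectors, dtype=float)
    return EmbeddingMatrix(vectors=v, posterior_means=v * (1 + kl_scale),
                           posterior_logvars=np.zeros_like(v))


class TestBootstrapCompare:
    def test_identical_candidates_not_significant(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        pred = y + 0.1 * rng.standard_normal(100)
        folds = make_folds(100, 10, seed=0)
        comp = bootstrap_compare(pred, pred.copy(), y, folds, n_trials=200, seed=1)
        assert comp.proportion == 0.0
        assert not comp.significant
        assert comp.direction == "tie"

    def test_planted_gap_detected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200)
        good = y + 0.05 * rng.standard_normal(200)
        bad = rng.permutation(y)
        folds = make_folds(200, 10, seed=0)
        comp = bootstrap_compare(good, bad, y, folds, n_trials=1000, seed=2)
        assert comp.significant
        assert comp.direction == "a"
        assert comp.proportion > 0.99

    def test_symmetry_swapping_candidates(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(150)
        a = y + 0.2 * rng.standard_normal(150)
        b = y + 0.4 * rng.standard_normal(150)
        folds = make_folds(150, 5, seed=0)
        ab = bootstrap_compare(a, b, y, folds, n_trials=300, seed=3)
        ba = bootstrap_compare(b, a, y, folds, n_trials=300, seed=3)
        assert ab.proportion == pytest.approx(ba.proportion)
        assert {ab.direction, ba.direction} == {"a", "b"}

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(100)
        a = y + 0.3 * rng.standard_normal(100)
        b = y + 0.35 * rng.standard_normal(100)
        folds = make_folds(100, 10, seed=0)
        c1 = bootstrap_compare(a, b, y, folds, n_trials=200, seed=9)
        c2 = bootstrap_compare(a, b, y, folds, n_trials=200, seed=9)
        assert c1.proportion == c2.proportion


class TestDatasetPriorDistance:
    def test_closed_form_single_molecule(self):
        mu = np.zeros((1, 8))
        mu[0, 0] = 2.0
        emb = EmbeddingMatrix(vectors=mu, posterior_means=mu,
                              posterior_logvars=np.zeros((1, 8)))
        assert float(_kl_rows(emb.posterior_means,
                              emb.posterior_logvars)[0]) == pytest.approx(2.0)

    def test_mean_linearity(self, overfit_pvae, tiny_corpus):
        whole = dataset_prior_distance(overfit_pvae, tiny_corpus)
        singles = [dataset_prior_distance(overfit_pvae, [s])
                   for s in tiny_corpus]
        assert whole == pytest.approx(np.mean(singles), rel=1e-9)

    def test_empty_list_raises(self, overfit_pvae):
        with pytest.raises(ValueError):
            dataset_prior_distance(overfit_pvae, [])

    def test_training_corpus_closer_than_disjoint_corpus(self):
        """Molecules the VAE was trained on sit nearer the prior than a
        structurally disjoint corpus of much larger molecules; majority
        over three seeds."""
        from descvae import (FixtureSpec, VAEConfig, build_vocabulary,
                             generate_corpus, train_vae)
        from descvae.vae_core import smiles_tokens
        small = generate_corpus(FixtureSpec(n_molecules=150,
                                            max_heavy_atoms=6, seed=31))
        pool = generate_corpus(FixtureSpec(n_molecules=200,
                                           max_heavy_atoms=12, seed=32))
        far = [s for s in pool if sum(c in "CNO" for c in s) >= 10][:40]
        maxlen = max(len(smiles_tokens(s)) for s in small + far) + 2
        vocab = build_vocabulary(small + far, maxlen)
        wins = 0
        for seed in (1, 2, 3):
            model = train_vae(
                VAEConfig(variant="pvae", latent_dim=16, hidden_dim=64,
                          embed_dim=32, epochs=60, seed=seed, lambda_pred=0.0),
                small, vocab=vocab)
            wins += (dataset_prior_distance(model, small)
                     < dataset_prior_distance(model, far))
        assert wins >= 2


class TestLinearProbe:
    def test_target_embedded_verbatim_probes_to_zero(self):
        rng = np.random.default_rng(0)
        target = rng.standard_normal(200)
        X = rng.standard_normal((200, 8))
        X[:, 0] = (target - target.mean()) / target.std()
        rm, _ = linear_probe(make_embedding(X), target, seed=0)
        assert rm == pytest.approx(0.0, abs=1e-9)

    def test_independent_embedding_probes_near_one(self):
        rng = np.random.default_rng(1)
        target = rng.standard_normal(500)
        X = rng.standard_normal((500, 8))
        rm, _ = linear_probe(make_embedding(X), target, seed=0)
        assert rm == pytest.approx(1.0, abs=0.15)

    def test_invariant_under_orthogonal_rotation(self):
        rng = np.random.default_rng(2)
        target = rng.standard_normal(150)
        X = rng.standard_normal((150, 6))
        X[:, 0] += target
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        r1, _ = linear_probe(make_embedding(X), target, seed=3)
        r2, _ = linear_probe(make_embedding(X @ Q), target, seed=3)
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_constant_target_raises(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        with pytest.raises(ValueError):
            linear_probe(make_embedding(X), np.ones(50))

    def test_joint_training_retains_more_descriptor_information(
            self, joint_and_plain_pvae, medium_corpus, medium_table):
        """The descriptor the VAE was jointly trained with must probe
        with lower RMSE than from a plain VAE, majority of 3 seeds."""
        logp = medium_table.column("MolLogP")
        wins = 0
        for seed, (joint, plain) in joint_and_plain_pvae.items():
            rj, _ = linear_probe(embed(joint, medium_corpus), logp, seed=seed)
            rp, _ = linear_probe(embed(plain, medium_corpus), logp, seed=seed)
            wins += rj < rp
        assert wins >= 2


class TestClusterDiagnostics:
    def test_single_cluster_rmse_equals_overall(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        pred = y + rng.standard_normal(60)
        diag = cluster_error_analysis(make_embedding(X), pred, y, k=1, seed=0)
        from descvae import metric_rmse
        assert diag.rmses[0] == pytest.approx(metric_rmse(y, pred))
        assert diag.sizes == [60]

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((40, 3)) + 10
        b = rng.standard_normal((40, 3)) - 10
        X = np.vstack([a, b])
        y = np.zeros(80)
        diag = cluster_error_analysis(make_embedding(X), y, y, k=2, seed=0)
        ids = diag.cluster_ids
        assert len(set(ids[:40])) == 1 and len(set(ids[40:])) == 1
        assert ids[0] != ids[-1]

    def test_seeded_assignments_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        d1 = cluster_error_analysis(make_embedding(X), y, y, k=5, seed=7)
        d2 = cluster_error_analysis(make_embedding(X), y, y, k=5, seed=7)
        assert np.array_equal(d1.cluster_ids, d2.cluster_ids)

    def test_planted_far_noisy_region_has_max_distance_and_rmse(self):
        """One region far from the prior with noisy predictions must
        surface as the cluster with both the largest KL distance and
        the largest RMSE."""
        rng = np.random.default_rng(3)
        n_main, n_far = 160, 40
        main = rng.standard_normal((n_main, 6)) * 0.3
        far = rng.standard_normal((n_far, 6)) * 0.3 + 6.0
        X = np.vstack([main, far])
        y = rng.standard_normal(n_main + n_far)
        pred = y.copy()
        pred[:n_main] += 0.1 * rng.standard_normal(n_main)
        pred[n_main:] += 2.0 * rng.standard_normal(n_far)
        emb = EmbeddingMatrix(vectors=X, posterior_means=X,
                              posterior_logvars=np.zeros_like(X))
        diag = cluster_error_analysis(emb, pred, y, k=5, seed=0)
        far_cluster = np.argmax([np.isin(m, np.arange(n_main, n_main + n_far)).mean()
                                 for m in diag.member_indices])
        assert np.argmax(diag.distances) == far_cluster
        assert np.argmax(diag.rmses) == far_cluster

    def test_k_exceeding_n_raises(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError):
            cluster_error_analysis(make_embedding(X), np.zeros(5), np.zeros(5),
                                   k=10)


class TestPCA:
    def test_line_explains_all_variance(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, np.array([1.0, 2.0, 3.0]))
        scores, ev = pca_project(make_embedding(X), n_components=2)
        assert ev[0] == pytest.approx(1.0)
        assert scores.shape == (30, 2)

    def test_full_rank_projection_preserves_distances(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 2))
        scores, ev = pca_project(make_embedding(X), n_components=2)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(X), pdist(scores), atol=1e-8)
        assert ev.sum() <= 1.0 + 1e-12

    def test_degenerate_rows_raise(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError):
            pca_project(make_embedding(X))
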