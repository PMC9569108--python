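"""Tokenization, loss components and VAE training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from descvae import (VAEConfig, build_vocabulary, char_weights, embed,
                     kl_to_prior, reconstruction_accuracy, tokenize,
                     train_vae, vae_loss)
from descvae.vae_core import (_VAENet, TrainedVAE, detokenize, load_model,
                              save_model, smiles_tokens)


class TestVocabularyAndTokenizer:
    def test_simple_symbol_set(self):
        vocab = build_vocabulary(["CCO"], 8)
        assert {"C", "O"} <= set(vocab.tokens)
        assert len(vocab) == 5    # C, O + pad/start/end

    def test_two_character_atoms_are_single_tokens(self):
        assert smiles_tokens("CCl") == ["C", "Cl"]
        assert smiles_tokens("BrCC[NH3+]") == ["Br", "C", "C", "[NH3+]"]

    def test_identical_corpora_identical_vocabularies(self):
        a = build_vocabulary(["CCO", "CCN"], 8)
        b = build_vocabulary(["CCO", "CCN"], 8)
        assert a.tokens == b.tokens

    def test_overlong_smiles_raises(self):
        with pytest.raises(ValueError):
            build_vocabulary(["CCCCCCCC"], 6)

    def test_empty_string_tokenizes_to_start_end_pad(self):
        vocab = build_vocabulary(["CCO"], 6)
        idx = tokenize("", vocab)
        assert idx[0] == vocab.start_index
        assert idx[1] == vocab.end_index
        assert all(i == vocab.pad_index for i in idx[2:])

    def test_round_trip_over_corpus(self, medium_corpus):
        maxlen = max(len(smiles_tokens(s)) for s in medium_corpus) + 2
        vocab = build_vocabulary(medium_corpus, maxlen)
        for s in medium_corpus[:100]:
            assert detokenize(tokenize(s, vocab), vocab) == s

    def test_unknown_symbol_raises(self):
        vocab = build_vocabulary(["CCO"], 8)
        with pytest.raises(KeyError):
            tokenize("CS", vocab)


class TestCharWeights:
    def test_cco_arithmetic(self):
        vocab = build_vocabulary(["CCO"], 8)
        w = char_weights(["CCO"], vocab)
        # N=3 symbols, V=2 distinct: w_C = 3/(2*2), w_O = 3/(2*1)
        assert w[vocab.token_to_index["C"]] == pytest.approx(0.75)
        assert w[vocab.token_to_index["O"]] == pytest.approx(1.5)

    def test_uniform_corpus_gives_unit_weights(self):
        vocab = build_vocabulary(["CN", "NC"], 8)
        w = char_weights(["CN", "NC"], vocab)
        assert w[vocab.token_to_index["C"]] == pytest.approx(1.0)
        assert w[vocab.token_to_index["N"]] == pytest.approx(1.0)

    def test_rarer_token_has_larger_weight(self, medium_corpus):
        maxlen = max(len(smiles_tokens(s)) for s in medium_corpus) + 2
        vocab = build_vocabulary(medium_corpus, maxlen)
        w = char_weights(medium_corpus, vocab)
        counts = {}
        for s in medium_corpus:
            for t in smiles_tokens(s):
                counts[t] = counts.get(t, 0) + 1
        items = sorted(counts.items(), key=lambda kv: kv[1])
        rare, common = items[0][0], items[-1][0]
        assert w[vocab.token_to_index[rare]] > w[vocab.token_to_index[common]]

    def test_weighted_token_mass_conserved(self, medium_corpus):
        """sum_c w_c * n_c = N for the seen symbols."""
        maxlen = max(len(smiles_tokens(s)) for s in medium_corpus) + 2
        vocab = build_vocabulary(medium_corpus, maxlen)
        w = char_weights(medium_corpus, vocab)
        counts = {}
        for s in medium_corpus:
            for t in smiles_tokens(s):
                counts[t] = counts.get(t, 0) + 1
        total = sum(w[vocab.token_to_index[t]] * n for t, n in counts.items())
        assert total == pytest.approx(sum(counts.values()))


class TestKLToPrior:
    def test_zero_at_prior(self):
        assert kl_to_prior(np.zeros(7), np.zeros(7)) == 0.0

    def test_hand_values(self):
        assert kl_to_prior(np.array([2.0]), np.array([0.0])) == pytest.approx(2.0)
        assert kl_to_prior(np.array([0.0]), np.array([np.log(4.0)])) == \
            pytest.approx(0.5 * (4 - np.log(4) - 1))

    def test_agrees_with_monte_carlo(self):
        """Closed form vs MC estimate E_q[log q - log p] at 1e6 samples."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            mu = rng.uniform(-1, 1, 4)
            logvar = rng.uniform(-1, 1, 4)
            sd = np.exp(0.5 * logvar)
            x = mu + sd * rng.standard_normal((1_000_000, 4))
            log_q = -0.5 * (((x - mu) / sd) ** 2 + logvar + np.log(2 * np.pi)).sum(1)
            log_p = -0.5 * (x ** 2 + np.log(2 * np.pi)).sum(1)
            mc = float(np.mean(log_q - log_p))
            assert kl_to_prior(mu, logvar) == pytest.approx(mc, abs=1e-2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=6),
           st.lists(st.floats(-3, 3), min_size=1, max_size=6))
    def test_nonnegative(self, mu, logvar):
        n = min(len(mu), len(logvar))
        assert kl_to_prior(np.array(mu[:n]), np.array(logvar[:n])) >= 0.0

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            kl_to_prior(np.array([np.inf]), np.array([0.0]))


class TestVAELoss:
    def _perfect_logits(self, targets, V):
        logits = np.full((*targets.shape, V), -1e3)
        for b in range(targets.shape[0]):
            for t in range(targets.shape[1]):
                logits[b, t, targets[b, t]] = 1e3
        return logits

    def test_perfect_reconstruction_at_prior_is_zero(self):
        targets = np.array([[1, 3, 4, 2, 0]])
        logits = self._perfect_logits(targets, 6)
        total, comp = vae_loss(logits, targets, np.zeros((1, 3)), np.zeros((1, 3)))
        assert total == pytest.approx(0.0, abs=1e-9)
        assert comp["kl"] == 0.0

    def test_lambda_zero_matches_no_predictor(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((2, 5, 6))
        targets = rng.integers(1, 6, (2, 5))
        mu, lv = rng.standard_normal((2, 3)), rng.standard_normal((2, 3))
        t0, _ = vae_loss(logits, targets, mu, lv)
        t1, _ = vae_loss(logits, targets, mu, lv,
                         pred_out=rng.standard_normal((2, 2)),
                         pred_targets=rng.standard_normal((2, 2)),
                         lambda_pred=0.0)
        assert t0 == pytest.approx(t1)

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((3, 4, 5))
        targets = rng.integers(1, 5, (3, 4))
        t0, _ = vae_loss(logits, targets, np.zeros((3, 2)), np.zeros((3, 2)))
        t1, _ = vae_loss(logits, targets, np.zeros((3, 2)), np.zeros((3, 2)),
                         weights=np.ones(5))
        assert t0 == pytest.approx(t1)

    def test_total_monotone_in_beta(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((2, 4, 5))
        targets = rng.integers(1, 5, (2, 4))
        mu, lv = rng.standard_normal((2, 3)), rng.standard_normal((2, 3))
        totals = [vae_loss(logits, targets, mu, lv, beta=b)[0]
                  for b in (0.0, 0.5, 1.0, 2.0)]
        assert totals == sorted(totals)


class TestTraining:
    def test_reconstruction_loss_decreases(self, overfit_pvae):
        hist = overfit_pvae.history
        assert hist[-1]["reconstruction"] < hist[0]["reconstruction"]
        assert all(np.isfinite(h["total"]) for h in hist)

    def test_overfit_model_memorizes_corpus(self, overfit_pvae, tiny_corpus):
        assert reconstruction_accuracy(overfit_pvae, tiny_corpus) >= 0.9

    def test_untrained_model_near_chance(self, medium_corpus):
        cfg = VAEConfig(variant="pvae", latent_dim=16, hidden_dim=64,
                        embed_dim=32, seed=0)
        from descvae import build_vocabulary
        maxlen = max(len(smiles_tokens(s)) for s in medium_corpus) + 2
        vocab = build_vocabulary(medium_corpus, maxlen)
        untrained = TrainedVAE(config=cfg, vocabulary=vocab,
                               net=_VAENet(cfg, vocab, 0))
        assert reconstruction_accuracy(untrained, medium_corpus[:100]) < 0.05

    def test_same_seed_reproduces_history(self, tiny_corpus):
        cfg = dict(variant="pvae", latent_dim=8, hidden_dim=16, embed_dim=8,
                   epochs=20, seed=5, lambda_pred=0.0)
        h1 = train_vae(VAEConfig(**cfg), tiny_corpus).history
        h2 = train_vae(VAEConfig(**cfg), tiny_corpus).history
        assert h1 == h2

    def test_joint_training_reduces_predictor_loss(self, joint_and_plain_pvae):
        for joint, _ in joint_and_plain_pvae.values():
            hist = joint.history
            assert hist[-1]["predictor"] < hist[0]["predictor"]

    def test_descriptor_coverage_gap_raises(self, tiny_corpus, medium_table):
        cfg = VAEConfig(variant="pvae", latent_dim=8, hidden_dim=16,
                        embed_dim=8, epochs=1, seed=0)
        with pytest.raises(ValueError):
            train_vae(cfg, tiny_corpus, medium_table)


class TestEmbedding:
    def test_mean_mode_deterministic(self, overfit_pvae, tiny_corpus):
        a = embed(overfit_pvae, tiny_corpus, mode="mean")
        b = embed(overfit_pvae, tiny_corpus, mode="mean")
        assert np.array_equal(a.vectors, b.vectors)
        assert np.array_equal(a.vectors, a.posterior_means)

    def test_sample_mode_seeded(self, overfit_pvae, tiny_corpus):
        a = embed(overfit_pvae, tiny_corpus, mode="sample", seed=1)
        b = embed(overfit_pvae, tiny_corpus, mode="sample", seed=1)
        c = embed(overfit_pvae, tiny_corpus, mode="sample", seed=2)
        assert np.array_equal(a.vectors, b.vectors)
        assert not np.array_equal(a.vectors, c.vectors)

    def test_latent_width_matches_config(self, overfit_pvae, tiny_corpus):
        emb = embed(overfit_pvae, tiny_corpus)
        assert emb.vectors.shape == (len(tiny_corpus),
                                     overfit_pvae.config.latent_dim)

    def test_default_latent_dim_is_196(self):
        assert VAEConfig().latent_dim == 196


class TestSerialization:
    def test_round_trip_preserves_embeddings(self, overfit_pvae, tiny_corpus,
                                             tmp_path):
        save_model(overfit_pvae, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        a = embed(overfit_pvae, tiny_corpus).vectors
        b = embed(loaded, tiny_corpus).vectors
        assert np.array_equal(a, b)
        assert loaded.config == overfit_pvae.config
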