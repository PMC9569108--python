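"""SMILES tokenization and the two VAE variants.

Two architectures are provided:

* **CVAE** — convolutional encoder over one-hot SMILES, GRU decoder,
  and a 3-hidden-layer perceptron predictor head.
* **PVAE** — GRU encoder and decoder, a single linear predictor head,
  and character-frequency weights on the decoder's output alphabet
  (rare SMILES characters get proportionally larger reconstruction
  penalties).

Both map a molecule to a diagonal-Gaussian posterior N(mu, diag(s^2))
over the latent space and are trained on

    reconstruction + beta * KL(posterior || N(0, I)) + lambda_pred * MSE

where the optional MSE term is a predictor of standardized molecular
descriptors computed from the latent code.  The joint descriptor
predictor is the mechanism under study: it pulls the latent space into
an arrangement where the chosen descriptors vary smoothly, which is
what downstream property models exploit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .chem_data import DescriptorTable

__all__ = [
    "Vocabulary",
    "VAEConfig",
    "TrainedVAE",
    "EmbeddingMatrix",
    "build_vocabulary",
    "tokenize",
    "detokenize",
    "char_weights",
    "kl_to_prior",
    "vae_loss",
    "train_vae",
    "reconstruction_accuracy",
    "embed",
    "save_model",
    "load_model",
]

START, END, PAD = "<start>", "<end>", "<pad>"

# multi-character tokens: bracket atoms, two-letter halogens, ring-bond
# escapes; everything else is a single character
_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")


def smiles_tokens(smiles: str) -> list[str]:
    return _TOKEN_RE.findall(smiles)


@dataclass
class Vocabulary:
    tokens: list[str]
    max_length: int
    token_to_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.token_to_index:
            self.token_to_index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def start_index(self) -> int:
        return self.token_to_index[START]

    @property
    def end_index(self) -> int:
        return self.token_to_index[END]

    @property
    def pad_index(self) -> int:
        return self.token_to_index[PAD]


def build_vocabulary(corpus: list[str], max_length: int) -> Vocabulary:
    """Sorted unique SMILES symbols of the corpus plus start/end/pad.

    Every corpus string must fit in ``max_length`` including the
    start/end markers.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    too_long = [s for s in corpus if len(smiles_tokens(s)) > max_length - 2]
    if too_long:
        raise ValueError(
            f"{len(too_long)} SMILES exceed max_length-2 tokens, e.g. {too_long[0]!r}")
    symbols = sorted({t for s in corpus for t in smiles_tokens(s)})
    return Vocabulary(tokens=[PAD, START, END] + symbols, max_length=max_length)


def tokenize(smiles: str, vocab: Vocabulary) -> np.ndarray:
    """start + symbols + end, right-padded to ``vocab.max_length``."""
    toks = smiles_tokens(smiles)
    unknown = [t for t in toks if t not in vocab.token_to_index]
    if unknown:
        raise KeyError(f"symbols not in vocabulary: {sorted(set(unknown))}")
    if len(toks) > vocab.max_length - 2:
        raise ValueError(f"SMILES too long for vocabulary: {smiles!r}")
    idx = [vocab.start_index] + [vocab.token_to_index[t] for t in toks] + [vocab.end_index]
    idx += [vocab.pad_index] * (vocab.max_length - len(idx))
    return np.array(idx, dtype=np.int64)


def detokenize(indices: np.ndarray, vocab: Vocabulary) -> str:
    """Inverse of tokenize: strips start/end/pad."""
    out = []
    for i in indices:
        t = vocab.tokens[int(i)]
        if t == END:
            break
        if t in (START, PAD):
            continue
        out.append(t)
    return "".join(out)


def char_weights(corpus: list[str], vocab: Vocabulary,
                 exponent: float = 1.0, pad_weight: float = 1.0) -> np.ndarray:
    """Inverse-relative-frequency weights over the vocabulary.

    For a symbol c seen n_c times in a corpus with N total symbol
    occurrences across V distinct seen symbols, w_c = (N / (V * n_c)) **
    exponent — a uniform corpus gives all-ones.  Symbols in the
    vocabulary but absent from the corpus get the maximum computed
    weight; start/end get weight 1 and pad gets ``pad_weight``.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for s in corpus:
        for t in smiles_tokens(s):
            counts[t] = counts.get(t, 0) + 1
    N = sum(counts.values())
    V = len(counts)
    w = np.ones(len(vocab))
    seen = {t: (N / (V * n)) ** exponent for t, n in counts.items()}
    w_max = max(seen.values())
    for t, i in vocab.token_to_index.items():
        if t in seen:
            w[i] = seen[t]
        elif t not in (START, END, PAD):
            w[i] = w_max
    w[vocab.pad_index] = pad_weight
    return w


def kl_to_prior(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form.

    0.5 * sum(mu^2 + exp(logvar) - logvar - 1); zero exactly at the
    prior.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("non-finite posterior parameters")
    return float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0))


def _kl_rows(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    return 0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=1)


def vae_loss(decoder_logits: np.ndarray, target_tokens: np.ndarray,
             mu: np.ndarray, logvar: np.ndarray,
             weights: np.ndarray | None = None, beta: float = 1.0,
             pred_out: np.ndarray | None = None,
             pred_targets: np.ndarray | None = None,
             lambda_pred: float = 0.0,
             pad_index: int = 0) -> tuple[float, dict[str, float]]:
    """Total loss and its components for one batch.

    reconstruction: token-wise cross-entropy over non-pad positions,
    optionally weighted per target token; kl: batch-mean KL to the
    prior; predictor: MSE on standardized descriptor targets.
    """
    if (pred_out is None) != (pred_targets is None):
        raise ValueError("pred_out and pred_targets must be given together")
    B, T, Vsz = decoder_logits.shape
    if target_tokens.shape != (B, T):
        raise ValueError("logits and targets have inconsistent shapes")
    flat_logits = decoder_logits.reshape(B * T, Vsz)
    flat_targets = target_tokens.reshape(B * T)
    sw = np.ones(B * T) if weights is None else np.asarray(weights)[flat_targets].astype(float)
    sw[flat_targets == pad_index] = 0.0
    recon, _ = nn.softmax_cross_entropy(flat_logits, flat_targets, sw)
    kl = float(np.mean(_kl_rows(mu, logvar)))
    pred = 0.0
    if pred_out is not None:
        pred = float(np.mean((pred_out - pred_targets) ** 2))
    total = recon + beta * kl + lambda_pred * pred
    return total, {"reconstruction": recon, "kl": kl, "predictor": pred}


@dataclass
class VAEConfig:
    """Architecture and training hyperparameters.

    ``beta`` is the KL weight (annealed linearly from 0 over
    ``beta_warmup_frac`` of the epochs); ``lambda_pred`` weights the
    descriptor-predictor loss and 0 disables the head entirely.
    """

    variant: str = "pvae"            # "pvae" | "cvae"
    latent_dim: int = 196
    hidden_dim: int = 64
    embed_dim: int = 32
    conv_channels: tuple[int, ...] = (9, 9, 10)
    conv_kernels: tuple[int, ...] = (9, 9, 11)
    predictor_hidden: int = 64       # CVAE MLP width (3 hidden layers)
    beta: float = 0.02
    beta_warmup_frac: float = 0.2
    lambda_pred: float = 1.0
    use_char_weights: bool | None = None   # default: True iff PVAE
    char_weight_exponent: float = 1.0
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.variant = self.variant.lower()
        if self.variant not in ("pvae", "cvae"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.use_char_weights is None:
            self.use_char_weights = self.variant == "pvae"
        self.conv_channels = tuple(self.conv_channels)
        self.conv_kernels = tuple(self.conv_kernels)


class _VAENet:
    """Encoder/decoder/predictor stack with hand-chained backprop."""

    def __init__(self, config: VAEConfig, vocab: Vocabulary, n_desc: int) -> None:
        self.config = config
        self.vocab = vocab
        self.n_desc = n_desc
        rng = np.random.default_rng(config.seed)
        V, E, H, L = len(vocab), config.embed_dim, config.hidden_dim, config.latent_dim

        if config.variant == "pvae":
            self.enc_embed = nn.Embedding(V, E, rng)
            self.enc_gru = nn.GRU(E, H, rng)
            enc_out = H
            self.convs = []
        else:
            self.convs = []
            c_in = V
            for ch, k in zip(config.conv_channels, config.conv_kernels):
                self.convs.append(nn.Conv1D(c_in, ch, k, rng, activation="relu"))
                c_in = ch
            self.enc_dense = nn.Dense(vocab.max_length * c_in, H, rng, activation="relu")
            enc_out = H
        self.mu_head = nn.Dense(enc_out, L, rng)
        self.logvar_head = nn.Dense(enc_out, L, rng)

        self.dec_embed = nn.Embedding(V, E, rng)
        self.dec_h0 = nn.Dense(L, H, rng, activation="tanh")
        self.dec_gru = nn.GRU(E + L, H, rng)
        self.dec_out = nn.Dense(H, V, rng)

        self.pred_layers: list[nn.Dense] = []
        if n_desc > 0:
            if config.variant == "cvae":
                P = config.predictor_hidden
                self.pred_layers = [
                    nn.Dense(L, P, rng, activation="relu"),
                    nn.Dense(P, P, rng, activation="relu"),
                    nn.Dense(P, P, rng, activation="relu"),
                    nn.Dense(P, n_desc, rng),
                ]
            else:
                self.pred_layers = [nn.Dense(L, n_desc, rng)]

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        if self.config.variant == "pvae":
            out += [self.enc_embed, self.enc_gru]
        else:
            out += list(self.convs) + [self.enc_dense]
        out += [self.mu_head, self.logvar_head,
                self.dec_embed, self.dec_h0, self.dec_gru, self.dec_out]
        out += self.pred_layers
        return out

    # ---- encoder -------------------------------------------------------
    def encode(self, tokens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.config.variant == "pvae":
            x = self.enc_embed.forward(tokens)
            hs = self.enc_gru.forward(x)
            feat = hs[:, -1, :]
        else:
            onehot = np.eye(len(self.vocab))[tokens]
            h = onehot
            for conv in self.convs:
                h = conv.forward(h)
            feat = self.enc_dense.forward(h.reshape(h.shape[0], -1))
        self._enc_feat_shape = feat.shape
        return self.mu_head.forward(feat), self.logvar_head.forward(feat)

    def _encode_backward(self, dmu: np.ndarray, dlogvar: np.ndarray,
                         tokens: np.ndarray) -> None:
        dfeat = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        if self.config.variant == "pvae":
            B, T = tokens.shape
            dhs = np.zeros((B, T, self.config.hidden_dim))
            dhs[:, -1, :] = dfeat
            dx, _ = self.enc_gru.backward(dhs)
            self.enc_embed.backward(dx)
        else:
            dh = self.enc_dense.backward(dfeat)
            B = tokens.shape[0]
            dh = dh.reshape(B, self.vocab.max_length, -1)
            for conv in reversed(self.convs):
                dh = conv.backward(dh)
            # gradient stops at the one-hot input

    # ---- decoder -------------------------------------------------------
    def decode_teacher(self, z: np.ndarray, tokens: np.ndarray) -> np.ndarray:
        """Teacher-forced logits for positions 1..T-1."""
        inp = tokens[:, :-1]
        emb = self.dec_embed.forward(inp)
        B, Tm1, _ = emb.shape
        zrep = np.repeat(z[:, None, :], Tm1, axis=1)
        x = np.concatenate([emb, zrep], axis=2)
        h0 = self.dec_h0.forward(z)
        hs = self.dec_gru.forward(x, h0)
        return self.dec_out.forward(hs)

    def _decode_backward(self, dlogits: np.ndarray) -> np.ndarray:
        dhs = self.dec_out.backward(dlogits)
        dx, dh0 = self.dec_gru.backward(dhs)
        E = self.config.embed_dim
        self.dec_embed.backward(dx[:, :, :E])
        dz = dx[:, :, E:].sum(axis=1)
        dz += self.dec_h0.backward(dh0)
        return dz

    # ---- predictor -----------------------------------------------------
    def predict_desc(self, z: np.ndarray) -> np.ndarray:
        h = z
        for ly in self.pred_layers:
            h = ly.forward(h)
        return h

    def _predict_backward(self, dout: np.ndarray) -> np.ndarray:
        for ly in reversed(self.pred_layers):
            dout = ly.backward(dout)
        return dout

    # ---- one training step --------------------------------------------
    def loss_and_grads(self, tokens: np.ndarray, weights: np.ndarray | None,
                       beta: float, desc_targets: np.ndarray | None,
                       lambda_pred: float, rng: np.random.Generator
                       ) -> dict[str, float]:
        B = tokens.shape[0]
        mu, logvar = self.encode(tokens)
        logvar = np.clip(logvar, -10.0, 10.0)
        std = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape)
        z = mu + std * eps

        logits = self.decode_teacher(z, tokens)
        targets = tokens[:, 1:]
        Bt, Tm1, Vsz = logits.shape
        flat_logits = logits.reshape(Bt * Tm1, Vsz)
        flat_targets = targets.reshape(Bt * Tm1)
        sw = np.ones(Bt * Tm1) if weights is None \
            else np.asarray(weights)[flat_targets].astype(float)
        sw[flat_targets == self.vocab.pad_index] = 0.0
        recon, dflat = nn.softmax_cross_entropy(flat_logits, flat_targets, sw)
        dlogits = dflat.reshape(Bt, Tm1, Vsz)

        dz = self._decode_backward(dlogits)

        pred = 0.0
        if desc_targets is not None and self.pred_layers:
            pred_out = self.predict_desc(z)
            resid = pred_out - desc_targets
            pred = float(np.mean(resid ** 2))
            dpred_out = lambda_pred * 2.0 * resid / resid.size
            dz += self._predict_backward(dpred_out)

        kl = float(np.mean(_kl_rows(mu, logvar)))
        dmu = dz + beta * mu / B
        dlogvar = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0) / B
        self._encode_backward(dmu, dlogvar, tokens)

        total = recon + beta * kl + lambda_pred * pred
        return {"total": total, "reconstruction": recon, "kl": kl, "predictor": pred}


@dataclass
class TrainedVAE:
    config: VAEConfig
    vocabulary: Vocabulary
    net: _VAENet
    descriptor_names: list[str] = field(default_factory=list)
    descriptor_standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    history: list[dict[str, float]] = field(default_factory=list)
    char_weight_vector: np.ndarray | None = None


@dataclass
class EmbeddingMatrix:
    vectors: np.ndarray
    posterior_means: np.ndarray
    posterior_logvars: np.ndarray
    mode: str = "mean"
    seed: int | None = None


def _tokenize_corpus(corpus: list[str], vocab: Vocabulary) -> np.ndarray:
    return np.stack([tokenize(s, vocab) for s in corpus])


def train_vae(config: VAEConfig, corpus: list[str],
              descriptor_table: DescriptorTable | None = None,
              descriptor_names: list[str] | None = None,
              vocab: Vocabulary | None = None) -> TrainedVAE:
    """Optimize the joint loss over the corpus.

    When a descriptor table is given, its (optionally ``descriptor_names``
    -restricted) columns become predictor targets, standardized to zero
    mean / unit variance with corpus statistics that are stored in the
    returned model.  One seed controls weight init, batch shuffling and
    posterior sampling, so a fixed (config, corpus) pair reproduces its
    loss history exactly.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if vocab is None:
        max_len = max(len(smiles_tokens(s)) for s in corpus) + 2
        vocab = build_vocabulary(corpus, max_len)
    tokens = _tokenize_corpus(corpus, vocab)

    desc_targets = None
    names: list[str] = []
    standardization: dict[str, tuple[float, float]] = {}
    if descriptor_table is not None and config.lambda_pred > 0:
        names = descriptor_names or descriptor_table.names
        if descriptor_table.n_molecules != len(corpus):
            raise ValueError(
                "descriptor table does not cover the corpus "
                f"({descriptor_table.n_molecules} rows vs {len(corpus)} molecules)")
        cols = []
        for n in names:
            col = descriptor_table.column(n)
            m, s = float(col.mean()), float(col.std())
            if s == 0:
                raise ValueError(f"descriptor {n!r} is constant on the corpus")
            standardization[n] = (m, s)
            cols.append((col - m) / s)
        desc_targets = np.stack(cols, axis=1)

    net = _VAENet(config, vocab, n_desc=len(names))
    weights = None
    if config.use_char_weights:
        weights = char_weights(corpus, vocab, exponent=config.char_weight_exponent)

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net.layers(), lr=config.learning_rate)
    n = len(corpus)
    warmup = max(1, int(round(config.beta_warmup_frac * config.epochs)))
    history: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        beta_t = config.beta * min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        sums = {"total": 0.0, "reconstruction": 0.0, "kl": 0.0, "predictor": 0.0}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            comp = net.loss_and_grads(
                tokens[idx], weights, beta_t,
                None if desc_targets is None else desc_targets[idx],
                config.lambda_pred, rng)
            if not np.isfinite(comp["total"]):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
            opt.step()
            for k in sums:
                sums[k] += comp[k]
            n_batches += 1
        history.append({k: v / n_batches for k, v in sums.items()} | {"beta": beta_t})

    return TrainedVAE(config=config, vocabulary=vocab, net=net,
                      descriptor_names=names,
                      descriptor_standardization=standardization,
                      history=history, char_weight_vector=weights)


def embed(model: TrainedVAE, smiles: list[str], mode: str = "mean",
          seed: int | None = None, batch_size: int = 256) -> EmbeddingMatrix:
    """Posterior parameters for each molecule; vectors are the means
    (deterministic) or one reparameterized sample per molecule."""
    if mode not in ("mean", "sample"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    if not smiles:
        raise ValueError("no molecules to embed")
    mus, logvars = [], []
    for start in range(0, len(smiles), batch_size):
        batch = smiles[start:start + batch_size]
        tokens = _tokenize_corpus(batch, model.vocabulary)
        mu, logvar = model.net.encode(tokens)
        mus.append(mu)
        logvars.append(np.clip(logvar, -10.0, 10.0))
    mu = np.vstack(mus)
    logvar = np.vstack(logvars)
    if mode == "mean":
        vectors = mu.copy()
    else:
        rng = np.random.default_rng(seed)
        vectors = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    return EmbeddingMatrix(vectors=vectors, posterior_means=mu,
                           posterior_logvars=logvar, mode=mode, seed=seed)


def greedy_decode(model: TrainedVAE, z: np.ndarray) -> list[str]:
    """Greedy argmax decoding of each latent vector to a SMILES string."""
    net, vocab = model.net, model.vocabulary
    B = z.shape[0]
    h = net.dec_h0.forward(z)
    prev = np.full(B, vocab.start_index, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    out_tokens = np.full((B, vocab.max_length), vocab.pad_index, dtype=np.int64)
    for t in range(vocab.max_length - 1):
        emb = net.dec_embed.forward(prev)
        x = np.concatenate([emb, z], axis=1)[:, None, :]
        hs = net.dec_gru.forward(x, h)
        h = hs[:, -1, :]
        logits = net.dec_out.forward(h)
        nxt = logits.argmax(axis=1)
        nxt[done] = vocab.pad_index
        out_tokens[:, t] = nxt
        done |= nxt == vocab.end_index
        if done.all():
            break
        prev = nxt
    return [detokenize(row, vocab) for row in out_tokens]


def reconstruction_accuracy(model: TrainedVAE, smiles: list[str],
                            return_per_char: bool = False):
    """Fraction of molecules whose greedy decoding from the posterior
    mean reproduces the input SMILES exactly.

    ``return_per_char`` additionally yields the mean per-character
    accuracy (prefix-aligned) as a softer diagnostic.
    """
    if not smiles:
        raise ValueError("no molecules given")
    emb_out = embed(model, smiles, mode="mean")
    decoded = greedy_decode(model, emb_out.posterior_means)
    exact = np.mean([d == s for d, s in zip(decoded, smiles)])
    if not return_per_char:
        return float(exact)
    per_char = []
    for d, s in zip(decoded, smiles):
        td, ts = smiles_tokens(d), smiles_tokens(s)
        m = max(len(ts), 1)
        per_char.append(sum(a == b for a, b in zip(td, ts)) / m)
    return float(exact), float(np.mean(per_char))


# ---- serialization -----------------------------------------------------

def save_model(model: TrainedVAE, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["conv_channels"] = list(cfg["conv_channels"])
    cfg["conv_kernels"] = list(cfg["conv_kernels"])
    (d / "config.yaml").write_text(yaml.safe_dump(cfg))
    (d / "vocabulary.json").write_text(json.dumps(
        {"tokens": model.vocabulary.tokens, "max_length": model.vocabulary.max_length}))
    (d / "standardization.json").write_text(json.dumps({
        "descriptor_names": model.descriptor_names,
        "standardization": {k: list(v) for k, v in model.descriptor_standardization.items()},
    }))
    (d / "history.json").write_text(json.dumps(model.history))
    arrays = {}
    for i, ly in enumerate(model.net.layers()):
        for k, v in ly.params.items():
            arrays[f"{i}::{k}"] = v
    np.savez(d / "weights.npz", **arrays)


def load_model(directory: str | Path) -> TrainedVAE:
    d = Path(directory)
    cfg = yaml.safe_load((d / "config.yaml").read_text())
    config = VAEConfig(**cfg)
    vj = json.loads((d / "vocabulary.json").read_text())
    vocab = Vocabulary(tokens=vj["tokens"], max_length=vj["max_length"])
    sj = json.loads((d / "standardization.json").read_text())
    net = _VAENet(config, vocab, n_desc=len(sj["descriptor_names"]))
    with np.load(d / "weights.npz") as z:
        for i, ly in enumerate(net.layers()):
            for k in ly.params:
                ly.params[k] = z[f"{i}::{k}"].copy()
    history = json.loads((d / "history.json").read_text())
    return TrainedVAE(config=config, vocabulary=vocab, net=net,
                      descriptor_names=sj["descriptor_names"],
                      descriptor_standardization={
                          k: tuple(v) for k, v in sj["standardization"].items()},
                      history=history)
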