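"""Functional-peptide classifier: tokenizer, pluggable residue embeddings,
parallel CNN and BiLSTM channels, and a batch-normalized MLP head.

One model instance is trained per task (ACP or AMP).  The embedding stage
is a contract: ``TrainableLookupProvider`` is a randomly initialized token
embedding trained jointly with the classifier (the default; needs no
downloaded weights), while ``ExternalProvider`` wraps any user-supplied
function that maps token-id matrices to per-residue embedding tensors
(e.g. a protein language model).

Channels:

* CNN: conv(256,k3) -> ReLU -> conv(128,k3) -> ReLU -> conv(64,k3) -> ReLU
  -> masked global average pooling over sequence positions (pads excluded).
* BiLSTM: forward-direction last-valid-step hidden state concatenated with
  the backward-direction state at its last step (sequence position 0).

The two channel outputs are concatenated, batch-normalized, and classified
by a three-layer MLP ending in a sigmoid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .metrics import ConfusionCounts, accuracy as _acc, f1_score, mcc
from .seqio import PeptideRecord
from .synthetic_data import stratified_split

AA20 = "ACDEFGHIKLMNPQRSTVWY"
SPECIALS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")


class TokenVocabulary:
    """26 tokens: 5 specials, the 20 standard amino acids, and X."""

    def __init__(self):
        self.tokens = list(SPECIALS) + list(AA20) + ["X"]
        if len(self.tokens) != 26:
            raise AssertionError("vocabulary must have exactly 26 tokens")
        self.id_of = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self):
        return self.id_of["[PAD]"]

    @property
    def cls_id(self):
        return self.id_of["[CLS]"]

    @property
    def sep_id(self):
        return self.id_of["[SEP]"]

    def residue_id(self, ch: str) -> int:
        return self.id_of.get(ch, self.id_of["X"])


@dataclasses.dataclass
class TokenizedPeptide:
    ids: np.ndarray
    attention_mask: np.ndarray
    original: PeptideRecord

    @property
    def n_residues(self) -> int:
        return int(self.attention_mask.sum()) - 2  # minus [CLS]/[SEP]


def tokenize(peptide: PeptideRecord, vocab: TokenVocabulary, max_len: int = 100) -> TokenizedPeptide:
    """[CLS] + residues + [SEP], right-padded with [PAD] to ``max_len``."""
    if not peptide.sequence:
        raise ValueError("empty peptide sequence")
    if max_len < 3:
        raise ValueError("max_len must be at least 3")
    residues = peptide.sequence[:max_len - 2]
    ids = [vocab.cls_id] + [vocab.residue_id(ch) for ch in residues] + [vocab.sep_id]
    mask = [1] * len(ids)
    while len(ids) < max_len:
        ids.append(vocab.pad_id)
        mask.append(0)
    return TokenizedPeptide(ids=np.array(ids, dtype=np.int64),
                            attention_mask=np.array(mask, dtype=np.int64),
                            original=peptide)


def detokenize(tok: TokenizedPeptide, vocab: TokenVocabulary) -> str:
    out = []
    for tid, m in zip(tok.ids, tok.attention_mask):
        if not m:
            break
        t = vocab.tokens[tid]
        if t not in SPECIALS:
            out.append(t)
    return "".join(out)


# -- embedding providers ----------------------------------------------------

class TrainableLookupProvider(nn.Module):
    """Randomly initialized token-embedding table trained with the model."""

    mode = "trainable_lookup"

    def __init__(self, vocab: TokenVocabulary, dim: int = 128, seed: int = 702):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.table = nn.Embedding(len(vocab), dim, rng, pad_id=vocab.pad_id)

    def __call__(self, ids: np.ndarray) -> nn.Tensor:
        return self.table(ids)       # (B, L, D)


class ExternalProvider(nn.Module):
    """Wraps a user-supplied embedding function (e.g. a protein LM).

    ``fn(ids) -> (B, L, D) array``; the result is treated as a constant
    input (no gradients flow into the external model).
    """

    mode = "external_lm"

    def __init__(self, fn, dim: int):
        super().__init__()
        self.fn = fn
        self.dim = dim

    def __call__(self, ids: np.ndarray) -> nn.Tensor:
        emb = np.asarray(self.fn(ids), dtype=np.float32)
        if emb.shape[-1] != self.dim or not np.all(np.isfinite(emb)):
            raise ValueError("external provider returned wrong width or non-finite values")
        return nn.Tensor(emb)


# -- configuration ----------------------------------------------------------

@dataclasses.dataclass
class PeptideModelConfig:
    cnn_filters: tuple = (256, 128, 64)
    cnn_kernel: int = 3
    lstm_hidden: int = 64
    mlp_widths: tuple = (64, 32)
    embed_dim: int = 128
    lr: float = 2e-5
    batch_size: int = 4
    max_epochs: int = 20
    patience: int = 3
    seed: int = 702
    max_len: int = 100

    def __post_init__(self):
        if len(self.cnn_filters) != 3:
            raise ValueError("exactly three CNN layers")
        if len(self.mlp_widths) != 2:
            raise ValueError("mlp_widths gives the two hidden MLP widths "
                             "(third layer is the scalar output)")
        if min(self.cnn_filters) <= 0 or self.lstm_hidden <= 0:
            raise ValueError("widths must be positive")

    @classmethod
    def desk(cls, seed: int = 702, **overrides) -> "PeptideModelConfig":
        """Compact single-CPU profile used by examples/tests."""
        kw = dict(cnn_filters=(32, 24, 16), lstm_hidden=16, mlp_widths=(24, 12),
                  embed_dim=16, lr=5e-3, batch_size=32, max_epochs=20,
                  patience=5, max_len=52, seed=seed)
        kw.update(overrides)
        return cls(**kw)


# -- channels ---------------------------------------------------------------

class CnnChannel(nn.Module):
    def __init__(self, in_dim: int, config: PeptideModelConfig, rng):
        super().__init__()
        f1, f2, f3 = config.cnn_filters
        k = config.cnn_kernel
        self.conv1 = nn.Conv1d(in_dim, f1, k, rng)
        self.conv2 = nn.Conv1d(f1, f2, k, rng)
        self.conv3 = nn.Conv1d(f2, f3, k, rng)
        self.shrink = 3 * (k - 1)

    def __call__(self, emb: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        """emb: (B, L, D); mask: (B, L) with pads marked 0.  Returns (B, f3)."""
        h = emb.transpose(0, 2, 1)                       # (B, D, L)
        h = self.conv3(self.conv2(self.conv1(h).relu()).relu()).relu()
        lengths = mask.sum(axis=1)
        if int(lengths.min()) <= self.shrink:
            raise ValueError(
                f"sequences must exceed {self.shrink} valid positions for the "
                "CNN channel; pad shorter peptides")
        valid = np.maximum(lengths - self.shrink, 1)     # valid conv outputs
        Lo = h.shape[2]
        pool_mask = (np.arange(Lo)[None, :] < valid[:, None]).astype(h.data.dtype)
        masked = h * nn.Tensor(pool_mask[:, None, :])
        return masked.sum(axis=2) * nn.Tensor((1.0 / valid)[:, None].astype(h.data.dtype))


class BiLstmChannel(nn.Module):
    def __init__(self, in_dim: int, config: PeptideModelConfig, rng):
        super().__init__()
        self.fwd = nn.LSTM(in_dim, config.lstm_hidden, rng)
        self.bwd = nn.LSTM(in_dim, config.lstm_hidden, rng)

    def __call__(self, emb: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        """Concat of forward last-valid-step and backward last-step states."""
        lengths = mask.sum(axis=1)
        hs_f = self.fwd(emb)
        h_fwd = nn.gather_timesteps(hs_f, lengths - 1)
        # Reverse each sequence within its valid span (pads stay at the end).
        B, L = mask.shape
        rev_idx = np.arange(L)[None, :].repeat(B, axis=0)
        for b in range(B):
            lb = int(lengths[b])
            rev_idx[b, :lb] = np.arange(lb - 1, -1, -1)
        emb_rev = emb[(np.arange(B)[:, None], rev_idx)]
        hs_b = self.bwd(emb_rev)
        h_bwd = nn.gather_timesteps(hs_b, lengths - 1)
        return nn.concat([h_fwd, h_bwd], axis=1)


class PeptideNet(nn.Module):
    def __init__(self, config: PeptideModelConfig, provider, vocab: TokenVocabulary):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.provider = provider
        self.vocab = vocab
        D = provider.dim
        self.cnn = CnnChannel(D, config, rng)
        self.lstm = BiLstmChannel(D, config, rng)
        concat_dim = config.cnn_filters[2] + 2 * config.lstm_hidden
        self.bn = nn.BatchNorm1d(concat_dim)
        w1, w2 = config.mlp_widths
        self.mlp1 = nn.Linear(concat_dim, w1, rng)
        self.mlp2 = nn.Linear(w1, w2, rng)
        self.mlp3 = nn.Linear(w2, 1, rng)

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> nn.Tensor:
        emb = self.provider(ids)
        feats = nn.concat([self.cnn(emb, mask), self.lstm(emb, mask)], axis=1)
        h = self.bn(feats)
        h = self.mlp2(self.mlp1(h).relu()).relu()
        return self.mlp3(h).sigmoid().reshape(ids.shape[0])


def classify(cnn_vec: nn.Tensor, lstm_vec: nn.Tensor, net: PeptideNet) -> nn.Tensor:
    """Head only: concat -> batchnorm -> 3-layer MLP -> sigmoid."""
    expected = net.config.cnn_filters[2] + 2 * net.config.lstm_hidden
    feats = nn.concat([cnn_vec, lstm_vec], axis=1)
    if feats.shape[1] != expected:
        raise ValueError(f"head expects width {expected}, got {feats.shape[1]}")
    h = net.bn(feats)
    h = net.mlp2(net.mlp1(h).relu()).relu()
    return net.mlp3(h).sigmoid().reshape(feats.shape[0])


@dataclasses.dataclass(frozen=True)
class PeptideScore:
    peptide_id: str
    probability: float
    label: str
    task: str


@dataclasses.dataclass
class TrainedPeptideModel:
    config: PeptideModelConfig
    net: PeptideNet
    task: str
    training_history: list
    threshold: float = 0.5

    def save(self, path):
        cfg = dataclasses.asdict(self.config)
        cfg["task"] = self.task
        cfg["threshold"] = self.threshold
        cfg["provider_mode"] = self.net.provider.mode
        nn.save_checkpoint(path, self.net.state_dict(), cfg, kind="peptide")

    @classmethod
    def load(cls, path, provider=None) -> "TrainedPeptideModel":
        state, cfg, _ = nn.load_checkpoint(path, expect_kind="peptide")
        task = cfg.pop("task")
        threshold = cfg.pop("threshold", 0.5)
        mode = cfg.pop("provider_mode")
        cfg["cnn_filters"] = tuple(cfg["cnn_filters"])
        cfg["mlp_widths"] = tuple(cfg["mlp_widths"])
        config = PeptideModelConfig(**cfg)
        vocab = TokenVocabulary()
        if provider is None:
            if mode != "trainable_lookup":
                raise ValueError("external-provider checkpoints need the provider passed in")
            provider = TrainableLookupProvider(vocab, dim=config.embed_dim,
                                               seed=config.seed)
        net = PeptideNet(config, provider, vocab)
        net.load_state_dict(state)
        return cls(config=config, net=net, task=task, training_history=[],
                   threshold=threshold)


def _batchify(tokens, order, batch_size):
    for i in range(0, order.size, batch_size):
        idx = order[i:i + batch_size]
        ids = np.stack([tokens[j].ids for j in idx])
        mask = np.stack([tokens[j].attention_mask for j in idx])
        yield idx, ids, mask


def train_peptide_model(records, labels, task: str,
                        config: PeptideModelConfig | None = None,
                        provider=None) -> TrainedPeptideModel:
    """Train a task-specific classifier (BCE, Adafactor, early stopping).

    Performs a stratified 8:2 train/validation split (seed from the
    config, 702 by default), oversamples the minority class to parity each
    epoch, and stops early when validation loss fails to improve for
    ``patience`` epochs.  Accuracy, F1 and MCC on the validation split are
    recorded per epoch.
    """
    if task not in {"ACP", "AMP"}:
        raise ValueError("task must be 'ACP' or 'AMP'")
    config = config or PeptideModelConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")
    vocab = TokenVocabulary()
    if provider is None:
        provider = TrainableLookupProvider(vocab, dim=config.embed_dim, seed=config.seed)
    tokens = [tokenize(r, vocab, config.max_len) for r in records]
    net = PeptideNet(config, provider, vocab)
    opt = nn.Adafactor(net.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    tr_idx, va_idx = stratified_split(records, labels, ratio=0.8, seed=config.seed)
    best_val, best_state, stale = np.inf, None, 0
    history = []
    from .gene_model import _oversampled_order
    for epoch in range(config.max_epochs):
        net.train()
        order = tr_idx[_oversampled_order(labels[tr_idx], rng)]
        losses = []
        for _, ids, mask in _batchify(tokens, order, config.batch_size):
            yb = labels[order[len(losses) * config.batch_size:
                              len(losses) * config.batch_size + ids.shape[0]]]
            p = net(ids, mask)
            loss = nn.binary_cross_entropy(p, yb.astype(np.float32))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        net.eval()
        vp = _predict_tokens(net, tokens, va_idx, config.batch_size)
        vy = labels[va_idx]
        eps = 1e-7
        val_loss = float(-(vy * np.log(np.clip(vp, eps, 1)) +
                           (1 - vy) * np.log(np.clip(1 - vp, eps, 1))).mean())
        pred = (vp >= 0.5).astype(int)
        c = ConfusionCounts(tp=int(((pred == 1) & (vy == 1)).sum()),
                            tn=int(((pred == 0) & (vy == 0)).sum()),
                            fp=int(((pred == 1) & (vy == 0)).sum()),
                            fn=int(((pred == 0) & (vy == 1)).sum()))
        entry = {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                 "val_loss": val_loss, "val_accuracy": _acc(c)}
        entry["val_f1"] = f1_score(c) if c.tp + c.fp > 0 else 0.0
        entry["val_mcc"] = mcc(c)
        history.append(entry)
        if val_loss < best_val - 1e-6:
            best_val, best_state, stale = val_loss, net.state_dict(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return TrainedPeptideModel(config=config, net=net, task=task,
                               training_history=history)


def _predict_tokens(net: PeptideNet, tokens, idx, batch_size) -> np.ndarray:
    out = np.empty(len(idx), dtype=np.float64)
    pos = 0
    for _, ids, mask in _batchify(tokens, np.asarray(idx), max(batch_size, 64)):
        out[pos:pos + ids.shape[0]] = net(ids, mask).data
        pos += ids.shape[0]
    return out


def predict_peptides(model: TrainedPeptideModel, records, threshold: float = 0.5):
    """Score peptides with a trained task model; deterministic."""
    vocab = model.net.vocab
    tokens = [tokenize(r, vocab, model.config.max_len) for r in records]
    model.net.eval()
    probs = _predict_tokens(model.net, tokens, np.arange(len(tokens)),
                            model.config.batch_size)
    return [PeptideScore(peptide_id=r.id, probability=float(p),
                         label="positive" if p >= threshold else "negative",
                         task=model.task)
            for r, p in zip(records, probs)]


def write_scores_tsv(scores, path):
    with open(path, "w") as fh:
        fh.write("id\ttask\tprobability\tlabel\n")
        for s in scores:
            fh.write(f"{s.peptide_id}\t{s.task}\t{s.probability:.6f}\t{s.label}\n")
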