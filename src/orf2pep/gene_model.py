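"""Coding-region classifier: CNN front end, Transformer-encoder context
stage, sigmoid head, GC-bucketed model library, and greedy overlap
resolution.

Architecture (1-D input = the fused feature vector):

    conv(64, k3) -> maxpool(2) -> conv(200, k3) -> maxpool(2) -> dropout
    -> flatten -> fc(-> 4096) -> Transformer encoder (8 heads)
    -> flatten -> fc(4096 -> 128) -> dropout(0.2) -> fc(128 -> 1) -> sigmoid

The flatten width is derived from the configured fused-vector length at
build time, never hard-coded.  The 4096-wide intermediate is reshaped into
(tokens x width) before the encoder; token count and width are
configurable.  ``GeneModelConfig()`` carries the reference hyper-parameters
(Adam, lr 1e-3, batch 32); ``GeneModelConfig.desk()`` is a smaller profile
with the same topology for single-CPU work, and is what the bundled
examples, tests and acceptance runs use.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .metrics import ConfusionCounts
from .orf_scanner import overlap_bp
from .seqio import GeneCall


@dataclasses.dataclass
class GeneModelConfig:
    conv1_filters: int = 64
    conv1_kernel: int = 3
    pool1: int = 2
    conv2_filters: int = 200
    conv2_kernel: int = 3
    pool2: int = 2
    dropout_cnn: float = 0.2
    fc1_out: int = 4096
    attn_heads: int = 8
    encoder_layers: int = 1
    encoder_tokens: int = 32
    encoder_ff: int = 256
    fc2_out: int = 128
    dropout_head: float = 0.2
    lr: float = 0.001
    batch_size: int = 32
    max_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.fc1_out % self.encoder_tokens:
            raise ValueError("encoder_tokens must divide fc1_out")
        width = self.fc1_out // self.encoder_tokens
        if width % self.attn_heads:
            raise ValueError("attn_heads must divide the encoder model width")
        for f in ("conv1_filters", "conv2_filters", "fc1_out", "fc2_out",
                  "encoder_layers", "batch_size", "max_epochs"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("dropout_cnn", "dropout_head"):
            if not 0.0 <= getattr(self, f) < 1.0:
                raise ValueError(f"{f} must be in [0, 1)")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "GeneModelConfig":
        """Compact profile for single-CPU training on synthetic data."""
        kw = dict(conv1_filters=8, conv2_filters=16, fc1_out=128,
                  encoder_tokens=8, attn_heads=8, encoder_ff=64,
                  fc2_out=32, seed=seed)
        kw.update(overrides)
        return cls(**kw)


class GeneNet(nn.Module):
    def __init__(self, config: GeneModelConfig, input_len: int):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        c = config
        self.config = config
        self.input_len = input_len
        l1 = input_len - c.conv1_kernel + 1
        p1 = l1 // c.pool1
        l2 = p1 - c.conv2_kernel + 1
        p2 = l2 // c.pool2
        if p2 < 1:
            raise ValueError("fused vector too short for two conv/pool stages")
        self.flat_width = p2 * c.conv2_filters
        self.conv1 = nn.Conv1d(1, c.conv1_filters, c.conv1_kernel, rng)
        self.pool1 = nn.MaxPool1d(c.pool1)
        self.conv2 = nn.Conv1d(c.conv1_filters, c.conv2_filters, c.conv2_kernel, rng)
        self.pool2 = nn.MaxPool1d(c.pool2)
        self.drop_cnn = nn.Dropout(c.dropout_cnn, rng)
        self.fc1 = nn.Linear(self.flat_width, c.fc1_out, rng)
        width = c.fc1_out // c.encoder_tokens
        self.encoder = [nn.TransformerEncoderLayer(width, c.attn_heads, c.encoder_ff,
                                                   rng, dropout=0.0)
                        for _ in range(c.encoder_layers)]
        self.fc2 = nn.Linear(c.fc1_out, c.fc2_out, rng)
        self.drop_head = nn.Dropout(c.dropout_head, rng)
        self.fc3 = nn.Linear(c.fc2_out, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        c = self.config
        B = x.shape[0]
        h = x.reshape(B, 1, self.input_len)
        h = self.pool1(self.conv1(h).relu())
        h = self.pool2(self.conv2(h).relu())
        h = self.drop_cnn(h)
        h = self.fc1(h.reshape(B, self.flat_width)).relu()
        tokens = h.reshape(B, c.encoder_tokens, c.fc1_out // c.encoder_tokens)
        for layer in self.encoder:
            tokens = layer(tokens)
        h = self.fc2(tokens.reshape(B, c.fc1_out))
        h = self.drop_head(h)
        return self.fc3(h).sigmoid().reshape(B)


@dataclasses.dataclass
class TrainedGeneModel:
    config: GeneModelConfig
    net: GeneNet
    training_history: list
    threshold: float = 0.5

    def save(self, path):
        cfg = dataclasses.asdict(self.config)
        cfg["input_len"] = self.net.input_len
        cfg["threshold"] = self.threshold
        nn.save_checkpoint(path, self.net.state_dict(), cfg, kind="gene")

    @classmethod
    def load(cls, path) -> "TrainedGeneModel":
        state, cfg, _ = nn.load_checkpoint(path, expect_kind="gene")
        input_len = cfg.pop("input_len")
        threshold = cfg.pop("threshold", 0.5)
        config = GeneModelConfig(**cfg)
        net = GeneNet(config, input_len)
        net.load_state_dict(state)
        return cls(config=config, net=net, training_history=[], threshold=threshold)


def build_gene_model(config: GeneModelConfig, input_len: int) -> GeneNet:
    return GeneNet(config, input_len)


@dataclasses.dataclass(frozen=True)
class ScoredOrf:
    candidate: object
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def _oversampled_order(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Epoch ordering: majority class + minority resampled to parity, shuffled."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training data must contain both classes")
    minority, majority = (pos, neg) if pos.size < neg.size else (neg, pos)
    extra = rng.choice(minority, size=majority.size - minority.size, replace=True) \
        if majority.size > minority.size else np.empty(0, dtype=np.int64)
    order = np.concatenate([majority, minority, extra])
    rng.shuffle(order)
    return order


def train_gene_model(features: np.ndarray, labels: np.ndarray,
                     config: GeneModelConfig,
                     val_features: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None,
                     start_from: GeneNet | None = None) -> TrainedGeneModel:
    """Train the classifier with BCE + Adam and minority oversampling.

    ``start_from`` continues from an existing network (GC-bucket
    fine-tuning); otherwise weights are freshly initialized from
    ``config.seed``.  Per-epoch loss/accuracy are recorded; a fixed seed
    reproduces the history exactly.
    """
    features = np.asarray(features, dtype=np.float32)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")
    net = start_from if start_from is not None else GeneNet(config, features.shape[1])
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net.parameters(), lr=config.lr)
    history = []
    for epoch in range(config.max_epochs):
        net.train()
        order = _oversampled_order(labels, rng)
        losses, correct, seen = [], 0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = nn.Tensor(features[idx])
            yb = labels[idx].astype(np.float32)
            p = net(xb)
            loss = nn.binary_cross_entropy(p, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int(((p.data >= 0.5) == (yb >= 0.5)).sum())
            seen += idx.size
        entry = {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                 "accuracy": correct / seen}
        if val_features is not None:
            vp = predict_proba(net, val_features)
            entry["val_accuracy"] = float(((vp >= 0.5) == (val_labels >= 0.5)).mean())
        history.append(entry)
    return TrainedGeneModel(config=config, net=net, training_history=history)


def predict_proba(net: GeneNet, features: np.ndarray, batch_size: int = 256) -> np.ndarray:
    net.eval()
    features = np.asarray(features, dtype=np.float32)
    out = np.empty(features.shape[0], dtype=np.float64)
    for i in range(0, features.shape[0], batch_size):
        out[i:i + batch_size] = net(nn.Tensor(features[i:i + batch_size])).data
    return out


def predict_orfs(model: TrainedGeneModel, candidates, features: np.ndarray):
    """Score candidates; deterministic (dropout off at inference)."""
    probs = predict_proba(model.net, features)
    return [ScoredOrf(candidate=c, probability=float(p))
            for c, p in zip(candidates, probs)]


# -- GC-bucketed model library --------------------------------------------

@dataclasses.dataclass
class GcBucketLibrary:
    """Ten decile GC ranges over [0,1], each optionally holding parameters.

    Buckets are left-closed; the last is right-closed so 1.0 falls in
    bucket 9.
    """

    models: dict = dataclasses.field(default_factory=dict)
    n_buckets: int = 10

    def bucket_range(self, bucket_id: int) -> tuple:
        w = 1.0 / self.n_buckets
        return bucket_id * w, (bucket_id + 1) * w

    def set_model(self, bucket_id: int, model: TrainedGeneModel):
        self.models[bucket_id] = model

    def get_model(self, bucket_id: int):
        return self.models.get(bucket_id)


def select_bucket(genome_gc: float, library: GcBucketLibrary) -> int:
    if not 0.0 <= genome_gc <= 1.0:
        raise ValueError("GC content must be in [0, 1]")
    b = int(genome_gc * library.n_buckets)
    return min(b, library.n_buckets - 1)


# -- greedy overlap resolution ---------------------------------------------

def greedy_resolve(scored, overlap_threshold: int = 60, min_prob: float = 0.5):
    """Keep the highest-probability candidates, discarding overlaps > threshold.

    Candidates below ``min_prob`` are dropped first.  The survivors are
    visited by descending probability (ties: longer ORF, then smaller start
    coordinate); each accepted call discards any remaining candidate whose
    forward-strand overlap with it exceeds ``overlap_threshold`` bp,
    regardless of strand.  Output is sorted by start coordinate.
    """
    kept = [s for s in scored if s.probability >= min_prob]
    kept.sort(key=lambda s: (-s.probability,
                             -(s.candidate.end - s.candidate.start),
                             s.candidate.start, s.candidate.strand))
    accepted = []
    for s in kept:
        c = s.candidate
        clash = any(a.seq_id == c.seq_id and overlap_bp(a, c) > overlap_threshold
                    for a in accepted)
        if not clash:
            accepted.append(GeneCall(seq_id=c.seq_id, start=c.start, end=c.end,
                                     strand=c.strand, probability=s.probability,
                                     source_orf=c))
    accepted.sort(key=lambda g: (g.seq_id, g.start, g.end))
    return accepted


def evaluate_calls(calls, truth, all_candidates=None) -> ConfusionCounts:
    """Confusion counts by 3'-end matching: a call is a true positive when
    its stop coordinate and strand match an annotated gene.

    With ``all_candidates`` the negative side is counted over the full
    candidate universe (candidates not called and not matching truth are
    true negatives); otherwise tn is 0.
    """
    if not truth:
        raise ValueError("empty truth annotation")
    truth_keys = {(t.stop_coordinate, t.strand) for t in truth}
    call_keys = {(c.stop_coordinate, c.strand) for c in calls}
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    tn = 0
    if all_candidates is not None:
        cand_keys = {(c.stop_coordinate, c.strand) for c in all_candidates}
        tn = len(cand_keys - truth_keys - call_keys)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
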