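"""Binary embedding + convolutional text classifier and its evaluation harness.

The model is a classic text CNN: a trainable word-embedding matrix, parallel
1-D convolutions of widths 3/4/5 with ReLU, global max-pooling, and a dense
softmax head.  The positive-class softmax output in [0, 1] is the per-text
mention score.  Implemented directly on numpy (forward and backward) so that
training is single-threaded-deterministic under a fixed seed and carries no
framework dependency.

Evaluation follows the strict >0.5 decision rule and reports accuracy,
precision, recall, F1, and AUC; AUC is the rank-based (pairwise concordance,
ties half-credit) estimator, which equals the area under the ROC curve swept
over all thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from acenet.text_preprocess import (
    DEFAULT_MAX_LEN,
    CleanedDocument,
    Vocabulary,
    build_vocabulary,
    pad_or_truncate,
)

__all__ = [
    "LabeledCorpus",
    "SplitCorpus",
    "TrainConfig",
    "ScorerModel",
    "ConfusionCounts",
    "ClassifierMetrics",
    "balance_classes",
    "split_corpus",
    "train",
    "score",
    "classify",
    "confusion",
    "metrics",
    "roc_auc",
]

DEFAULT_THRESHOLD = 0.5


@dataclass
class LabeledCorpus:
    """Documents with binary labels (1 = positive/disclosure class)."""

    documents: list[CleanedDocument]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.labels):
            raise ValueError("one label per document required")
        if any(lab not in (0, 1) for lab in self.labels):
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.documents)

    def subset(self, idx: Sequence[int]) -> "LabeledCorpus":
        return LabeledCorpus(
            documents=[self.documents[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )

    def class_counts(self) -> tuple[int, int]:
        pos = sum(self.labels)
        return pos, len(self.labels) - pos


@dataclass
class SplitCorpus:
    train: LabeledCorpus
    validation: LabeledCorpus
    test: LabeledCorpus
    split_seed: int


def balance_classes(corpus: LabeledCorpus, seed: int) -> LabeledCorpus:
    """Downsample the majority class uniformly at random to the minority size.

    Every minority-class document is preserved; original document order is
    kept among the retained documents.
    """
    pos_idx = [i for i, lab in enumerate(corpus.labels) if lab == 1]
    neg_idx = [i for i, lab in enumerate(corpus.labels) if lab == 0]
    if not pos_idx or not neg_idx:
        raise ValueError("both classes must be non-empty to balance")
    rng = np.random.default_rng(seed)
    if len(pos_idx) > len(neg_idx):
        pos_idx = list(rng.choice(pos_idx, size=len(neg_idx), replace=False))
    elif len(neg_idx) > len(pos_idx):
        neg_idx = list(rng.choice(neg_idx, size=len(pos_idx), replace=False))
    keep = sorted(pos_idx + neg_idx)
    return corpus.subset(keep)


def split_corpus(
    corpus: LabeledCorpus,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    seed: int = 0,
) -> SplitCorpus:
    """Stratified random train/validation/test split, reproducible under seed."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pos, neg = corpus.class_counts()
    if min(pos, neg) < 5:
        raise ValueError("need at least 5 documents per class to split")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for lab in (1, 0):
        idx = np.array([i for i, l in enumerate(corpus.labels) if l == lab])
        rng.shuffle(idx)
        n = len(idx)
        n_train = round(fractions[0] * n)
        n_val = round(fractions[1] * n)
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return SplitCorpus(
        train=corpus.subset(sorted(parts[0])),
        validation=corpus.subset(sorted(parts[1])),
        test=corpus.subset(sorted(parts[2])),
        split_seed=seed,
    )


@dataclass
class TrainConfig:
    max_len: int = DEFAULT_MAX_LEN
    embedding_dim: int = 16
    filter_widths: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 8
    learning_rate: float = 5e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 3  # early stopping on validation loss
    l2: float = 1e-5
    seed: int = 0


@dataclass
class ScorerModel:
    """Trained CNN scorer.  ``score`` maps any document into [0, 1]."""

    vocab: Vocabulary
    config: TrainConfig
    embedding: np.ndarray  # (V, d); row 0 frozen at zero (padding)
    conv_w: dict[int, np.ndarray]  # width -> (width*d, F)
    conv_b: dict[int, np.ndarray]  # width -> (F,)
    dense_w: np.ndarray  # (len(widths)*F, 2)
    dense_b: np.ndarray  # (2,)
    training_seed: int = 0

    # -- forward ---------------------------------------------------------
    def _features(self, x: np.ndarray) -> np.ndarray:
        """x: (n, max_len) int indices -> pooled feature matrix (n, W*F)."""
        emb = self.embedding[x]  # (n, L, d)
        feats = []
        for w in self.config.filter_widths:
            windows = np.lib.stride_tricks.sliding_window_view(emb, w, axis=1)
            # (n, P, d, w) -> (n, P, w*d) matching conv_w layout (w, d) flattened
            windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2))
            n, p = windows.shape[:2]
            flat = windows.reshape(n, p, -1)
            z = flat @ self.conv_w[w] + self.conv_b[w]
            feats.append(np.maximum(z, 0.0).max(axis=1))
        return np.concatenate(feats, axis=1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Positive-class softmax probability for index matrix x."""
        logits = self._features(x) @ self.dense_w + self.dense_b
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        return ez[:, 1] / ez.sum(axis=1)

    def encode(self, docs: Sequence[CleanedDocument]) -> np.ndarray:
        return np.array(
            [pad_or_truncate(d, self.vocab, self.config.max_len) for d in docs],
            dtype=np.int64,
        )

    def score_documents(self, docs: Sequence[CleanedDocument]) -> np.ndarray:
        return self.predict_proba(self.encode(docs))

    # -- serialization ---------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {
            "embedding": self.embedding,
            "dense_w": self.dense_w,
            "dense_b": self.dense_b,
        }
        for w in self.config.filter_widths:
            arrays[f"conv_w_{w}"] = self.conv_w[w]
            arrays[f"conv_b_{w}"] = self.conv_b[w]
        meta = {
            "vocab": dict(self.vocab.index),
            "config": {
                "max_len": self.config.max_len,
                "embedding_dim": self.config.embedding_dim,
                "filter_widths": list(self.config.filter_widths),
                "n_filters": self.config.n_filters,
            },
            "training_seed": self.training_seed,
        }
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "ScorerModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = TrainConfig(
                max_len=meta["config"]["max_len"],
                embedding_dim=meta["config"]["embedding_dim"],
                filter_widths=tuple(meta["config"]["filter_widths"]),
                n_filters=meta["config"]["n_filters"],
            )
            return cls(
                vocab=Vocabulary(index=meta["vocab"]),
                config=cfg,
                embedding=data["embedding"],
                conv_w={w: data[f"conv_w_{w}"] for w in cfg.filter_widths},
                conv_b={w: data[f"conv_b_{w}"] for w in cfg.filter_widths},
                dense_w=data["dense_w"],
                dense_b=data["dense_b"],
                training_seed=meta["training_seed"],
            )


class _Adam:
    def __init__(self, shapes: dict[str, tuple[int, ...]], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_model(vocab: Vocabulary, config: TrainConfig) -> ScorerModel:
    rng = np.random.default_rng(config.seed)
    v = len(vocab)
    d, f = config.embedding_dim, config.n_filters
    emb = rng.normal(0.0, 0.1, size=(v, d))
    emb[0] = 0.0  # padding row stays zero
    conv_w = {
        w: rng.normal(0.0, np.sqrt(2.0 / (w * d)), size=(w * d, f))
        for w in config.filter_widths
    }
    conv_b = {w: np.zeros(f) for w in config.filter_widths}
    nfeat = len(config.filter_widths) * f
    dense_w = rng.normal(0.0, np.sqrt(1.0 / nfeat), size=(nfeat, 2))
    dense_b = np.zeros(2)
    return ScorerModel(
        vocab=vocab,
        config=config,
        embedding=emb,
        conv_w=conv_w,
        conv_b=conv_b,
        dense_w=dense_w,
        dense_b=dense_b,
        training_seed=config.seed,
    )


def _batch_loss_and_grads(model: ScorerModel, x: np.ndarray, y: np.ndarray):
    """Cross-entropy loss and gradients for one mini-batch (manual backprop)."""
    cfg = model.config
    n = x.shape[0]
    emb = model.embedding[x]  # (n, L, d)

    cache = {}
    feats = []
    for w in cfg.filter_widths:
        windows = np.lib.stride_tricks.sliding_window_view(emb, w, axis=1)
        windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2))
        flat = windows.reshape(n, windows.shape[1], -1)  # (n, P, w*d)
        z = flat @ model.conv_w[w] + model.conv_b[w]  # (n, P, F)
        a = np.maximum(z, 0.0)
        arg = a.argmax(axis=1)  # (n, F)
        feats.append(np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :])
        cache[w] = (flat, z, arg)
    h = np.concatenate(feats, axis=1)  # (n, W*F)

    logits = h @ model.dense_w + model.dense_b
    logits -= logits.max(axis=1, keepdims=True)
    ez = np.exp(logits)
    probs = ez / ez.sum(axis=1, keepdims=True)
    loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads: dict[str, np.ndarray] = {}
    grads["dense_w"] = h.T @ dlogits + cfg.l2 * model.dense_w
    grads["dense_b"] = dlogits.sum(axis=0)
    dh = dlogits @ model.dense_w.T

    demb = np.zeros_like(emb)
    col = 0
    f = cfg.n_filters
    for w in cfg.filter_widths:
        flat, z, arg = cache[w]
        dpool = dh[:, col : col + f]  # (n, F)
        col += f
        dz = np.zeros_like(z)
        np.put_along_axis(dz, arg[:, None, :], dpool[:, None, :], axis=1)
        dz *= z > 0
        grads[f"conv_w_{w}"] = (
            np.einsum("npk,npf->kf", flat, dz) + cfg.l2 * model.conv_w[w]
        )
        grads[f"conv_b_{w}"] = dz.sum(axis=(0, 1))
        dflat = dz @ model.conv_w[w].T  # (n, P, w*d)
        dwin = dflat.reshape(n, dflat.shape[1], w, cfg.embedding_dim)
        p = dwin.shape[1]
        for j in range(w):
            demb[:, j : j + p, :] += dwin[:, :, j, :]

    grads["embedding"] = np.zeros_like(model.embedding)
    np.add.at(grads["embedding"], x, demb)
    grads["embedding"][0] = 0.0  # padding stays frozen
    return loss, grads


def _mean_loss(model: ScorerModel, x: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(x)
    p_true = np.where(y == 1, p, 1.0 - p)
    return float(-np.log(p_true + 1e-12).mean())


def train(
    split: SplitCorpus,
    config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
) -> ScorerModel:
    """Train the CNN on the train partition with early stopping on validation loss.

    Deterministic for a fixed ``config.seed`` under single-threaded execution.
    The vocabulary is built from the training partition unless supplied.
    """
    if config is None:
        config = TrainConfig()
    if len(split.train) == 0:
        raise ValueError("empty training set")
    if vocab is None:
        vocab = build_vocabulary(split.train.documents)
    model = _init_model(vocab, config)

    x_train = model.encode(split.train.documents)
    y_train = np.asarray(split.train.labels, dtype=np.int64)
    x_val = model.encode(split.validation.documents)
    y_val = np.asarray(split.validation.labels, dtype=np.int64)

    params = {
        "embedding": model.embedding,
        "dense_w": model.dense_w,
        "dense_b": model.dense_b,
    }
    for w in config.filter_widths:
        params[f"conv_w_{w}"] = model.conv_w[w]
        params[f"conv_b_{w}"] = model.conv_b[w]
    opt = _Adam({k: p.shape for k, p in params.items()}, config.learning_rate)

    rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_state = None
    stale = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            _, grads = _batch_loss_and_grads(model, x_train[batch], y_train[batch])
            opt.step(params, grads)
        val_loss = _mean_loss(model, x_val, y_val) if len(x_val) else _mean_loss(
            model, x_train, y_train
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: p.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for k in params:
            params[k][...] = best_state[k]
    return model


def score(model: ScorerModel, doc: CleanedDocument) -> float:
    """Mention score of one document: positive-class probability in [0, 1]."""
    return float(model.score_documents([doc])[0])


def classify(score_value: float, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Strict decision rule: positive iff score > threshold."""
    return int(score_value > threshold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    model: ScorerModel,
    test: LabeledCorpus,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    if len(test) == 0:
        raise ValueError("empty test partition")
    scores = model.score_documents(test.documents)
    return confusion_from_scores(scores, test.labels, threshold)


def confusion_from_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = DEFAULT_THRESHOLD
) -> ConfusionCounts:
    tp = tn = fp = fn = 0
    for s, lab in zip(scores, labels, strict=True):
        pred = classify(s, threshold)
        if lab == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """Area under the ROC curve, rank-based with half-credit for ties.

    Equals the probability that a random positive outscores a random
    negative (ties count 1/2).  None when a class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ClassifierMetrics:
    """Five performance measures; a measure with a zero denominator is None."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None

    def to_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def metrics(
    cc: ConfusionCounts,
    scores: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> ClassifierMetrics:
    """Accuracy/precision/recall/F1 from counts; AUC from scores when given."""
    accuracy = (cc.tp + cc.tn) / cc.total if cc.total else None
    precision = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) else None
    recall = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    auc = roc_auc(scores, labels) if scores is not None and labels is not None else None
    return ClassifierMetrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, auc=auc
    )
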