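"""Sequence-to-repression classifier for histone tails.

A dual-branch 1D convolutional network maps a fixed-length tail sequence to
the probability that it represses a chromatin signal (e.g. total H3K9me3).
One branch convolves the one-hot encoding, the other a per-residue embedding;
each branch uses 128 hidden channels, kernel size 5, ReLU and global
(adaptive) max pooling, and the pooled vectors are concatenated into a fully
connected head with a single logistic output.  Training uses weighted binary
cross-entropy with class balancing (pos_weight = #neg/#pos) and Adam at
lr 1e-3 for 50 epochs.

The wild-type tail is anchored as non-repressive: it is added to the training
split with increased sample weight and repetition, and its predicted score is
tracked across epochs to confirm the anchoring takes hold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._nn import Adam, DualBranchConvNet, sigmoid, weighted_bce_grad
from .encode import TAIL_LENGTH, encode_batch, get_embedder
from .refs import H4_TAIL


@dataclass
class TrainConfig:
    """Hyperparameters of the tail repression classifier."""

    hidden_channels: int = 128
    kernel_size: int = 5
    head_hidden: int = 64
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    wt_anchor_weight: float = 10.0
    wt_repetitions: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_channels", "kernel_size", "head_hidden", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.wt_anchor_weight < 1 or self.wt_repetitions < 1:
            raise ValueError("wt anchoring requires weight >= 1 and repetitions >= 1")


@dataclass
class LabeledTailDataset:
    """Tail sequences with binary repressor labels, weights and splits.

    ``frame`` columns: sequence, label (1 = repressor), weight (> 0),
    split ("train"/"test").  ``wt_sequence`` names the anchored wild type.
    """

    frame: pd.DataFrame
    wt_sequence: str = H4_TAIL
    length: int = TAIL_LENGTH

    def __post_init__(self) -> None:
        required = {"sequence", "label", "weight", "split"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (self.frame["weight"] <= 0).any():
            raise ValueError("weights must be positive")
        bad = self.frame["sequence"].str.len() != self.length
        if bad.any():
            raise ValueError(f"{int(bad.sum())} sequences not of length {self.length}")

    def split_frame(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split]

    @classmethod
    def from_labels(
        cls,
        seqs: list[str],
        labels: list[int] | np.ndarray,
        test_fraction: float = 0.2,
        split_seed: int = 0,
        wt_sequence: str = H4_TAIL,
        length: int = TAIL_LENGTH,
    ) -> "LabeledTailDataset":
        """Build a dataset with a seeded, label-stratified 80:20 split."""
        frame = pd.DataFrame({"sequence": seqs, "label": np.asarray(labels, dtype=int)})
        frame["weight"] = 1.0
        try:
            idx_train, idx_test = train_test_split(
                frame.index,
                test_size=test_fraction,
                random_state=split_seed,
                stratify=frame["label"],
            )
        except ValueError:  # too few items per class to stratify
            idx_train, idx_test = train_test_split(
                frame.index, test_size=test_fraction, random_state=split_seed
            )
        frame["split"] = "train"
        frame.loc[idx_test, "split"] = "test"
        return cls(frame=frame, wt_sequence=wt_sequence, length=length)

    def with_wt_anchor(self, weight: float = 10.0, repetitions: int = 20) -> "LabeledTailDataset":
        """Append the wild-type anchor rows (label 0) to the training split."""
        anchor = pd.DataFrame(
            {
                "sequence": [self.wt_sequence] * repetitions,
                "label": 0,
                "weight": weight,
                "split": "train",
            }
        )
        frame = pd.concat([self.frame, anchor], ignore_index=True)
        return LabeledTailDataset(frame=frame, wt_sequence=self.wt_sequence, length=self.length)


def labels_from_screen(
    result: pd.DataFrame,
    seq_map: dict[str, str],
    alpha: float = 0.05,
    wt_sequence: str = H4_TAIL,
    test_fraction: float = 0.2,
    split_seed: int = 0,
    length: int = TAIL_LENGTH,
) -> LabeledTailDataset:
    """Binary labels from a screen result: repressor iff significant and
    depleted from the high-signal bin (padj < alpha and log2fc < 0).

    Controls are excluded.  If the wild-type tail itself is called a
    repressor by the screen it is still labeled 0 (the anchor overrides),
    with a warning.  The wild-type anchor rows themselves are added by
    :meth:`LabeledTailDataset.with_wt_anchor` (typically at train time).
    """
    usable = result[~result.get("is_control", pd.Series(False, index=result.index)).astype(bool)]
    seqs, labels = [], []
    for cid, row in usable.iterrows():
        if cid not in seq_map:
            raise KeyError(f"construct {cid!r} has no tail sequence mapping")
        label = int((row["padj"] < alpha) and (row["log2fc"] < 0))
        seq = seq_map[cid]
        if seq == wt_sequence and label == 1:
            warnings.warn("wild-type tail called a repressor by the screen; anchored to 0")
            label = 0
        seqs.append(seq)
        labels.append(label)
    if len(set(labels)) < 2:
        warnings.warn("screen labels are single-class; training will fail")
    return LabeledTailDataset.from_labels(
        seqs, labels, test_fraction=test_fraction, split_seed=split_seed,
        wt_sequence=wt_sequence, length=length,
    )


@dataclass
class RepressionModel:
    """Trained dual-branch classifier with scalar probability output."""

    net: DualBranchConvNet
    embedder_id: str
    config: TrainConfig
    length: int = TAIL_LENGTH
    wt_sequence: str = H4_TAIL
    wt_trace: list[float] = field(default_factory=list)

    def predict(self, seqs: list[str]) -> np.ndarray:
        """Repression probability per sequence, in input order."""
        if not seqs:
            return np.empty(0)
        embedder = get_embedder(self.embedder_id)
        X1, X2 = encode_batch(list(seqs), embedder, self.length)
        return sigmoid(self.net.predict_logits(X1, X2))

    def save(self, path: str) -> None:
        meta = {
            "embedder_id": self.embedder_id,
            "config": asdict(self.config),
            "length": self.length,
            "wt_sequence": self.wt_sequence,
            "wt_trace": self.wt_trace,
            "d_onehot": self.net.d_onehot,
            "d_embed": self.net.d_embed,
        }
        with open(path, "wb") as fh:  # file handle: keep the exact path
            np.savez(fh, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **self.net.state_dict())

    @classmethod
    def load(cls, path: str) -> "RepressionModel":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        config = TrainConfig(**meta["config"])
        net = DualBranchConvNet(
            d_onehot=meta["d_onehot"],
            d_embed=meta["d_embed"],
            hidden_channels=config.hidden_channels,
            kernel_size=config.kernel_size,
            head_hidden=config.head_hidden,
            seed=config.seed,
        )
        net.load_state_dict({k: data[k] for k in data.files if k != "_meta"})
        return cls(
            net=net,
            embedder_id=meta["embedder_id"],
            config=config,
            length=meta["length"],
            wt_sequence=meta["wt_sequence"],
            wt_trace=list(meta["wt_trace"]),
        )


def train(
    dataset: LabeledTailDataset,
    config: TrainConfig | None = None,
    embedder_id: str = "fallback",
    anchor_wt: bool = True,
) -> RepressionModel:
    """Train the dual-branch classifier; fully reproducible from the seed.

    When ``anchor_wt`` is true the wild-type anchor rows are appended to the
    training split with ``config.wt_anchor_weight`` and
    ``config.wt_repetitions``; the wild-type score is recorded each epoch.
    """
    config = config or TrainConfig()
    if anchor_wt:
        dataset = dataset.with_wt_anchor(config.wt_anchor_weight, config.wt_repetitions)
    tr = dataset.split_frame("train")
    n_pos = int((tr["label"] == 1).sum())
    n_neg = int((tr["label"] == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training split must contain both classes")
    pos_weight = n_neg / n_pos

    embedder = get_embedder(embedder_id)
    X1, X2 = encode_batch(tr["sequence"].tolist(), embedder, dataset.length)
    y = tr["label"].to_numpy(dtype=np.float64)
    w = tr["weight"].to_numpy(dtype=np.float64)

    net = DualBranchConvNet(
        d_onehot=X1.shape[2],
        d_embed=X2.shape[2],
        hidden_channels=config.hidden_channels,
        kernel_size=config.kernel_size,
        head_hidden=config.head_hidden,
        seed=config.seed,
    )
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    model = RepressionModel(
        net=net, embedder_id=embedder_id, config=config,
        length=dataset.length, wt_sequence=dataset.wt_sequence,
    )
    n = len(y)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits, cache = net.forward(X1[idx], X2[idx])
            _loss, dlogits = weighted_bce_grad(logits, y[idx], w[idx], pos_weight)
            grads = net.backward(cache, dlogits)
            opt.step(grads)
        model.wt_trace.append(float(model.predict([dataset.wt_sequence])[0]))
    return model


@dataclass
class EvalReport:
    """Held-out performance: AUC, precision@N and enrichment over random."""

    auc: float
    precision_at_n: float
    n: int
    prevalence: float
    enrichment: float
    n_test: int
    wt_trace: list[float] = field(default_factory=list)


def precision_at_n(scores: np.ndarray, labels: np.ndarray, n: int) -> float:
    """Fraction of positives among the n top-scored items (stable order)."""
    order = np.argsort(-scores, kind="stable")[:n]
    return float(np.asarray(labels)[order].mean())


def evaluate(model: RepressionModel, dataset: LabeledTailDataset, n: int = 100) -> EvalReport:
    """Score the held-out test split: AUC, precision@n, enrichment.

    Enrichment divides precision@n by the test-set positive prevalence, i.e.
    the fold improvement over random guessing at the same list size.
    """
    te = dataset.split_frame("test")
    labels = te["label"].to_numpy(dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("test split must contain both classes")
    if n > len(te):
        warnings.warn(f"n={n} exceeds test size {len(te)}; clipping")
        n = len(te)
    scores = model.predict(te["sequence"].tolist())
    auc = float(roc_auc_score(labels, scores))
    prec = precision_at_n(scores, labels, n)
    prevalence = float(labels.mean())
    return EvalReport(
        auc=auc,
        precision_at_n=prec,
        n=n,
        prevalence=prevalence,
        enrichment=prec / prevalence,
        n_test=len(te),
        wt_trace=list(getattr(model, "wt_trace", [])),
    )


def delta_wt(model: RepressionModel, seq: str, wt_seq: str | None = None) -> float:
    """Predicted score of ``seq`` minus the wild-type score."""
    wt = wt_seq if wt_seq is not None else model.wt_sequence
    scores = model.predict([seq, wt])
    return float(scores[0] - scores[1])


def score_sequence_set(
    model: RepressionModel, seqs: dict[str, str], wt_seq: str | None = None
) -> pd.DataFrame:
    """Score a set of tails (id -> sequence); skip off-length entries.

    Returns a table (id, sequence, score, delta_wt) sorted by score, with
    distribution quantiles relative to the wild type in ``attrs``.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    wt = wt_seq if wt_seq is not None else model.wt_sequence
    usable = {k: s for k, s in seqs.items() if len(s) == model.length}
    skipped = len(seqs) - len(usable)
    if skipped:
        warnings.warn(f"skipped {skipped} sequences not of length {model.length}")
    ids = list(usable)
    scores = model.predict([usable[i] for i in ids])
    wt_score = float(model.predict([wt])[0])
    df = pd.DataFrame(
        {"sequence": [usable[i] for i in ids], "score": scores, "delta_wt": scores - wt_score},
        index=ids,
    ).sort_values("score", ascending=False)
    df.attrs["wt_score"] = wt_score
    df.attrs["quantiles"] = {
        q: float(np.quantile(scores, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
    }
    return df
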