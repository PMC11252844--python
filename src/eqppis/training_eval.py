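"""Cross-entropy training loop and residue-level evaluation.

Training is plain Adam on the unweighted cross-entropy of the two-class
softmax head, one protein graph per optimisation step, with a
reduce-on-plateau learning-rate schedule and a small seeded validation
split used to retain the best checkpoint.

Evaluation pools residues from all chains into a single confusion table
(macro per-chain averaging available via a flag) and reports accuracy,
precision, recall, F1, Matthews correlation, AUROC and AUPRC; the two
threshold-free areas are computed from the positive-class scores with
scikit-learn. Per-chain confusion counts can be emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import Tensor
from .graph_construction import ProteinGraph
from .model import (
    ModelConfig,
    ModelParameters,
    forward,
    forward_tensor,
    init_parameters,
    log_softmax,
)

CE_EPS = 1e-12


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 50
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float | None
    auprc: float | None
    threshold: float = 0.5
    per_chain: list[tuple[str, int, int, int, int]] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["per_chain"] is not None:
            d["per_chain"] = [list(t) for t in d["per_chain"]]
        return d


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def ce_loss(probabilities: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean cross-entropy  -1/n * sum_i sum_c y_ic log p_ic  with the log
    clipped at log(1e-12) for numerical safety."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.ndim != 2 or p.shape[0] < 1:
        raise ValueError("inputs must be (n, m) with n >= 1")
    logp = np.log(np.clip(p, CE_EPS, None))
    return float(-(y * logp).sum(axis=1).mean() + 0.0)  # +0.0 normalises -0.0


def _ce_loss_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy from pre-softmax logits."""
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    logp = log_softmax(logits)
    return -(logp * Tensor(onehot)).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# optimiser and scheduler
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, tensors: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.tensors = list(tensors)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.tensors]
        self.v = [np.zeros_like(p.data) for p in self.tensors]

    def zero_grad(self) -> None:
        for p in self.tensors:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.tensors):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = math.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-10:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    dataset: Sequence[ProteinGraph],
    model_config: ModelConfig,
    train_config: TrainConfig,
    params: ModelParameters | None = None,
) -> tuple[ModelParameters, list[dict]]:
    """Train on labelled graphs (one graph per Adam step).

    Returns the best parameters (lowest validation loss, falling back to
    training loss when the validation split is empty) and the per-epoch
    history of mean losses and learning rate.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    for g in dataset:
        if g.labels is None:
            raise ValueError("every training graph must carry labels")

    rng = np.random.default_rng(train_config.seed)
    n_val = int(round(train_config.val_fraction * len(dataset)))
    perm = rng.permutation(len(dataset))
    val_ids = set(perm[:n_val].tolist())
    train_graphs = [g for i, g in enumerate(dataset) if i not in val_ids]
    val_graphs = [g for i, g in enumerate(dataset) if i in val_ids]
    if not train_graphs:  # degenerate split on tiny datasets
        train_graphs, val_graphs = list(dataset), []

    if params is None:
        params = init_parameters(model_config, seed=model_config.seed)
    opt = Adam(params.tensors(), lr=train_config.learning_rate)
    sched = ReduceLROnPlateau(
        opt,
        factor=train_config.scheduler_factor,
        patience=train_config.scheduler_patience,
        min_lr=train_config.min_lr,
    )

    best_loss = math.inf
    best_state = [t.data.copy() for t in params.tensors()]
    history: list[dict] = []

    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train_graphs))
        losses = []
        for gi in order:
            g = train_graphs[gi]
            opt.zero_grad()
            loss = _ce_loss_from_logits(
                forward_tensor(g, model_config, params), g.labels
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))

        if val_graphs:
            val_losses = [
                float(
                    _ce_loss_from_logits(
                        forward_tensor(g, model_config, params), g.labels
                    ).data
                )
                for g in val_graphs
            ]
            monitored = float(np.mean(val_losses))
        else:
            monitored = train_loss

        sched.step(train_loss)
        if monitored < best_loss:
            best_loss = monitored
            best_state = [t.data.copy() for t in params.tensors()]
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": monitored if val_graphs else None,
                "lr": opt.lr,
            }
        )

    for t, saved in zip(params.tensors(), best_state):
        t.data = saved
    return params, history


def predict_scores(
    graphs: Sequence[ProteinGraph], config: ModelConfig, params: ModelParameters
) -> list[np.ndarray]:
    """Positive-class probability per residue for each chain."""
    return [forward(g, config, params).scores for g in graphs]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from a confusion table
    (conventions: undefined ratios are reported as 0)."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return {
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def evaluate(
    scores: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence[np.ndarray] | np.ndarray,
    threshold: float = 0.5,
    chain_ids: Sequence[str] | None = None,
    macro: bool = False,
) -> EvalReport:
    """Residue-level evaluation of positive-class scores against binary labels.

    `scores`/`labels` may be single arrays or per-chain lists; residues are
    pooled across chains before the confusion table and the threshold-free
    areas are computed (set ``macro=True`` to average the five thresholded
    metrics per chain instead). AUROC/AUPRC are ``None`` when the pooled
    labels contain a single class.
    """
    if isinstance(scores, np.ndarray) and scores.ndim == 1:
        scores = [scores]
        labels = [np.asarray(labels)]
    scores = [np.asarray(s, dtype=np.float64) for s in scores]
    labels = [np.asarray(l, dtype=np.int64) for l in labels]
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have the same number of chains")
    for s, l in zip(scores, labels):
        if s.shape != l.shape:
            raise ValueError(f"length mismatch in a chain: {s.shape} vs {l.shape}")

    per_chain = []
    for ci, (s, l) in enumerate(zip(scores, labels)):
        pred = (s >= threshold).astype(np.int64)
        tp = int(np.sum((pred == 1) & (l == 1)))
        tn = int(np.sum((pred == 0) & (l == 0)))
        fp = int(np.sum((pred == 1) & (l == 0)))
        fn = int(np.sum((pred == 0) & (l == 1)))
        cid = chain_ids[ci] if chain_ids is not None else str(ci)
        per_chain.append((cid, tp, tn, fp, fn))

    tp = sum(c[1] for c in per_chain)
    tn = sum(c[2] for c in per_chain)
    fp = sum(c[3] for c in per_chain)
    fn = sum(c[4] for c in per_chain)

    if macro:
        chain_metrics = [metrics_from_counts(*c[1:]) for c in per_chain]
        m = {
            k: float(np.mean([cm[k] for cm in chain_metrics]))
            for k in ("acc", "precision", "recall", "f1", "mcc")
        }
    else:
        m = metrics_from_counts(tp, tn, fp, fn)

    all_scores = np.concatenate(scores)
    all_labels = np.concatenate(labels)
    if len(np.unique(all_labels)) < 2:
        auroc = auprc = None
    else:
        auroc = float(roc_auc_score(all_labels, all_scores))
        auprc = float(average_precision_score(all_labels, all_scores))

    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=m["acc"], precision=m["precision"], recall=m["recall"],
        f1=m["f1"], mcc=m["mcc"],
        auroc=auroc, auprc=auprc,
        threshold=threshold,
        per_chain=per_chain,
    )
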