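"""Multi-task training: shared encoder, two binary heads, Adam, early stopping.

Each optimisation step draws one batch per task.  The validator loss and the
link loss are mean binary cross-entropies; head parameters receive only their
own task's gradient while the shared embedding block receives the gradient of
the summed loss (this routing falls out of backpropagating loss_V + loss_L,
since each head lies on exactly one loss path).  Class imbalance is handled by
per-epoch undersampling of the majority class, independently per task, with a
fresh shuffle every epoch.  Early stopping monitors the summed validation loss
(class-balanced, the deterministic counterpart of balanced training) with a
fixed patience and restores the best parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, gather_rows
from .graphs import positional_encoding
from .model import MacroActivityNetwork
from .synthdata import LabeledSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "multitask_loss",
    "balanced_indices",
    "balance_batches",
    "train_network",
    "train",
    "set_global_seed",
]

_CLIP = 1e-7  # probability clipping for cross-entropy stability


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    patience: int = 10
    max_epochs: int = 500
    seed: int = 0
    balance: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("learning rate, batch size and patience must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss_v: list[float] = field(default_factory=list)
    train_loss_l: list[float] = field(default_factory=list)
    val_loss_v: list[float] = field(default_factory=list)
    val_loss_l: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    @property
    def val_loss(self) -> list[float]:
        return [v + l for v, l in zip(self.val_loss_v, self.val_loss_l)]


class Adam:
    """Standard Adam on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce(probs: Tensor, labels: np.ndarray, class_balanced: bool = False) -> Tensor:
    """Mean binary cross-entropy with probability clipping.

    ``class_balanced`` weights samples so both classes contribute equally
    (used for the early-stopping monitor, matching the balanced training
    objective on the naturally imbalanced validation split).
    """
    p = probs.clip(_CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, dtype=np.float64)
    per_sample = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    if not class_balanced:
        return per_sample.mean()
    n_pos, n_neg = max(y.sum(), 1.0), max((1.0 - y).sum(), 1.0)
    w = np.where(y == 1, 0.5 / n_pos, 0.5 / n_neg)
    return (per_sample * Tensor(w)).sum()


def multitask_loss(
    v_probs: Tensor | None,
    v_labels: np.ndarray | None,
    l_probs: Tensor | None,
    l_labels: np.ndarray | None,
    class_balanced: bool = False,
) -> tuple[Tensor, Tensor, Tensor]:
    """(loss_V, loss_L, loss_E) with loss_E = loss_V + loss_L.

    An absent task (empty batch) contributes a constant zero, so its head
    receives no gradient that step.
    """
    zero = Tensor(0.0)
    loss_v = (
        _bce(v_probs, v_labels, class_balanced)
        if v_probs is not None and v_probs.shape[0]
        else zero
    )
    loss_l = (
        _bce(l_probs, l_labels, class_balanced)
        if l_probs is not None and l_probs.shape[0]
        else zero
    )
    return loss_v, loss_l, loss_v + loss_l


def balanced_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffled index list with the majority class undersampled to the minority count.

    Raises if a class is entirely absent.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        missing = 1 if pos.size == 0 else 0
        raise ValueError(f"cannot balance: class {missing} has no samples")
    k = min(pos.size, neg.size)
    take = np.concatenate(
        [
            rng.choice(pos, size=k, replace=False),
            rng.choice(neg, size=k, replace=False),
        ]
    )
    rng.shuffle(take)
    return take


def balance_batches(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator, balance: bool = True
) -> list[np.ndarray]:
    """One epoch's batches of sample indices for a task, balanced and reshuffled."""
    if balance:
        idx = balanced_indices(labels, rng)
    else:
        idx = rng.permutation(len(labels))
    return [idx[i : i + batch_size] for i in range(0, len(idx), batch_size)]


def _prepare_vertices(samples: Sequence[LabeledSample], use_pe: bool) -> list[np.ndarray]:
    out = []
    for s in samples:
        V = s.embeddings
        if use_pe:
            V = V + positional_encoding(V.shape[0], V.shape[1])
        out.append(V)
    return out


class _SplitTensors:
    """Pre-indexed view of a sample list for fast epoch iteration."""

    def __init__(self, samples: Sequence[LabeledSample], use_pe: bool):
        self.samples = list(samples)
        self.vertices = _prepare_vertices(self.samples, use_pe)
        self.v_labels = np.array([s.validator_label for s in self.samples], dtype=np.int64)
        # flat link table: (graph index, link embedding, label)
        self.link_graph: list[int] = []
        link_emb, link_lab = [], []
        for gi, s in enumerate(self.samples):
            for l in s.links:
                self.link_graph.append(gi)
                link_emb.append(l.embedding)
                link_lab.append(l.label)
        self.link_graph_arr = np.asarray(self.link_graph, dtype=np.int64)
        self.link_emb = (
            np.stack(link_emb) if link_emb else np.empty((0, self.vertices[0].shape[1]))
        )
        self.l_labels = np.asarray(link_lab, dtype=np.int64)

    def forward(
        self,
        net: MacroActivityNetwork,
        v_idx: np.ndarray | None,
        l_idx: np.ndarray | None,
    ):
        """Joint forward for a validator batch and a link batch, sharing embeddings."""
        v_idx = np.asarray(v_idx, dtype=np.int64) if v_idx is not None else np.empty(0, np.int64)
        l_idx = np.asarray(l_idx, dtype=np.int64) if l_idx is not None else np.empty(0, np.int64)
        l_graphs = self.link_graph_arr[l_idx] if l_idx.size else np.empty(0, np.int64)
        needed = np.unique(np.concatenate([v_idx, l_graphs]))
        if needed.size == 0:
            return None, None, None, None
        lookup = {int(g): i for i, g in enumerate(needed)}
        emb = net.embed_sequences([self.vertices[int(g)] for g in needed])
        v_probs = v_labels = l_probs = l_labels = None
        if v_idx.size:
            rows = np.array([lookup[int(g)] for g in v_idx])
            v_probs = net.validate(gather_rows(emb, rows))
            v_labels = self.v_labels[v_idx]
        if l_idx.size:
            rows = np.array([lookup[int(g)] for g in l_graphs])
            l_probs = net.predict_link(gather_rows(emb, rows), self.link_emb[l_idx])
            l_labels = self.l_labels[l_idx]
        return v_probs, v_labels, l_probs, l_labels


def train_network(
    net: MacroActivityNetwork,
    train_samples: Sequence[LabeledSample],
    val_samples: Sequence[LabeledSample] | None,
    config: TrainConfig | None = None,
    *,
    use_positional_encoding: bool = True,
) -> tuple[MacroActivityNetwork, TrainHistory]:
    """Train E, V and L jointly; returns the best-validation network and the history."""
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    tr = _SplitTensors(train_samples, use_positional_encoding)
    va = _SplitTensors(val_samples, use_positional_encoding) if val_samples else None
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best = net.copy_params()
    best_loss = np.inf
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        v_batches = balance_batches(tr.v_labels, config.batch_size, rng, config.balance)
        l_batches = (
            balance_batches(tr.l_labels, config.batch_size, rng, config.balance)
            if tr.l_labels.size
            else []
        )
        ep_v, ep_l, n_steps = 0.0, 0.0, 0
        for vb, lb in zip_longest(v_batches, l_batches):
            opt.zero_grad()
            v_probs, v_lab, l_probs, l_lab = tr.forward(net, vb, lb)
            loss_v, loss_l, loss_e = multitask_loss(v_probs, v_lab, l_probs, l_lab)
            if not np.isfinite(loss_e.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; training aborted"
                )
            loss_e.backward()
            opt.step()
            ep_v += float(loss_v.data)
            ep_l += float(loss_l.data)
            n_steps += 1
        history.train_loss_v.append(ep_v / max(n_steps, 1))
        history.train_loss_l.append(ep_l / max(n_steps, 1))

        if va is not None and va.samples:
            v_probs, v_lab, l_probs, l_lab = va.forward(
                net, np.arange(len(va.samples)), np.arange(len(va.l_labels))
            )
            lv, ll, le = multitask_loss(
                v_probs, v_lab, l_probs, l_lab, class_balanced=config.balance
            )
            history.val_loss_v.append(float(lv.data))
            history.val_loss_l.append(float(ll.data))
            current = float(le.data)
            if current < best_loss:
                best_loss = current
                best = net.copy_params()
                history.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
            if since_best >= config.patience:
                history.stopped_epoch = epoch
                break
        else:  # no validation split: keep the last parameters
            best = net.copy_params()
            history.best_epoch = epoch
    if history.stopped_epoch == 0:
        history.stopped_epoch = len(history.train_loss_v)
    net.set_params_from(best)
    return net, history


def train(model, dataset, config: TrainConfig | None = None):
    """Convenience wrapper: train a MacroActivityNetwork on a LabeledDataset."""
    return train_network(model, dataset.train, dataset.val, config)


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed numpy's global state and return a fresh Generator for explicit use."""
    np.random.seed(seed)
    return np.random.default_rng(seed)
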