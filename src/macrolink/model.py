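"""The three-component network: graph embedding block E, graph validator V, link predictor L.

E is a single graph-attention layer with five heads and 2F output channels,
followed by Last Vertex Pooling.  On the star graph the in-neighbourhood of the
last vertex v_T is the whole vertex set (every v_t sends its one edge to v_T,
including the self-loop), so the layer reduces to attention of v_T over all T
vertices; the remaining vertices have no in-edges and simply keep their
projected self-features, which pooling then discards.

V and L are identical multilayer perceptrons: three hidden ReLU layers of width
2F and a sigmoid output.  V reads E(G_T) (width 2F); L reads the concatenation
of E(G_T) with the candidate next embedding m_{T+1} (width 3F).  Decisions use
a 0.5 threshold on the sigmoid output.

`MacroActivityGNN` wraps network construction, multi-task training and
prediction as a scikit-learn estimator.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor, concat, gather_rows, softmax
from .graphs import positional_encoding

__all__ = [
    "GraphAttentionEncoder",
    "MLPHead",
    "MacroActivityNetwork",
    "MacroActivityGNN",
    "last_vertex_pool",
    "embed_graph",
    "validate_graph",
    "predict_link",
]

_LEAKY_SLOPE = 0.2  # attention nonlinearity, standard GAT value


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class GraphAttentionEncoder:
    """Single GAT layer specialised to the star topology, fused with last-vertex pooling.

    ``2F`` output channels split over H heads (per-head width 2F/H, concatenated)
    when divisible; otherwise each head has width 2F and head outputs are averaged.
    """

    def __init__(self, F: int, n_heads: int = 5, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.F = F
        self.n_heads = n_heads
        out = 2 * F
        if out % n_heads == 0:
            self.head_dim = out // n_heads
            self.concat_heads = True
        else:
            self.head_dim = out
            self.concat_heads = False
        self.out_dim = out
        # one shared projection per head, stored stacked: (F, H*D)
        self.W = Tensor(_glorot(rng, (F, n_heads * self.head_dim)), requires_grad=True)
        self.a_src = Tensor(_glorot(rng, (n_heads, self.head_dim)), requires_grad=True)
        self.a_dst = Tensor(_glorot(rng, (n_heads, self.head_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.a_src, self.a_dst, self.bias]

    def attention(self, V: np.ndarray) -> np.ndarray:
        """Attention coefficients of v_T over v_1..v_T, shape (T, H); each head's column sums to 1."""
        return self._forward(Tensor(V[None, :, :]), return_alpha=True)[0]

    def _forward(self, V: Tensor, return_alpha: bool = False):
        """V: (B, T, F) batch of equal-length graphs -> (B, 2F) pooled embeddings."""
        B, T, F = V.shape
        H, D = self.n_heads, self.head_dim
        Wx = (V.reshape(B * T, F) @ self.W).reshape(B, T, H, D)
        s_src = (Wx * self.a_src.reshape(1, 1, H, D)).sum(axis=-1)  # (B, T, H)
        s_dst = (Wx * self.a_dst.reshape(1, 1, H, D)).sum(axis=-1)
        logits = (s_src + s_dst[:, T - 1 : T, :]).leaky_relu(_LEAKY_SLOPE)  # (B, T, H)
        alpha = softmax(logits, axis=1)
        if return_alpha:
            return alpha.data
        pooled = (alpha.reshape(B, T, H, 1) * Wx).sum(axis=1)  # (B, H, D)
        if self.concat_heads:
            out = pooled.reshape(B, H * D)
        else:
            out = pooled.mean(axis=1)
        return out + self.bias

    def __call__(self, V: Tensor) -> Tensor:
        return self._forward(V)

    def node_features(self, V: np.ndarray) -> np.ndarray:
        """Full per-vertex output (T, 2F): attention aggregate at v_T, projected
        self-features elsewhere (vertices without in-edges)."""
        V = np.asarray(V, dtype=np.float64)
        T = V.shape[0]
        H, D = self.n_heads, self.head_dim
        Wx = (V @ self.W.data).reshape(T, H, D)
        pooled = self(Tensor(V[None, :, :])).data[0]
        if self.concat_heads:
            feats = Wx.reshape(T, H * D) + self.bias.data
        else:
            feats = Wx.mean(axis=1) + self.bias.data
        feats[T - 1] = pooled
        return feats


class MLPHead:
    """h=3 hidden ReLU layers of width ``hidden``, sigmoid binary output."""

    def __init__(
        self,
        in_dim: int,
        hidden: int,
        n_hidden: int = 3,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        dims = [in_dim] + [hidden] * n_hidden + [1]
        self.weights = [
            Tensor(_glorot(rng, (a, b)), requires_grad=True) for a, b in zip(dims[:-1], dims[1:])
        ]
        self.biases = [Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]]

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, in_dim) -> probabilities (B,)."""
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input width {self.in_dim}, got {x.shape[-1]}")
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = (h @ W + b).relu()
        logits = h @ self.weights[-1] + self.biases[-1]
        return logits.reshape(-1).sigmoid()


class MacroActivityNetwork:
    """E + V + L with a shared embedding block; parameters are autodiff tensors."""

    def __init__(self, F: int, n_heads: int = 5, n_hidden: int = 3, seed: int = 0):
        self.F = F
        self.n_heads = n_heads
        self.n_hidden = n_hidden
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = GraphAttentionEncoder(F, n_heads, rng)
        self.validator = MLPHead(2 * F, 2 * F, n_hidden, rng)
        self.link = MLPHead(3 * F, 2 * F, n_hidden, rng)

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.validator.parameters() + self.link.parameters()

    # -- forward passes ------------------------------------------------------

    def embed_batch(self, V: np.ndarray) -> Tensor:
        """Equal-length graph batch (B, T, F) -> graph embeddings (B, 2F)."""
        if V.ndim != 3 or V.shape[-1] != self.F:
            raise ValueError(f"expected (B, T, {self.F}) vertex batch, got {V.shape}")
        return self.encoder(Tensor(V))

    def embed_sequences(self, seqs: Sequence[np.ndarray]) -> Tensor:
        """Arbitrary-length graph list -> (N, 2F), grouped internally by length."""
        order: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            order.setdefault(int(np.asarray(s).shape[0]), []).append(i)
        pieces, perm = [], []
        for T, idxs in sorted(order.items()):
            batch = np.stack([np.asarray(seqs[i], dtype=np.float64) for i in idxs])
            pieces.append(self.embed_batch(batch))
            perm.extend(idxs)
        emb = pieces[0] if len(pieces) == 1 else concat(pieces, axis=0)
        inv = np.argsort(perm)
        return gather_rows(emb, inv)

    def validate(self, emb: Tensor) -> Tensor:
        return self.validator(emb)

    def predict_link(self, emb: Tensor, next_emb: np.ndarray | Tensor) -> Tensor:
        nxt = next_emb if isinstance(next_emb, Tensor) else Tensor(np.asarray(next_emb))
        return self.link(concat([emb, nxt], axis=-1))

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict:
        params = self.parameters()
        return {
            "config": {
                "F": self.F,
                "n_heads": self.n_heads,
                "n_hidden": self.n_hidden,
                "seed": self.seed,
            },
            "params": [p.data.tolist() for p in params],
        }

    def load_state(self, params: list) -> None:
        own = self.parameters()
        if len(params) != len(own):
            raise ValueError("checkpoint parameter count mismatch")
        for p, arr in zip(own, params):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MacroActivityNetwork":
        blob = json.loads(Path(path).read_text())
        net = cls(**blob["config"])
        net.load_state(blob["params"])
        return net

    def copy_params(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_params_from(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()


# -- functional surface ------------------------------------------------------


def last_vertex_pool(node_features: np.ndarray) -> np.ndarray:
    """Return the last row of a (T, width) node-feature table."""
    x = np.asarray(node_features)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need a non-empty 2-D node-feature table")
    return x[-1]


def embed_graph(network: MacroActivityNetwork, graph) -> np.ndarray:
    """E(G_T) for a single graph whose vertices already include PE."""
    return network.embed_batch(graph.vertices[None, :, :]).data[0]


def validate_graph(network: MacroActivityNetwork, emb: np.ndarray) -> float:
    """Validator probability for one graph embedding (decision at 0.5)."""
    return float(network.validate(Tensor(np.asarray(emb)[None, :])).data[0])


def predict_link(network: MacroActivityNetwork, emb: np.ndarray, next_emb: np.ndarray) -> float:
    """Link-predictor probability for one (graph embedding, candidate) pair."""
    return float(
        network.predict_link(Tensor(np.asarray(emb)[None, :]), np.asarray(next_emb)[None, :]).data[
            0
        ]
    )


class MacroActivityGNN(BaseEstimator):
    """Multi-task graph network for macro-activity validation and link prediction.

    scikit-learn-style estimator over `LabeledSample` collections (see
    `macrolink.synthdata`).  ``fit`` trains the shared graph-attention encoder
    plus both binary heads with Adam, per-task class balancing and early
    stopping; prediction methods consume raw embedding sequences and apply the
    star-graph + positional-encoding transform internally.

    Parameters
    ----------
    n_heads : int, default 5
        Attention heads of the graph embedding block.
    n_hidden : int, default 3
        Hidden layers in each head MLP.
    positional_encoding : bool, default True
        Add the sinusoidal table to vertex features before encoding.
    learning_rate, batch_size, patience, max_epochs
        Adam/early-stopping configuration.
    balance : bool, default True
        Per-epoch undersampling of the majority class, per task.
    random_state : int, default 0
        Seed for parameter init and batch shuffling.

    Attributes
    ----------
    network_ : MacroActivityNetwork
        The trained parameters.
    history_ : TrainHistory
        Per-epoch losses, stopping epoch, best epoch.
    n_features_in_ : int
        Embedding dimension F seen during fit.
    """

    def __init__(
        self,
        n_heads: int = 5,
        n_hidden: int = 3,
        positional_encoding: bool = True,
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        patience: int = 10,
        max_epochs: int = 500,
        balance: bool = True,
        random_state: int = 0,
    ):
        self.n_heads = n_heads
        self.n_hidden = n_hidden
        self.positional_encoding = positional_encoding
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.balance = balance
        self.random_state = random_state

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None, validation=None):
        """Train on a list of LabeledSample (or a LabeledDataset, using its splits).

        ``y`` is ignored; labels live inside the samples.  ``validation``
        supplies the early-stopping split when ``X`` is a plain list.
        """
        from .synthdata import LabeledDataset
        from .training import TrainConfig, train_network

        if isinstance(X, LabeledDataset):
            train_samples, val_samples = X.train, X.val
        else:
            train_samples, val_samples = list(X), validation
        if not train_samples:
            raise ValueError("empty training set")
        F = int(train_samples[0].embeddings.shape[1])
        self.n_features_in_ = F
        net = MacroActivityNetwork(
            F, n_heads=self.n_heads, n_hidden=self.n_hidden, seed=self.random_state
        )
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.random_state,
            balance=self.balance,
        )
        self.network_, self.history_ = train_network(
            net,
            train_samples,
            val_samples,
            cfg,
            use_positional_encoding=self.positional_encoding,
        )
        return self

    # -- prediction ----------------------------------------------------------

    def _prepare(self, sequences: Sequence[np.ndarray]) -> list[np.ndarray]:
        out = []
        for s in sequences:
            V = np.atleast_2d(np.asarray(s, dtype=np.float64))
            if self.positional_encoding:
                V = V + positional_encoding(V.shape[0], V.shape[1])
            out.append(V)
        return out

    def embed(self, sequences: Sequence[np.ndarray]) -> np.ndarray:
        """Graph embeddings E(G_T), shape (N, 2F)."""
        check_is_fitted(self, "network_")
        return self.network_.embed_sequences(self._prepare(sequences)).data

    def predict_validity_proba(self, sequences: Sequence[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "network_")
        emb = self.network_.embed_sequences(self._prepare(sequences))
        return self.network_.validate(emb).data

    def predict_validity(self, sequences: Sequence[np.ndarray]) -> np.ndarray:
        """Binary validity decisions (threshold 0.5)."""
        return (self.predict_validity_proba(sequences) >= 0.5).astype(int)

    def predict_link_proba(
        self, sequences: Sequence[np.ndarray], next_embeddings: Sequence[np.ndarray]
    ) -> np.ndarray:
        check_is_fitted(self, "network_")
        if len(sequences) != len(next_embeddings):
            raise ValueError("sequences and next_embeddings must align")
        emb = self.network_.embed_sequences(self._prepare(sequences))
        nxt = np.asarray([np.asarray(v, dtype=np.float64) for v in next_embeddings])
        return self.network_.predict_link(emb, nxt).data

    def predict_link(
        self, sequences: Sequence[np.ndarray], next_embeddings: Sequence[np.ndarray]
    ) -> np.ndarray:
        """Binary link decisions (threshold 0.5)."""
        return (self.predict_link_proba(sequences, next_embeddings) >= 0.5).astype(int)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "network_")
        blob = self.network_.state_dict()
        blob["estimator"] = self.get_params()
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "MacroActivityGNN":
        blob = json.loads(Path(path).read_text())
        est = cls(**blob.get("estimator", {}))
        net = MacroActivityNetwork(**blob["config"])
        net.load_state(blob["params"])
        est.network_ = net
        est.n_features_in_ = net.F
        return est
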