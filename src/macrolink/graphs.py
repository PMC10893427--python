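"""Star-graph encoding of micro-activity sequences and sinusoidal positional encodings.

A sequence of T micro-activity embeddings becomes a directed star graph: every
vertex v_t carries the F-dimensional embedding of micro-activity m_t and has a
single outgoing edge to the last vertex v_T, which also carries a self-loop.
The adjacency matrix is therefore all zeros except for a last column of ones,
and the graph has exactly T edges.

The star topology erases temporal order (any permutation of v_1..v_{T-1} yields
the same message set into v_T), so vertex features are enriched with sinusoidal
positional encodings before the attention layer:

    PE(t, f) = cos(t / 10000^(2f/F))   if f is even,
               sin(t / 10000^(2f/F))   if f is odd,

with t the 1-based temporal vertex index and f the 0-based feature index.  Note
two deliberate departures from the classic transformer convention, kept exactly
as the architecture defines them: cos on even features (not sin), and the raw
feature index f in the exponent (not the pair index floor(f/2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MicroActivityGraph",
    "build_graph",
    "positional_encoding",
    "apply_positional_encoding",
    "star_adjacency",
    "edge_list",
    "export_graph",
    "StarGraphTransformer",
]


@dataclass
class MicroActivityGraph:
    """A star graph over a micro-activity sequence.

    vertices : (T, F) float array, row t-1 = embedding of the t-th micro-activity
    adjacency : (T, T) int array, ones exactly in the last column
    """

    vertices: np.ndarray
    adjacency: np.ndarray

    @property
    def T(self) -> int:
        return self.vertices.shape[0]

    @property
    def F(self) -> int:
        return self.vertices.shape[1]


def star_adjacency(T: int) -> np.ndarray:
    """The T x T star adjacency: last column all ones, zeros elsewhere."""
    if T < 1:
        raise ValueError(f"need T >= 1, got {T}")
    A = np.zeros((T, T), dtype=np.int64)
    A[:, -1] = 1
    return A


def build_graph(seq: np.ndarray) -> MicroActivityGraph:
    """Turn an ordered embedding sequence (T x F) into its star graph.

    Raises on an empty sequence or ragged rows.
    """
    V = np.asarray(seq, dtype=np.float64)
    if V.size == 0 or V.ndim == 0 or V.shape[0] == 0:
        raise ValueError("cannot build a graph from an empty sequence")
    if V.ndim == 1:  # a single embedding row is a T=1 sequence only if explicitly 2-D
        raise ValueError("expected a 2-D array of shape (T, F); reshape single rows to (1, F)")
    if V.ndim != 2:
        raise ValueError(f"expected a 2-D array of shape (T, F), got ndim={V.ndim}")
    return MicroActivityGraph(vertices=V, adjacency=star_adjacency(V.shape[0]))


def positional_encoding(T: int, F: int, *, one_based: bool = True) -> np.ndarray:
    """The (T, F) sinusoidal positional-encoding table.

    ``one_based`` selects the temporal index convention t in {1..T} (default);
    set False for a 0-based ablation.  All entries lie in [-1, 1].
    """
    if T < 1 or F < 1:
        raise ValueError(f"need T >= 1 and F >= 1, got T={T}, F={F}")
    t = np.arange(1, T + 1, dtype=np.float64) if one_based else np.arange(T, dtype=np.float64)
    f = np.arange(F, dtype=np.float64)
    angles = t[:, None] / np.power(10000.0, 2.0 * f / F)[None, :]
    pe = np.where(f[None, :] % 2 == 0, np.cos(angles), np.sin(angles))
    return pe


def apply_positional_encoding(
    graph: MicroActivityGraph, *, one_based: bool = True
) -> MicroActivityGraph:
    """Element-wise sum of vertex features and their positional encodings.

    Returns a new graph; the adjacency is unchanged.
    """
    pe = positional_encoding(graph.T, graph.F, one_based=one_based)
    return MicroActivityGraph(vertices=graph.vertices + pe, adjacency=graph.adjacency)


def edge_list(graph: MicroActivityGraph) -> list[tuple[int, int]]:
    """Directed edges as 1-based (source, target) pairs: {(t, T) : t = 1..T}."""
    src, dst = np.nonzero(graph.adjacency)
    return [(int(s) + 1, int(d) + 1) for s, d in zip(src, dst)]


def export_graph(graph: MicroActivityGraph, prefix: str | Path) -> None:
    """Debug export: ``<prefix>.edges`` (source target per line) and ``<prefix>.csv``."""
    prefix = Path(prefix)
    lines = [f"{s} {t}" for s, t in edge_list(graph)]
    prefix.with_suffix(".edges").write_text("\n".join(lines) + "\n")
    np.savetxt(prefix.with_suffix(".csv"), graph.vertices, delimiter=",")


class StarGraphTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: embedding sequences -> star graphs (optionally with PE).

    Parameters
    ----------
    add_positional_encoding : bool, default True
        Add the sinusoidal table to the vertex features.
    one_based : bool, default True
        Temporal index convention of the encoding.
    """

    def __init__(self, add_positional_encoding: bool = True, one_based: bool = True):
        self.add_positional_encoding = add_positional_encoding
        self.one_based = one_based

    def fit(self, X=None, y=None):
        self.n_features_in_ = None if not X else int(np.asarray(X[0]).shape[-1])
        return self

    def transform(self, X) -> list[MicroActivityGraph]:
        graphs = [build_graph(np.atleast_2d(np.asarray(x, dtype=np.float64))) for x in X]
        if self.add_positional_encoding:
            graphs = [apply_positional_encoding(g, one_based=self.one_based) for g in graphs]
        return graphs
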