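"""Streaming segmentation of micro-activity embeddings into macro-activities.

The state machine consumes one embedding at a time.  With the current sequence
M_T (always non-empty; the first stream item seeds it directly) and the next
embedding m_{T+1}, the validator decision v = V(E(G_T)) and the link decision
l = L(E(G_T), m_{T+1}) select exactly one of four cases:

    (a) not v and l      -> append m_{T+1}, keep going            (CONTINUE)
    (b) v and not l      -> emit E(G_T), restart with m_{T+1}     (EMIT)
    (c) v and l          -> emit E(G_T) AND append m_{T+1}        (EMIT, sequence grows)
    (d) not v and not l  -> archive E(G_T), restart with m_{T+1}  (INTERRUPT)

The four predicates partition {v, not v} x {l, not l}, so exactly one case
fires per step.  At stream end a final validator check on the residual
sequence produces a terminal EMIT or INTERRUPT.  Case (c) covers a valid
macro-activity that is also a prefix of a longer one: it emits and keeps
growing; deduplicating a later emission of the longer completion is the
consumer's concern.  Archived (interrupted) sequences are kept FIFO up to an
optional maximum; reloading them later is deliberately not implemented.

Decisions come from a ``DecisionHeads`` implementation: ``ModelHeads`` wraps a
trained estimator (0.5 threshold), ``mock_oracle_heads`` wraps a grammar so
the control flow can be tested exactly, independent of learned weights (the
stream must then carry class ids alongside the embeddings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from .grammar import Grammar

__all__ = [
    "StreamEvent",
    "StreamState",
    "DecisionHeads",
    "ModelHeads",
    "OracleHeads",
    "mock_oracle_heads",
    "stream_step",
    "run_stream",
]

EMIT = "EMIT"
CONTINUE = "CONTINUE"
INTERRUPT = "INTERRUPT"


@dataclass
class StreamEvent:
    kind: str  # EMIT | CONTINUE | INTERRUPT
    step: int
    embedding: np.ndarray | None = None  # E(G_T) payload for EMIT / INTERRUPT
    prefix: tuple[int, ...] | None = None  # class ids when known (oracle mode)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "step": self.step,
            "embedding": None if self.embedding is None else np.asarray(self.embedding).tolist(),
            "prefix": None if self.prefix is None else list(self.prefix),
        }


@dataclass
class ArchivedSequence:
    embedding: np.ndarray | None
    prefix: tuple[int, ...] | None
    step: int


@dataclass
class StreamState:
    """Current sequence plus the archive of interrupted-sequence embeddings."""

    embeddings: list[np.ndarray] = field(default_factory=list)
    class_ids: list[int] = field(default_factory=list)
    archive: list[ArchivedSequence] = field(default_factory=list)
    step: int = 0
    max_archive: int | None = None

    @property
    def T(self) -> int:
        return len(self.embeddings)

    def _archive_add(self, item: ArchivedSequence) -> None:
        self.archive.append(item)
        if self.max_archive is not None and len(self.archive) > self.max_archive:
            del self.archive[0]  # FIFO eviction


class DecisionHeads(Protocol):
    """Validator/link decisions plus the emitted graph embedding."""

    def validate(self, embeddings: Sequence[np.ndarray], class_ids: Sequence[int]) -> bool: ...

    def link(
        self,
        embeddings: Sequence[np.ndarray],
        class_ids: Sequence[int],
        next_embedding: np.ndarray,
        next_class: int | None,
    ) -> bool: ...

    def embed(self, embeddings: Sequence[np.ndarray]) -> np.ndarray | None: ...


class ModelHeads:
    """Decisions from a trained MacroActivityGNN at the 0.5 threshold."""

    def __init__(self, estimator):
        self.estimator = estimator

    def _seq(self, embeddings: Sequence[np.ndarray]) -> np.ndarray:
        return np.stack([np.asarray(e, dtype=np.float64) for e in embeddings])

    def validate(self, embeddings, class_ids) -> bool:
        return bool(self.estimator.predict_validity([self._seq(embeddings)])[0])

    def link(self, embeddings, class_ids, next_embedding, next_class=None) -> bool:
        return bool(
            self.estimator.predict_link([self._seq(embeddings)], [np.asarray(next_embedding)])[0]
        )

    def embed(self, embeddings) -> np.ndarray:
        return self.estimator.embed([self._seq(embeddings)])[0]


class OracleHeads:
    """Exact decisions from the grammar; requires class ids in the stream.

    The emitted payload is the stacked raw embedding sequence (there are no
    learned weights to produce E(G_T) from); pass a trained estimator via
    ``embedder`` to emit model embeddings instead.
    """

    def __init__(self, grammar: Grammar, embedder=None):
        self.grammar = grammar
        self.embedder = embedder

    def _require_ids(self, class_ids) -> None:
        if class_ids is None or any(c is None for c in class_ids):
            raise ValueError("oracle heads need class ids alongside the embeddings")

    def validate(self, embeddings, class_ids) -> bool:
        self._require_ids(class_ids)
        return self.grammar.is_valid_macro(list(class_ids))

    def link(self, embeddings, class_ids, next_embedding, next_class=None) -> bool:
        self._require_ids(class_ids)
        if next_class is None:
            raise ValueError("oracle heads need the class id of the next micro-activity")
        return self.grammar.is_possible_link(list(class_ids), next_class)

    def embed(self, embeddings):
        if self.embedder is not None:
            return self.embedder.embed([np.stack(embeddings)])[0]
        return np.stack([np.asarray(e) for e in embeddings])


def mock_oracle_heads(grammar: Grammar, embedder=None) -> OracleHeads:
    """Decision functions that answer from the grammar oracle (for testing the pipeline)."""
    return OracleHeads(grammar, embedder=embedder)


def _known_prefix(class_ids: Sequence[int | None]) -> tuple[int, ...] | None:
    if class_ids and all(c is not None for c in class_ids):
        return tuple(class_ids)
    return None


def stream_step(
    state: StreamState,
    heads: DecisionHeads,
    next_embedding: np.ndarray,
    next_class: int | None = None,
) -> tuple[StreamState, list[StreamEvent]]:
    """Advance the state machine by one micro-activity embedding (cases a-d above)."""
    if state.T < 1:
        raise ValueError("stream_step needs a non-empty current sequence; seed it first")
    next_embedding = np.asarray(next_embedding, dtype=np.float64)
    if next_embedding.shape != np.asarray(state.embeddings[0]).shape:
        raise ValueError(
            f"embedding width mismatch: {next_embedding.shape} vs "
            f"{np.asarray(state.embeddings[0]).shape}"
        )
    v = heads.validate(state.embeddings, state.class_ids)
    l = heads.link(state.embeddings, state.class_ids, next_embedding, next_class)
    prefix = _known_prefix(state.class_ids)
    events: list[StreamEvent] = []
    state.step += 1

    def append_next() -> None:
        state.embeddings.append(next_embedding)
        state.class_ids.append(next_class)

    def restart_with_next() -> None:
        state.embeddings = [next_embedding]
        state.class_ids = [next_class]

    if not v and l:  # (a) grow the sequence
        append_next()
        events.append(StreamEvent(CONTINUE, state.step, prefix=prefix))
    elif v and not l:  # (b) sequence complete, next starts something new
        events.append(StreamEvent(EMIT, state.step, heads.embed(state.embeddings), prefix))
        restart_with_next()
    elif v and l:  # (c) complete AND extendable: emit and keep growing
        events.append(StreamEvent(EMIT, state.step, heads.embed(state.embeddings), prefix))
        append_next()
    else:  # (d) unknown or interrupted: archive and restart
        emb = heads.embed(state.embeddings)
        state._archive_add(ArchivedSequence(emb, prefix, state.step))
        events.append(StreamEvent(INTERRUPT, state.step, emb, prefix))
        restart_with_next()
    return state, events


def run_stream(
    heads: DecisionHeads,
    stream: Iterable[tuple[np.ndarray, int | None] | np.ndarray],
    initial_state: StreamState | None = None,
) -> tuple[StreamState, list[StreamEvent]]:
    """Consume a finite stream; items are embeddings or (embedding, class id) pairs.

    The first item seeds the current sequence; a terminal validator check on
    the residual sequence yields a final EMIT or INTERRUPT.  An empty stream
    with no seeded state produces no events.
    """
    state = initial_state or StreamState()
    log: list[StreamEvent] = []
    for item in stream:
        emb, cid = item if isinstance(item, tuple) else (item, None)
        emb = np.asarray(emb, dtype=np.float64)
        if state.T == 0:
            state.embeddings = [emb]
            state.class_ids = [cid]
            state.step += 1
            continue
        state, events = stream_step(state, heads, emb, cid)
        log.extend(events)
    if state.T > 0:
        state.step += 1
        prefix = _known_prefix(state.class_ids)
        if heads.validate(state.embeddings, state.class_ids):
            log.append(StreamEvent(EMIT, state.step, heads.embed(state.embeddings), prefix))
        else:
            emb = heads.embed(state.embeddings)
            state._archive_add(ArchivedSequence(emb, prefix, state.step))
            log.append(StreamEvent(INTERRUPT, state.step, emb, prefix))
    return state, log
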