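"""Macro-activity grammars: the exact oracle for sequence validity and link possibility.

A grammar is the set of valid micro-activity sequences (macro-activities) over a
fixed alphabet of micro-activity classes, e.g. the strokes of a table-tennis
exercise or the preparation steps of a recipe.  Two queries matter downstream:

* *validity* -- is a sequence exactly one of the listed macro-activities?
* *possibility* -- can a class be appended to a prefix so that the result is
  still a prefix (proper or full) of at least one macro-activity?

Possibility uses prefix semantics across the whole grammar: different
macro-activities may share prefixes and a streaming consumer cannot know which
one is underway.  Queries are answered from a prefix trie; brute-force scans
over the sequence list give the same answers (property-tested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "MicroActivityClass",
    "MacroSequence",
    "Grammar",
    "is_valid_macro",
    "is_possible_link",
    "successors",
    "enumerate_prefixes",
    "load_grammar",
    "save_grammar",
]


@dataclass(frozen=True)
class MicroActivityClass:
    """One atomic activity class (a stroke type, a recipe step)."""

    id: int
    name: str

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"class id must be non-negative, got {self.id}")
        if not self.name:
            raise ValueError("class name must be non-empty")


@dataclass(frozen=True)
class MacroSequence:
    """An ordered, complete macro-activity given as class ids."""

    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise ValueError("a macro-activity sequence needs at least one micro-activity")
        object.__setattr__(self, "classes", tuple(int(c) for c in self.classes))

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)


class _TrieNode:
    __slots__ = ("children", "terminal")

    def __init__(self) -> None:
        self.children: dict[int, _TrieNode] = {}
        self.terminal = False


@dataclass
class Grammar:
    """Alphabet of micro-activity classes plus the valid macro-activity sequences.

    The prefix trie is built eagerly; all queries are O(prefix length).
    """

    classes: list[MicroActivityClass]
    sequences: list[MacroSequence]
    _root: _TrieNode = field(init=False, repr=False, compare=False)
    _name_to_id: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if sorted(ids) != list(range(len(ids))):
            raise ValueError("class ids must be unique and contiguous from 0")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if not self.sequences:
            raise ValueError("a grammar needs at least one macro-activity sequence")
        seen: set[tuple[int, ...]] = set()
        for seq in self.sequences:
            if seq.classes in seen:
                raise ValueError(f"duplicate macro-activity sequence {list(seq.classes)}")
            seen.add(seq.classes)
        self._name_to_id = {c.name: c.id for c in self.classes}
        self._root = _TrieNode()
        valid = {c.id for c in self.classes}
        for seq in self.sequences:
            node = self._root
            for cid in seq.classes:
                if cid not in valid:
                    raise ValueError(f"sequence {list(seq.classes)} uses unknown class id {cid}")
                node = node.children.setdefault(cid, _TrieNode())
            node.terminal = True

    # -- basic introspection -------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_id(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise KeyError(f"unknown micro-activity class name {name!r}") from None

    def class_name(self, cid: int) -> str:
        self._check_ids([cid])
        return self.classes[cid].name

    def _check_ids(self, ids: Iterable[int]) -> None:
        n = self.n_classes
        for cid in ids:
            if not (0 <= int(cid) < n):
                raise ValueError(f"unknown micro-activity class id {cid}")

    def _walk(self, prefix: Sequence[int]) -> _TrieNode | None:
        node = self._root
        for cid in prefix:
            node = node.children.get(int(cid))
            if node is None:
                return None
        return node

    # -- oracle queries ------------------------------------------------------

    def is_valid_macro(self, seq: Sequence[int]) -> bool:
        """True iff ``seq`` is exactly one of the grammar's macro-activities."""
        self._check_ids(seq)
        if len(seq) == 0:
            return False
        node = self._walk(seq)
        return node is not None and node.terminal

    def is_possible_link(self, prefix: Sequence[int], next_class: int) -> bool:
        """True iff ``prefix + [next_class]`` is a prefix of some macro-activity.

        Possible sequences include both partial subsequences and complete
        macro-activities; the empty prefix means "start of a new sequence".
        """
        self._check_ids(prefix)
        self._check_ids([next_class])
        node = self._walk(prefix)
        return node is not None and int(next_class) in node.children

    def successors(self, prefix: Sequence[int]) -> set[int]:
        """All classes c with ``is_possible_link(prefix, c)``; empty iff dead end."""
        self._check_ids(prefix)
        node = self._walk(prefix)
        if node is None:
            return set()
        return set(node.children)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": [c.name for c in self.classes],
            "sequences": [[self.classes[cid].name for cid in seq] for seq in self.sequences],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Grammar":
        try:
            names = list(data["classes"])
            raw_seqs = list(data["sequences"])
        except (KeyError, TypeError) as exc:
            raise ValueError("grammar file needs 'classes' and 'sequences' fields") from exc
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in grammar file")
        classes = [MicroActivityClass(i, str(n)) for i, n in enumerate(names)]
        name_to_id = {c.name: c.id for c in classes}
        sequences = []
        for raw in raw_seqs:
            try:
                sequences.append(MacroSequence(tuple(name_to_id[str(n)] for n in raw)))
            except KeyError as exc:
                raise ValueError(f"sequence {raw} uses unknown class name {exc.args[0]!r}") from None
        return cls(classes=classes, sequences=sequences)

    @classmethod
    def from_sequences(cls, names: Sequence[str], seqs: Sequence[Sequence[int]]) -> "Grammar":
        """Build directly from class names and id sequences (convenience for tests)."""
        classes = [MicroActivityClass(i, str(n)) for i, n in enumerate(names)]
        return cls(classes=classes, sequences=[MacroSequence(tuple(s)) for s in seqs])


def is_valid_macro(grammar: Grammar, seq: Sequence[int]) -> bool:
    return grammar.is_valid_macro(seq)


def is_possible_link(grammar: Grammar, prefix: Sequence[int], next_class: int) -> bool:
    return grammar.is_possible_link(prefix, next_class)


def successors(grammar: Grammar, prefix: Sequence[int]) -> set[int]:
    return grammar.successors(prefix)


def enumerate_prefixes(seq: MacroSequence | Sequence[int]) -> list[tuple[int, ...]]:
    """All prefixes of a macro-activity, shortest first: seq[:1], ..., seq[:T]."""
    classes = tuple(seq.classes if isinstance(seq, MacroSequence) else seq)
    if len(classes) < 1:
        raise ValueError("cannot enumerate prefixes of an empty sequence")
    return [classes[: t + 1] for t in range(len(classes))]


def load_grammar(path: str | Path) -> Grammar:
    """Read a grammar from JSON or YAML (chosen by extension, YAML parses both)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return Grammar.from_dict(data)


def save_grammar(grammar: Grammar, path: str | Path) -> None:
    path = Path(path)
    data = grammar.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
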