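"""Synthetic micro-activity embeddings with exact, oracle-checkable labels.

Real deployments obtain micro-activity embeddings from a classifier or a
dimensionality reduction (e.g. a seeded UMAP) over homogeneous sensor windows.
This module reproduces the statistical shape of that setting without sensor
data: each micro-activity class i gets a prototype mean vector mu_i, and
embeddings are drawn from the isotropic Gaussian N(mu_i, sigma) with a shared,
pre-defined standard deviation.  Class separability is summarised by

    s = (1/n^2) * sum_{i<j} 1 / ||mu_i - mu_j||

(the normalisation is 1/n^2, not 1/C(n,2)); smaller s means more distinctive
classes.

Dataset generation walks every grammar sequence: per repetition one embedding
is drawn per position and the T prefix slices share those identical vectors,
so a prefix and its extensions are consistent views of the same execution.
Repetitions are split 60/20/20 per sequence (largest-remainder rounding), and
labels come from the grammar oracle: the validator label marks exact
macro-activity matches, link samples pair each graph with possible successor
embeddings (label 1, one per successor class) and with impossible embeddings
drawn from the same split's pool of previously generated vectors (label 0),
the impossible count following

    n_imp = round(0.1 * n_total)  if n_pos = 0,
            mean(n_pos)           otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grammar import Grammar, MacroSequence, enumerate_prefixes

__all__ = [
    "PrototypeSet",
    "GeneratorConfig",
    "LinkSample",
    "LabeledSample",
    "LabeledDataset",
    "fit_class_prototypes",
    "random_prototypes",
    "embedding_similarity",
    "sample_embedding",
    "generate_subsequence_embeddings",
    "n_impossible",
    "split_repetitions",
    "generate_dataset",
    "dataset_summary",
]


@dataclass
class PrototypeSet:
    """Per-class Gaussian prototypes: means (n_classes, F), shared sigma."""

    means: np.ndarray
    sigma: float
    seed: int = 0
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.ndim != 2:
            raise ValueError("means must be a 2-D (n_classes, F) array")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.class_names is not None and len(self.class_names) != self.means.shape[0]:
            raise ValueError("one class name per mean required")

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def F(self) -> int:
        return self.means.shape[1]

    def save(self, path: str | Path) -> None:
        """CSV of means (one row per class, name first) + JSON sidecar for sigma/seed."""
        path = Path(path)
        names = self.class_names or [str(i) for i in range(self.n_classes)]
        df = pd.DataFrame(self.means, index=pd.Index(names, name="class"))
        df.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"sigma": self.sigma, "seed": self.seed}))

    @classmethod
    def load(cls, path: str | Path) -> "PrototypeSet":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"sigma": 0.0, "seed": 0}
        return cls(
            means=df.to_numpy(dtype=np.float64),
            sigma=float(meta["sigma"]),
            seed=int(meta["seed"]),
            class_names=[str(i) for i in df.index],
        )


@dataclass
class GeneratorConfig:
    """Study conditions of the generator: 30 repetitions per sequence, 60/20/20 split,
    impossible-link base rate 0.1."""

    repetitions: int = 30
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    impossible_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")


@dataclass
class LinkSample:
    """One candidate next micro-activity for a graph: embedding, binary label, source class."""

    embedding: np.ndarray
    label: int
    source_class: int


@dataclass
class LabeledSample:
    """A prefix graph with its validator label and link candidates."""

    embeddings: np.ndarray  # (T, F), row t = drawn embedding of prefix position t
    prefix: tuple[int, ...]  # class ids
    validator_label: int
    links: list[LinkSample] = field(default_factory=list)
    sequence_index: int = -1
    repetition: int = -1

    @property
    def T(self) -> int:
        return len(self.prefix)


@dataclass
class LabeledDataset:
    train: list[LabeledSample]
    val: list[LabeledSample]
    test: list[LabeledSample]
    grammar: Grammar | None = None
    prototypes: PrototypeSet | None = None
    config: GeneratorConfig | None = None

    def split(self, name: str) -> list[LabeledSample]:
        return {"train": self.train, "val": self.val, "test": self.test}[name]

    # -- text serialization (JSON lines per split) ---------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("train", "val", "test"):
            with open(directory / f"{name}.jsonl", "w") as fh:
                for s in self.split(name):
                    fh.write(
                        json.dumps(
                            {
                                "prefix": list(s.prefix),
                                "embeddings": s.embeddings.tolist(),
                                "validator_label": s.validator_label,
                                "sequence_index": s.sequence_index,
                                "repetition": s.repetition,
                                "links": [
                                    {
                                        "embedding": l.embedding.tolist(),
                                        "label": l.label,
                                        "source_class": l.source_class,
                                    }
                                    for l in s.links
                                ],
                            }
                        )
                        + "\n"
                    )
        if self.grammar is not None:
            (directory / "grammar.json").write_text(json.dumps(self.grammar.to_dict(), indent=2))
        if self.prototypes is not None:
            self.prototypes.save(directory / "prototypes.csv")
        if self.config is not None:
            (directory / "generator.json").write_text(
                json.dumps(
                    {
                        "repetitions": self.config.repetitions,
                        "fractions": list(self.config.fractions),
                        "impossible_rate": self.config.impossible_rate,
                        "seed": self.config.seed,
                    }
                )
            )

    @classmethod
    def load(cls, directory: str | Path) -> "LabeledDataset":
        directory = Path(directory)
        splits = {}
        for name in ("train", "val", "test"):
            samples = []
            path = directory / f"{name}.jsonl"
            if path.exists():
                for line in path.read_text().splitlines():
                    rec = json.loads(line)
                    samples.append(
                        LabeledSample(
                            embeddings=np.asarray(rec["embeddings"], dtype=np.float64),
                            prefix=tuple(rec["prefix"]),
                            validator_label=int(rec["validator_label"]),
                            links=[
                                LinkSample(
                                    embedding=np.asarray(l["embedding"], dtype=np.float64),
                                    label=int(l["label"]),
                                    source_class=int(l["source_class"]),
                                )
                                for l in rec["links"]
                            ],
                            sequence_index=int(rec.get("sequence_index", -1)),
                            repetition=int(rec.get("repetition", -1)),
                        )
                    )
            splits[name] = samples
        grammar = None
        gpath = directory / "grammar.json"
        if gpath.exists():
            grammar = Grammar.from_dict(json.loads(gpath.read_text()))
        protos = None
        ppath = directory / "prototypes.csv"
        if ppath.exists():
            protos = PrototypeSet.load(ppath)
        config = None
        cpath = directory / "generator.json"
        if cpath.exists():
            raw = json.loads(cpath.read_text())
            config = GeneratorConfig(
                repetitions=raw["repetitions"],
                fractions=tuple(raw["fractions"]),
                impossible_rate=raw["impossible_rate"],
                seed=raw["seed"],
            )
        return cls(grammar=grammar, prototypes=protos, config=config, **splits)


# -- prototypes --------------------------------------------------------------


def fit_class_prototypes(
    features: np.ndarray,
    labels: Sequence[int],
    projector,
    sigma: float,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> PrototypeSet:
    """Per-class mean of projected windows; sigma is caller-supplied, not estimated.

    ``projector`` is any transformer with ``fit_transform`` (a seeded UMAP in
    the real workflow, any deterministic reducer in tests).  Every class in
    0..max(labels) needs at least one window.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    projected = np.asarray(projector.fit_transform(features), dtype=np.float64)
    n_classes = int(labels.max()) + 1
    names = list(class_names) if class_names is not None else None
    means = np.empty((n_classes, projected.shape[1]))
    for c in range(n_classes):
        mask = labels == c
        if not mask.any():
            label = names[c] if names else str(c)
            raise ValueError(f"no windows for micro-activity class {label!r}")
        means[c] = projected[mask].mean(axis=0)
    return PrototypeSet(means=means, sigma=sigma, seed=seed, class_names=names)


def random_prototypes(
    n_classes: int,
    F: int,
    sigma: float,
    seed: int = 0,
    *,
    min_distance: float | None = None,
    spread: float = 1.0,
    class_names: Sequence[str] | None = None,
) -> PrototypeSet:
    """Random Gaussian prototype means, optionally rescaled to a minimum pairwise distance.

    Used wherever real window data is unavailable: study sweeps, tests, the
    worked examples.  With ``min_distance`` set, the mean cloud is isotropically
    scaled until the closest pair is at least that far apart, giving a
    controllable separability (e.g. ``min_distance=10*sigma`` for a
    well-separated regime).
    """
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, spread, size=(n_classes, F))
    if min_distance is not None and n_classes >= 2:
        d_min = pdist(means).min()
        if d_min <= 0:
            raise ValueError("degenerate random means; change the seed")
        if d_min < min_distance:
            means *= min_distance / d_min
    return PrototypeSet(
        means=means,
        sigma=sigma,
        seed=seed,
        class_names=list(class_names) if class_names is not None else None,
    )


def embedding_similarity(prototypes: PrototypeSet) -> float:
    """Class-separability score s = (1/n^2) sum_{i<j} 1/||mu_i - mu_j||; lower is better."""
    n = prototypes.n_classes
    if n < 2:
        raise ValueError("similarity needs at least two classes")
    d = pdist(prototypes.means)
    if (d == 0).any():
        sq = squareform(d)
        i, j = [(i, j) for i in range(n) for j in range(i + 1, n) if sq[i, j] == 0][0]
        names = prototypes.class_names or [str(k) for k in range(n)]
        raise ZeroDivisionError(
            f"classes {names[i]!r} and {names[j]!r} have identical prototype means"
        )
    return float((1.0 / d).sum() / n**2)


def sample_embedding(
    prototypes: PrototypeSet, class_id: int, rng: np.random.Generator
) -> np.ndarray:
    """One draw from the isotropic Gaussian N(mu_i, sigma)."""
    if not (0 <= class_id < prototypes.n_classes):
        raise ValueError(f"unknown class id {class_id}")
    return rng.normal(prototypes.means[class_id], prototypes.sigma)


def generate_subsequence_embeddings(
    seq: MacroSequence | Sequence[int],
    prototypes: PrototypeSet,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One repetition of the prefix-embedding procedure.

    Draws ONE embedding per sequence position, then returns the T prefix
    slices; prefixes of the same repetition share the identical drawn vectors.
    """
    classes = tuple(seq.classes if isinstance(seq, MacroSequence) else seq)
    if len(classes) < 1:
        raise ValueError("need a sequence of length >= 1")
    E = np.stack([sample_embedding(prototypes, c, rng) for c in classes])
    return [E[: t + 1].copy() for t in range(len(classes))]


def n_impossible(n_pos: int, n_total: int, n_pos_mean: int, rate: float = 0.1) -> int:
    """Impossible-link count: round(rate * n_total) when no successor exists, else n_pos_mean.

    Rounding is half-up on the rate term.
    """
    if n_pos < 0 or n_total < 0 or n_pos_mean < 0:
        raise ValueError("counts must be non-negative")
    if n_pos == 0:
        return int(np.floor(rate * n_total + 0.5))
    return int(n_pos_mean)


def split_repetitions(
    R: int, fractions: tuple[float, float, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Assign repetition indices to train/val/test with largest-remainder rounding."""
    exact = np.array(fractions) * R
    base = np.floor(exact).astype(int)
    rem = R - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for k in range(rem):
        base[order[k]] += 1
    perm = rng.permutation(R)
    out, at = {}, 0
    for name, count in zip(("train", "val", "test"), base):
        out[name] = np.sort(perm[at : at + count])
        at += count
    return out


def generate_dataset(
    grammar: Grammar,
    prototypes: PrototypeSet,
    config: GeneratorConfig | None = None,
) -> LabeledDataset:
    """Full labelled dataset for a grammar: prefix graphs, validator and link labels.

    See the module docstring for the procedure.  Labels are exact by
    construction (computed from the grammar oracle, never from the embeddings).
    """
    config = config or GeneratorConfig()
    if prototypes.n_classes != grammar.n_classes:
        raise ValueError(
            f"prototypes cover {prototypes.n_classes} classes, grammar has {grammar.n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    splits: dict[str, list[LabeledSample]] = {"train": [], "val": [], "test": []}
    # full drawn matrices per (split, seq, repetition), for successor lookup and pools
    rep_matrices: dict[str, list[tuple[int, int, np.ndarray]]] = {
        "train": [],
        "val": [],
        "test": [],
    }

    for si, seq in enumerate(grammar.sequences):
        assignment = split_repetitions(config.repetitions, config.fractions, rng)
        rep_to_split = {int(r): name for name, reps in assignment.items() for r in reps}
        prefixes = enumerate_prefixes(seq)
        for r in range(config.repetitions):
            split_name = rep_to_split[r]
            E = np.stack([sample_embedding(prototypes, c, rng) for c in seq.classes])
            rep_matrices[split_name].append((si, r, E))
            for t, prefix in enumerate(prefixes):
                splits[split_name].append(
                    LabeledSample(
                        embeddings=E[: t + 1].copy(),
                        prefix=prefix,
                        validator_label=int(grammar.is_valid_macro(prefix)),
                        sequence_index=si,
                        repetition=r,
                    )
                )

    for split_name, samples in splits.items():
        _attach_links(grammar, prototypes, config, rng, samples, rep_matrices[split_name])

    return LabeledDataset(
        train=splits["train"],
        val=splits["val"],
        test=splits["test"],
        grammar=grammar,
        prototypes=prototypes,
        config=config,
    )


def _attach_links(
    grammar: Grammar,
    prototypes: PrototypeSet,
    config: GeneratorConfig,
    rng: np.random.Generator,
    samples: list[LabeledSample],
    matrices: list[tuple[int, int, np.ndarray]],
) -> None:
    """Attach possible/impossible link candidates to every sample of one split."""
    if not samples:
        return
    # pool of all drawn embeddings in this split, tagged with their class
    pool_class: list[int] = []
    pool_vecs: list[np.ndarray] = []
    by_class: dict[int, list[int]] = {}
    for si, _r, E in matrices:
        for t, cid in enumerate(grammar.sequences[si].classes):
            by_class.setdefault(cid, []).append(len(pool_vecs))
            pool_class.append(cid)
            pool_vecs.append(E[t])
    pool_class_arr = np.asarray(pool_class)
    n_total = len(pool_vecs)

    same_rep = {(si, r): E for si, r, E in matrices}
    succ_cache: dict[tuple[int, ...], set[int]] = {}

    def successors_of(prefix: tuple[int, ...]) -> set[int]:
        if prefix not in succ_cache:
            succ_cache[prefix] = grammar.successors(prefix)
        return succ_cache[prefix]

    n_pos_values = [len(s) for s in (successors_of(x.prefix) for x in samples) if len(s) > 0]
    n_pos_mean = max(1, int(np.floor(np.mean(n_pos_values) + 0.5))) if n_pos_values else 1

    for sample in samples:
        succ = successors_of(sample.prefix)
        links: list[LinkSample] = []
        own_seq = grammar.sequences[sample.sequence_index].classes
        own_next = own_seq[sample.T] if sample.T < len(own_seq) else None
        for c in sorted(succ):
            if c == own_next:
                vec = same_rep[(sample.sequence_index, sample.repetition)][sample.T].copy()
            else:
                cand = by_class.get(c)
                if cand:
                    vec = pool_vecs[cand[int(rng.integers(len(cand)))]].copy()
                else:  # class absent from this split's pool: fall back to a fresh draw
                    vec = sample_embedding(prototypes, c, rng)
            links.append(LinkSample(embedding=vec, label=1, source_class=c))
        n_imp = n_impossible(len(succ), n_total, n_pos_mean, config.impossible_rate)
        imp_idx = np.flatnonzero(~np.isin(pool_class_arr, sorted(succ)))
        if n_imp > 0 and imp_idx.size == 0:
            warnings.warn(
                f"no impossible-link candidates for prefix {sample.prefix}; "
                "every class is a possible successor",
                stacklevel=2,
            )
        elif n_imp > 0:
            chosen = rng.choice(imp_idx, size=n_imp, replace=True)
            for k in chosen:
                links.append(
                    LinkSample(
                        embedding=pool_vecs[int(k)].copy(),
                        label=0,
                        source_class=int(pool_class_arr[k]),
                    )
                )
        sample.links = links


def dataset_summary(dataset: LabeledDataset) -> pd.DataFrame:
    """Label counts per task and split (valid/invalid graphs, possible/impossible links)."""
    rows = []
    for name in ("train", "val", "test"):
        samples = dataset.split(name)
        v = sum(s.validator_label for s in samples)
        pos = sum(l.label for s in samples for l in s.links)
        n_links = sum(len(s.links) for s in samples)
        rows.append(
            {
                "split": name,
                "graphs": len(samples),
                "valid": v,
                "invalid": len(samples) - v,
                "possible": pos,
                "impossible": n_links - pos,
            }
        )
    return pd.DataFrame(rows).set_index("split")
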