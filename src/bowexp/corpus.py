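"""Single-label tokenized corpora: loading, validation, prevalence, splitting.

A corpus is the unit of every downstream operation: documents carry an
ordered token sequence and exactly one class label.  Splitting is always
stratified per class so that even classes with two documents appear on both
sides of a train/test partition, and learning-curve subsamples are *nested*
(the 10% training set is contained in the 20% set, and so on) so that curves
from one run are comparable across training proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Document",
    "Corpus",
    "SplitPlan",
    "load_corpus",
    "save_corpus",
    "class_prevalence",
    "rare_subset",
    "stratified_split",
    "nested_subsample",
]


@dataclass(frozen=True)
class Document:
    """One labeled document: an id, a token sequence and a single class label."""

    id: str
    tokens: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) == 0:
            raise ValueError(f"document {self.id!r} has an empty token list")


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of documents plus the class vocabulary.

    ``classes`` is ordered by first appearance in ``documents``; this order is
    the deterministic tie-break used throughout (feature-class association,
    prediction argmax).
    """

    documents: tuple[Document, ...]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        docs = tuple(self.documents)
        object.__setattr__(self, "documents", docs)
        if not docs:
            raise ValueError("corpus must contain at least one document")
        seen_ids: set[str] = set()
        for d in docs:
            if d.id in seen_ids:
                raise ValueError(f"duplicate document id {d.id!r}")
            seen_ids.add(d.id)
        first_appearance: list[str] = []
        present: set[str] = set()
        for d in docs:
            if d.label not in present:
                present.add(d.label)
                first_appearance.append(d.label)
        if not self.classes:
            object.__setattr__(self, "classes", tuple(first_appearance))
        else:
            object.__setattr__(self, "classes", tuple(self.classes))
            unknown = present - set(self.classes)
            if unknown:
                raise ValueError(f"labels not in class vocabulary: {sorted(unknown)}")
            empty = set(self.classes) - present
            if empty:
                raise ValueError(f"classes with no documents: {sorted(empty)}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for d in self.documents:
            counts[d.label] += 1
        return counts

    def by_class(self) -> dict[str, list[Document]]:
        groups: dict[str, list[Document]] = {c: [] for c in self.classes}
        for d in self.documents:
            groups[d.label].append(d)
        return groups

    def subset(self, ids: Iterable[str]) -> "Corpus":
        """Documents whose id is in ``ids``, keeping corpus order and class order."""
        wanted = set(ids)
        docs = tuple(d for d in self.documents if d.id in wanted)
        kept_classes = tuple(c for c in self.classes if any(d.label == c for d in docs))
        return Corpus(docs, kept_classes)


@dataclass(frozen=True)
class SplitPlan:
    """Protocol for the learning-curve harness.

    ``test_fraction`` is the held-out share of each class; ``proportions`` the
    strictly increasing training fractions ending at 1.0; ``n_runs`` the number
    of independent resplits averaged; ``seed`` the master seed from which all
    run- and class-level randomness is derived.
    """

    test_fraction: float = 0.2
    proportions: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.1, 10))
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        ps = self.proportions
        if not ps or any(b <= a for a, b in zip(ps, ps[1:])):
            raise ValueError("proportions must be strictly increasing")
        if not all(0.0 < p <= 1.0 for p in ps):
            raise ValueError("proportions must lie in (0, 1]")
        if ps[-1] != 1.0:
            raise ValueError("last proportion must be 1.0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")


def _parse_jsonl(path: Path) -> list[Document]:
    docs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            try:
                docs.append(Document(str(rec["id"]), tuple(rec["tokens"]), str(rec["label"])))
            except KeyError as e:
                raise ValueError(f"{path}:{lineno}: missing key {e}") from None
    return docs


def _parse_tsv(path: Path) -> list[Document]:
    docs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            doc_id, label, text = parts
            docs.append(Document(doc_id, tuple(text.split()), label))
    return docs


def load_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Load a corpus from JSONL ({"id", "label", "tokens"}) or 3-column TSV.

    Raises ``ValueError`` on duplicate ids, empty token lists or an unknown
    format.  Class order is first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        docs = _parse_jsonl(path)
    elif format == "tsv":
        docs = _parse_tsv(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}; expected 'jsonl' or 'tsv'")
    return Corpus(tuple(docs))


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the JSONL dialect ``load_corpus`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in corpus:
            fh.write(json.dumps({"id": d.id, "label": d.label, "tokens": list(d.tokens)},
                                ensure_ascii=False) + "\n")


def class_prevalence(corpus: Corpus) -> dict[str, float]:
    """Fraction of documents carrying each label; values sum to 1."""
    n = len(corpus)
    return {c: cnt / n for c, cnt in corpus.class_counts().items()}


def rare_subset(corpus: Corpus, threshold: float = 0.0002) -> set[str]:
    """Classes with prevalence ≤ threshold (inclusive: 2 docs in 10,000 at 0.0002)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    prev = class_prevalence(corpus)
    return {c for c, p in prev.items() if p <= threshold}


def _class_rng(seed: int, class_index: int) -> np.random.Generator:
    # Child seed mixes the class index into the master seed so appending a new
    # class leaves every other class's shuffle unchanged.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(class_index,)))


def stratified_split(
    corpus: Corpus, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Per-class random split into train/test.

    Each class is shuffled with its own seeded generator; the train side gets
    ``ceil((1 - test_fraction) * n_c)`` documents, clamped so both sides keep
    at least one document.  A class with a single document cannot satisfy that
    guarantee and raises ``ValueError`` naming the class.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = corpus.by_class()
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    for ci, c in enumerate(corpus.classes):
        docs = groups[c]
        n_c = len(docs)
        if n_c < 2:
            raise ValueError(
                f"class {c!r} has only {n_c} document(s); every class needs >= 2 "
                "to appear on both sides of the split (merge or drop it first)"
            )
        order = _class_rng(seed, ci).permutation(n_c)
        n_train = int(np.ceil((1.0 - test_fraction) * n_c))
        n_train = min(max(n_train, 1), n_c - 1)
        for j, idx in enumerate(order):
            (train_ids if j < n_train else test_ids).add(docs[idx].id)
    return corpus.subset(train_ids), corpus.subset(test_ids)


def nested_subsample(
    train: Corpus, proportions: Sequence[float], seed: int = 0
) -> list[Corpus]:
    """Nested training subsets at increasing proportions.

    One seeded shuffle per class; subset *i* takes the first
    ``ceil(p_i * n_c)`` documents (at least 1) of that shuffle, so subsets are
    nested by construction and the final subset (p = 1.0) is the full training
    corpus.
    """
    ps = [float(p) for p in proportions]
    if any(b <= a for a, b in zip(ps, ps[1:])) or not ps:
        raise ValueError("proportions must be strictly increasing")
    if ps[-1] != 1.0:
        raise ValueError("last proportion must be 1.0")
    groups = train.by_class()
    orders = {
        c: [groups[c][i].id for i in _class_rng(seed, ci).permutation(len(groups[c]))]
        for ci, c in enumerate(train.classes)
    }
    subsets = []
    for p in ps:
        ids: set[str] = set()
        for c, order in orders.items():
            take = max(1, int(np.ceil(p * len(order))))
            ids.update(order[:take])
        subsets.append(train.subset(ids))
    return subsets
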