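"""Document representations: sparse TF-IDF bag-of-words, the chi-square-selected
synonym-expanded variant, and dense averaged-embedding vectors.

The expanded representation works in three steps on training data:

1. every vocabulary token is scored against every class with a one-vs-rest
   2x2 chi-square statistic on document-level presence;
2. each token is *associated* with the class maximizing p(class | token), and
   for each class the k highest-scoring associated tokens are selected; their
   union is the selected feature set F;
3. for every token occurrence u in a document, the count of each w in F with
   cos(u, w) >= t in the embedding space is incremented by one before the
   TF-IDF transformation — conceptually adding w to the document whenever one
   of its synonyms occurs.

Because step 3 looks at raw document tokens (not just in-vocabulary ones), a
test document written with a synonym never seen in training still activates
the selected feature, which is precisely the mechanism that helps when
training data are scarce.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from .corpus import Corpus, Document
from .embeddings import EmbeddingTable, cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelectionConfig",
    "SelectedFeatureSet",
    "fit_vocabulary",
    "count_matrix",
    "chi_square_score",
    "associate_class",
    "select_features",
    "expand_counts",
    "TfidfWeighter",
    "cbow_vector",
    "BowRepresentation",
    "BowExpRepresentation",
    "CbowRepresentation",
]

# numerical slack so an exact self-match (cos = 1) survives float rounding
_COS_EPS = 1e-12


@dataclass(frozen=True)
class FeatureSelectionConfig:
    """Selection metric, per-class feature budget k, and cosine threshold t."""

    metric: str = "chi_square"
    k: int = 2
    t: float = 0.9

    def __post_init__(self) -> None:
        if self.metric != "chi_square":
            raise ValueError(f"unsupported selection metric {self.metric!r}")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not (0.0 < self.t <= 1.0):
            raise ValueError("t must lie in (0, 1]")


@dataclass(frozen=True)
class SelectedFeatureSet:
    """The selected feature universe F with each feature's class and score."""

    features: tuple[str, ...]
    class_of: dict[str, str]
    score_of: dict[str, float]

    def __contains__(self, feature: str) -> bool:
        return feature in self.class_of

    def __len__(self) -> int:
        return len(self.features)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("class\tfeature\tchi_square\n")
            for w in self.features:
                fh.write(f"{self.class_of[w]}\t{w}\t{self.score_of[w]:.6g}\n")


def fit_vocabulary(train: Corpus) -> list[str]:
    """Training vocabulary in first-appearance order (deterministic)."""
    vocab: list[str] = []
    seen: set[str] = set()
    for doc in train:
        for tok in doc.tokens:
            if tok not in seen:
                seen.add(tok)
                vocab.append(tok)
    return vocab


def count_matrix(docs: Sequence[Document], vocabulary: Sequence[str]) -> sp.csr_matrix:
    """Raw per-occurrence counts over a frozen vocabulary; unseen tokens dropped."""
    index = {t: j for j, t in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, doc in enumerate(docs):
        counts = Counter(tok for tok in doc.tokens if tok in index)
        for tok, n in counts.items():
            rows.append(i)
            cols.append(index[tok])
            data.append(n)
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), (rows, cols)),
        shape=(len(docs), len(vocabulary)),
    )


def _presence_stats(train: Corpus, vocabulary: Sequence[str]):
    """Document-level presence counts a[w, c] plus margins."""
    index = {t: j for j, t in enumerate(vocabulary)}
    class_index = {c: j for j, c in enumerate(train.classes)}
    a = np.zeros((len(vocabulary), len(train.classes)), dtype=np.float64)
    present = np.zeros(len(vocabulary), dtype=np.float64)
    class_n = np.zeros(len(train.classes), dtype=np.float64)
    for doc in train:
        cj = class_index[doc.label]
        class_n[cj] += 1
        for tok in set(doc.tokens):
            if tok in index:
                a[index[tok], cj] += 1
                present[index[tok]] += 1
    return a, present, class_n


def _chi_square_matrix(a: np.ndarray, present: np.ndarray, class_n: np.ndarray, n_docs: int) -> np.ndarray:
    """One-vs-rest chi-square for every (feature, class) pair.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with a = present & class,
    b = present & not-class, c = absent & class, d = absent & not-class;
    defined as 0 whenever a margin is 0.
    """
    b = present[:, None] - a
    c = class_n[None, :] - a
    d = n_docs - present[:, None] - c
    num = n_docs * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return chi2


def chi_square_score(feature: str, cls: str, train: Corpus) -> float:
    """One-vs-rest 2x2 chi-square of document-level feature presence vs class."""
    vocab = fit_vocabulary(train)
    if feature not in vocab:
        raise KeyError(f"feature {feature!r} not in training vocabulary")
    if cls not in train.classes:
        raise KeyError(f"unknown class {cls!r}")
    a, present, class_n = _presence_stats(train, vocab)
    chi2 = _chi_square_matrix(a, present, class_n, len(train))
    return float(chi2[vocab.index(feature), train.classes.index(cls)])


def associate_class(feature: str, train: Corpus) -> str:
    """argmax_c p(c | feature) over classes; ties go to the earlier class."""
    vocab = fit_vocabulary(train)
    if feature not in vocab:
        raise KeyError(f"feature {feature!r} not in training vocabulary")
    a, present, _ = _presence_stats(train, vocab)
    wi = vocab.index(feature)
    if present[wi] == 0:
        raise ValueError(f"feature {feature!r} occurs in no training document")
    return train.classes[int(np.argmax(a[wi]))]


def select_features(train: Corpus, config: FeatureSelectionConfig = FeatureSelectionConfig()) -> SelectedFeatureSet:
    """Per class, the k highest chi-square features among those associated with it.

    Deterministic: ranking is by score descending then token lexicographic.
    A class whose every token is dominated by another class may contribute
    fewer than k features.
    """
    vocab = fit_vocabulary(train)
    a, present, class_n = _presence_stats(train, vocab)
    chi2 = _chi_square_matrix(a, present, class_n, len(train))
    # association: argmax of p(c|w) = a[w, c] / present[w]; argmax on counts
    # is identical and np.argmax breaks ties toward the earlier class.
    assoc = np.argmax(a, axis=1)
    features: list[str] = []
    class_of: dict[str, str] = {}
    score_of: dict[str, float] = {}
    for cj, c in enumerate(train.classes):
        candidates = [vocab[wi] for wi in np.flatnonzero(assoc == cj) if present[wi] > 0]
        ranked = sorted(candidates, key=lambda w: (-chi2[vocab.index(w), cj], w))
        for w in ranked[: config.k]:
            features.append(w)
            class_of[w] = c
            score_of[w] = float(chi2[vocab.index(w), cj])
    return SelectedFeatureSet(tuple(features), class_of, score_of)


def expand_counts(
    doc: Document,
    raw: Mapping[str, float],
    selected: SelectedFeatureSet,
    emb: EmbeddingTable,
    t: float = 0.9,
) -> dict[str, float]:
    """Synonym-expanded per-document counts.

    For each token occurrence u in ``doc`` and each selected feature w, the
    count of w is incremented by 1 when cos(u, w) >= t.  A selected feature
    present in the document matches itself (cos = 1), so its count doubles.
    Tokens or features without embeddings trigger no increments.  Counts of
    non-selected features are returned unchanged.
    """
    if not (0.0 < t <= 1.0):
        raise ValueError("t must lie in (0, 1]")
    out = dict(raw)
    skipped = 0
    for u in doc.tokens:
        uv = emb.get(u)
        if uv is None:
            skipped += 1
            continue
        for w in selected.features:
            wv = emb.get(w)
            if wv is None:
                continue
            if cosine_similarity(uv, wv) >= t - _COS_EPS:
                out[w] = out.get(w, 0.0) + 1.0
    if skipped:
        logger.debug("expand_counts: %d token occurrence(s) without embeddings skipped", skipped)
    return out


class TfidfWeighter:
    """tf * idf weighting with idf = ln((1+N)/(1+df)) + 1 and L2 row norm.

    idf statistics are fitted once on (possibly expanded) training counts and
    reused verbatim for test rows.
    """

    def __init__(self) -> None:
        self._transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)

    def fit(self, train_counts: sp.spmatrix) -> "TfidfWeighter":
        self._transformer.fit(train_counts)
        return self

    def transform(self, counts: sp.spmatrix) -> sp.csr_matrix:
        return self._transformer.transform(counts)

    @property
    def idf(self) -> np.ndarray:
        return self._transformer.idf_


def cbow_vector(doc: Document, emb: EmbeddingTable) -> np.ndarray:
    """Per-occurrence mean of the document's token vectors (repeats weigh more)."""
    vecs = [emb[t] for t in doc.tokens if t in emb]
    if not vecs:
        raise ValueError(f"document {doc.id!r} has no token with an embedding")
    return np.mean(vecs, axis=0)


class _ExpansionIndex:
    """Maps any embedded token to the vocabulary columns of matched features."""

    def __init__(self, selected: SelectedFeatureSet, vocabulary: Sequence[str],
                 emb: EmbeddingTable, t: float):
        self.t = t
        self.emb = emb
        col = {tok: j for j, tok in enumerate(vocabulary)}
        self.feature_cols = np.asarray(
            [col[w] for w in selected.features if w in emb], dtype=np.int64
        )
        kept = [w for w in selected.features if w in emb]
        if len(kept) < len(selected.features):
            logger.info("expansion: %d selected feature(s) lack embeddings and cannot "
                        "receive increments", len(selected.features) - len(kept))
        if kept:
            W = emb.matrix(kept)
            self._W_unit = W / np.linalg.norm(W, axis=1, keepdims=True)
        else:
            self._W_unit = np.empty((0, emb.dimension))
        self._cache: dict[str, np.ndarray] = {}

    def matches(self, token: str) -> np.ndarray | None:
        """Vocabulary columns whose feature is cosine-similar to ``token``."""
        if token in self._cache:
            return self._cache[token]
        uv = self.emb.get(token)
        if uv is None or self._W_unit.shape[0] == 0:
            res = None if uv is None else np.empty(0, dtype=np.int64)
        else:
            u = uv / np.linalg.norm(uv)
            sims = self._W_unit @ u
            res = self.feature_cols[sims >= self.t - _COS_EPS]
        self._cache[token] = res
        return res

    def expand(self, docs: Sequence[Document], raw: sp.csr_matrix) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        n_skipped = 0
        for i, doc in enumerate(docs):
            occ = Counter(doc.tokens)
            for tok, n in occ.items():
                m = self.matches(tok)
                if m is None:
                    n_skipped += n
                    continue
                for j in m:
                    rows.append(i)
                    cols.append(j)
                    data.append(float(n))
        if n_skipped:
            logger.debug("expansion: %d token occurrence(s) without embeddings skipped", n_skipped)
        inc = sp.csr_matrix(
            (np.asarray(data, dtype=np.float64), (rows, cols)), shape=raw.shape
        )
        return (raw + inc).tocsr()


class BowRepresentation:
    """TF-IDF-weighted sparse bag-of-words over the training vocabulary."""

    kind = "bow"

    def fit(self, train: Corpus) -> "BowRepresentation":
        self.vocabulary = fit_vocabulary(train)
        counts = count_matrix(train.documents, self.vocabulary)
        self.tfidf = TfidfWeighter().fit(counts)
        self._train_matrix = self.tfidf.transform(counts)
        return self

    def transform(self, docs: Sequence[Document]) -> sp.csr_matrix:
        return self.tfidf.transform(count_matrix(docs, self.vocabulary))


class BowExpRepresentation:
    """Bag-of-words with chi-square-selected, synonym-expanded counts.

    Expansion happens before the TF-IDF fit, so document frequencies reflect
    the expanded counts.
    """

    kind = "bow_exp"

    def __init__(self, emb: EmbeddingTable, config: FeatureSelectionConfig = FeatureSelectionConfig()):
        self.emb = emb
        self.config = config

    def fit(self, train: Corpus) -> "BowExpRepresentation":
        self.vocabulary = fit_vocabulary(train)
        self.selected = select_features(train, self.config)
        self._index = _ExpansionIndex(self.selected, self.vocabulary, self.emb, self.config.t)
        counts = self._index.expand(
            train.documents, count_matrix(train.documents, self.vocabulary)
        )
        self.tfidf = TfidfWeighter().fit(counts)
        self._train_matrix = self.tfidf.transform(counts)
        return self

    def transform(self, docs: Sequence[Document]) -> sp.csr_matrix:
        counts = self._index.expand(docs, count_matrix(docs, self.vocabulary))
        return self.tfidf.transform(counts)


class CbowRepresentation:
    """Dense document vectors: per-occurrence mean of token embeddings.

    Documents with no embedded token are represented by the zero vector at
    transform time (with a warning), keeping prediction on arbitrary test
    documents well-defined.
    """

    kind = "cbow"

    def __init__(self, emb: EmbeddingTable):
        self.emb = emb

    def fit(self, train: Corpus) -> "CbowRepresentation":
        self._train_matrix = self.transform(train.documents)
        if not np.any(self._train_matrix):
            raise ValueError("no training document has any embedded token")
        return self

    def transform(self, docs: Sequence[Document]) -> np.ndarray:
        out = np.zeros((len(docs), self.emb.dimension))
        n_empty = 0
        for i, doc in enumerate(docs):
            try:
                out[i] = cbow_vector(doc, self.emb)
            except ValueError:
                n_empty += 1
        if n_empty:
            logger.warning("cbow: %d document(s) without embedded tokens mapped to the zero vector", n_empty)
        return out
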