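"""Linear classifiers over the document representations.

All sparse and dense variants share one estimator: an L2-regularized linear
support-vector machine trained one-vs-rest, predicting the argmax of the
per-class decision values.  Labels are encoded as integers in corpus class
order before fitting so that decision ties resolve toward the earlier class.

The :class:`Classifier` protocol (train on a corpus, predict labels for
documents) is the plug-in contract: external sequence models can join the
learning-curve harness by implementing it; none ship here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence, runtime_checkable

import joblib
import numpy as np
from sklearn.svm import LinearSVC

from .corpus import Corpus, Document
from .embeddings import EmbeddingTable, load_word2vec_text
from .features import (
    BowExpRepresentation,
    BowRepresentation,
    CbowRepresentation,
    FeatureSelectionConfig,
)

__all__ = ["C_GRID", "ClassifierConfig", "TrainedModel", "Classifier", "train", "predict",
           "save_model", "load_model"]

C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)

_KINDS = ("bow", "bow_exp", "bow_exp_kg", "cbow", "cbow_kg")


@runtime_checkable
class Classifier(Protocol):
    """Plug-in contract for the learning-curve harness."""

    def fit(self, train: Corpus, seed: int = 0) -> "Classifier": ...

    def predict(self, docs: Sequence[Document]) -> list[str]: ...


@dataclass(frozen=True)
class ClassifierConfig:
    """Which representation to build and how hard to regularize.

    ``kind`` selects the representation; the ``_kg`` variants differ from
    their base kinds only in the embedding table supplied.  ``C`` is the SVM
    regularization strength (the tuned default is 1; the grid used for tuning
    is :data:`C_GRID`).
    """

    kind: str = "bow"
    C: float = 1.0
    embedding_path: Optional[str] = None
    selection: FeatureSelectionConfig = FeatureSelectionConfig()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {_KINDS}")
        if self.C <= 0:
            raise ValueError("C must be positive")

    @property
    def needs_embeddings(self) -> bool:
        return self.kind != "bow"


def _resolve_embeddings(config: ClassifierConfig, embeddings: Optional[EmbeddingTable]) -> Optional[EmbeddingTable]:
    if not config.needs_embeddings:
        return None
    if embeddings is not None:
        return embeddings
    if config.embedding_path is None:
        raise ValueError(f"classifier kind {config.kind!r} requires an embedding table")
    return load_word2vec_text(config.embedding_path)


def _build_representation(config: ClassifierConfig, emb: Optional[EmbeddingTable]):
    if config.kind == "bow":
        return BowRepresentation()
    if config.kind in ("bow_exp", "bow_exp_kg"):
        return BowExpRepresentation(emb, config.selection)
    return CbowRepresentation(emb)


@dataclass
class TrainedModel:
    """A fitted representation plus per-class linear scoring functions."""

    config: ClassifierConfig
    representation: object
    svm: LinearSVC
    classes: tuple[str, ...]

    def decision_values(self, docs: Sequence[Document]) -> np.ndarray:
        X = self.representation.transform(docs)
        scores = self.svm.decision_function(X)
        if scores.ndim == 1:  # binary case: one margin column
            scores = np.stack([-scores, scores], axis=1)
        return scores

    def predict(self, docs: Sequence[Document]) -> list[str]:
        scores = self.decision_values(docs)
        return [self.classes[i] for i in np.argmax(scores, axis=1)]

    # Classifier-protocol alias
    def fit(self, train_corpus: Corpus, seed: int = 0) -> "TrainedModel":
        refit = train(train_corpus, self.config, seed=seed)
        self.__dict__.update(refit.__dict__)
        return self


def train(
    train_corpus: Corpus,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    embeddings: Optional[EmbeddingTable] = None,
) -> TrainedModel:
    """Build the representation on training data only, then fit the linear SVM.

    ``embeddings`` overrides ``config.embedding_path`` (useful for in-memory
    synthetic tables).  Deterministic for fixed inputs and seed.
    """
    if len(train_corpus.classes) < 2:
        raise ValueError("training corpus must contain at least two classes")
    emb = _resolve_embeddings(config, embeddings)
    rep = _build_representation(config, emb).fit(train_corpus)
    X = rep._train_matrix
    label_index = {c: i for i, c in enumerate(train_corpus.classes)}
    y = np.asarray([label_index[d.label] for d in train_corpus])
    svm = LinearSVC(C=config.C, random_state=seed)
    svm.fit(X, y)
    return TrainedModel(config, rep, svm, tuple(train_corpus.classes))


def predict(model: TrainedModel, docs: Sequence[Document]) -> list[str]:
    """Per-document argmax of one-vs-rest decision values.

    Documents sharing no token with the training vocabulary score as the
    all-zeros vector and receive the deterministic argmax of the intercepts.
    """
    return model.predict(docs)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the full bundle (vocabulary, idf, feature set, weights, class order)."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} does not contain a model bundle")
    return model
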