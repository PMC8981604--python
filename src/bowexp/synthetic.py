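"""Reproducible synthetic corpora and embedding tables.

The generator emulates the statistical structure the analysis assumes in real
patient-description corpora: a long-tailed class-frequency law (some classes
as rare as 2 in 10,000 documents), short documents of a few dozen tokens,
class-indicative *signature* vocabulary organized into synonym clusters whose
members are close in embedding space, and a Zipfian background vocabulary
shared by all classes.  Everything is driven by one integer seed and a
:class:`SyntheticConfig`, so every pipeline stage is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .corpus import Corpus, Document
from .embeddings import EmbeddingTable

__all__ = [
    "SyntheticConfig",
    "long_tail_config",
    "generate_corpus",
    "generate_embeddings",
    "synonym_split_scenario",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a fixture corpus.

    ``zipf_exponent`` shapes the class-frequency law (0 = uniform, larger =
    heavier tail); ``signal_probability`` is the chance each token is drawn
    from the document's class signature clusters rather than the background;
    ``intra_cluster_cosine_min`` lower-bounds pairwise cosine similarity
    within a synonym cluster and must exceed the expansion threshold for the
    expansion mechanism to fire; ``max_offcluster_cosine`` upper-bounds the
    similarity between unrelated vocabulary items.
    """

    n_classes: int = 12
    n_documents: int = 600
    zipf_exponent: float = 1.0
    doc_length_mean: float = 27.0
    signature_words_per_class: int = 3
    synonyms_per_signature: int = 3
    signal_probability: float = 0.35
    background_vocab_size: int = 400
    embedding_dimension: int = 256
    intra_cluster_cosine_min: float = 0.95
    max_offcluster_cosine: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_documents < 2 * self.n_classes:
            raise ValueError(
                f"n_documents={self.n_documents} cannot give every one of "
                f"{self.n_classes} classes its minimum of 2 documents"
            )
        if not (0.0 < self.signal_probability < 1.0):
            raise ValueError("signal_probability must lie in (0, 1)")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be positive")
        if not (0.0 < self.intra_cluster_cosine_min < 1.0):
            raise ValueError("intra_cluster_cosine_min must lie in (0, 1)")


def long_tail_config(n_documents: int = 10_000, n_classes: int = 150,
                     zipf_exponent: float = 2.0, seed: int = 0) -> SyntheticConfig:
    """A long-tail fixture whose smallest classes sit at prevalence 2/10,000.

    With this exponent the tail classes receive only their forced minimum of
    two documents, reproducing the "2 in 10,000" rare-class regime.
    """
    return replace(SyntheticConfig(), n_documents=n_documents, n_classes=n_classes,
                   zipf_exponent=zipf_exponent, seed=seed)


def _class_label(ci: int) -> str:
    return f"disease{ci:03d}"


def _signature_token(ci: int, si: int, vi: int) -> str:
    return f"c{ci:03d}s{si}v{vi}"


def _background_token(j: int) -> str:
    return f"bg{j:05d}"


def _class_doc_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Zipf-shaped class sizes: every class forced to >= 2 documents, the
    remainder realized multinomially over the rank-power weights."""
    ranks = np.arange(1, config.n_classes + 1, dtype=np.float64)
    weights = ranks ** (-config.zipf_exponent)
    weights /= weights.sum()
    counts = np.full(config.n_classes, 2, dtype=np.int64)
    remainder = config.n_documents - 2 * config.n_classes
    if remainder > 0:
        counts += rng.multinomial(remainder, weights)
    return counts


def _background_probs(config: SyntheticConfig) -> np.ndarray:
    ranks = np.arange(1, config.background_vocab_size + 1, dtype=np.float64)
    p = 1.0 / ranks
    return p / p.sum()


def _sample_document(
    doc_id: str,
    ci: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    bg_probs: np.ndarray,
    variants: Optional[tuple[int, ...]] = None,
) -> Document:
    """One document of class ``ci``; ``variants`` restricts which synonym
    variant of each signature cluster may be emitted (None = all)."""
    length = max(1, int(rng.poisson(config.doc_length_mean)))
    allowed = variants if variants is not None else tuple(range(config.synonyms_per_signature))
    tokens: list[str] = []
    is_signal = rng.random(length) < config.signal_probability
    clusters = rng.integers(0, config.signature_words_per_class, size=length)
    variant_picks = rng.integers(0, len(allowed), size=length)
    bg_picks = rng.choice(len(bg_probs), size=length, p=bg_probs)
    for pos in range(length):
        if is_signal[pos]:
            tokens.append(_signature_token(ci, int(clusters[pos]), allowed[int(variant_picks[pos])]))
        else:
            tokens.append(_background_token(int(bg_picks[pos])))
    return Document(doc_id, tuple(tokens), _class_label(ci))


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Draw a full corpus from the generative model, reproducibly from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    counts = _class_doc_counts(config, rng)
    bg_probs = _background_probs(config)
    docs: list[Document] = []
    i = 0
    for ci, n_c in enumerate(counts):
        for _ in range(int(n_c)):
            docs.append(_sample_document(f"d{i:06d}", ci, config, rng, bg_probs))
            i += 1
    return Corpus(tuple(docs))


def generate_embeddings(config: SyntheticConfig, max_retries: int = 50) -> EmbeddingTable:
    """Unit-sphere embeddings with tight synonym clusters and separated noise.

    Each synonym cluster gets a random unit centroid; members sit within
    half the cluster's angular budget of it, guaranteeing every intra-cluster
    pairwise cosine >= ``intra_cluster_cosine_min``.  Centroids and
    background vectors are rejection-resampled until all off-cluster cosines
    stay below ``max_offcluster_cosine``; if the dimension is too small to
    separate the requested vocabulary the construction fails after bounded
    retries.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    dim = config.embedding_dimension
    n_clusters = config.n_classes * config.signature_words_per_class
    n_anchor = n_clusters + config.background_vocab_size

    # member angular radius: pairwise angle <= 2*theta => cos >= intra_min
    theta = 0.5 * np.arccos(config.intra_cluster_cosine_min)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    anchors = unit(rng.standard_normal((n_anchor, dim)))
    # anchors must be separated by more than the cluster radius on each side
    anchor_budget = np.cos(np.arccos(config.max_offcluster_cosine) + 2 * theta)
    for _ in range(max_retries):
        sims = anchors @ anchors.T
        np.fill_diagonal(sims, -1.0)
        bad = np.unique(np.argwhere(sims >= anchor_budget)[:, 0])
        if bad.size == 0:
            break
        anchors[bad] = unit(rng.standard_normal((bad.size, dim)))
    else:
        raise ValueError(
            f"embedding dimension {dim} too small to separate {n_anchor} "
            f"vocabulary anchors below cosine {config.max_offcluster_cosine}"
        )

    vectors: dict[str, np.ndarray] = {}
    cluster_idx = 0
    for ci in range(config.n_classes):
        for si in range(config.signature_words_per_class):
            centroid = anchors[cluster_idx]
            cluster_idx += 1
            for vi in range(config.synonyms_per_signature):
                noise = rng.standard_normal(dim)
                noise -= (noise @ centroid) * centroid  # orthogonal component
                noise = unit(noise)
                member = np.cos(theta) * centroid + np.sin(theta) * noise
                vectors[_signature_token(ci, si, vi)] = member
    for j in range(config.background_vocab_size):
        vectors[_background_token(j)] = anchors[n_clusters + j]
    return EmbeddingTable(vectors, dimension=dim)


def synonym_split_scenario(
    config: SyntheticConfig = SyntheticConfig(), test_fraction: float = 0.2
) -> tuple[Corpus, Corpus, EmbeddingTable]:
    """A paired train/test pair exhibiting train/test synonym mismatch.

    Training documents of every class voice their signature clusters through
    the first synonym variant only; test documents use only the remaining
    variants of the *same* clusters.  Surface-form bag-of-words therefore
    sees none of its class-indicative training tokens at test time, while
    embedding-based expansion maps the test variants back onto the selected
    features — the regime in which expansion is designed to help.
    """
    if config.synonyms_per_signature < 2:
        raise ValueError("synonym_split_scenario needs synonyms_per_signature >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))
    counts = _class_doc_counts(config, rng)
    bg_probs = _background_probs(config)
    train_variants = (0,)
    test_variants = tuple(range(1, config.synonyms_per_signature))
    train_docs: list[Document] = []
    test_docs: list[Document] = []
    i = 0
    for ci, n_c in enumerate(counts):
        n_test = max(1, int(round(test_fraction * int(n_c))))
        n_train = max(1, int(n_c) - n_test)
        for _ in range(n_train):
            train_docs.append(_sample_document(f"d{i:06d}", ci, config, rng, bg_probs, train_variants))
            i += 1
        for _ in range(n_test):
            test_docs.append(_sample_document(f"d{i:06d}", ci, config, rng, bg_probs, test_variants))
            i += 1
    emb = generate_embeddings(config)
    return Corpus(tuple(train_docs)), Corpus(tuple(test_docs)), emb
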