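import numpy as np
import pytest

from bowexp import Corpus, Document, EmbeddingTable


def make_corpus(spec: dict[str, list[list[str]]]) -> Corpus:
    """Build a corpus from {label: [token lists]} with generated ids."""
    docs = []
    i = 0
    for label, token_lists in spec.items():
        for toks in token_lists:
            docs.append(Document(f"d{i}", tuple(toks), label))
            i += 1
    return Corpus(tuple(docs))


@pytest.fixture
def separable_corpus() -> Corpus:
    """Two classes, each with an exclusive signature token plus shared noise."""
    return make_corpus({
        "flu": [["cough", "fever", "ache"], ["fever", "cough"], ["cough", "tired"],
                ["fever", "ache", "cough"], ["cough", "cough", "rest"]],
        "rash": [["itch", "red", "skin"], ["itch", "skin"], ["red", "itch", "tired"],
                 ["itch", "rest"], ["skin", "itch", "red"]],
    })


@pytest.fixture
def toy_embeddings() -> EmbeddingTable:
    """2-d unit vectors: 'syn' is a near-synonym of 'sig' (cos ~ 0.95),
    'far' is unrelated (cos = 0.5)."""
    c = 0.95
    return EmbeddingTable({
        "sig": np.array([1.0, 0.0]),
        "syn": np.array([c, np.sqrt(1 - c * c)]),
        "far": np.array([0.5, np.sqrt(0.75)]),
        "noise": np.array([0.0, 1.0]),
    })


def random_label_corpus(rng: np.random.Generator, n_docs: int = 50, n_classes: int = 5,
                        vocab_size: int = 30, doc_len: int = 8) -> Corpus:
    """Random corpus where tokens carry a mild class bias."""
    vocab = [f"w{j}" for j in range(vocab_size)]
    docs = []
    for i in range(n_docs):
        c = i % n_classes  # every class guaranteed present
        # bias: class c prefers tokens c*3 .. c*3+4
        probs = np.ones(vocab_size)
        probs[(c * 3) % vocab_size:(c * 3) % vocab_size + 5] += 4.0
        probs /= probs.sum()
        toks = rng.choice(vocab, size=doc_len, p=probs)
        docs.append(Document(f"d{i}", tuple(toks), f"class{c}"))
    return Corpus(tuple(docs))
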