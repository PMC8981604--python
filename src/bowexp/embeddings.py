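"""Dense word-vector tables and cosine similarity.

Tables are read and written in word2vec text format (a ``count dim`` header
line followed by one ``token v1 ... vd`` line per word).  The same table type
serves both the pretrained-corpus vectors and knowledge-graph-refined vectors:
the downstream representations differ only in which table they are handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = ["EmbeddingTable", "cosine_similarity", "load_word2vec_text", "save_word2vec_text"]


@dataclass
class EmbeddingTable:
    """token -> fixed-dimension vector map.

    Zero-norm vectors are rejected at construction: every stored vector must
    be usable in a cosine-similarity query.
    """

    dimension: int
    vectors: dict[str, np.ndarray]

    def __init__(self, vectors: Mapping[str, np.ndarray] | None = None, dimension: int | None = None):
        vecs: dict[str, np.ndarray] = {}
        dim = dimension
        for tok, v in (vectors or {}).items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"vector for {tok!r} is not 1-dimensional")
            if dim is None:
                dim = arr.shape[0]
            if arr.shape[0] != dim:
                raise ValueError(f"vector for {tok!r} has dimension {arr.shape[0]}, expected {dim}")
            if not np.linalg.norm(arr) > 0:
                raise ValueError(f"zero-norm vector for {tok!r}")
            vecs[tok] = arr
        if dim is None:
            raise ValueError("dimension must be given for an empty table")
        self.dimension = int(dim)
        self.vectors = vecs

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, token: str, default=None):
        return self.vectors.get(token, default)

    def tokens(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, tokens: Iterable[str]) -> np.ndarray:
        """Stack vectors for ``tokens`` (all must be present) into a matrix."""
        return np.vstack([self.vectors[t] for t in tokens]) if tokens else np.empty((0, self.dimension))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); raises on a zero vector or dimension mismatch."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def load_word2vec_text(path: str | Path) -> EmbeddingTable:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        count, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise ValueError(f"{path}: short vector line for {parts[0]!r}")
            vectors[parts[0]] = np.asarray([float(x) for x in parts[1 : dim + 1]])
    if len(vectors) != count:
        raise ValueError(f"{path}: header promised {count} vectors, found {len(vectors)}")
    return EmbeddingTable(vectors, dimension=dim)


def save_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for tok, vec in table.vectors.items():
            fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")
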