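"""Word-embedding container and word2vec text-format I/O.

Format: a header line ``n_terms dim`` followed by one ``term v1 ... vdim``
line per term.  Gzip-compressed files (``.gz``) are accepted transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

__all__ = ["EmbeddingModel", "read_word2vec", "write_word2vec"]


@dataclass
class EmbeddingModel:
    vectors: dict[str, np.ndarray]
    dimension: int

    def __post_init__(self) -> None:
        for t, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {t!r} has wrong dimension")

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def get(self, term: str) -> np.ndarray | None:
        """Vector for ``term``, or None if absent (never fabricated)."""
        return self.vectors.get(term)


def _open(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_word2vec(path) -> EmbeddingModel:
    with _open(path, "r") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: malformed vector line for {parts[0]!r}")
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != n:
        raise ValueError(f"{path}: header declares {n} terms, found {len(vectors)}")
    return EmbeddingModel(vectors=vectors, dimension=dim)


def write_word2vec(emb: EmbeddingModel, path) -> None:
    with _open(path, "w") as fh:
        fh.write(f"{len(emb.vectors)} {emb.dimension}\n")
        for term, vec in emb.vectors.items():
            vals = " ".join(f"{x:.8g}" for x in vec)
            fh.write(f"{term} {vals}\n")
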