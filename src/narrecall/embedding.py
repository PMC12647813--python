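"""Sentence-embedding backends and cosine similarity.

Two backends satisfy one contract (:class:`Embedder`):

* :class:`HashingEmbedder` — the default, dependency-free backend.  Tokens are
  lowercased, stripped of non-alphanumerics, and scattered into a
  fixed-dimension vector by a documented 64-bit hash (BLAKE2b, digest size 8):
  the bucket is ``h % dim`` and the sign is ``+1`` when the top bit of ``h``
  is 0, else ``-1``.  Counts accumulate and the row is L2-normalized.  This is
  a deterministic signed bag-of-words: identical token multisets map to
  identical vectors on every platform.
* :class:`PretrainedEmbedder` — optional wrapper over a pretrained sentence
  encoder (512-d); raises a clear error when the model stack is absent so the
  package works fully offline.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_DIM = 512

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


class BackendUnavailableError(RuntimeError):
    """A requested embedding backend cannot run in this environment."""


class Embedder(Protocol):
    backend_id: str
    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Embeddings for an ordered list of texts (rows L2-normalized)."""

    texts: tuple[str, ...]
    vectors: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.texts):
            raise ValueError("one vector row per text required")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["text"] + [f"v{i}" for i in range(self.dim)])
            for text, row in zip(self.texts, self.vectors):
                w.writerow([text] + [repr(float(x)) for x in row])


def _tokenize_for_hash(text: str) -> list[str]:
    return [t for t in _NON_ALNUM.split(text.lower()) if t]


def hash_token(token: str) -> int:
    """Stable 64-bit hash of a token (BLAKE2b, 8-byte digest, big-endian)."""
    return int.from_bytes(hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest(), "big")


def token_bucket(token: str, dim: int = DEFAULT_DIM) -> tuple[int, int]:
    """(index, sign) the hashing backend assigns to one token."""
    h = hash_token(token)
    sign = 1 if (h >> 63) & 1 == 0 else -1
    return h % dim, sign


class HashingEmbedder:
    """Deterministic signed bag-of-words embedder (no model downloads)."""

    def __init__(self, dim: int = DEFAULT_DIM):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = int(dim)
        self.backend_id = f"hash-{self.dim}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = _tokenize_for_hash(text)
            if not tokens:
                logger.warning("text %d has no tokens; embedding is the zero vector", i)
                continue
            for tok in tokens:
                idx, sign = token_bucket(tok, self.dim)
                out[i, idx] += sign
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
            else:  # signs cancelled exactly
                logger.warning("text %d hashed to the zero vector", i)
        return out


class PretrainedEmbedder:
    """Pretrained 512-d sentence encoder behind the same contract (optional)."""

    def __init__(self, model_url: str = "https://tfhub.dev/google/universal-sentence-encoder/4"):
        try:
            import tensorflow_hub  # type: ignore
        except ImportError as exc:
            raise BackendUnavailableError(
                "the pretrained sentence-encoder backend needs tensorflow_hub and a "
                "downloaded model; use the 'hash' backend (HashingEmbedder) instead"
            ) from exc
        self._model = tensorflow_hub.load(model_url)
        self.dim = 512
        self.backend_id = "pretrained-use"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        vecs = np.asarray(self._model(list(texts)))
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vecs / norms


def get_backend(name: str = "hash", dim: int = DEFAULT_DIM) -> Embedder:
    if name == "hash":
        return HashingEmbedder(dim=dim)
    if name == "pretrained":
        return PretrainedEmbedder()
    raise ValueError(f"unknown backend {name!r}; choose 'hash' or 'pretrained'")


def embed(texts: Sequence[str], backend: Embedder | None = None) -> EmbeddingMatrix:
    """Embed a non-empty list of texts with the given (default: hashing) backend."""
    if not texts:
        raise ValueError("texts must be a non-empty list")
    backend = backend or HashingEmbedder()
    vectors = backend.encode(texts)
    return EmbeddingMatrix(texts=tuple(texts), vectors=vectors, backend_id=backend.backend_id)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two equal-dimension vectors.

    Defined as 0 (with a warning) when either vector is zero.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        logger.warning("cosine similarity of a zero vector defined as 0")
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
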