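"""Word vectors, phrase preprocessing and phrase-level similarity.

Mentions and ontology terms are embedded the same way: the string is
lowercased, stripped of non-ASCII characters, split on any non-alphanumeric
character, stop words are dropped, and the remaining in-vocabulary token
vectors are averaged into a single phrase vector.  Phrase similarity is
cosine by default; word mover's distance (exact optimal transport between
the two uniform token-vector distributions) is available as an alternative
ranking metric.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

__all__ = [
    "EmbeddingStore",
    "TokenizedPhrase",
    "PhraseVector",
    "EmbeddingFormatError",
    "EmptyPhraseError",
    "AllOOVError",
    "load_word_vectors",
    "default_stopwords",
    "load_stopwords",
    "preprocess",
    "compose_vector",
    "cosine_similarity",
    "word_movers_distance",
]


class EmbeddingFormatError(ValueError):
    """Malformed word-vector file."""


class EmptyPhraseError(ValueError):
    """Preprocessing removed every token; the caller must fall back."""


class AllOOVError(ValueError):
    """Every token of a phrase is out of vocabulary."""


@dataclass
class EmbeddingStore:
    """A token -> vector map of fixed dimension."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)

    def add(self, token: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.dim,):
            raise EmbeddingFormatError(
                f"vector for {token!r} has shape {vector.shape}, expected ({self.dim},)"
            )
        self.vectors[token] = vector

    def write_text(self, fh: IO[str]) -> None:
        """Write in word2vec text format (header line, one token per line)."""
        fh.write(f"{len(self.vectors)} {self.dim}\n")
        for token, vec in self.vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


@dataclass
class TokenizedPhrase:
    """A preprocessed string: kept tokens plus bookkeeping of removals."""

    source: str
    tokens: list[str]
    removed_stopwords: list[str] = field(default_factory=list)
    removed_nonascii: int = 0


@dataclass
class PhraseVector:
    """Average of the in-vocabulary token vectors of a phrase."""

    vector: np.ndarray
    contributing: int
    oov_tokens: list[str] = field(default_factory=list)


def _load_text(stream: IO[str]) -> EmbeddingStore:
    header = stream.readline()
    if not header.strip():
        raise EmbeddingFormatError("empty word-vector file")
    parts = header.split()
    if len(parts) != 2:
        raise EmbeddingFormatError(f"malformed header line: {header!r}")
    _, dim = int(parts[0]), int(parts[1])
    store = EmbeddingStore(dim=dim)
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split(" ")
        token, values = fields[0], fields[1:]
        if len(values) != dim:
            raise EmbeddingFormatError(
                f"line {lineno}: expected {dim} values for token {token!r}, "
                f"got {len(values)}"
            )
        store.vectors[token] = np.array([float(v) for v in values])
    return store


def _load_binary(stream: IO[bytes]) -> EmbeddingStore:
    header = stream.readline()
    if not header.strip():
        raise EmbeddingFormatError("empty word-vector file")
    try:
        vocab_size, dim = (int(x) for x in header.split())
    except ValueError as exc:
        raise EmbeddingFormatError(f"malformed header line: {header!r}") from exc
    store = EmbeddingStore(dim=dim)
    for i in range(vocab_size):
        token_bytes = bytearray()
        while True:
            ch = stream.read(1)
            if not ch:
                raise EmbeddingFormatError(f"truncated file at entry {i + 1}")
            if ch == b" ":
                break
            if ch != b"\n":  # tolerate newline between entries
                token_bytes += ch
        raw = stream.read(4 * dim)
        if len(raw) != 4 * dim:
            raise EmbeddingFormatError(f"truncated vector at entry {i + 1}")
        vec = np.array(struct.unpack(f"<{dim}f", raw), dtype=float)
        store.vectors[token_bytes.decode("utf-8")] = vec
    return store


def load_word_vectors(stream, format: str = "text") -> EmbeddingStore:
    """Load a word2vec-format vector file.

    ``format`` is ``"text"`` (header ``<vocab> <dim>`` then one
    ``token v1 ... vdim`` line per entry) or ``"binary"`` (the original
    word2vec little-endian float32 layout).  Later duplicates of a token
    overwrite earlier ones.
    """
    if format == "text":
        return _load_text(stream)
    if format == "binary":
        return _load_binary(stream)
    raise ValueError(f"unknown format {format!r}")


def default_stopwords() -> frozenset[str]:
    """The packaged stop-word list (the classic 127-word English list)."""
    text = resources.files("ontonorm").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(t for t in text.split() if t)


def load_stopwords(stream: Iterable[str]) -> frozenset[str]:
    """Read a custom stop-word list, one token per line."""
    return frozenset(line.strip() for line in stream if line.strip())


_SPLIT_RE = re.compile(r"[^a-z0-9]+")


def preprocess(text: str, stopwords: frozenset[str] | set[str] | None = None) -> TokenizedPhrase:
    """Normalize a mention or term string into tokens.

    Pipeline: lowercase, strip non-ASCII characters, split on any
    non-alphanumeric character, drop empty tokens, drop stop words.
    Raises :class:`EmptyPhraseError` when nothing survives so the caller
    can apply its fallback.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    lowered = text.lower()
    ascii_only = lowered.encode("ascii", "ignore").decode("ascii")
    removed_nonascii = len(lowered) - len(ascii_only)
    raw_tokens = [t for t in _SPLIT_RE.split(ascii_only) if t]
    tokens = [t for t in raw_tokens if t not in stopwords]
    removed = [t for t in raw_tokens if t in stopwords]
    if not tokens:
        raise EmptyPhraseError(f"no tokens survive preprocessing of {text!r}")
    return TokenizedPhrase(
        source=text,
        tokens=tokens,
        removed_stopwords=removed,
        removed_nonascii=removed_nonascii,
    )


def compose_vector(tokens: Sequence[str], store: EmbeddingStore) -> PhraseVector:
    """Average the vectors of the in-vocabulary tokens of a phrase.

    Out-of-vocabulary tokens are skipped and recorded; if every token is
    OOV an :class:`AllOOVError` is raised so the caller can fall back.
    """
    if not tokens:
        raise ValueError("compose_vector requires at least one token")
    present = [t for t in tokens if t in store]
    oov = [t for t in tokens if t not in store]
    if not present:
        raise AllOOVError(f"all tokens out of vocabulary: {list(tokens)}")
    total = np.sum([store[t] for t in present], axis=0)
    return PhraseVector(vector=total / len(present), contributing=len(present), oov_tokens=oov)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def word_movers_distance(
    tokens_a: Sequence[str], tokens_b: Sequence[str], store: EmbeddingStore
) -> float:
    """Exact word mover's distance between two token multisets.

    Each side is the uniform (count-normalized) distribution over its
    in-vocabulary token vectors; the ground metric is Euclidean.  Phrases
    are tiny, so the transportation LP is solved exactly.
    """
    va, ca = _token_distribution(tokens_a, store)
    vb, cb = _token_distribution(tokens_b, store)
    cost = cdist(va, vb)  # n x m Euclidean ground distances
    n, m = cost.shape
    if n == 1:
        return float(np.dot(cost[0], cb))
    if m == 1:
        return float(np.dot(cost[:, 0], ca))
    # transportation LP: minimize <cost, P> s.t. row sums = ca, col sums = cb
    a_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        a_eq.append(row)
    for j in range(m):
        col = np.zeros(n * m)
        col[j::m] = 1.0
        a_eq.append(col)
    res = linprog(
        cost.ravel(),
        A_eq=np.array(a_eq)[:-1],  # drop one redundant constraint
        b_eq=np.concatenate([ca, cb])[:-1],
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - tiny feasible LPs always solve
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(max(res.fun, 0.0))


def _token_distribution(
    tokens: Sequence[str], store: EmbeddingStore
) -> tuple[np.ndarray, np.ndarray]:
    counts: dict[str, int] = {}
    for t in tokens:
        if t in store:
            counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise AllOOVError(f"all tokens out of vocabulary: {list(tokens)}")
    vectors = np.array([store[t] for t in counts])
    weights = np.array(list(counts.values()), dtype=float)
    return vectors, weights / weights.sum()
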