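"""Word-embedding file I/O, frequency-ordered vocabularies and window selection.

Pre-trained word vectors arrive either in word2vec text format (one ``"N D"``
header line, then ``word v1 ... vD`` rows), GloVe text format (the same rows
with no header) or, optionally, word2vec binary.  Released embedding files are
frequency-sorted, so the row order doubles as a frequency rank; an explicit
``word<TAB>count`` side file can override that assumption.

The manifold model is trained not on the whole vocabulary but on a contiguous
*window* of the frequency ranking — frequent words sample the underlying
semantic manifold densely and keep the training cost bounded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WordEmbeddingSet",
    "TrainingWindow",
    "EmbeddingParseError",
    "load_embeddings",
    "save_embeddings",
    "load_word_counts",
    "rank_by_counts",
    "select_window",
]

FORMATS = ("word2vec_text", "glove_text", "word2vec_bin")


class EmbeddingParseError(ValueError):
    """Raised when an embedding file violates its declared format."""


@dataclass
class WordEmbeddingSet:
    """An ordered vocabulary with a dense vector per word.

    Parameters
    ----------
    vocab : list of str
        Words, aligned with the rows of ``vectors``.  No duplicates.
    vectors : ndarray of shape (N, D)
        Real word vectors; all entries finite.
    rank : ndarray of shape (N,), optional
        Frequency rank per word (0 = most frequent), a permutation of
        ``0..N-1``.  Defaults to the row order.
    """

    vocab: list[str]
    vectors: np.ndarray
    rank: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-d array")
        n = self.vectors.shape[0]
        if len(self.vocab) != n:
            raise ValueError(
                f"vocab length {len(self.vocab)} != vector rows {n}"
            )
        if n == 0:
            raise ValueError("empty embedding set")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain NaN or Inf")
        if self.rank is None:
            self.rank = np.arange(n)
        else:
            self.rank = np.asarray(self.rank, dtype=np.intp)
            if sorted(self.rank.tolist()) != list(range(n)):
                raise ValueError("rank must be a permutation of 0..N-1")
        self._index = {}
        for i, w in enumerate(self.vocab):
            if w in self._index:
                raise EmbeddingParseError(f"duplicate word {w!r}")
            self._index[w] = i

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def row(self, word: str) -> int:
        return self._index[word]

    def get(self, word: str) -> np.ndarray | None:
        """Vector for ``word``, or None when out of vocabulary."""
        i = self._index.get(word)
        return None if i is None else self.vectors[i]


@dataclass
class TrainingWindow:
    """A contiguous slice of the frequency ranking used to fit the manifold."""

    parent: WordEmbeddingSet
    start: int
    size: int
    indices: np.ndarray  # rows of parent, in rank order
    X_train: np.ndarray  # (size, D) copy

    @property
    def vocab(self) -> list[str]:
        return [self.parent.vocab[i] for i in self.indices]

    @property
    def dim(self) -> int:
        return self.X_train.shape[1]


def _parse_text_rows(lines, path, dim_hint=None, start_lineno=1):
    vocab, rows = [], []
    dim = dim_hint
    for off, line in enumerate(lines):
        lineno = start_lineno + off
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        if len(parts) < 2:
            raise EmbeddingParseError(f"{path}:{lineno}: no vector components")
        word = parts[0]
        try:
            vec = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise EmbeddingParseError(f"{path}:{lineno}: {exc}") from None
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise EmbeddingParseError(
                f"{path}:{lineno}: expected {dim} floats, got {len(vec)}"
            )
        vocab.append(word)
        rows.append(vec)
    return vocab, rows, dim


def load_embeddings(
    path: str | Path,
    format: str = "word2vec_text",
    lowercase: bool = False,
) -> WordEmbeddingSet:
    """Read an embedding file; row order defines the frequency rank.

    ``word2vec_text`` expects a first line ``"N D"`` and exactly N data rows;
    ``glove_text`` has no header and the dimension is inferred from the first
    row; ``word2vec_bin`` is the word2vec C binary layout (float32).
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "word2vec_bin":
        vocab, mat = _load_w2v_bin(path)
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        if not lines:
            raise EmbeddingParseError(f"{path}: empty file")
        if format == "word2vec_text":
            header = lines[0].split()
            if len(header) != 2:
                raise EmbeddingParseError(
                    f"{path}:1: header must be 'N D', got {lines[0]!r}"
                )
            try:
                n_decl, d_decl = int(header[0]), int(header[1])
            except ValueError:
                raise EmbeddingParseError(
                    f"{path}:1: non-integer header {lines[0]!r}"
                ) from None
            vocab, rows, _ = _parse_text_rows(
                lines[1:], path, dim_hint=d_decl, start_lineno=2
            )
            if len(vocab) != n_decl:
                raise EmbeddingParseError(
                    f"{path}: header declares {n_decl} rows, found {len(vocab)}"
                )
        else:
            vocab, rows, _ = _parse_text_rows(lines, path)
        if not vocab:
            raise EmbeddingParseError(f"{path}: no data rows")
        mat = np.asarray(rows, dtype=np.float64)

    if lowercase:
        vocab = [w.lower() for w in vocab]
        seen: dict[str, int] = {}
        keep = []
        for i, w in enumerate(vocab):
            if w not in seen:  # first (most frequent) occurrence wins
                seen[w] = i
                keep.append(i)
        vocab = [vocab[i] for i in keep]
        mat = mat[keep]
    return WordEmbeddingSet(vocab=vocab, vectors=mat)


def _load_w2v_bin(path: Path):
    with open(path, "rb") as fh:
        header = fh.readline().decode("utf-8")
        try:
            n, d = (int(x) for x in header.split())
        except ValueError:
            raise EmbeddingParseError(f"{path}: bad binary header {header!r}") from None
        vocab, mat = [], np.empty((n, d), dtype=np.float64)
        for i in range(n):
            chars = []
            while True:
                ch = fh.read(1)
                if not ch:
                    raise EmbeddingParseError(f"{path}: truncated at word {i}")
                if ch == b" ":
                    break
                if ch != b"\n":
                    chars.append(ch)
            vocab.append(b"".join(chars).decode("utf-8"))
            buf = fh.read(4 * d)
            if len(buf) != 4 * d:
                raise EmbeddingParseError(f"{path}: truncated vector for word {i}")
            mat[i] = np.frombuffer(buf, dtype="<f4")
    return vocab, mat


def save_embeddings(
    emb: WordEmbeddingSet,
    path: str | Path,
    format: str = "word2vec_text",
    precision: int = 8,
) -> None:
    """Write ``emb`` so that :func:`load_embeddings` reproduces it.

    Word order is preserved.  Text formats keep ``precision`` significant
    digits (``%.8g`` default, ample for float32-era embeddings); the binary
    format stores float32.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    if emb.n == 0:
        raise ValueError("refusing to write an empty embedding set")
    if format == "word2vec_bin":
        with open(path, "wb") as fh:
            fh.write(f"{emb.n} {emb.dim}\n".encode("utf-8"))
            for w, vec in zip(emb.vocab, emb.vectors):
                fh.write(w.encode("utf-8") + b" ")
                fh.write(struct.pack(f"<{emb.dim}f", *vec))
                fh.write(b"\n")
        return
    fmt = f"%.{precision}g"
    with open(path, "w", encoding="utf-8") as fh:
        if format == "word2vec_text":
            fh.write(f"{emb.n} {emb.dim}\n")
        for w, vec in zip(emb.vocab, emb.vectors):
            fh.write(w + " " + " ".join(fmt % v for v in vec) + "\n")


def load_word_counts(path: str | Path) -> dict[str, int]:
    """Read a ``word<TAB>count`` side file into a dict."""
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                word, cnt = line.split("\t")
                counts[word] = int(cnt)
            except ValueError:
                raise EmbeddingParseError(
                    f"{path}:{lineno}: expected 'word<TAB>count'"
                ) from None
    return counts


def rank_by_counts(emb: WordEmbeddingSet, counts: dict[str, int]) -> WordEmbeddingSet:
    """Re-rank ``emb`` by descending count (row order breaks ties).

    Words missing from ``counts`` get count 0 and sink to the tail.
    """
    c = np.array([counts.get(w, 0) for w in emb.vocab], dtype=np.int64)
    order = np.argsort(-c, kind="stable")  # stable: ties keep file order
    rank = np.empty(emb.n, dtype=np.intp)
    rank[order] = np.arange(emb.n)
    return WordEmbeddingSet(vocab=list(emb.vocab), vectors=emb.vectors.copy(), rank=rank)


def select_window(emb: WordEmbeddingSet, start: int, size: int) -> TrainingWindow:
    """The ``size`` words with frequency rank in ``[start, start+size)``.

    Returned in rank order; vectors are copied so the window can outlive the
    parent array.
    """
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    if start < 0:
        raise ValueError(f"window start must be >= 0, got {start}")
    if start + size > emb.n:
        raise ValueError(
            f"window [{start}, {start + size}) exceeds vocabulary of {emb.n} words"
        )
    order = np.argsort(emb.rank, kind="stable")
    indices = order[start : start + size]
    return TrainingWindow(
        parent=emb,
        start=start,
        size=size,
        indices=indices,
        X_train=emb.vectors[indices].copy(),
    )
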