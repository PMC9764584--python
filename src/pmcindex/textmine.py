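"""Term frequencies and co-word matrices over a policy corpus.

The indicator system behind a PMC evaluation is usually grounded in a co-word
analysis of the policy corpus: high-frequency terms ("health", "education",
"service", "management", ...) suggest the evaluation dimensions, and the
co-occurrence structure shows which concepts travel together.  This module
provides that step generically: whitespace-free tokenisation of Latin-script
text (maximal alphanumeric runs, optionally lowercased, stopwords removed),
ranked term frequencies, and symmetric co-occurrence counts at document or
sliding-window scope.  Corpora in languages needing real word segmentation
(e.g. Chinese) should be tokenised upstream and supplied pre-tokenized.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TokenizedCorpus", "CowordMatrix", "tokenize",
           "term_frequencies", "coword_matrix"]

DEFAULT_TOKEN_PATTERN = r"[A-Za-z0-9]+"


@dataclass(frozen=True)
class TokenizedCorpus:
    """Ordered token lists per document."""

    doc_ids: tuple[str, ...]
    tokens: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("duplicate document ids")
        if len(self.doc_ids) != len(self.tokens):
            raise ValueError("one token list per document id required")

    @classmethod
    def from_texts(cls, docs: dict[str, str], **tokenize_options) -> "TokenizedCorpus":
        ids = tuple(docs)
        return cls(ids, tuple(tuple(tokenize(docs[d], **tokenize_options))
                              for d in ids))


@dataclass(frozen=True)
class CowordMatrix:
    """Symmetric term x term co-occurrence counts.

    ``counts[a, b]`` is the number of documents (or sliding windows)
    containing both terms; the diagonal is each term's document (or window)
    frequency.  ``scope`` is ``"document"`` or ``"window"`` (with ``window``
    the window size).
    """

    terms: tuple[str, ...]
    counts: np.ndarray
    scope: str
    window: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.terms),
                            columns=list(self.terms))

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero co-occurrences as (term_a, term_b, count)."""
        rows = [
            (self.terms[i], self.terms[j], int(self.counts[i, j]))
            for i in range(len(self.terms))
            for j in range(i + 1, len(self.terms))
            if self.counts[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["term_a", "term_b", "count"])


def tokenize(
    text: str,
    *,
    lowercase: bool = True,
    pattern: str = DEFAULT_TOKEN_PATTERN,
    stopwords: Iterable[str] = (),
) -> list[str]:
    """Deterministic token stream: regex matches, case-folded, stopwords removed.

    Stopword filtering happens after case folding, so a stopword list given in
    lower case covers all spellings when ``lowercase`` is on.
    """
    tokens = re.findall(pattern, text)
    if lowercase:
        tokens = [t.lower() for t in tokens]
    stop = set(stopwords)
    return [t for t in tokens if t not in stop]


def term_frequencies(corpus: TokenizedCorpus, top_k: int) -> list[tuple[str, int]]:
    """Top-k terms by total frequency, ties broken lexicographically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not corpus.doc_ids:
        raise ValueError("empty corpus")
    counts = Counter(t for doc in corpus.tokens for t in doc)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def _windows(doc: Sequence[str], size: int) -> Iterable[Sequence[str]]:
    if len(doc) <= size:
        yield doc
    else:
        for start in range(len(doc) - size + 1):
            yield doc[start:start + size]


def coword_matrix(
    corpus: TokenizedCorpus,
    terms: Sequence[str],
    *,
    scope: str = "document",
    window: int | None = None,
) -> CowordMatrix:
    """Presence-based co-occurrence counts over documents or sliding windows.

    Cell (a, b) counts the units (documents, or windows of ``window`` tokens)
    in which both terms appear at least once; multiplicity within a unit is
    ignored, the standard co-word convention.  Terms absent from the corpus
    are allowed and yield zero rows.
    """
    terms = tuple(terms)
    if not terms:
        raise ValueError("term list must be nonempty")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms")
    if scope == "document":
        units: Iterable[Sequence[str]] = corpus.tokens
    elif scope == "window":
        if not window or window < 1:
            raise ValueError("window scope requires a window size >= 1")
        units = (w for doc in corpus.tokens for w in _windows(doc, window))
    else:
        raise ValueError(f"scope must be 'document' or 'window', got {scope!r}")

    idx = {t: i for i, t in enumerate(terms)}
    counts = np.zeros((len(terms), len(terms)), dtype=np.int64)
    for unit in units:
        present = sorted({idx[t] for t in unit if t in idx})
        for a in present:
            for b in present:
                counts[a, b] += 1
    return CowordMatrix(terms, counts, scope,
                        window if scope == "window" else None)
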