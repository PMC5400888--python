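"""Cluster keyword scoring: frequency x log inverse cluster-rank.

For an n-gram w and cluster C_i among C_1..C_N, with f(w, C_i) the raw
occurrence count of w across all texts in C_i:

    score(w, C_i) = f(w, C_i) * ln( N / m ),
    m = |{ C_j : f(w, C_j) >= f(w, C_i) }|

m always counts C_i itself, so m >= 1; a term equally frequent in every
cluster scores 0 everywhere, and a unique maximum scores f * ln N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import extract_ngrams
from .text import default_stopwords, tokenize


@dataclass(frozen=True)
class KeywordScore:
    term: str
    cluster: int
    freq: float
    score: float


def cluster_term_frequencies(
    texts: Sequence[str],
    labels: Sequence[int],
    ngram_range: tuple[int, int] = (1, 3),
) -> dict[str, np.ndarray]:
    """Raw n-gram occurrence counts per cluster: term -> vector of length N."""
    if len(texts) != len(labels):
        raise ValueError("texts and labels must align")
    clusters = sorted(set(int(l) for l in labels))
    index = {c: i for i, c in enumerate(clusters)}
    freq: dict[str, np.ndarray] = {}
    for text, label in zip(texts, labels):
        ci = index[int(label)]
        for term, count in extract_ngrams(tokenize(text), ngram_range).items():
            vec = freq.get(term)
            if vec is None:
                vec = freq[term] = np.zeros(len(clusters))
            vec[ci] += count
    return freq


def keyword_score(
    freq_by_cluster: Mapping[str, Sequence[float]], n_clusters: int
) -> list[KeywordScore]:
    """Score every (term, cluster) pair with the frequency x ln(N/m) rule."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    out: list[KeywordScore] = []
    for term, freqs in freq_by_cluster.items():
        f = np.asarray(freqs, dtype=float)
        if len(f) != n_clusters:
            raise ValueError(f"frequency vector for {term!r} has wrong length")
        if np.any(f < 0):
            raise ValueError("frequencies must be nonnegative")
        for i in range(n_clusters):
            m = int(np.sum(f >= f[i]))  # includes cluster i itself
            score = f[i] * math.log(n_clusters / m) if f[i] > 0 else 0.0
            out.append(KeywordScore(term=term, cluster=i, freq=float(f[i]), score=score))
    return out


def top_keywords(
    scores: Iterable[KeywordScore],
    cluster: int,
    k: int = 20,
    stoplist: frozenset[str] | set[str] | None = None,
) -> list[KeywordScore]:
    """Top-k keywords of one cluster after stoplist filtering.

    Stopword unigrams are removed, as are n-grams consisting entirely of
    stopwords; multi-word n-grams containing a content word survive
    (phrases like "thank you" or "my husband" are signal). Ordering:
    descending score, then descending frequency, then lexicographic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    stop = default_stopwords() if stoplist is None else {w.lower() for w in stoplist}

    def keep(term: str) -> bool:
        toks = term.split()
        return not all(t in stop for t in toks)

    pool = [s for s in scores if s.cluster == cluster and s.score > 0 and keep(s.term)]
    pool.sort(key=lambda s: (-s.score, -s.freq, s.term))
    return pool[:k]
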