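"""Unit x feature matrix construction.

Four feature families, mirroring authorship-analysis practice:

* F1 (style): number of messages, average sentences per message, words
  per message — defined for member documents only.
* F2 (n-grams): word unigram/bigram/trigram counts.
* F3 (medical): counts of matched medical lexicon terms.
* F4 (kinship): counts of matched kinship lexicon terms.

The stakeholder task builds the matrix over merged member documents with
all four families; the topic task uses single messages with F2+F3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .corpus_io import MemberDoc, Message
from .lexicons import TermLexicon, match_terms
from .text import tokenize

NGRAM_SEP = " "

FAMILIES = ("F1", "F2", "F3", "F4")


class FeatureSpec(BaseModel):
    """Which feature families to build and how to prune/weight them."""

    families: set[Literal["F1", "F2", "F3", "F4"]] = Field(
        default={"F1", "F2", "F3", "F4"}
    )
    ngram_range: tuple[int, int] = (1, 3)
    min_doc_freq: int = 3
    vocabulary_cap: int | None = 5000
    weighting: Literal["raw_count", "relative_freq"] = "raw_count"

    @field_validator("ngram_range")
    @classmethod
    def _check_range(cls, v):
        lo, hi = v
        if not (1 <= lo <= hi <= 3):
            raise ValueError("ngram_range must lie within [1, 3]")
        return v

    @field_validator("min_doc_freq")
    @classmethod
    def _check_mdf(cls, v):
        if v < 1:
            raise ValueError("min_doc_freq must be >= 1")
        return v


@dataclass
class FeatureMatrix:
    """Dense units x features matrix with family-tagged column names.

    ``feature_names`` are prefixed ``f1:`` ... ``f4:``; ``is_count`` marks
    columns holding counts (log1p-transformed before mixture fitting).
    """

    unit_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_units, n_features), float64, nonnegative
    is_count: np.ndarray  # (n_features,), bool

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def family_columns(self, family: str) -> list[int]:
        prefix = family.lower() + ":"
        return [j for j, n in enumerate(self.feature_names) if n.startswith(prefix)]


def extract_style_features(doc: MemberDoc) -> tuple[float, float, float]:
    """(message_count, avg sentences/message, words/message)."""
    return (
        float(doc.message_count),
        doc.avg_sentences_per_message,
        doc.words_per_message,
    )


def extract_ngrams(tokens: Sequence[str], ngram_range: tuple[int, int] = (1, 3)) -> Counter:
    """Counts of all contiguous n-grams for n in the inclusive range."""
    lo, hi = ngram_range
    counts: Counter = Counter()
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            counts[NGRAM_SEP.join(tokens[i : i + n])] += 1
    return counts


def fuse_lexicon_terms(tokens: Sequence[str], lexicon: TermLexicon) -> list[str]:
    """Fuse multi-word lexicon terms into atomic tokens for n-gram counting.

    Greedy longest-match left to right over both term categories; a
    matched multi-word span becomes one underscore-joined token. This
    keeps a terminology mention a single n-gram unit instead of spraying
    its inner words across many near-duplicate columns.
    """
    spans = {t for t in lexicon.terms() if len(t) > 1}
    if not spans:
        return list(tokens)
    max_len = max(len(t) for t in spans)
    out: list[str] = []
    i, n = 0, len(tokens)
    while i < n:
        matched = 0
        for length in range(min(max_len, n - i), 1, -1):
            if tuple(tokens[i : i + length]) in spans:
                out.append("_".join(tokens[i : i + length]))
                matched = length
                break
        if not matched:
            out.append(tokens[i])
            matched = 1
        i += matched
    return out


def _unit_id(u) -> str:
    if isinstance(u, MemberDoc):
        return u.author_id
    return u.message_id


def _unit_text(u) -> str:
    if isinstance(u, MemberDoc):
        return u.merged_text
    return u.text


def build_feature_matrix(
    units: Sequence[MemberDoc | Message],
    spec: FeatureSpec | None = None,
    lexicon: TermLexicon | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for a sequence of analysis units.

    N-gram columns are pruned by document frequency, then capped to the
    ``vocabulary_cap`` highest-total-frequency n-grams (ties broken
    lexicographically). Lexicon-term columns never occurring are dropped.
    Column order is deterministic: family, then name.
    """
    if len(units) == 0:
        raise ValueError("units must be non-empty")
    spec = spec or FeatureSpec()
    families = spec.families
    if ("F3" in families or "F4" in families) and lexicon is None:
        raise ValueError("F3/F4 features require a term lexicon")
    if "F1" in families and not all(isinstance(u, MemberDoc) for u in units):
        raise ValueError("F1 style features are defined for MemberDoc units only")

    token_lists = [tokenize(_unit_text(u)) for u in units]
    blocks: list[np.ndarray] = []
    names: list[str] = []
    is_count: list[bool] = []

    if "F1" in families:
        f1 = np.array([extract_style_features(u) for u in units], dtype=float)
        # Deterministic name order within the family.
        order = [("avg_sentences_per_message", 1), ("message_count", 0), ("words_per_message", 2)]
        blocks.append(f1[:, [i for _, i in order]])
        names.extend("f1:" + n for n, _ in order)
        is_count.extend([False, True, False])

    if "F2" in families:
        # Terminology-aware n-grams: matched lexicon spans count as one
        # token. Applied whenever a lexicon is supplied — independent of
        # which families are enabled — so growing the family set only
        # ever adds columns.
        f2_tokens = (
            [fuse_lexicon_terms(toks, lexicon) for toks in token_lists]
            if lexicon is not None
            else token_lists
        )
        per_unit = [extract_ngrams(toks, spec.ngram_range) for toks in f2_tokens]
        doc_freq: Counter = Counter()
        total_freq: Counter = Counter()
        for c in per_unit:
            doc_freq.update(c.keys())
            total_freq.update(c)
        vocab = [t for t, df in doc_freq.items() if df >= spec.min_doc_freq]
        if spec.vocabulary_cap is not None and len(vocab) > spec.vocabulary_cap:
            vocab = sorted(vocab, key=lambda t: (-total_freq[t], t))[: spec.vocabulary_cap]
        vocab = sorted(vocab)
        index = {t: j for j, t in enumerate(vocab)}
        f2 = np.zeros((len(units), len(vocab)))
        for i, c in enumerate(per_unit):
            for t, v in c.items():
                j = index.get(t)
                if j is not None:
                    f2[i, j] = v
        if spec.weighting == "relative_freq":
            sums = f2.sum(axis=1, keepdims=True)
            np.divide(f2, sums, out=f2, where=sums > 0)
        blocks.append(f2)
        names.extend("f2:" + t for t in vocab)
        is_count.extend([True] * len(vocab))

    for family, category in (("F3", "medical"), ("F4", "kinship")):
        if family not in families:
            continue
        terms = [" ".join(t) for t in lexicon.terms(category)]
        index = {t: j for j, t in enumerate(terms)}
        mat = np.zeros((len(units), len(terms)))
        for i, toks in enumerate(token_lists):
            for t, v in match_terms(toks, lexicon, category).items():
                mat[i, index[t]] = v
        keep = mat.sum(axis=0) > 0
        blocks.append(mat[:, keep])
        names.extend(f"{family.lower()}:{t}" for t, k in zip(terms, keep) if k)
        is_count.extend([True] * int(keep.sum()))

    values = np.hstack(blocks) if blocks else np.zeros((len(units), 0))
    if values.shape[1] == 0:
        raise ValueError("empty feature space: all columns pruned")
    return FeatureMatrix(
        unit_ids=[_unit_id(u) for u in units],
        feature_names=names,
        values=values,
        is_count=np.array(is_count, dtype=bool),
    )
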