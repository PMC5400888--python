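"""Lexicon-based sentiment scoring, group measures and trend series.

Every token of a message found in the sentiment lexicon contributes its
aggregated (positive, negative) intensity to the message sums; a
message's subjectivity is positive + negative. Group-level measures are
per-message means:

    PositiveScores  = sum(pos_sum)  / n_messages
    NegativeScores  = sum(neg_sum)  / n_messages
    SubjectiveScores = sum(subjective_sum) / n_messages

Trend series bin each author's messages into 15-day half-months counted
from the author's first post; only the first year (24 bins, days
[0, 360)) is kept.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

from .corpus_io import Corpus, Message
from .lexicons import SentimentLexicon
from .text import tokenize

BIN_DAYS = 15
N_BINS = 24  # first year of involvement


@dataclass(frozen=True)
class MessageSentiment:
    message_id: str
    pos_sum: float
    neg_sum: float

    @property
    def subjective_sum(self) -> float:
        return self.pos_sum + self.neg_sum


@dataclass(frozen=True)
class SentimentMeasures:
    group: Hashable
    n_messages: int
    positive_scores: float
    negative_scores: float

    @property
    def subjective_scores(self) -> float:
        return self.positive_scores + self.negative_scores


@dataclass
class TrendSeries:
    """Per-group sentiment measures over 24 half-month bins."""

    group: Hashable
    bins: dict[int, SentimentMeasures]  # bin index -> pooled measures


def score_message(
    tokens: Sequence[str], lex: SentimentLexicon, message_id: str = ""
) -> MessageSentiment:
    """Sum lexicon (pos, neg) intensities over every token occurrence."""
    pos = neg = 0.0
    for tok in tokens:
        p, n = lex.lookup(tok)
        pos += p
        neg += n
    return MessageSentiment(message_id=message_id, pos_sum=pos, neg_sum=neg)


def score_corpus(corpus: Corpus, lex: SentimentLexicon) -> dict[str, MessageSentiment]:
    """message_id -> MessageSentiment for every message of a corpus."""
    return {
        m.message_id: score_message(tokenize(m.text), lex, message_id=m.message_id)
        for m in corpus
    }


def sentiment_measures(
    sentiments: Sequence[MessageSentiment],
    groups: Sequence[Hashable],
) -> dict[Hashable, SentimentMeasures]:
    """Pooled per-message means of the three measures, per group."""
    if len(sentiments) != len(groups):
        raise ValueError("sentiments and groups must align")
    pos: dict[Hashable, float] = defaultdict(float)
    neg: dict[Hashable, float] = defaultdict(float)
    n: dict[Hashable, int] = defaultdict(int)
    for ms, g in zip(sentiments, groups):
        pos[g] += ms.pos_sum
        neg[g] += ms.neg_sum
        n[g] += 1
    return {
        g: SentimentMeasures(
            group=g,
            n_messages=n[g],
            positive_scores=pos[g] / n[g],
            negative_scores=neg[g] / n[g],
        )
        for g in n
    }


def classify_polarity(ms: MessageSentiment) -> str:
    """'positive', 'negative' or 'neutral' by comparing the two sums."""
    if ms.pos_sum > ms.neg_sum:
        return "positive"
    if ms.neg_sum > ms.pos_sum:
        return "negative"
    return "neutral"


def trend_series(
    corpus: Corpus,
    sentiments: Mapping[str, MessageSentiment],
    group_of_author: Mapping[str, Hashable] | Callable[[str], Hashable],
) -> dict[Hashable, TrendSeries]:
    """Half-month sentiment trends per group over each author's first year.

    Bin b pools messages with days-since-author's-first-post in
    [15b, 15(b+1)); messages at day >= 360 are excluded.
    """
    getter = (
        group_of_author if callable(group_of_author) else group_of_author.__getitem__
    )
    first_post: dict[str, object] = {}
    for m in corpus:  # corpus is timestamp-ordered per forum
        key = m.author_id
        if key not in first_post or m.timestamp < first_post[key]:
            first_post[key] = m.timestamp

    binned: dict[Hashable, dict[int, list[MessageSentiment]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for m in corpus:
        days = (m.timestamp - first_post[m.author_id]).total_seconds() / 86400.0
        b = int(days // BIN_DAYS)
        if not (0 <= b < N_BINS):
            continue
        binned[getter(m.author_id)][b].append(sentiments[m.message_id])

    out: dict[Hashable, TrendSeries] = {}
    for group, per_bin in binned.items():
        bins = {}
        for b, mss in sorted(per_bin.items()):
            measures = sentiment_measures(mss, [group] * len(mss))[group]
            bins[b] = SentimentMeasures(
                group=group,
                n_messages=measures.n_messages,
                positive_scores=measures.positive_scores,
                negative_scores=measures.negative_scores,
            )
        out[group] = TrendSeries(group=group, bins=bins)
    return out
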