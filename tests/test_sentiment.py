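from datetime import datetime, timedelta

import numpy as np
import pytest

from stakeminer import (
    Corpus,
    Message,
    MessageSentiment,
    classify_polarity,
    score_corpus,
    score_message,
    sentiment_measures,
    trend_series,
)
from stakeminer.lexicons import SentimentLexicon

LEX = SentimentLexicon({"good": (0.75, 0.0), "sad": (0.0, 0.625)})


class TestScoreMessage:
    def test_additivity_over_occurrences(self):
        ms = score_message(["good", "good"], LEX)
        assert ms.pos_sum == 1.5 and ms.neg_sum == 0.0

    def test_no_lexicon_terms(self):
        ms = score_message(["scan", "result"], LEX)
        assert (ms.pos_sum, ms.neg_sum, ms.subjective_sum) == (0, 0, 0)

    def test_mixed_polarity_sum(self):
        ms = score_message(["good", "sad"], LEX)
        assert ms.subjective_sum == pytest.approx(1.375)

    def test_subjectivity_identity(self):
        ms = score_message(["good", "sad", "good"], LEX)
        assert ms.subjective_sum == ms.pos_sum + ms.neg_sum


class TestSentimentMeasures:
    def test_worked_group_means(self):
        sentiments = [
            MessageSentiment("m1", 1.5, 0.0),
            MessageSentiment("m2", 0.0, 0.625),
        ]
        (g,) = sentiment_measures(sentiments, ["g", "g"]).values()
        assert g.positive_scores == pytest.approx(0.75)
        assert g.negative_scores == pytest.approx(0.3125)
        assert g.subjective_scores == pytest.approx(1.0625)
        assert g.n_messages == 2

    def test_all_neutral(self):
        (g,) = sentiment_measures([MessageSentiment("m", 0, 0)] * 3, ["g"] * 3).values()
        assert (g.positive_scores, g.negative_scores, g.subjective_scores) == (0, 0, 0)

    def test_linearity(self):
        base = [MessageSentiment("a", 0.5, 0.25), MessageSentiment("b", 1.0, 0.0)]
        double = [MessageSentiment(m.message_id, 2 * m.pos_sum, 2 * m.neg_sum) for m in base]
        g1 = sentiment_measures(base, ["g", "g"])["g"]
        g2 = sentiment_measures(double, ["g", "g"])["g"]
        assert g2.positive_scores == pytest.approx(2 * g1.positive_scores)
        assert g2.subjective_scores == pytest.approx(2 * g1.subjective_scores)

    def test_order_invariance(self):
        sentiments = [MessageSentiment(str(i), i * 0.1, 0.05) for i in range(5)]
        groups = ["g"] * 5
        fwd = sentiment_measures(sentiments, groups)["g"]
        rev = sentiment_measures(sentiments[::-1], groups)["g"]
        assert fwd.n_messages == rev.n_messages
        assert fwd.positive_scores == pytest.approx(rev.positive_scores)
        assert fwd.negative_scores == pytest.approx(rev.negative_scores)


class TestClassifyPolarity:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [(1.5, 0.2, "positive"), (0.1, 0.9, "negative"), (0.3, 0.3, "neutral"), (0, 0, "neutral")],
    )
    def test_rules(self, pos, neg, expected):
        assert classify_polarity(MessageSentiment("m", pos, neg)) == expected

    def test_positive_share_from_printed_counts(self):
        # 562 positive of 562+1261 classified emotional messages: 30.83%
        assert round(100 * 562 / (562 + 1261), 2) == 30.83

    def test_polarity_counts_partition_group(self, tiny_bundle, sentiment_lexicon):
        corpus, _ = tiny_bundle
        sentiments = score_corpus(corpus, sentiment_lexicon)
        labels = [classify_polarity(s) for s in sentiments.values()]
        assert len(labels) == len(corpus)
        assert set(labels) <= {"positive", "negative", "neutral"}


def make_corpus(days):
    t0 = datetime(2012, 1, 1)
    msgs = [
        Message(f"m{i}", "a1", "f", t0 + timedelta(days=d), "good text")
        for i, d in enumerate(days)
    ]
    return Corpus(msgs)


class TestTrendSeries:
    def lex(self):
        return SentimentLexicon({"good": (0.5, 0.0)})

    def trend(self, days):
        corpus = make_corpus(days)
        sentiments = score_corpus(corpus, self.lex())
        return trend_series(corpus, sentiments, {"a1": "g"})["g"]

    def test_bin_arithmetic(self):
        ts = self.trend([0, 16])
        assert sorted(ts.bins) == [0, 1]

    def test_day_360_excluded_half_open(self):
        ts = self.trend([0, 359.5, 360])
        assert sorted(ts.bins) == [0, 23]
        assert sum(b.n_messages for b in ts.bins.values()) == 2

    def test_bin_edge_day_15(self):
        ts = self.trend([0, 14.9, 15])
        assert ts.bins[0].n_messages == 2
        assert ts.bins[1].n_messages == 1

    def test_planted_trend_sign_recovery(self, paperlike_bundle, sentiment_lexicon):
        # patients are generated with polarity drifting positive over the
        # first year: fitted slopes must be + for positive scores and -
        # for negative scores
        corpus, gold = paperlike_bundle
        sentiments = score_corpus(corpus, sentiment_lexicon)
        ts = trend_series(corpus, sentiments, gold.member_group)["patient"]
        bins = sorted(ts.bins)
        x = np.array(bins, dtype=float)
        pos = np.array([ts.bins[b].positive_scores for b in bins])
        neg = np.array([ts.bins[b].negative_scores for b in bins])
        assert np.polyfit(x, pos, 1)[0] > 0
        assert np.polyfit(x, neg, 1)[0] < 0

    def test_group_identity_subjective_sum(self, tiny_bundle, sentiment_lexicon):
        corpus, gold = tiny_bundle
        sentiments = score_corpus(corpus, sentiment_lexicon)
        measures = sentiment_measures(
            list(sentiments.values()),
            [gold.member_group[m.author_id] for m in corpus],
        )
        for g in measures.values():
            assert g.subjective_scores == pytest.approx(
                g.positive_scores + g.negative_scores
            )
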