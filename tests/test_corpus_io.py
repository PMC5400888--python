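import json
from datetime import datetime

import pytest

from stakeminer import (
    Corpus,
    Message,
    PreprocessConfig,
    filter_informational,
    merge_by_author,
    preprocess,
    read_corpus,
    write_corpus,
)


def make_message(i, author="a1", forum="lung_cancer", text="hello world", day=1):
    return Message(f"m{i}", author, forum, datetime(2010, 1, day), text)


def write_jsonl(path, records):
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r) + "\n")


VALID = [
    dict(message_id=f"m{i}", author_id="a1", forum="f", timestamp=f"2010-01-0{i}T00:00:00", text=f"text {i}")
    for i in (1, 2, 3)
]


class TestReadWrite:
    def test_identity_load(self, tmp_path):
        p = tmp_path / "c.jsonl"
        write_jsonl(p, VALID)
        corpus = read_corpus(p)
        assert len(corpus) == 3
        assert corpus.provenance["load_report"]["dropped"] == 0

    def test_empty_text_record_dropped_and_reported(self, tmp_path):
        p = tmp_path / "c.jsonl"
        write_jsonl(p, VALID + [dict(VALID[0], message_id="m9", text="")])
        corpus = read_corpus(p)
        assert len(corpus) == 3
        assert corpus.provenance["load_report"]["dropped"] == 1

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_round_trip(self, tmp_path, fmt):
        original = Corpus([make_message(i, day=i + 1) for i in range(3)])
        p = tmp_path / f"c.{fmt}"
        write_corpus(original, p, fmt)
        back = read_corpus(p, fmt)
        assert back.messages == original.messages

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_corpus(tmp_path / "absent.jsonl")


class TestPreprocess:
    def test_message_without_word_tokens_dropped(self):
        corpus = Corpus([make_message(1, text="!!!")])
        assert len(preprocess(corpus, PreprocessConfig(min_tokens=1))) == 0

    def test_duplicate_posts_collapse_to_earliest(self):
        corpus = Corpus(
            [make_message(1, text="same post", day=5), make_message(2, text="same post", day=1)]
        )
        out = preprocess(corpus)
        assert len(out) == 1
        assert out.messages[0].timestamp.day == 1

    def test_same_text_different_authors_kept(self):
        corpus = Corpus(
            [make_message(1, author="a1", text="same"), make_message(2, author="a2", text="same")]
        )
        assert len(preprocess(corpus)) == 2

    def test_urls_and_markup_stripped(self):
        corpus = Corpus([make_message(1, text="see https://x.org/page <b>now</b> ok")])
        out = preprocess(corpus)
        assert "https" not in out.messages[0].text
        assert "<b>" not in out.messages[0].text


class TestMergeByAuthor:
    def test_sentence_and_message_counts(self):
        corpus = Corpus(
            [make_message(1, text="I cough. Often.", day=1), make_message(2, text="Help me", day=2)]
        )
        (doc,) = merge_by_author(corpus)
        assert doc.message_count == 2
        assert doc.sentence_count == 3
        assert doc.avg_sentences_per_message == 1.5

    def test_single_message_identity(self):
        (doc,) = merge_by_author(Corpus([make_message(1, text="one two three")]))
        assert doc.message_count == 1
        assert doc.word_count == 3

    def test_merged_text_preserves_posting_order(self):
        corpus = Corpus(
            [make_message(2, text="second", day=9), make_message(1, text="first", day=1)]
        )
        (doc,) = merge_by_author(corpus)
        assert doc.merged_text == "first\nsecond"

    def test_message_count_conserved_per_forum(self, tiny_bundle):
        corpus, _ = tiny_bundle
        docs = merge_by_author(corpus)
        assert sum(d.message_count for d in docs) == len(corpus)

    def test_posting_volume_matches_community_census_shape(self):
        # A cluster of 161 members posting 2332 messages averages 14.48
        # messages per member (2 d.p.).
        assert round(2332 / 161, 2) == 14.48


class TestFilterInformational:
    def test_partition_property(self, tiny_bundle, sentiment_lexicon):
        corpus, _ = tiny_bundle
        info, emo = filter_informational(corpus, sentiment_lexicon, tau=1.0)
        assert len(info) + len(emo) == len(corpus)
        ids = {m.message_id for m in info} | {m.message_id for m in emo}
        assert len(ids) == len(corpus)

    def test_monotone_in_tau(self, tiny_bundle, sentiment_lexicon):
        corpus, _ = tiny_bundle
        counts = []
        for tau in (0.0, 0.5, 1.0, 2.0, 5.0):
            _, emo = filter_informational(corpus, sentiment_lexicon, tau)
            counts.append(len(emo))
        assert counts == sorted(counts, reverse=True)

    def test_tau_zero_sends_everything_emotional(self, tiny_bundle, sentiment_lexicon):
        corpus, _ = tiny_bundle
        info, emo = filter_informational(corpus, sentiment_lexicon, tau=0.0)
        assert len(info) == 0  # every message has subjective sum >= 0 == tau

    def test_no_lexicon_terms_is_informational(self, sentiment_lexicon):
        corpus = Corpus([make_message(1, text="the biopsy was inconclusive")])
        info, emo = filter_informational(corpus, sentiment_lexicon, tau=0.5)
        assert len(info) == 1 and len(emo) == 0
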