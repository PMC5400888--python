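import numpy as np
import pytest
from scipy import stats

from stakeminer import (
    filter_informational,
    generate_corpus,
    preprocess,
    preset,
    read_corpus,
    write_corpus,
)
from stakeminer.synthetic import TOPIC_POOLS, GeneratorConfig
from stakeminer.lexicons import default_term_lexicon
from stakeminer.text import tokenize


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            corpus, _ = generate_corpus(preset("tiny", seed=5))
            write_corpus(corpus, tmp_path / f"{run}.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()

    def test_different_seeds_differ(self):
        c1, _ = generate_corpus(preset("tiny", seed=1))
        c2, _ = generate_corpus(preset("tiny", seed=2))
        assert [m.text for m in c1] != [m.text for m in c2]


class TestConfig:
    def test_member_counts_exact(self):
        cfg = preset("tiny", seed=0)
        cfg.forums[0].members = {"patient": 100, "caregiver": 50, "specialist": 10}
        corpus, gold = generate_corpus(cfg)
        from collections import Counter

        counts = Counter(gold.member_group.values())
        assert counts == {"patient": 100, "caregiver": 50, "specialist": 10}

    def test_invalid_mixture_rejected(self):
        cfg = preset("tiny", seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.forums[0].topic_mixture["patient"] = {"symptom": 0.9}
            GeneratorConfig(seed=0, forums=[cfg.forums[0]])

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("bogus")

    def test_pool_terms_exist_in_packaged_lexicon(self):
        lex = default_term_lexicon()
        medical = set(lex.terms("medical"))
        for pools in TOPIC_POOLS.values():
            for terms in pools.values():
                for term in terms:
                    assert tuple(tokenize(term)) in medical


class TestGeneratedCorpusQuality:
    def test_passes_io_validation_with_zero_drops(self, tmp_path):
        corpus, _ = generate_corpus(preset("tiny", seed=9))
        write_corpus(corpus, tmp_path / "c.jsonl")
        back = read_corpus(tmp_path / "c.jsonl")
        assert back.provenance["load_report"]["dropped"] == 0
        assert len(preprocess(back)) == len(corpus)

    def test_gold_labels_complete(self):
        corpus, gold = generate_corpus(preset("tiny", seed=9))
        for m in corpus:
            assert m.author_id in gold.member_group
            assert m.message_id in gold.message_topic
            assert m.message_id in gold.message_emotional

    def test_topic_mixture_matches_config(self):
        # chi-square goodness of fit of empirical topics vs configured
        # mixture, uniform over 5 topics, >= 2000 messages
        corpus, gold = generate_corpus(preset("topics", seed=3))
        topics = sorted(TOPIC_POOLS["lung_cancer"])
        observed = np.array(
            [sum(1 for t in gold.message_topic.values() if t == topic) for topic in topics]
        )
        n = observed.sum()
        assert n >= 2000
        _, p = stats.chisquare(observed, f_exp=np.full(5, n / 5))
        assert p > 0.01

    def test_emotional_fraction_recovered_by_filter(self, sentiment_lexicon):
        corpus, gold = generate_corpus(preset("paperlike", seed=4))
        corpus = preprocess(corpus)
        _, emo = filter_informational(corpus, sentiment_lexicon, tau=1.0)
        planted = np.mean([gold.message_emotional[m.message_id] for m in corpus])
        recovered = len(emo) / len(corpus)
        assert abs(recovered - planted) <= 0.03

    def test_planted_polarity_recovered(self, sentiment_lexicon):
        from stakeminer import classify_polarity, score_corpus

        corpus, gold = generate_corpus(preset("tiny", seed=6))
        sentiments = score_corpus(corpus, sentiment_lexicon)
        for m in corpus:
            planted = gold.message_polarity[m.message_id]
            if planted is not None:
                assert classify_polarity(sentiments[m.message_id]) == planted


class TestPaperlikePreset:
    def test_group_ratios_match_census_shape(self):
        cfg = preset("paperlike", seed=0)
        lung = next(f for f in cfg.forums if f.name == "lung_cancer")
        total = sum(lung.members.values())
        shares = {g: 100 * n / total for g, n in lung.members.items()}
        assert abs(shares["patient"] - 49.75) <= 2
        assert abs(shares["caregiver"] - 43.58) <= 2
        assert abs(shares["specialist"] - 6.66) <= 2

    def test_specialist_posting_volume_skew(self):
        cfg = preset("paperlike", seed=0)
        for forum in cfg.forums:
            vols = forum.messages_per_member_mean
            assert vols["specialist"] >= 10 * vols["patient"]

    def test_total_members_near_three_hundred(self):
        cfg = preset("paperlike", seed=0)
        assert 250 <= sum(sum(f.members.values()) for f in cfg.forums) <= 350
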