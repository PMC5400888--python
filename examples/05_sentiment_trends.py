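"""Measure sentiment per stakeholder group and over time.

Scores every message against the packaged sentiment lexicon, splits
informational from emotional messages at the subjectivity threshold
tau = 1.0, reports the three group measures (PositiveScores,
NegativeScores, SubjectiveScores = sums of lexicon intensities divided
by the number of messages) and fits a linear trend over 15-day bins of
each author's first year.
"""

import numpy as np

from stakeminer import (
    default_sentiment_lexicon,
    filter_informational,
    generate_corpus,
    preprocess,
    preset,
    score_corpus,
    sentiment_measures,
    trend_series,
)

corpus, gold = generate_corpus(preset("paperlike", seed=42))
corpus = preprocess(corpus)
lex = default_sentiment_lexicon()

info, emo = filter_informational(corpus, lex, tau=1.0)
print(f"informational {len(info)} / emotional {len(emo)} of {len(corpus)} "
      f"({100 * len(emo) / len(corpus):.2f}% emotional)")

sentiments = score_corpus(corpus, lex)
groups = [gold.member_group[m.author_id] for m in corpus]
for g, m in sorted(sentiment_measures(list(sentiments.values()), groups).items()):
    print(f"{g:10s} n={m.n_messages:4d}  Positive={m.positive_scores:.3f}  "
          f"Negative={m.negative_scores:.3f}  Subjective={m.subjective_scores:.3f}")

trends = trend_series(corpus, sentiments, gold.member_group)
for g in ("patient", "caregiver", "specialist"):
    bins = sorted(trends[g].bins)
    x = np.array(bins, dtype=float)
    pos = [trends[g].bins[b].positive_scores for b in bins]
    neg = [trends[g].bins[b].negative_scores for b in bins]
    print(f"{g:10s} trend slopes per half-month: "
          f"positive {np.polyfit(x, pos, 1)[0]:+.4f}, "
          f"negative {np.polyfit(x, neg, 1)[0]:+.4f}")
# Patients and caregivers are generated with polarity drifting positive
# over their first year, so their positive slope is + and negative is -.
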