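"""Identify stakeholder groups by EM mixture clustering of member features.

Merges each author's posts into one document, builds the four-family
feature matrix (style, n-grams, medical terms, kinship terms), selects
the number of clusters by cross-validated EM and scores the hard labels
against the planted groups.
"""

from stakeminer import (
    FeatureSpec,
    build_feature_matrix,
    default_term_lexicon,
    fit_em,
    generate_corpus,
    merge_by_author,
    partition_metrics,
    preprocess,
    preset,
    select_k,
)

corpus, gold = generate_corpus(preset("tiny", seed=42))
corpus = preprocess(corpus)
lexicon = default_term_lexicon()

docs = merge_by_author(corpus)
X = build_feature_matrix(docs, FeatureSpec(), lexicon)
print(f"feature matrix: {X.n_units} members x {len(X.feature_names)} features")

k, cv_table = select_k(X, k_max=6, folds=10, seed=0)
print("CV log-likelihood per k:", {kk: round(v, 2) for kk, v in cv_table.items()})
print(f"selected k = {k}  (the corpus plants 3 author populations)")

model, assign = fit_em(X, k, seed=0)
reference = [gold.member_group[d.author_id] for d in docs]
pm = partition_metrics(assign.labels, reference)
print(f"agreement with planted groups: Rand={pm.rand:.3f} "
      f"Jaccard={pm.jaccard:.3f} FM={pm.fm:.3f}")
# Rand near 1.0 means the clustering reproduces the planted
# patient/caregiver/specialist partition almost exactly.
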