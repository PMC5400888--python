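# Methods

## Analysis units and text normalization

All counting goes through one tokenizer: lowercase maximal runs of
Unicode letters/digits with internal apostrophes; URLs and angle-bracket
markup are noise. Sentences split on terminal punctuation (`. ! ?`) with
a small abbreviation guard; text without terminal punctuation is one
sentence. Preprocessing drops messages with fewer than `min_tokens`
word tokens (default 1) and collapses exact (author, text) duplicates to
the earliest timestamp.

The stakeholder task clusters *member documents* (all of an author's
posts in a forum, merged in posting order); the topic task clusters
single informational messages. Clustering runs per forum, matching how
community censuses are reported.

## Features

* **F1 style** (member documents only): message count, mean sentences
  per message, mean words per message. "Frequency of words per message"
  is implemented as the scalar mean words per message.
* **F2 n-grams**: word uni/bi/trigram counts. When a term lexicon is
  supplied, multi-word lexicon terms are fused into atomic tokens before
  n-gram extraction (terminology-aware tokenization), so a mention of
  "coughing up blood" is one n-gram unit rather than a spray of
  near-duplicate columns. Fusion is applied whenever a lexicon is
  present, independent of which families are enabled, so growing the
  family set only ever adds columns. Columns are pruned by document
  frequency (default floor 3 for member corpora; 10 for message corpora,
  ~0.5% of units, because message-level corpora have thousands of units)
  and capped at the 5000 highest-total-frequency n-grams.
* **F3 medical terms / F4 kinship terms**: per-lexicon-term occurrence
  counts from greedy longest-match over the token stream; matched spans
  are consumed, so "father in law" never also counts "father".

The packaged term lexicons map each term to a coarse UMLS-style semantic
type (sosy, dsyn, patf, diap, lbpr, topp, phsu for medical; famg for
kinship); real MeSH/UMLS exports in the same three-column TSV layout can
be dropped in. The packaged sentiment lexicon is a small synthetic file
in the native SentiWordNet 3.0 layout; per-term scores aggregate over
senses, by default rank-weighted (`sum(score/rank) / sum(1/rank)`),
capped at 1.

## Mixture model

Features are conditionally independent given the component. Count
features follow Poisson components; continuous style ratios follow
Gaussians. This mixed form fits sparse text counts far better than a
Gaussian on transformed counts: zero inflation is native to the Poisson,
and no variance floor heuristics are needed on the count block.

* Rates are MAP-smoothed toward the global mean rate with
  `rate_smoothing` pseudocounts (default 5) — a Gamma prior that keeps
  held-out likelihoods finite when a component never saw a term and
  damps single-term overfitting. The EM ascent guarantee therefore
  applies to the penalized objective, which is asserted non-decreasing
  every iteration (the guarantee restarts when an empty component is
  re-seeded at a random unit).
* Gaussian variances are floored at
  `max(1e-6, 0.1 x global feature variance)`. A purely absolute floor
  lets a component collapse onto a value shared by its members and turn
  into a density spike; the relative floor keeps all components on the
  data's scale.
* Initialization is k-means++-style D² seeding on log1p counts plus the
  continuous block; `n_init` restarts (default 5), best training
  likelihood wins. Convergence: relative log-likelihood change below
  `tol` (1e-6 for final fits, 1e-5 inside cross-validation), cap 200
  iterations.
* Hard labels are the posterior argmax; ties break to the lowest index.

**Model selection.** K grows from 1 while the mean held-out
log-likelihood over k folds (default 10, same fold split for every K)
improves; the search returns the last improving K. This forward search
reproduces the classic cross-validated-EM procedure.

**Cluster separation.** Welch's unequal-variance t test with
Welch–Satterthwaite degrees of freedom, applied pairwise between
clusters to the members' posterior-weighted component-summary scores
(`posterior · rowmean(component parameters)`); the degenerate
constant-equal case returns (t, p) = (0, 1).

**Partition metrics.** Pair counting via the contingency table: with a =
pairs co-clustered in both partitions, b = reference only, c = prediction
only, d = neither: Rand = (a+d)/total, Jaccard = a/(a+b+c), FM =
a/sqrt((a+b)(a+c)), FM and Jaccard defined 0 when a = 0. Verified
against an O(n²) brute-force counter and a reference library
implementation in the tests.

## Keyword scoring

`score(w, C_i) = f(w, C_i) · ln(N/m)`, m = number of clusters whose
frequency of w is ≥ f(w, C_i) (C_i counts itself, so m ≥ 1; natural log
— ranking is base-invariant). Frequencies are raw occurrence counts over
the cluster's texts. The default stoplist (packaged English function
words) removes stopword unigrams and n-grams made entirely of stopwords;
multi-word n-grams containing a content word survive, since phrases like
"thank you" or "my husband" are exactly the signal a human uses to name
clusters.

## Sentiment

Every token occurrence found in the lexicon adds its (positive,
negative) intensities to the message sums; subjectivity = positive +
negative, an exact identity maintained at message and group level. A
message is *emotional* iff its subjectivity ≥ tau (default 1.0 — the
threshold is a config knob; the packaged generator calibrates
informational text below 0.9 and emotional clauses at ≥ 1.25, so any tau
in between separates them cleanly). Polarity: positive iff pos > neg,
negative iff neg > pos, ties neutral; positive/negative proportions use
classified messages only. Group measures are pooled per-message means.
Trend series: bin b holds messages with days-since-author's-first-post
in [15b, 15(b+1)), 24 bins, day ≥ 360 excluded.

## Synthetic forum generator

Template-based slot filling, not a language model: every lexical signal
is planted deliberately and is inspectable.

* **Groups.** Patients (first-person symptom talk), caregivers
  (kinship-referential talk), specialists (second-person advice talk).
  Each message is an opener + middle + closer drawn independently from
  the group's sentence pools. Within a pool the sentences are
  micro-variants of one skeleton, so the group signature is a dense set
  of shared n-grams present in every message, while within-group lexical
  variance is confined to single-word alternations — no sentence can act
  as a spurious sub-cluster.
* **Posting volume.** Members write floor(mean) or floor(mean)+1
  messages, hitting the configured mean (from the census tables:
  patients/caregivers ~1.2–1.6, specialists ~14–34) exactly with minimal
  spread; volume separates specialists without planting a within-group
  volume axis.
* **Topics.** Five term pools per disease forum keyed to semantic types
  (symptom/sosy, complication/dsyn+patf, examination/diap+lbpr,
  procedure/topp, drug/phsu), drawn from the packaged medical lexicon.
  Member-corpus messages anchor one on-topic term and one free term; the
  per-group topic mixtures skew patients toward each forum's hallmark
  topic while specialists are uniform.
* **Topic corpora** (for topic-identification studies) use a single
  neutral population: fixed opener/closer skeletons and one listing
  sentence carrying a fixed number of iid uniform draws from the topic
  pool, comma-separated and bracketed by random day/count numbers. By
  Poissonization-style reasoning the per-term counts are then
  independent within a topic, and every n-gram adjacent to a term or
  number is a rare combination that falls below the document-frequency
  floor — the within-topic distribution matches the mixture's
  independence assumptions, so held-out likelihood genuinely stops
  improving at the planted K.
* **Sentiment.** Emotional messages (per-group probabilities ~0.14–0.25)
  append one clause: a frame shared across groups filled with 2–3
  sentiment words (each ≥ 0.625 intensity) of the message's polarity;
  intensity differs between groups only through words-per-clause.
  Polarity is positive with a per-group base probability plus an
  optional linear drift over the author's first year (patients and
  caregivers drift positive; specialists are stable and
  positive-leaning). Frames reuse function words already abundant in
  informational text so the emotional signal cannot form its own cluster
  axis.
* **Presets.** `tiny` (60 members, one forum, seconds), `paperlike`
  (three forums, ~300 members, census-shaped group ratios ~50/44/7,
  ~50/42/9, ~68/25/7 and posting-volume skew), `topics` (400 authors,
  ~2000 informational messages, five planted vocabularies).

What the generator does **not** emulate: real English fluency, thread
and reply structure, vocabulary drift over a decade, misspellings,
authors active in several forums, role ambiguity (patients who also give
advice), and topic mixtures *within* one message. Passing recovery tests
therefore shows the pipeline is correct and well-calibrated on cleanly
planted structure; it does not certify accuracy on scraped forum text,
where class overlap is far larger and printed cluster-agreement values
(Rand ≈ 0.7–0.8) are the realistic regime.

## Numerical and reporting conventions

Proportions and messages-per-member are presented at 2 d.p., half-up;
every reported proportion carries its numerator/denominator pair. All
randomness flows from explicit integer seeds (generator, EM restarts,
fold shuffling); reruns with the same config and seed are byte-identical.
Degenerate inputs: empty corpora are permitted with a warning; an
all-pruned feature space and mismatched label vectors raise; K > n
raises; empty mixture components are re-seeded.

Problem sizes used by the packaged studies: stakeholder recovery runs 20
replicates x 3 forums of ~100 members each (~300 members per replicate,
feature dimension ~800–1500); topic recovery runs 20 replicates of 2000
messages (~600–1000 features after pruning). These sizes give stable
modal selection while keeping a full study in the minutes range on one
CPU.
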