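"""End-to-end orchestration and tabular reporting.

Runs the three analyses — stakeholder identification, topic
identification, sentiment measurement — from a single config, and
produces the descriptive tables: per-forum counts, group/topic
cross-tabulations with auditable numerator/denominator pairs, keyword
tables and trend series. Clustering is per forum, matching how the
community census tables are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .clustering import fit_em, partition_metrics, select_k
from .corpus_io import (
    Corpus,
    MemberDoc,
    PreprocessConfig,
    filter_informational,
    merge_by_author,
    preprocess,
    read_corpus,
)
from .features import FeatureSpec, build_feature_matrix
from .keywords import cluster_term_frequencies, keyword_score, top_keywords
from .lexicons import (
    default_sentiment_lexicon,
    default_term_lexicon,
    load_sentiment_lexicon,
    load_term_lexicon,
)
from .sentiment import classify_polarity, score_corpus, sentiment_measures, trend_series

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Presentation rounding: 2 d.p., half away from zero-half-up."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def descriptive_stats(
    corpus: Corpus, labels: dict[str, Hashable] | None = None
) -> pd.DataFrame:
    """Per-forum (and per-group) message/member counts and messages per member.

    ``labels`` maps author_id -> group; when given, rows are broken down
    by group within forum. messages_per_member is reported at 2 d.p.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    rows = []
    df = pd.DataFrame(
        {
            "forum": [m.forum for m in corpus],
            "author": [m.author_id for m in corpus],
        }
    )
    if labels is not None:
        df["group"] = df["author"].map(labels)
    keys = ["forum"] + (["group"] if labels is not None else [])
    for key, sub in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        n_messages = len(sub)
        n_members = sub["author"].nunique()
        rows.append(
            dict(
                zip(keys, key),
                n_messages=n_messages,
                n_members=n_members,
                messages_per_member=round_half_up(n_messages / n_members),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class CrossTab:
    """Counts with row denominators and half-up 2 d.p. percentages."""

    counts: pd.DataFrame  # rows x columns counts
    proportions: pd.DataFrame  # row-relative percentages (2 d.p.)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def crosstab(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> CrossTab:
    """Cross-tabulate two aligned label vectors with row-wise proportions."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    counts = pd.crosstab(pd.Series(labels_a, name="row"), pd.Series(labels_b, name="col"))
    denom = counts.sum(axis=1)
    props = counts.div(denom, axis=0).mul(100.0).map(round_half_up)
    return CrossTab(counts=counts, proportions=props)


class PipelineConfig(BaseModel):
    """Everything needed to re-run an analysis from scratch."""

    corpus_path: str
    term_lexicon_path: str | None = None  # None -> packaged lexicons
    sentiment_lexicon_path: str | None = None
    reference_member_labels: str | None = None  # TSV author_id<TAB>...<TAB>group
    stakeholder_features: FeatureSpec = Field(
        default_factory=lambda: FeatureSpec(families={"F1", "F2", "F3", "F4"})
    )
    # Message-level corpora have thousands of units, so the document-
    # frequency floor scales up accordingly (~0.5% of units).
    topic_features: FeatureSpec = Field(
        default_factory=lambda: FeatureSpec(families={"F2", "F3"}, min_doc_freq=10)
    )
    k_stakeholder: int | None = None  # None -> cross-validated selection
    k_topic: int | None = None
    k_max: int = 6
    folds: int = 10
    n_init: int = 5
    tau: float = 1.0
    min_tokens: int = 1
    top_k_keywords: int = 20
    seed: int = 0
    out_dir: str = "stakeminer_out"


def _load_reference_labels(path: str) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rec = dict(zip(header, parts))
            labels[rec[header[0]]] = rec[header[-1]]
    return labels


def run_pipeline(cfg: PipelineConfig, task: str = "all") -> dict:
    """Run the stakeholder / topic / sentiment analyses and write artifacts.

    Returns the manifest dict; all outputs land in ``cfg.out_dir``. Any
    stage failure is recorded in the manifest before the error is
    re-raised, so partial outputs stay auditable.
    """
    if task not in {"stakeholder", "topic", "sentiment", "all"}:
        raise ValueError(f"unknown task {task!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    term_lex = (
        load_term_lexicon(cfg.term_lexicon_path)
        if cfg.term_lexicon_path
        else default_term_lexicon()
    )
    senti_lex = (
        load_sentiment_lexicon(cfg.sentiment_lexicon_path)
        if cfg.sentiment_lexicon_path
        else default_sentiment_lexicon()
    )
    manifest: dict = {
        "config": cfg.model_dump(),
        "task": task,
        "version": __version__,
        "started": datetime.now().isoformat(timespec="seconds"),
        "outputs": [],
        "status": "running",
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    try:
        corpus = preprocess(
            read_corpus(cfg.corpus_path), PreprocessConfig(min_tokens=cfg.min_tokens)
        )
        member_labels: dict[str, str] = {}

        if task in {"stakeholder", "all"}:
            stake_rows, kw_rows, metric_rows = [], [], []
            reference = (
                _load_reference_labels(cfg.reference_member_labels)
                if cfg.reference_member_labels
                else None
            )
            for fi, forum in enumerate(corpus.forums):
                docs = merge_by_author(corpus.by_forum(forum))
                X = build_feature_matrix(docs, cfg.stakeholder_features, term_lex)
                if cfg.k_stakeholder is None:
                    k, _ = select_k(
                        X, k_max=cfg.k_max, folds=cfg.folds, seed=cfg.seed + fi
                    )
                else:
                    k = cfg.k_stakeholder
                model, assign = fit_em(X, k, seed=cfg.seed + fi, n_init=cfg.n_init)
                for doc, label, post in zip(docs, assign.labels, assign.posterior):
                    member_labels[doc.author_id] = f"{forum}/c{label}"
                    stake_rows.append(
                        dict(
                            forum=forum,
                            author_id=doc.author_id,
                            cluster=int(label),
                            max_posterior=float(post.max()),
                        )
                    )
                freqs = cluster_term_frequencies(
                    [d.merged_text for d in docs], assign.labels
                )
                scores = keyword_score(freqs, int(assign.labels.max()) + 1)
                for c in range(int(assign.labels.max()) + 1):
                    for rank, s in enumerate(
                        top_keywords(scores, c, cfg.top_k_keywords), 1
                    ):
                        kw_rows.append(
                            dict(forum=forum, cluster=c, rank=rank,
                                 term=s.term, freq=s.freq, score=s.score)
                        )
                if reference:
                    ref = [reference.get(d.author_id) for d in docs]
                    if all(r is not None for r in ref):
                        pm = partition_metrics(assign.labels, ref)
                        metric_rows.append(
                            dict(forum=forum, rand=pm.rand, jaccard=pm.jaccard, fm=pm.fm)
                        )
            emit("stakeholder_labels.tsv",
                 lambda p: pd.DataFrame(stake_rows).to_csv(p, sep="\t", index=False))
            emit("stakeholder_keywords.tsv",
                 lambda p: pd.DataFrame(kw_rows).to_csv(p, sep="\t", index=False))
            if metric_rows:
                emit("stakeholder_metrics.tsv",
                     lambda p: pd.DataFrame(metric_rows).to_csv(p, sep="\t", index=False))
            stats = descriptive_stats(corpus, member_labels or None)
            emit("descriptive_stats.tsv",
                 lambda p: stats.to_csv(p, sep="\t", index=False))

        if task in {"topic", "all"}:
            informational, _ = filter_informational(corpus, senti_lex, cfg.tau)
            topic_rows, kw_rows = [], []
            message_topics: dict[str, str] = {}
            for fi, forum in enumerate(informational.forums):
                msgs = list(informational.by_forum(forum))
                X = build_feature_matrix(msgs, cfg.topic_features, term_lex)
                if cfg.k_topic is None:
                    k, _ = select_k(
                        X, k_max=max(cfg.k_max, 8), folds=cfg.folds, seed=cfg.seed + fi
                    )
                else:
                    k = cfg.k_topic
                model, assign = fit_em(X, k, seed=cfg.seed + fi, n_init=cfg.n_init)
                for m, label in zip(msgs, assign.labels):
                    message_topics[m.message_id] = f"{forum}/t{label}"
                    topic_rows.append(
                        dict(forum=forum, message_id=m.message_id, cluster=int(label))
                    )
                freqs = cluster_term_frequencies([m.text for m in msgs], assign.labels)
                scores = keyword_score(freqs, int(assign.labels.max()) + 1)
                for c in range(int(assign.labels.max()) + 1):
                    for rank, s in enumerate(
                        top_keywords(scores, c, cfg.top_k_keywords), 1
                    ):
                        kw_rows.append(
                            dict(forum=forum, cluster=c, rank=rank,
                                 term=s.term, freq=s.freq, score=s.score)
                        )
            emit("topic_labels.tsv",
                 lambda p: pd.DataFrame(topic_rows).to_csv(p, sep="\t", index=False))
            emit("topic_keywords.tsv",
                 lambda p: pd.DataFrame(kw_rows).to_csv(p, sep="\t", index=False))
            if member_labels and message_topics:
                pairs = [
                    (member_labels[m.author_id], message_topics[m.message_id])
                    for m in informational
                    if m.author_id in member_labels and m.message_id in message_topics
                ]
                if pairs:
                    ct = crosstab([a for a, _ in pairs], [b for _, b in pairs])
                    emit("group_topic_counts.tsv",
                         lambda p: ct.counts.to_csv(p, sep="\t"))
                    emit("group_topic_proportions.tsv",
                         lambda p: ct.proportions.to_csv(p, sep="\t"))

        if task in {"sentiment", "all"}:
            sentiments = score_corpus(corpus, senti_lex)
            per_msg = pd.DataFrame(
                dict(
                    message_id=m.message_id,
                    author_id=m.author_id,
                    forum=m.forum,
                    pos=sentiments[m.message_id].pos_sum,
                    neg=sentiments[m.message_id].neg_sum,
                    subjective=sentiments[m.message_id].subjective_sum,
                    polarity=classify_polarity(sentiments[m.message_id]),
                )
                for m in corpus
            )
            emit("message_sentiment.tsv",
                 lambda p: per_msg.to_csv(p, sep="\t", index=False))
            group_of = (
                member_labels if member_labels
                else {m.author_id: m.forum for m in corpus}
            )
            keys = [group_of.get(m.author_id, "all") for m in corpus]
            measures = sentiment_measures(
                [sentiments[m.message_id] for m in corpus], keys
            )
            mdf = pd.DataFrame(
                dict(
                    group=g,
                    n_messages=sm.n_messages,
                    positive_scores=sm.positive_scores,
                    negative_scores=sm.negative_scores,
                    subjective_scores=sm.subjective_scores,
                )
                for g, sm in sorted(measures.items())
            )
            emit("group_sentiment_measures.tsv",
                 lambda p: mdf.to_csv(p, sep="\t", index=False))
            trends = trend_series(corpus, sentiments, lambda a: group_of.get(a, "all"))
            trend_rows = [
                dict(
                    group=g,
                    bin=b,
                    n_messages=sm.n_messages,
                    positive_scores=sm.positive_scores,
                    negative_scores=sm.negative_scores,
                    subjective_scores=sm.subjective_scores,
                )
                for g, ts in sorted(trends.items())
                for b, sm in ts.bins.items()
            ]
            emit("sentiment_trends.tsv",
                 lambda p: pd.DataFrame(trend_rows).to_csv(p, sep="\t", index=False))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["finished"] = datetime.now().isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def feature_ablation(
    docs: list[MemberDoc],
    reference: dict[str, str],
    k: int = 3,
    seed: int = 0,
    n_init: int = 5,
) -> pd.DataFrame:
    """Cluster member docs under the cumulative family sweep.

    Fits a k-component mixture for each of F1, F1+F2, F1+F2+F3,
    F1+F2+F3+F4 and scores the hard labels against ``reference``
    (author_id -> group). Returns one row of partition metrics per
    feature set.
    """
    from .lexicons import default_term_lexicon

    lex = default_term_lexicon()
    ref = [reference[d.author_id] for d in docs]
    sweeps = [
        ("F1", {"F1"}),
        ("F1+F2", {"F1", "F2"}),
        ("F1+F2+F3", {"F1", "F2", "F3"}),
        ("F1+F2+F3+F4", {"F1", "F2", "F3", "F4"}),
    ]
    rows = []
    for name, fams in sweeps:
        X = build_feature_matrix(docs, FeatureSpec(families=fams), lex)
        _, assign = fit_em(X, k, seed=seed, n_init=n_init)
        pm = partition_metrics(assign.labels, ref)
        rows.append(dict(feature_set=name, rand=pm.rand, jaccard=pm.jaccard, fm=pm.fm))
    return pd.DataFrame(rows)
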