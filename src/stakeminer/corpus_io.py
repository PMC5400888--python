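"""Forum-corpus data model, readers/writers, preprocessing and merging.

A :class:`Corpus` is a flat, timestamp-ordered collection of forum posts.
Analysis units are either single messages (topic task) or one merged
document per author and forum (:class:`MemberDoc`, stakeholder task).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .text import count_sentences, strip_noise, tokenize

logger = logging.getLogger(__name__)

_REQUIRED_FIELDS = ("message_id", "author_id", "forum", "timestamp", "text")


@dataclass(frozen=True)
class Message:
    """One forum post. Timestamps are stored timezone-naive in UTC."""

    message_id: str
    author_id: str
    forum: str
    timestamp: datetime
    text: str


@dataclass
class Corpus:
    """An ordered collection of messages plus provenance metadata.

    Messages are kept sorted by timestamp within each forum; the
    ``provenance`` dict records where the corpus came from (file path or
    generator config/seed) and the load report of the last read.
    """

    messages: list[Message]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.messages = sorted(
            self.messages, key=lambda m: (m.forum, m.timestamp, m.message_id)
        )

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    @property
    def forums(self) -> list[str]:
        return sorted({m.forum for m in self.messages})

    def by_forum(self, forum: str) -> "Corpus":
        return Corpus(
            [m for m in self.messages if m.forum == forum],
            provenance={**self.provenance, "forum": forum},
        )


@dataclass(frozen=True)
class MemberDoc:
    """All of one author's posts in one forum, merged in first-posted order.

    Carries the counts behind the three writing-style features: number of
    messages, average sentences per message (sentence_count/message_count)
    and words per message (word_count/message_count).
    """

    author_id: str
    forum: str
    merged_text: str
    message_count: int
    sentence_count: int
    word_count: int

    @property
    def avg_sentences_per_message(self) -> float:
        return self.sentence_count / self.message_count

    @property
    def words_per_message(self) -> float:
        return self.word_count / self.message_count


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(str(value))
    if ts.tzinfo is not None:
        ts = ts.astimezone(timezone.utc).replace(tzinfo=None)
    return ts


def _record_to_message(rec: dict) -> Message:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] in (None, ""):
            raise ValueError(f"missing field {f!r}")
    return Message(
        message_id=str(rec["message_id"]),
        author_id=str(rec["author_id"]),
        forum=str(rec["forum"]),
        timestamp=_parse_timestamp(rec["timestamp"]),
        text=str(rec["text"]),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Load a corpus from JSONL or CSV.

    Records missing any mandatory field (or with empty text) are dropped
    and counted in the load report stored under
    ``corpus.provenance["load_report"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    messages: list[Message] = []
    dropped = 0
    if fmt == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    messages.append(_record_to_message(json.loads(line)))
                except (ValueError, KeyError, TypeError) as exc:
                    dropped += 1
                    logger.warning("skipping line %d of %s: %s", lineno, path, exc)
    elif fmt == "csv":
        with path.open(newline="") as fh:
            for lineno, rec in enumerate(csv.DictReader(fh), 1):
                try:
                    messages.append(_record_to_message(rec))
                except (ValueError, KeyError, TypeError) as exc:
                    dropped += 1
                    logger.warning("skipping row %d of %s: %s", lineno, path, exc)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    report = {"path": str(path), "loaded": len(messages), "dropped": dropped}
    return Corpus(messages, provenance={"source": str(path), "load_report": report})


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL or CSV (ISO-8601 timestamps)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w") as fh:
            for m in corpus:
                fh.write(
                    json.dumps(
                        {
                            "message_id": m.message_id,
                            "author_id": m.author_id,
                            "forum": m.forum,
                            "timestamp": m.timestamp.isoformat(),
                            "text": m.text,
                        }
                    )
                    + "\n"
                )
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REQUIRED_FIELDS)
            for m in corpus:
                writer.writerow(
                    [m.message_id, m.author_id, m.forum, m.timestamp.isoformat(), m.text]
                )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


@dataclass(frozen=True)
class PreprocessConfig:
    min_tokens: int = 1
    drop_duplicates: bool = True
    strip_urls_markup: bool = True


def preprocess(corpus: Corpus, rules: PreprocessConfig = PreprocessConfig()) -> Corpus:
    """Normalize text and drop noisy messages.

    Messages with fewer than ``min_tokens`` word tokens after URL/markup
    stripping are dropped; exact (author_id, normalized text) duplicates
    collapse to the earliest timestamp.
    """
    kept: list[Message] = []
    seen: set[tuple[str, str]] = set()
    dropped_short = dropped_dup = 0
    for m in corpus:  # corpus iterates in timestamp order per forum
        text = strip_noise(m.text) if rules.strip_urls_markup else m.text
        toks = tokenize(text)
        if len(toks) < rules.min_tokens:
            dropped_short += 1
            continue
        if rules.drop_duplicates:
            key = (m.author_id, " ".join(toks))
            if key in seen:
                dropped_dup += 1
                continue
            seen.add(key)
        kept.append(
            Message(m.message_id, m.author_id, m.forum, m.timestamp, text)
        )
    if not kept:
        logger.warning("preprocess produced an empty corpus")
    return Corpus(
        kept,
        provenance={
            **corpus.provenance,
            "preprocess": {
                "min_tokens": rules.min_tokens,
                "dropped_short": dropped_short,
                "dropped_duplicate": dropped_dup,
            },
        },
    )


def merge_by_author(corpus: Corpus) -> list[MemberDoc]:
    """One MemberDoc per (author_id, forum), messages joined in posting order."""
    grouped: dict[tuple[str, str], list[Message]] = {}
    for m in corpus:
        grouped.setdefault((m.author_id, m.forum), []).append(m)
    docs = []
    for (author, forum), msgs in sorted(grouped.items()):
        msgs = sorted(msgs, key=lambda m: (m.timestamp, m.message_id))
        merged = "\n".join(m.text for m in msgs)
        docs.append(
            MemberDoc(
                author_id=author,
                forum=forum,
                merged_text=merged,
                message_count=len(msgs),
                sentence_count=sum(count_sentences(m.text) for m in msgs),
                word_count=sum(len(tokenize(m.text)) for m in msgs),
            )
        )
    return docs


def filter_informational(
    corpus: Corpus, lex, tau: float = 1.0
) -> tuple[Corpus, Corpus]:
    """Partition a corpus into (informational, emotional) messages.

    A message is emotional iff the sum of its matched sentiment terms'
    subjectivity (positive + negative intensity) is >= ``tau``; everything
    else is informational. The two outputs partition the input exactly.
    """
    from .sentiment import score_message  # local import to avoid a cycle

    if tau < 0:
        raise ValueError("tau must be >= 0")
    info, emo = [], []
    for m in corpus:
        ms = score_message(tokenize(m.text), lex, message_id=m.message_id)
        (emo if ms.subjective_sum >= tau else info).append(m)
    prov = dict(corpus.provenance)
    return (
        Corpus(info, provenance={**prov, "partition": "informational", "tau": tau}),
        Corpus(emo, provenance={**prov, "partition": "emotional", "tau": tau}),
    )
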