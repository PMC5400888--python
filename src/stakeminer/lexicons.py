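"""Term lexicons (medical / kinship) and the sentiment lexicon.

The medical and kinship lexicons are flat term -> semantic-type maps in
the spirit of a MeSH/UMLS export: each entry carries a coarse UMLS-style
semantic type code (sosy, dsyn, patf, diap, topp, phsu, lbpr for medical
terms; famg for kinship terms). Matching is greedy longest-match over the
same token stream used everywhere else, so "father in law" wins over
"father".

The sentiment lexicon assigns each term aggregated positive and negative
intensity scores in [0, 1]; it reads both native SentiWordNet 3.0 files
and a simplified three-column (term, pos, neg) layout.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .text import tokenize

logger = logging.getLogger(__name__)

VALID_SEMTYPES = frozenset(
    {"sosy", "dsyn", "patf", "diap", "topp", "phsu", "lbpr", "famg"}
)
VALID_CATEGORIES = frozenset({"medical", "kinship"})


@dataclass
class TermLexicon:
    """Normalized multi-word term entries with category and semantic type."""

    # (token tuple, category) -> semtype
    entries: dict[tuple[tuple[str, ...], str], str] = field(default_factory=dict)

    def add(self, term_tokens: Sequence[str], category: str, semtype: str) -> None:
        self.entries.setdefault((tuple(term_tokens), category), semtype)

    def terms(self, category: str | None = None) -> list[tuple[str, ...]]:
        return sorted(
            t for (t, c) in self.entries if category is None or c == category
        )

    def semtype(self, term: str | Sequence[str], category: str = "medical") -> str | None:
        key = tuple(term.split()) if isinstance(term, str) else tuple(term)
        return self.entries.get((key, category))

    def __len__(self) -> int:
        return len(self.entries)

    def merged_with(self, other: "TermLexicon") -> "TermLexicon":
        out = TermLexicon(dict(self.entries))
        for (t, c), s in other.entries.items():
            out.add(t, c, s)
        return out


def load_term_lexicon(path: str | Path) -> TermLexicon:
    """Read a tab-separated term lexicon: term, category, semtype.

    Terms are normalized with the package tokenizer; lines with an unknown
    semtype or category are skipped with a warning; duplicates collapse.
    """
    path = Path(path)
    lex = TermLexicon()
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split("\t")
        if len(parts) != 3:
            logger.warning("%s:%d: expected 3 columns, got %d", path, lineno, len(parts))
            continue
        term, category, semtype = (p.strip().lower() for p in parts)
        if category not in VALID_CATEGORIES or semtype not in VALID_SEMTYPES:
            logger.warning("%s:%d: bad category/semtype %r/%r", path, lineno, category, semtype)
            continue
        toks = tuple(tokenize(term))
        if toks:
            lex.add(toks, category, semtype)
    if n_lines == 0:
        logger.warning("term lexicon %s is empty", path)
    return lex


@dataclass
class SentimentLexicon:
    """Per-term aggregated (positive, negative) intensity in [0, 1]."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def lookup(self, term: str) -> tuple[float, float]:
        """(pos, neg) for a term; absent terms score (0, 0)."""
        return self.entries.get(term.lower(), (0.0, 0.0))

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _aggregate(senses: list[tuple[int, float, float]], how: str) -> tuple[float, float]:
    # senses: (rank, pos, neg); ranks start at 1
    if how == "first_sense":
        rank, pos, neg = min(senses)
        return pos, neg
    if how == "mean":
        pos = sum(s[1] for s in senses) / len(senses)
        neg = sum(s[2] for s in senses) / len(senses)
        return pos, neg
    if how == "rank_weighted":
        wsum = sum(1.0 / r for r, _, _ in senses)
        pos = sum(p / r for r, p, _ in senses) / wsum
        neg = sum(n / r for r, _, n in senses) / wsum
        return pos, neg
    raise ValueError(f"unknown aggregation {how!r}")


def load_sentiment_lexicon(
    path: str | Path, aggregation: str = "rank_weighted"
) -> SentimentLexicon:
    """Read a sentiment lexicon.

    Accepts the native SentiWordNet 3.0 layout (POS, id, PosScore,
    NegScore, SynsetTerms with ``term#rank`` entries, gloss; '#'-comment
    lines skipped) or a simplified 3-column file (term, pos, neg). Scores
    of a term appearing in several synsets are aggregated with the chosen
    rule; the default is rank-weighted: sum(score/rank) / sum(1/rank).
    """
    path = Path(path)
    senses: dict[str, list[tuple[int, float, float]]] = defaultdict(list)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if len(parts) >= 5:  # native SentiWordNet layout
                pos_score, neg_score = float(parts[2]), float(parts[3])
                for entry in parts[4].split():
                    term, _, rank = entry.rpartition("#")
                    senses[term.lower()].append(
                        (int(rank) if rank.isdigit() else 1, pos_score, neg_score)
                    )
            elif len(parts) == 3:  # simplified term<TAB>pos<TAB>neg
                term = parts[0].strip().lower()
                senses[term].append((len(senses[term]) + 1, float(parts[1]), float(parts[2])))
            else:
                raise ValueError(f"expected 3 or >=5 columns, got {len(parts)}")
        except ValueError as exc:
            logger.warning("%s:%d: %s", path, lineno, exc)
    entries = {}
    for term, term_senses in senses.items():
        pos, neg = _aggregate(sorted(term_senses), aggregation)
        entries[term] = (min(pos, 1.0), min(neg, 1.0))
    return SentimentLexicon(entries)


def match_terms(
    tokens: Sequence[str], lex: TermLexicon, category: str
) -> Counter:
    """Count lexicon term occurrences by greedy longest-match, left to right.

    A matched span is consumed: shorter terms overlapping it are not
    counted again. Keys of the result are space-joined lexicon terms.
    """
    terms = {t for t in lex.terms(category)}
    if not terms:
        return Counter()
    max_len = max(len(t) for t in terms)
    counts: Counter = Counter()
    i, n = 0, len(tokens)
    while i < n:
        matched = 0
        for length in range(min(max_len, n - i), 0, -1):
            cand = tuple(tokens[i : i + length])
            if cand in terms:
                counts[" ".join(cand)] += 1
                matched = length
                break
        i += matched if matched else 1
    return counts


# ---------------------------------------------------------------------------
# Packaged default lexicons

def _data_path(name: str) -> Path:
    return Path(str(resources.files("stakeminer.data").joinpath(name)))


def default_medical_lexicon() -> TermLexicon:
    return load_term_lexicon(_data_path("medical_terms.tsv"))


def default_kinship_lexicon() -> TermLexicon:
    return load_term_lexicon(_data_path("kinship_terms.tsv"))


def default_term_lexicon() -> TermLexicon:
    """Medical + kinship terms in one lexicon."""
    return default_medical_lexicon().merged_with(default_kinship_lexicon())


def default_sentiment_lexicon() -> SentimentLexicon:
    """The packaged synthetic SentiWordNet-layout lexicon."""
    return load_sentiment_lexicon(_data_path("sentiment_synthetic.tsv"))
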