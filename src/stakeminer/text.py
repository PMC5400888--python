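"""Text normalization primitives shared by every module.

All token counting in the package (style features, n-grams, lexicon
matching, sentiment lookups) goes through :func:`tokenize`, so the
definition of a "word" is fixed in exactly one place: lowercase maximal
runs of Unicode letters/digits, with internal apostrophes kept
(``don't`` is one token). URLs and markup are treated as noise.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MARKUP_RE = re.compile(r"<[^>]{1,200}>")
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)

# Common abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = frozenset(
    "dr mr mrs ms st vs etc e.g i.e jr sr prof dept approx".split()
)
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def strip_noise(text: str) -> str:
    """Remove URLs and angle-bracket markup, collapse whitespace."""
    text = _URL_RE.sub(" ", text)
    text = _MARKUP_RE.sub(" ", text)
    return " ".join(text.split())


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: maximal runs of letters/digits/apostrophes."""
    return _TOKEN_RE.findall(text.lower())


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation (. ! ?), abbreviation-safe.

    A segment counts as a sentence only if it contains at least one word
    token; text without terminal punctuation is a single sentence.
    """
    # Shield abbreviation periods so they do not terminate a sentence.
    def _shield(m: re.Match) -> str:
        return m.group(1) + "\x00"

    shielded = re.sub(
        r"\b(" + "|".join(re.escape(a) for a in _ABBREVIATIONS) + r")\.",
        _shield,
        text,
        flags=re.IGNORECASE,
    )
    segments = _SENT_BOUNDARY_RE.split(shielded)
    out = []
    for seg in segments:
        seg = seg.replace("\x00", ".").strip()
        if seg and _TOKEN_RE.search(seg):
            out.append(seg)
    return out


def count_sentences(text: str) -> int:
    return len(split_sentences(text))


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """English function words packaged with the library."""
    raw = (
        resources.files("stakeminer.data").joinpath("stopwords.txt").read_text()
    )
    return frozenset(
        w.strip().lower() for w in raw.splitlines() if w.strip() and not w.startswith("#")
    )
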