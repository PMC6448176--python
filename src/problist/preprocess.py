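"""Minimal language-dependent normalization and character n-gram extraction.

The normalization chain mirrors a Lucene-style analyzer for very short
German clinical narratives: tokenize on non-word characters, lowercase,
remove stopwords, stem with the Snowball German stemmer, and finally strip
character spans matching a configurable regular expression (by default
digits, dots, commas, underscores and colons — dates, dose numbers and
similar context fragments).

German word compounds are not decompounded; instead documents are modelled
as bags of character n-grams (default n = 3) over the normalized token
stream, which also makes the representation robust to typing errors.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .stemmer import stem_german

__all__ = [
    "NormalizationConfig",
    "NgramDocument",
    "load_stopwords",
    "default_stopwords",
    "normalize",
    "char_ngrams",
    "DEFAULT_STRIP_PATTERN",
]

DEFAULT_STRIP_PATTERN = r"[\d\.\,\_\:]+"

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword list (one token per line, ``#`` comments, UTF-8)."""
    words = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                words.add(token.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The packaged German function-word list."""
    text = (
        resources.files("problist").joinpath("data/stopwords_de.txt").read_text("utf-8")
    )
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class NormalizationConfig:
    """Parameters of the normalization chain."""

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    stemmer_language: str = "german"
    strip_pattern: str = DEFAULT_STRIP_PATTERN
    ngram_size: int = 3

    def __post_init__(self) -> None:
        if self.ngram_size < 1:
            raise ValueError("ngram_size must be >= 1")
        if self.stemmer_language != "german":
            raise ValueError("only the German Snowball stemmer is available")
        re.compile(self.strip_pattern)  # must compile; raises re.error otherwise


@dataclass(frozen=True)
class NgramDocument:
    """Bag of character n-gram types with counts for one list item."""

    item_id: str
    grams: dict[str, int]

    def __post_init__(self) -> None:
        if any(count <= 0 for count in self.grams.values()):
            raise ValueError("gram counts must be positive")


def normalize(description: str, config: NormalizationConfig | None = None) -> list[str]:
    """Run the full normalization chain on one description.

    Order: tokenize -> lowercase -> stopword removal -> Snowball German
    stemming -> strip-pattern removal (matching spans deleted inside tokens,
    fully matched tokens dropped).  Empty input yields an empty list.
    """
    if config is None:
        config = NormalizationConfig()
    strip_re = re.compile(config.strip_pattern)
    tokens = _TOKEN_RE.findall(description.lower())
    tokens = [t for t in tokens if t not in config.stopwords]
    tokens = [stem_german(t) for t in tokens]
    stripped = [strip_re.sub("", t) for t in tokens]
    return [t for t in stripped if t]


def char_ngrams(tokens: Sequence[str], n: int = 3) -> dict[str, int]:
    """Sliding-window character n-grams per token, counts pooled over tokens.

    Windows never cross token boundaries and no padding is added; a token
    shorter than *n* is kept whole as a single gram so that short clinical
    abbreviations survive.
    """
    if n < 1:
        raise ValueError("n-gram size must be >= 1")
    counts: Counter[str] = Counter()
    for token in tokens:
        if len(token) < n:
            counts[token] += 1
        else:
            for i in range(len(token) - n + 1):
                counts[token[i : i + n]] += 1
    return dict(counts)


def ngram_document(
    item_id: str, description: str, config: NormalizationConfig | None = None
) -> NgramDocument:
    """Normalize one description and extract its n-gram bag."""
    if config is None:
        config = NormalizationConfig()
    return NgramDocument(
        item_id=item_id,
        grams=char_ngrams(normalize(description, config), config.ngram_size),
    )
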