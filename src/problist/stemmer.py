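"""Snowball stemming algorithm for German.

Implements the published Snowball German stemmer: prelude (ß → ss,
consonant-marking of intervocalic u/y), the R1/R2 region definitions with
the minimum three-letter prefix before R1, the three suffix-stripping steps,
and the postlude that strips umlaut diacritics.  Stemming is the one stage of
the normalization chain for which no suitable library is available, so the
algorithm is authored here; it is deliberately dependency-free.

Only lowercase input is meaningful (the normalization chain lowercases
before stemming); uppercase input is lowercased defensively.
"""

from __future__ import annotations

__all__ = ["stem_german"]

_VOWELS = frozenset("aeiouyäöü")
# consonants that may precede a deletable final 's' / 'st'
_S_ENDING = frozenset("bdfghklmnrt")
_ST_ENDING = frozenset("bdfghklmnt")


def _mark_consonant_uy(word: str) -> str:
    """Uppercase u/y between vowels so they are treated as consonants."""
    chars = list(word)
    for i in range(1, len(chars) - 1):
        if chars[i] in "uy" and chars[i - 1] in _VOWELS and chars[i + 1] in _VOWELS:
            chars[i] = chars[i].upper()
    return "".join(chars)


def _region_start(word: str, begin: int) -> int:
    """Index after the first non-vowel that follows a vowel, else len(word)."""
    i = begin
    n = len(word)
    while i < n and word[i] not in _VOWELS:
        i += 1
    while i < n and word[i] in _VOWELS:
        i += 1
    return i + 1 if i < n else n


def _step1(word: str, r1: int) -> str:
    for suffix in ("ern", "em", "er"):
        if word.endswith(suffix):
            if suffix == "em" and word[:-2].endswith("syst"):
                return word
            if len(word) - len(suffix) >= r1:
                word = word[: -len(suffix)]
            return word
    for suffix in ("en", "es", "e"):
        if word.endswith(suffix):
            if len(word) - len(suffix) >= r1:
                word = word[: -len(suffix)]
                if word.endswith("niss"):
                    word = word[:-1]
            return word
    if word.endswith("s"):
        if len(word) - 1 >= r1 and len(word) >= 2 and word[-2] in _S_ENDING:
            word = word[:-1]
    return word


def _step2(word: str, r1: int) -> str:
    if word.endswith("est"):
        if len(word) - 3 >= r1:
            word = word[:-3]
        return word
    for suffix in ("en", "er"):
        if word.endswith(suffix):
            if len(word) - 2 >= r1:
                word = word[:-2]
            return word
    if word.endswith("st"):
        # the st-ending consonant must itself be preceded by >= 3 letters
        if len(word) - 2 >= r1 and len(word) >= 6 and word[-3] in _ST_ENDING:
            word = word[:-2]
    return word


def _step3(word: str, r1: int, r2: int) -> str:
    for suffix in ("end", "ung"):
        if word.endswith(suffix):
            if len(word) - 3 >= r2:
                word = word[:-3]
                if (
                    word.endswith("ig")
                    and len(word) - 2 >= r2
                    and not word[:-2].endswith("e")
                ):
                    word = word[:-2]
            return word
    for suffix in ("isch", "ik", "ig"):
        if word.endswith(suffix):
            k = len(word) - len(suffix)
            if k >= r2 and not word[:k].endswith("e"):
                word = word[:k]
            return word
    for suffix in ("lich", "heit"):
        if word.endswith(suffix):
            if len(word) - 4 >= r2:
                word = word[:-4]
                for pre in ("er", "en"):
                    if word.endswith(pre) and len(word) - 2 >= r1:
                        word = word[:-2]
                        break
            return word
    if word.endswith("keit"):
        if len(word) - 4 >= r2:
            word = word[:-4]
            for pre in ("lich", "ig"):
                if word.endswith(pre) and len(word) - len(pre) >= r2:
                    word = word[: -len(pre)]
                    break
    return word


_POSTLUDE = str.maketrans({"U": "u", "Y": "y", "ä": "a", "ö": "o", "ü": "u"})


def stem_german(word: str) -> str:
    """Return the Snowball German stem of *word*."""
    word = word.lower().replace("ß", "ss")
    if len(word) <= 2:
        return word.translate(_POSTLUDE)
    word = _mark_consonant_uy(word)
    r1 = _region_start(word, 0)
    r2 = _region_start(word, r1)
    r1 = max(r1, 3)  # region before R1 spans at least three letters
    word = _step1(word, r1)
    word = _step2(word, r1)
    word = _step3(word, r1, r2)
    return word.translate(_POSTLUDE)
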