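"""Readability formulas: FORCAST, Flesch-Kincaid grade level, Flesch
Reading Ease.

FORCAST is designed for non-prose material (questionnaire items): it uses
only the monosyllabic-word rate, grade = 20 - N/10 where N is the number
of monosyllabic words per 150-word sample.  The Flesch formulas use words
per sentence and syllables per word.  Syllables are counted with a
vowel-group heuristic (silent final e, common suffixes) plus a small
exception lexicon; counts for unusual words may differ from commercial
tools, so published grade levels from such tools are approximated rather
than reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import re

__all__ = ["ReadabilityResult", "forcast", "flesch", "count_syllables"]

# words the heuristic would miscount
_SYLLABLE_EXCEPTIONS = {
    "people": 2, "area": 3, "being": 2, "quiet": 2, "science": 2,
    "create": 2, "idea": 3, "real": 1, "really": 2, "feeling": 2,
    "feelings": 2, "every": 2, "everything": 3, "interest": 3,
    "interesting": 4, "different": 3, "evening": 2, "business": 2,
    "usually": 4, "doesn": 2, "don": 1, "aren": 1, "isn": 1,
}

_VOWEL_GROUPS = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Heuristic syllable count for one word (minimum 1)."""
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 0
    if w in _SYLLABLE_EXCEPTIONS:
        return _SYLLABLE_EXCEPTIONS[w]
    groups = _VOWEL_GROUPS.findall(w)
    count = len(groups)
    # silent final e ("make", "close") but not "-le" endings ("little")
    if w.endswith("e") and not w.endswith(("le", "ee", "ye", "oe")) and count > 1:
        count -= 1
    # -ed after most consonants is silent ("helped", but not "needed")
    if w.endswith("ed") and not w.endswith(("ted", "ded")) and count > 1:
        count -= 1
    # "-ing" after a vowel starts a new syllable ("going", "seeing")
    if w.endswith("ing") and len(w) > 4 and w[-4] in "aeiou":
        count += 1
    return max(count, 1)


def _words(text: str) -> list[str]:
    return re.findall(r"[A-Za-z]+(?:'[A-Za-z]+)?", text)


def _sentences(text: str) -> int:
    parts = [s for s in re.split(r"[.!?]+", text) if s.strip()]
    return max(len(parts), 1)


@dataclasses.dataclass(frozen=True)
class ReadabilityResult:
    forcast_grade: float
    fkgl: float
    fre: float
    n_words: int
    n_sentences: int
    n_syllables: int
    n_monosyllabic: int
    short_sample: bool  # fewer than 150 words: FORCAST rate was scaled


def forcast(text: str) -> float:
    """FORCAST grade level: 20 - (monosyllabic words per 150 words)/10."""
    words = _words(text)
    if not words:
        raise ValueError("empty text")
    mono = sum(1 for w in words if count_syllables(w) == 1)
    rate = mono * 150.0 / len(words)
    return 20.0 - rate / 10.0


def flesch(text: str) -> tuple[float, float]:
    """(FKGL, FRE) for a text with at least one sentence.

    FKGL = 0.39 W/S + 11.8 Sy/W - 15.59;
    FRE = 206.835 - 1.015 W/S - 84.6 Sy/W.
    """
    words = _words(text)
    if not words:
        raise ValueError("no words in text")
    n_s = _sentences(text)
    syll = sum(count_syllables(w) for w in words)
    wps = len(words) / n_s
    spw = syll / len(words)
    fkgl = 0.39 * wps + 11.8 * spw - 15.59
    fre = 206.835 - 1.015 * wps - 84.6 * spw
    return fkgl, fre


def readability(text: str) -> ReadabilityResult:
    """Full readability battery for one text."""
    words = _words(text)
    if not words:
        raise ValueError("empty text")
    fkgl, fre = flesch(text)
    mono = sum(1 for w in words if count_syllables(w) == 1)
    return ReadabilityResult(
        forcast_grade=forcast(text),
        fkgl=fkgl,
        fre=fre,
        n_words=len(words),
        n_sentences=_sentences(text),
        n_syllables=sum(count_syllables(w) for w in words),
        n_monosyllabic=mono,
        short_sample=len(words) < 150,
    )
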