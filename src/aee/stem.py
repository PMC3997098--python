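"""Porter stemmer (the classic 1980 suffix-stripping algorithm).

Only the original algorithm is implemented — no extensions, no special-case
word lists.  Words shorter than three letters are returned unchanged, as in
the original description.  Input is lowercased before stemming.

``nonstem(word)`` returns the suffix that stemming removed (the part of the
lowercased word after its longest common prefix with the stem), used as a
lexical feature alongside the stem itself; it is empty when stemming leaves
the word unchanged.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences [C](VC)^m[V] -> m."""
    m = 0
    i = 0
    n = len(stem)
    while i < n and _is_consonant(stem, i):
        i += 1
    while i < n:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(stem, i):
            i += 1
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, replacement: str, min_measure: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure - 1:
        return stem + replacement
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem = word[:-3]
        return stem + "ee" if _measure(stem) > 0 else word
    applied = None
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        applied = word[:-2]
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        applied = word[:-3]
    if applied is None:
        return word
    if applied.endswith(("at", "bl", "iz")):
        return applied + "e"
    if _ends_double_consonant(applied) and applied[-1] not in "lsz":
        return applied[:-1]
    if _measure(applied) == 1 and _ends_cvc(applied):
        return applied + "e"
    return applied


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step2(word: str) -> str:
    for suffix, replacement in _STEP2:
        if word.endswith(suffix):
            out = _replace(word, suffix, replacement, 1)
            return out if out is not None else word
    return word


def _step3(word: str) -> str:
    for suffix, replacement in _STEP3:
        if word.endswith(suffix):
            out = _replace(word, suffix, replacement, 1)
            return out if out is not None else word
    return word


def _step4(word: str) -> str:
    for suffix in _STEP4:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                return word
            return stem if _measure(stem) > 1 else word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if _measure(word) > 1 and _ends_double_consonant(word) and word.endswith("l"):
        return word[:-1]
    return word


def stem(word: str) -> str:
    """Porter stem of ``word`` (lowercased before stemming)."""
    word = word.lower()
    if len(word) <= 2:
        return word
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4, _step5a, _step5b):
        word = step(word)
    return word


def nonstem(word: str) -> str:
    """Suffix removed by stemming: the part of the word the stem drops.

    Computed as the remainder of the lowercased word after its longest
    common prefix with the stem, so rewritten endings (``happy`` ->
    ``happi``) still yield the changed tail (``y``).
    """
    lowered = word.lower()
    stemmed = stem(word)
    i = 0
    while i < min(len(lowered), len(stemmed)) and lowered[i] == stemmed[i]:
        i += 1
    return lowered[i:]
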