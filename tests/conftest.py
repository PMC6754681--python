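import pytest

from lexiscreen.lexicon import (
    Category,
    Language,
    Lexicon,
    LexiconEntry,
    VariantKind,
)


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    """Small hand-built lexicon with a pronoun, an emoticon and a phrase."""
    return Lexicon(
        [
            LexiconEntry("sad", Category.MOOD),
            LexiconEntry("tired", Category.FATIGUE),
            LexiconEntry("i", Category.FIRST_PERSON_PRONOUN),
            LexiconEntry("myself", Category.FIRST_PERSON_PRONOUN),
            LexiconEntry(":(", Category.MOOD, Language.MIXED, VariantKind.EMOTICON),
            LexiconEntry("no sleep", Category.SLEEP),
        ]
    )


def brute_force_match(text: str, lexicon: Lexicon) -> dict:
    """Independent oracle: try every lexicon surface at every character
    position (longest surface wins, scanning left to right), then count the
    remaining single words by membership."""
    import re

    counts: dict = {}
    surfaces = sorted(lexicon.surfaces(), key=len, reverse=True)
    special = [s for s in surfaces if re.search(r"[^\w']", s)]
    low = text.lower()
    consumed = [False] * len(low)
    for s in special:
        start = 0
        while True:
            idx = low.find(s, start)
            if idx == -1:
                break
            if any(consumed[idx : idx + len(s)]):
                start = idx + 1
                continue
            # word-boundary guard for word-edged surfaces
            ok = True
            if re.match(r"\w", s[0]) and idx > 0 and re.match(r"\w", low[idx - 1]):
                ok = False
            end = idx + len(s)
            if re.match(r"\w", s[-1]) and end < len(low) and re.match(r"\w", low[end]):
                ok = False
            if ok:
                for k in range(idx, end):
                    consumed[k] = True
                cat = lexicon.category_of(s)
                counts[cat] = counts.get(cat, 0) + 1
                start = end
            else:
                start = idx + 1
    remainder = "".join(
        c if not consumed[k] else " " for k, c in enumerate(low)
    )
    for w in re.findall(r"[^\W_]+(?:'[^\W_]+)*", remainder):
        cat = lexicon.category_of(w)
        if cat is not None:
            counts[cat] = counts.get(cat, 0) + 1
    return counts
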