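"""Match free text against a small depression lexicon.

Builds a six-entry lexicon (a mood word, a fatigue word, two first-person
pronouns, an emoticon and a sleep phrase) and counts keyword occurrences in
a couple of messages.  Every matched occurrence adds one point to the total
and to its category's tally.
"""

from lexiscreen import Category, Lexicon, LexiconEntry, match_text
from lexiscreen.lexicon import Language, VariantKind

lexicon = Lexicon(
    [
        LexiconEntry("sad", Category.MOOD),
        LexiconEntry("tired", Category.FATIGUE),
        LexiconEntry("i", Category.FIRST_PERSON_PRONOUN),
        LexiconEntry("myself", Category.FIRST_PERSON_PRONOUN),
        LexiconEntry(":(", Category.MOOD, Language.MIXED, VariantKind.EMOTICON),
        LexiconEntry("no sleep", Category.SLEEP),
    ]
)

for text in ["I am so sad today :(", "no sleep again, tired tired", "all good!"]:
    m = match_text(text, lexicon)
    cats = {c.value: n for c, n in m.per_category.items()}
    print(f"{text!r:40} -> total={m.total} {cats}")

# The total is the building block of the screening score: summed over a
# participant's days it becomes the windowed total score.
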