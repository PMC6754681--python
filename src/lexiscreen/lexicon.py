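"""Depression lexicon representation and free-text matching.

The screening method rests on a categorized keyword inventory: 13 depressive
symptom categories derived from DSM/ICD criteria plus a first-person-pronoun
category capturing self-focus. Each keyword (a *surface form*) may be a plain
word, a multi-word phrase, an SMS-style shortening ("textolog"), a spelling
variant, or an emoticon, in English or Tagalog. Matching is exact on
normalized tokens: the lexicon itself enumerates derivatives and variants, so
morphology is the lexicon's job, not the matcher's.

Scoring is occurrence counting — every token whose normalized form appears in
the lexicon contributes one point to the total and to its category's tally.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Category",
    "SYMPTOM_CATEGORIES",
    "Language",
    "VariantKind",
    "LexiconEntry",
    "Lexicon",
    "TextEvent",
    "MatchResult",
    "LexiconError",
    "normalize_token",
    "tokenize",
    "match_text",
    "load_lexicon",
    "load_events",
]


class LexiconError(ValueError):
    """Malformed lexicon content or malformed token input."""


class Category(str, Enum):
    """The 13 symptom categories plus first-person pronouns (self-focus)."""

    MOOD = "mood"
    INTEREST = "interest"
    APPETITE_WEIGHT = "appetite_weight"
    SLEEP = "sleep"
    PSYCHOMOTOR_AGITATION = "psychomotor_agitation"
    PSYCHOMOTOR_RETARDATION = "psychomotor_retardation"
    FATIGUE = "fatigue"
    GUILT_SELF_ESTEEM = "guilt_self_esteem"
    CONCENTRATION = "concentration"
    SUICIDE = "suicide"
    ALCOHOL_SUBSTANCE = "alcohol_substance"
    ANXIETY = "anxiety"
    HISTRIONIC = "histrionic"
    FIRST_PERSON_PRONOUN = "first_person_pronoun"


#: The 13 clinical symptom categories (everything except pronouns).
SYMPTOM_CATEGORIES: tuple[Category, ...] = tuple(
    c for c in Category if c is not Category.FIRST_PERSON_PRONOUN
)


class Language(str, Enum):
    EN = "en"
    TL = "tl"
    MIXED = "mixed"


class VariantKind(str, Enum):
    MAIN = "main"
    DERIVATIVE = "derivative"
    SPELLING_VARIANT = "spelling_variant"
    TEXTOLOG = "textolog"
    EMOTICON = "emoticon"


# Word characters for tokenisation: unicode letters/digits plus apostrophes
# inside words ("can't").  Everything else separates tokens.
_WORD_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)
_EDGE_STRIP_RE = re.compile(
    r"^[\W_]+(?=.*[^\W_])|(?<=[^\W_])[\W_]+$", re.UNICODE
)


def normalize_token(raw: str) -> str:
    """Normalize a single token: lower-case, strip surrounding punctuation.

    Internal apostrophes are retained ("can't" stays "can't").  Tokens made
    entirely of symbols (emoticons such as ``:(``) are lower-cased but
    otherwise kept verbatim.  Idempotent.

    Raises
    ------
    LexiconError
        If ``raw`` is empty or whitespace-only.
    """
    if not raw or not raw.strip():
        raise LexiconError("cannot normalize an empty token")
    tok = raw.strip().lower()
    # Strip leading/trailing non-word chars only when a word core exists;
    # a pure-symbol token (emoticon) must survive untouched.
    tok = _EDGE_STRIP_RE.sub("", tok)
    # Normalize curly apostrophe to ASCII so variants collapse.
    return tok.replace("’", "'")


def _is_plain_word(surface: str) -> bool:
    """True when the surface is a single ordinary word (no pre-pass needed)."""
    return _WORD_RE.fullmatch(surface) is not None


@dataclass(frozen=True)
class LexiconEntry:
    """One keyword: a normalized surface form assigned to a single category."""

    surface: str
    category: Category
    language: Language = Language.EN
    variant_kind: VariantKind = VariantKind.MAIN

    def __post_init__(self) -> None:
        if not self.surface:
            raise LexiconError("lexicon surface form must be non-empty")
        norm = _normalize_surface(self.surface)
        if norm != self.surface:
            raise LexiconError(
                f"surface {self.surface!r} is not in normalized form "
                f"(expected {norm!r})"
            )


def _normalize_surface(surface: str) -> str:
    """Normalize a lexicon surface: per-word normalization, single spaces."""
    parts = surface.split()
    if not parts:
        raise LexiconError("lexicon surface form must be non-empty")
    return " ".join(normalize_token(p) for p in parts)


class Lexicon:
    """A validated keyword inventory with a surface -> category index.

    Each surface form maps to exactly one category; the loader rejects
    cross-category duplicates so that per-word scoring stays well defined.
    Lookup is case-insensitive by construction (surfaces are normalized).
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        self._index: dict[str, Category] = {}
        self._special: list[str] = []  # multi-word / symbol surfaces
        for e in entries:
            prev = self._index.get(e.surface)
            if prev is not None:
                if prev is not e.category:
                    raise LexiconError(
                        f"surface {e.surface!r} assigned to both "
                        f"{prev.value!r} and {e.category.value!r}"
                    )
                continue  # exact duplicate after normalization: keep first
            self.entries.append(e)
            self._index[e.surface] = e.category
            if not _is_plain_word(e.surface):
                self._special.append(e.surface)
        self._special.sort(key=len, reverse=True)
        self._special_re = self._build_special_re()

    def _build_special_re(self) -> re.Pattern[str] | None:
        if not self._special:
            return None
        parts = []
        for s in self._special:
            pat = re.escape(s).replace(r"\ ", r"\s+")
            # word-boundary guard only where the surface edge is a word char,
            # so emoticons still match flush against text
            if _WORD_RE.match(s[0]):
                pat = r"\b" + pat
            if _WORD_RE.match(s[-1]):
                pat = pat + r"\b"
            parts.append(pat)
        return re.compile("|".join(parts), re.IGNORECASE | re.UNICODE)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return surface in self._index

    def category_of(self, surface: str) -> Category | None:
        return self._index.get(surface)

    @property
    def index(self) -> dict[str, Category]:
        return dict(self._index)

    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]

    def to_tsv(self) -> str:
        """Serialize to the on-disk TSV format (surface/category/language/variant_kind)."""
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(["surface", "category", "language", "variant_kind"])
        for e in self.entries:
            w.writerow(
                [e.surface, e.category.value, e.language.value, e.variant_kind.value]
            )
        return buf.getvalue()


@dataclass(frozen=True)
class TextEvent:
    """One timestamped free-text input from a participant.

    Participants are identified by opaque number codes, never by name; the
    timestamp must carry a UTC offset so events can be bucketed into local
    calendar days downstream.
    """

    participant_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError(
                f"event for {self.participant_id!r} has a naive timestamp; "
                "an explicit UTC offset is required"
            )


@dataclass
class MatchResult:
    """Counts of lexicon hits in one piece of text.

    ``total`` equals the sum of ``per_category`` by construction; every
    matched token occurrence counts once (occurrence counting, not
    unique-word counting).
    """

    total: int
    per_category: dict[Category, int]
    matched_tokens: list[tuple[str, Category]] = field(default_factory=list)


def tokenize(text: str, lexicon: Lexicon) -> list[str]:
    """Split raw text into normalized-comparable tokens, lexicon-aware.

    Emoticon and multi-word surfaces present in the lexicon are extracted
    first by greedy longest-match, left to right, non-overlapping (plain
    punctuation splitting would destroy them); the remaining text is split
    on whitespace and punctuation.  Output order follows text order.
    """
    if not text:
        return []
    pieces: list[tuple[int, str]] = []
    spans: list[tuple[int, int]] = []
    if lexicon._special_re is not None:
        for m in lexicon._special_re.finditer(text):
            spans.append(m.span())
            pieces.append((m.start(), _normalize_surface(m.group(0))))
    pos = 0
    for start, end in spans + [(len(text), len(text))]:
        segment = text[pos:start]
        for m in _WORD_RE.finditer(segment):
            pieces.append((pos + m.start(), m.group(0)))
        pos = end
    pieces.sort(key=lambda p: p[0])
    return [tok for _, tok in pieces]


def match_text(
    text: str, lexicon: Lexicon, include_pronouns: bool = True
) -> MatchResult:
    """Count lexicon keyword occurrences in ``text``.

    Every token whose normalized form is in the lexicon contributes exactly
    one point to the total and to its category's count; repeats each count.
    ``include_pronouns=False`` drops first-person-pronoun hits entirely (the
    total score is defined over all matched words regardless of category, so
    pronouns are included by default).
    """
    per_category: dict[Category, int] = {}
    matched: list[tuple[str, Category]] = []
    for tok in tokenize(text, lexicon):
        norm = normalize_token(tok)
        cat = lexicon.category_of(norm)
        if cat is None:
            continue
        if not include_pronouns and cat is Category.FIRST_PERSON_PRONOUN:
            continue
        per_category[cat] = per_category.get(cat, 0) + 1
        matched.append((norm, cat))
    return MatchResult(
        total=sum(per_category.values()),
        per_category=per_category,
        matched_tokens=matched,
    )


_REQUIRED_COLUMNS = ("surface", "category", "language", "variant_kind")


def load_lexicon(source) -> Lexicon:
    """Load and validate a lexicon from TSV (path, file object, or content).

    Expected columns: ``surface  category  language  variant_kind`` (UTF-8,
    tab-separated).  Surfaces are normalized on load; rows that collapse to
    the same surface within one category deduplicate silently, while a
    cross-category duplicate is an error because it would make per-word
    scoring ambiguous.
    """
    if hasattr(source, "read"):
        content = source.read()
    else:
        text = str(source)
        if "\t" in text or "\n" in text:
            content = text
        else:
            with open(text, encoding="utf-8") as fh:
                content = fh.read()
    reader = csv.DictReader(io.StringIO(content), delimiter="\t")
    if reader.fieldnames is None:
        raise LexiconError("empty lexicon file")
    missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise LexiconError(f"lexicon TSV is missing columns: {missing}")
    entries: list[LexiconEntry] = []
    for lineno, row in enumerate(reader, start=2):
        surface = (row.get("surface") or "").strip()
        if not surface:
            raise LexiconError(f"line {lineno}: empty surface form")
        try:
            category = Category(row["category"].strip())
        except ValueError:
            raise LexiconError(
                f"line {lineno}: unknown category {row['category']!r} "
                f"for surface {surface!r}"
            ) from None
        try:
            language = Language((row.get("language") or "en").strip())
            variant = VariantKind((row.get("variant_kind") or "main").strip())
        except ValueError as exc:
            raise LexiconError(f"line {lineno}: {exc}") from None
        entries.append(
            LexiconEntry(_normalize_surface(surface), category, language, variant)
        )
    if not entries:
        raise LexiconError("lexicon file contains no entries")
    return Lexicon(entries)


def load_events(source) -> list[TextEvent]:
    """Read a JSONL event log: ``{participant_id, timestamp, text}`` per line.

    Timestamps must be ISO-8601 with a UTC offset; an unparseable record is
    reported by line number.
    """
    import json

    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    events: list[TextEvent] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            ts = datetime.fromisoformat(rec["timestamp"])
            ev = TextEvent(str(rec["participant_id"]), ts, str(rec["text"]))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"event log line {lineno}: {exc}") from None
        events.append(ev)
    return events


def events_to_jsonl(events: Sequence[TextEvent]) -> str:
    """Serialize events to the JSONL interchange format."""
    import json

    out = []
    for e in events:
        out.append(
            json.dumps(
                {
                    "participant_id": e.participant_id,
                    "timestamp": e.timestamp.isoformat(),
                    "text": e.text,
                },
                ensure_ascii=False,
            )
        )
    return "\n".join(out) + ("\n" if out else "")
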