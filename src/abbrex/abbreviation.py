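"""The abbreviation algebra for abbreviated text entry.

A phrase is abbreviated one segment per word.  Four segment kinds exist:

* ``INITIAL`` -- a single letter, the word's initial (case-insensitive).
  Contractions ("you're") contribute only their initial.
* ``KEYWORD_FULL`` -- the word spelled out completely.
* ``KEYWORD_PREFIX`` -- two or more characters forming a prefix of the word.
* ``KEYWORD_CONSONANT`` -- two or more characters forming a prefix of the
  word's consonant skeleton (vowels dropped except word-initially).

Mid-sentence punctuation (by default ``, ; :``) adjacent to a word is kept in
the abbreviation; sentence-final punctuation (``. ! ?``) is dropped.  Example:
``"ok, sounds good"`` abbreviates (initials, compact form) to ``"o,sd"``.

Two string dialects are defined.  COMPACT is the display form: runs of
initials are concatenated and keywords are space-delimited
(``"ishpit bedroom"``).  SPACED is the serialization form used for model
training data: one space between every segment (``"i s h p i t bedroom"``).
Free-string parsing is only supported for SPACED, because COMPACT is
ambiguous without a reference phrase; :func:`validate_shorthand` resolves the
ambiguity against a known phrase by backtracking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .errors import ParseError, ValidationError

__all__ = [
    "SegmentKind",
    "AbbrevSegment",
    "Abbreviation",
    "PunctuationConvention",
    "RenderStyle",
    "WordToken",
    "tokenize_phrase",
    "word_initial",
    "consonant_skeleton",
    "abbreviate_initials",
    "abbreviate_with_keywords",
    "render",
    "parse_spaced",
    "matches",
    "validate_shorthand",
]

VOWELS = frozenset("aeiou")


class SegmentKind(enum.Enum):
    INITIAL = "initial"
    KEYWORD_FULL = "keyword_full"
    KEYWORD_PREFIX = "keyword_prefix"
    KEYWORD_CONSONANT = "keyword_consonant"


class RenderStyle(enum.Enum):
    COMPACT = "compact"
    SPACED = "spaced"


@dataclass(frozen=True)
class PunctuationConvention:
    """Which punctuation is kept in abbreviations and which is dropped.

    ``mid_sentence`` marks are preserved attached to the preceding word;
    ``sentence_final`` marks are omitted from abbreviations.  The two sets
    must be disjoint.
    """

    mid_sentence: frozenset[str] = frozenset(",;:")
    sentence_final: frozenset[str] = frozenset(".!?")

    def __post_init__(self) -> None:
        if self.mid_sentence & self.sentence_final:
            raise ValidationError("mid-sentence and sentence-final punctuation sets overlap")

    @property
    def all_punct(self) -> frozenset[str]:
        return self.mid_sentence | self.sentence_final


DEFAULT_CONVENTION = PunctuationConvention()


@dataclass(frozen=True)
class AbbrevSegment:
    """One word's contribution to an abbreviation."""

    word_index: int
    kind: SegmentKind
    typed: str
    trailing_punct: str = ""

    def __post_init__(self) -> None:
        if not self.typed:
            raise ValidationError("segment typed text must be non-empty")
        if self.typed != self.typed.lower():
            raise ValidationError("segment typed text must be lowercase")
        if self.kind is SegmentKind.INITIAL and len(self.typed) != 1:
            raise ValidationError("INITIAL segments carry exactly one character")
        if self.kind in (SegmentKind.KEYWORD_PREFIX, SegmentKind.KEYWORD_CONSONANT) and len(self.typed) < 2:
            raise ValidationError(f"{self.kind.name} requires two or more typed characters")

    @property
    def typed_chars(self) -> int:
        return len(self.typed)


@dataclass(frozen=True)
class Abbreviation:
    """Ordered segments, one per word of the target phrase."""

    segments: tuple[AbbrevSegment, ...]
    convention: PunctuationConvention = field(default=DEFAULT_CONVENTION, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("abbreviation must have at least one segment")
        indices = [s.word_index for s in self.segments]
        if indices != list(range(len(self.segments))):
            raise ValidationError("segment word indices must be 0..n-1 in order")
        for seg in self.segments:
            if any(c not in self.convention.mid_sentence for c in seg.trailing_punct):
                raise ValidationError(f"trailing punctuation {seg.trailing_punct!r} outside the mid-sentence set")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def typed_chars(self) -> int:
        """Characters the user types, excluding punctuation."""
        return sum(s.typed_chars for s in self.segments)

    @property
    def key_count(self) -> int:
        """Keystrokes to enter this abbreviation (typed chars + punctuation)."""
        return sum(s.typed_chars + len(s.trailing_punct) for s in self.segments)

    def with_segment(self, index: int, segment: AbbrevSegment) -> "Abbreviation":
        segs = list(self.segments)
        segs[index] = segment
        return replace(self, segments=tuple(segs))


# ---------------------------------------------------------------------------
# phrase tokenization


@dataclass(frozen=True)
class WordToken:
    """A whitespace word of a phrase, split into core and kept punctuation.

    ``core`` is the raw word with trailing punctuation removed (case and
    apostrophes preserved); ``trailing_punct`` holds the mid-sentence marks
    that followed it.  Sentence-final marks are dropped at tokenization.
    """

    core: str
    trailing_punct: str = ""

    @property
    def norm(self) -> str:
        return self.core.lower()


def tokenize_phrase(phrase: str, convention: PunctuationConvention = DEFAULT_CONVENTION) -> list[WordToken]:
    """Split a phrase into :class:`WordToken` items.

    Words are whitespace-delimited; hyphenated tokens are single words.  A
    bare punctuation token attaches to the preceding word.  Sentence-final
    punctuation is dropped wherever it occurs.
    """
    tokens: list[WordToken] = []
    for raw in phrase.split():
        core = raw
        tail: list[str] = []
        while core and core[-1] in convention.all_punct:
            tail.append(core[-1])
            core = core[:-1]
        kept = "".join(c for c in reversed(tail) if c in convention.mid_sentence)
        if not core:
            if not kept:
                continue  # token was sentence-final punctuation only
            if not tokens:
                raise ValidationError(f"phrase {phrase!r} starts with bare punctuation")
            prev = tokens[-1]
            tokens[-1] = WordToken(prev.core, prev.trailing_punct + kept)
            continue
        tokens.append(WordToken(core, kept))
    return tokens


def word_initial(core: str) -> str | None:
    """The first alphanumeric character of a word, lowercased."""
    for c in core:
        if c.isalnum():
            return c.lower()
    return None


def consonant_skeleton(word: str) -> str:
    """Lowercase the word, keep its first letter, drop later vowels.

    ``"bedroom"`` -> ``"bdrm"``; ``"in"`` -> ``"in"`` (initial vowel kept);
    ``"aeiou"`` -> ``"a"``.  Non-letter characters such as apostrophes are
    not vowels and are kept.
    """
    if not any(c.isalpha() for c in word):
        raise ValidationError(f"word {word!r} has no alphabetic character")
    w = word.lower()
    return w[0] + "".join(c for c in w[1:] if c not in VOWELS)


# ---------------------------------------------------------------------------
# construction


def _initial_segment(index: int, token: WordToken) -> AbbrevSegment:
    initial = word_initial(token.core)
    if initial is None:
        raise ValidationError(f"word {token.core!r} has no alphanumeric character to abbreviate")
    return AbbrevSegment(index, SegmentKind.INITIAL, initial, token.trailing_punct)


def abbreviate_initials(phrase: str, convention: PunctuationConvention = DEFAULT_CONVENTION) -> Abbreviation:
    """Initials-only abbreviation of a phrase.

    One INITIAL segment per word; mid-sentence punctuation stays attached;
    sentence-final punctuation is dropped; a contraction contributes only its
    initial letter ("you're" -> "y").
    """
    if not phrase.strip():
        raise ValidationError("phrase must be non-empty")
    tokens = tokenize_phrase(phrase, convention)
    if not tokens:
        raise ValidationError(f"phrase {phrase!r} contains no abbreviatable word")
    return Abbreviation(
        tuple(_initial_segment(i, t) for i, t in enumerate(tokens)),
        convention,
    )


def abbreviate_with_keywords(
    phrase: str,
    keyword_spec: dict[int, tuple[SegmentKind, int | None]],
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> Abbreviation:
    """Abbreviation with selected words spelled fully or partially.

    ``keyword_spec`` maps word index to ``(kind, typed_length)``; the length
    is ignored for KEYWORD_FULL.  Prefixes require two or more characters and
    at most the word length; consonant shorthands two or more characters and
    at most the skeleton length.
    """
    tokens = tokenize_phrase(phrase, convention)
    if not tokens:
        raise ValidationError(f"phrase {phrase!r} contains no abbreviatable word")
    segments: list[AbbrevSegment] = []
    for i, tok in enumerate(tokens):
        if i not in keyword_spec:
            segments.append(_initial_segment(i, tok))
            continue
        kind, length = keyword_spec[i]
        core = tok.norm
        if kind is SegmentKind.KEYWORD_FULL:
            typed = core
        elif kind is SegmentKind.KEYWORD_PREFIX:
            if length is None or length < 2:
                raise ValidationError("keyword prefixes require two or more characters")
            if length > len(core):
                raise ValidationError(f"prefix length {length} exceeds word {core!r}")
            typed = core[:length]
        elif kind is SegmentKind.KEYWORD_CONSONANT:
            skeleton = consonant_skeleton(core)
            if length is None or length < 2:
                raise ValidationError("consonant shorthands require two or more characters")
            if length > len(skeleton):
                raise ValidationError(f"consonant length {length} exceeds skeleton {skeleton!r}")
            typed = skeleton[:length]
        else:
            raise ValidationError(f"cannot request kind {kind} as a keyword")
        segments.append(AbbrevSegment(i, kind, typed, tok.trailing_punct))
    bad = set(keyword_spec) - set(range(len(tokens)))
    if bad:
        raise ValidationError(f"keyword indices {sorted(bad)} out of range for {len(tokens)} words")
    return Abbreviation(tuple(segments), convention)


# ---------------------------------------------------------------------------
# rendering and parsing


def render(abbrev: Abbreviation, style: RenderStyle = RenderStyle.COMPACT) -> str:
    """Serialize an abbreviation to one of the two string dialects."""
    if style is RenderStyle.SPACED:
        return " ".join(s.typed + s.trailing_punct for s in abbrev)
    # COMPACT: concatenate runs of initials, space-delimit keywords.
    chunks: list[str] = []
    run = ""
    for seg in abbrev:
        if seg.kind is SegmentKind.INITIAL:
            run += seg.typed + seg.trailing_punct
        else:
            if run:
                chunks.append(run)
                run = ""
            chunks.append(seg.typed + seg.trailing_punct)
    if run:
        chunks.append(run)
    return " ".join(chunks)


def _split_token(token: str, convention: PunctuationConvention) -> tuple[str, str]:
    core = token
    punct = ""
    while core and core[-1] in convention.mid_sentence:
        punct = core[-1] + punct
        core = core[:-1]
    return core, punct


def parse_spaced(shorthand: str, convention: PunctuationConvention = DEFAULT_CONVENTION) -> Abbreviation:
    """Parse the SPACED dialect back into an :class:`Abbreviation`.

    Single-letter tokens become INITIAL segments; longer tokens become
    KEYWORD_PREFIX (promotion to KEYWORD_FULL needs a reference phrase, see
    :func:`validate_shorthand`).
    """
    if not shorthand.strip():
        raise ParseError("empty shorthand")
    segments: list[AbbrevSegment] = []
    for i, token in enumerate(shorthand.split(" ")):
        if not token:
            raise ParseError(f"empty token at position {i} in {shorthand!r}")
        core, punct = _split_token(token, convention)
        if not core:
            raise ParseError(f"token {token!r} has no typed characters")
        if any(not (c.isalnum() or c == "'") for c in core):
            raise ParseError(f"token {token!r} contains interior punctuation")
        kind = SegmentKind.INITIAL if len(core) == 1 else SegmentKind.KEYWORD_PREFIX
        segments.append(AbbrevSegment(i, kind, core.lower(), punct))
    return Abbreviation(tuple(segments), convention)


# ---------------------------------------------------------------------------
# matching and validation


def _segment_consistent(seg: AbbrevSegment, word: str, *, promote: bool = False) -> bool:
    """Is ``seg`` consistent with the (normalized) ``word``?

    With ``promote`` a keyword segment may match as full, prefix, or
    consonant-prefix regardless of its declared kind (used when the kind was
    lost in serialization).
    """
    if seg.kind is SegmentKind.INITIAL:
        return word_initial(word) == seg.typed
    if promote:
        try:
            skel = consonant_skeleton(word)
        except ValidationError:
            skel = ""
        return word == seg.typed or word.startswith(seg.typed) or skel.startswith(seg.typed)
    if seg.kind is SegmentKind.KEYWORD_FULL:
        return word == seg.typed
    if seg.kind is SegmentKind.KEYWORD_PREFIX:
        return word.startswith(seg.typed)
    if seg.kind is SegmentKind.KEYWORD_CONSONANT:
        try:
            return consonant_skeleton(word).startswith(seg.typed)
        except ValidationError:
            return False
    raise AssertionError(seg.kind)


def matches(
    abbrev: Abbreviation,
    phrase: str,
    convention: PunctuationConvention | None = None,
    *,
    require_punct: bool = True,
) -> bool:
    """Is ``phrase`` a valid expansion of ``abbrev``?

    Word counts must agree and each segment must be consistent with its word
    under its declared kind (case-insensitive).  With ``require_punct`` each
    segment's trailing punctuation must equal the word's; predictor options
    live in punctuation-stripped space and are checked with it off.
    """
    conv = convention or abbrev.convention
    try:
        tokens = tokenize_phrase(phrase, conv)
    except ValidationError:
        return False
    if len(tokens) != len(abbrev):
        return False
    for seg, tok in zip(abbrev, tokens):
        if require_punct and seg.trailing_punct != tok.trailing_punct:
            return False
        if not _segment_consistent(seg, tok.norm):
            return False
    return True


def validate_shorthand(
    shorthand: str,
    phrase: str,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> bool:
    """Does ``shorthand`` (COMPACT or SPACED dialect) abbreviate ``phrase``?

    Keyword tokens are accepted as full words, prefixes, or consonant
    shorthands of the aligned word.  COMPACT runs of initials are resolved by
    backtracking: a multi-letter token may be either one keyword or a run of
    initials, e.g. in "i saw hpit bedroom" the token "saw" is a keyword while
    "hpit" is four initials.
    """
    try:
        tokens = [t for t in shorthand.split() if t]
        if not tokens:
            return False
        words = tokenize_phrase(phrase, convention)
    except (ValidationError, ParseError):
        return False
    split = [_split_token(t, convention) for t in tokens]

    def kw_seg(core: str, punct: str) -> AbbrevSegment | None:
        if len(core) < 2 or any(not (c.isalnum() or c == "'") for c in core):
            return None
        return AbbrevSegment(0, SegmentKind.KEYWORD_PREFIX, core.lower(), punct)

    def consume_initials(core: str, punct: str, wi: int) -> int | None:
        """Match a compact initials run starting at word ``wi``; return the
        next word index or None."""
        text = core.lower() + punct
        pos = 0
        while pos < len(text):
            if wi >= len(words):
                return None
            tok = words[wi]
            if word_initial(tok.core) != text[pos]:
                return None
            pos += 1
            if text[pos : pos + len(tok.trailing_punct)] != tok.trailing_punct:
                return None
            pos += len(tok.trailing_punct)
            wi += 1
        return wi

    memo: dict[tuple[int, int], bool] = {}

    def align(ti: int, wi: int) -> bool:
        if (ti, wi) in memo:
            return memo[ti, wi]
        if ti == len(tokens):
            result = wi == len(words)
        else:
            result = False
            core, punct = split[ti]
            if core:
                # option 1: this token is a keyword for exactly one word
                seg = kw_seg(core, punct)
                if (
                    seg is not None
                    and wi < len(words)
                    and punct == words[wi].trailing_punct
                    and _segment_consistent(seg, words[wi].norm, promote=True)
                    and align(ti + 1, wi + 1)
                ):
                    result = True
                # option 2: this token is a run of initials
                if not result:
                    nxt = consume_initials(core, punct, wi)
                    if nxt is not None and align(ti + 1, nxt):
                        result = True
        memo[ti, wi] = result
        return result

    return align(0, 0)
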