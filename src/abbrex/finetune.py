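"""Synthesis of training/evaluation triplets from a dialogue corpus.

Two triplet kinds are produced, one per prediction task:

* abbreviation-expansion triplets ``{context, shorthand, full}`` where the
  shorthand is the SPACED dialect (one space between every letter and
  keyword) of one of the four abbreviation schemes, and the context is the
  prior turns each wrapped in curly braces;
* fill-mask triplets ``{context, phrase_with_mask, word}`` where exactly one
  word of the turn is replaced by its initial letter plus ``_`` (surrounding
  punctuation intact), e.g. ``"Oh, I'm s_."`` masking ``"sorry"``.  Words
  starting with a digit or punctuation mark are never masked.

No model training happens here; this is data construction only.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .abbreviation import (
    DEFAULT_CONVENTION,
    PunctuationConvention,
    RenderStyle,
    SegmentKind,
    abbreviate_initials,
    abbreviate_with_keywords,
    consonant_skeleton,
    render,
    tokenize_phrase,
    validate_shorthand,
)
from .corpus import Dialogue
from .errors import ValidationError

__all__ = [
    "AETriplet",
    "FillMaskTriplet",
    "SynthesisConfig",
    "SCHEMES",
    "context_string",
    "synthesize_ae",
    "synthesize_fillmask",
    "write_triplets",
    "read_triplets",
]

logger = logging.getLogger(__name__)

SCHEMES = ("initials", "complete_keywords", "prefix_keywords", "consonant_keywords")


@dataclass(frozen=True)
class AETriplet:
    context: str
    shorthand: str  # SPACED dialect
    full: str


@dataclass(frozen=True)
class FillMaskTriplet:
    context: str
    phrase_with_mask: str
    word: str


@dataclass(frozen=True)
class SynthesisConfig:
    """Which schemes to emit and how keyword positions/lengths are sampled.

    Keywords per variant are drawn uniformly from ``keyword_counts``,
    positions uniformly without replacement, prefix lengths uniformly from
    2..len-1 and consonant lengths from 2..skeleton length.  The mixing
    proportions of the reference fine-tuning set are not public; these
    defaults are placeholders and fully configurable.
    """

    schemes: tuple[str, ...] = SCHEMES
    keyword_counts: tuple[int, ...] = (1, 2)
    include_no_context_fillmask: bool = True
    masks_per_turn: int | None = 1  # None = every maskable position
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValidationError(f"unknown schemes {sorted(unknown)}")
        if not self.keyword_counts or min(self.keyword_counts) < 1:
            raise ValidationError("keyword_counts must be positive")
        if self.masks_per_turn is not None and self.masks_per_turn < 1:
            raise ValidationError("masks_per_turn must be >= 1 or None")


def context_string(dialogue: Dialogue, turn_index: int) -> str:
    """Prior turns, each wrapped in curly braces, concatenated in order."""
    return "".join("{" + t.text + "}" for t in dialogue.turns[:turn_index])


# ---------------------------------------------------------------------------
# abbreviation-expansion triplets


def _keyword_variant(
    text: str,
    scheme: str,
    keyword_counts: tuple[int, ...],
    rng: random.Random,
    convention: PunctuationConvention,
) -> str | None:
    """One sampled keyword shorthand of ``text`` in the SPACED dialect."""
    tokens = tokenize_phrase(text, convention)
    if scheme == "complete_keywords":
        eligible = [i for i, t in enumerate(tokens) if any(c.isalpha() for c in t.core)]
    elif scheme == "prefix_keywords":
        eligible = [i for i, t in enumerate(tokens) if len(t.core) >= 3 and any(c.isalpha() for c in t.core)]
    else:  # consonant_keywords
        eligible = [
            i
            for i, t in enumerate(tokens)
            if any(c.isalpha() for c in t.core) and len(consonant_skeleton(t.core)) >= 2
        ]
    if not eligible:
        return None
    n_kw = min(rng.choice(sorted(set(keyword_counts))), len(eligible))
    positions = sorted(rng.sample(eligible, n_kw))
    spec: dict[int, tuple[SegmentKind, int | None]] = {}
    for p in positions:
        core = tokens[p].core
        if scheme == "complete_keywords":
            spec[p] = (SegmentKind.KEYWORD_FULL, None)
        elif scheme == "prefix_keywords":
            spec[p] = (SegmentKind.KEYWORD_PREFIX, rng.randint(2, len(core) - 1))
        else:
            spec[p] = (SegmentKind.KEYWORD_CONSONANT, rng.randint(2, len(consonant_skeleton(core))))
    return render(abbreviate_with_keywords(text, spec, convention), RenderStyle.SPACED)


def synthesize_ae(
    corpus: Sequence[Dialogue],
    config: SynthesisConfig | None = None,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> list[AETriplet]:
    """AE triplets for every turn of every dialogue.

    Every turn yields an initials-only triplet (when that scheme is enabled)
    plus one sampled variant per enabled keyword scheme.  Deterministic for
    a fixed config seed.  Every emitted shorthand validates against its full
    phrase.
    """
    if not corpus:
        raise ValidationError("corpus must be non-empty")
    config = config or SynthesisConfig()
    rng = random.Random(config.seed)
    triplets: list[AETriplet] = []
    for dialogue in corpus:
        for ti, turn in enumerate(dialogue.turns):
            ctx = context_string(dialogue, ti)
            if "initials" in config.schemes:
                shorthand = render(abbreviate_initials(turn.text, convention), RenderStyle.SPACED)
                triplets.append(AETriplet(ctx, shorthand, turn.text))
            for scheme in ("complete_keywords", "prefix_keywords", "consonant_keywords"):
                if scheme not in config.schemes:
                    continue
                shorthand = _keyword_variant(turn.text, scheme, config.keyword_counts, rng, convention)
                if shorthand is not None:
                    triplets.append(AETriplet(ctx, shorthand, turn.text))
    return triplets


# ---------------------------------------------------------------------------
# fill-mask triplets


def _maskable_positions(raw_tokens: list[str]) -> list[int]:
    return [i for i, t in enumerate(raw_tokens) if t[:1].isalpha()]


def _mask_token(raw: str, convention: PunctuationConvention) -> tuple[str, str]:
    """Masked rendering of a raw whitespace token and the masked word."""
    core = raw
    tail = ""
    while core and core[-1] in convention.all_punct:
        tail = core[-1] + tail
        core = core[:-1]
    return core[0].lower() + "_" + tail, core


def synthesize_fillmask(
    corpus: Sequence[Dialogue],
    config: SynthesisConfig | None = None,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> list[FillMaskTriplet]:
    """Fill-mask triplets; digit- and punctuation-initial words are never masked.

    Per turn, ``masks_per_turn`` positions are sampled without replacement
    (all positions when ``None``).  When configured, a no-context variant is
    emitted alongside each with-context example.  Turns with no maskable
    word are skipped (logged).
    """
    if not corpus:
        raise ValidationError("corpus must be non-empty")
    config = config or SynthesisConfig()
    rng = random.Random(config.seed + 1)
    triplets: list[FillMaskTriplet] = []
    n_skipped = 0
    for dialogue in corpus:
        for ti, turn in enumerate(dialogue.turns):
            raw_tokens = turn.text.split()
            maskable = _maskable_positions(raw_tokens)
            if not maskable:
                n_skipped += 1
                continue
            if config.masks_per_turn is None:
                positions = maskable
            else:
                positions = sorted(rng.sample(maskable, min(config.masks_per_turn, len(maskable))))
            ctx = context_string(dialogue, ti)
            for p in positions:
                masked, word = _mask_token(raw_tokens[p], convention)
                phrase = " ".join(raw_tokens[:p] + [masked] + raw_tokens[p + 1 :])
                if ctx:
                    triplets.append(FillMaskTriplet(ctx, phrase, word))
                    if config.include_no_context_fillmask:
                        triplets.append(FillMaskTriplet("", phrase, word))
                else:
                    triplets.append(FillMaskTriplet("", phrase, word))
    if n_skipped:
        logger.info("skipped %d turns with no maskable word", n_skipped)
    return triplets


# ---------------------------------------------------------------------------
# serialization


def write_triplets(
    triplets: Sequence[AETriplet | FillMaskTriplet],
    path: str | Path,
    format: str = "jsonl",
) -> None:
    """Write triplets as JSONL records or the concatenated text layout.

    The text layout mirrors how examples are fed to a language model::

        Context: {...} Shorthand: {i s h p i t b} Full: {I saw him ...}
        Context: {...} Phrase: {Oh, I'm s_.} Word: {sorry}
    """
    if format not in ("jsonl", "prompt_text"):
        raise ValidationError(f"unknown format {format!r}")
    lines = []
    for t in triplets:
        if isinstance(t, AETriplet):
            if format == "jsonl":
                lines.append(json.dumps({"context": t.context, "shorthand": t.shorthand, "full": t.full}, ensure_ascii=False))
            else:
                lines.append(f"Context: {t.context} Shorthand: {{{t.shorthand}}} Full: {{{t.full}}}")
        else:
            if format == "jsonl":
                lines.append(json.dumps({"context": t.context, "phrase_with_mask": t.phrase_with_mask, "word": t.word}, ensure_ascii=False))
            else:
                lines.append(f"Context: {t.context} Phrase: {{{t.phrase_with_mask}}} Word: {{{t.word}}}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def read_triplets(path: str | Path) -> list[AETriplet | FillMaskTriplet]:
    """Read JSONL triplets back (the text layout is write-only)."""
    out: list[AETriplet | FillMaskTriplet] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            if "shorthand" in record:
                out.append(AETriplet(record["context"], record["shorthand"], record["full"]))
            elif "phrase_with_mask" in record:
                out.append(FillMaskTriplet(record["context"], record["phrase_with_mask"], record["word"]))
            else:
                raise ValidationError(f"{path} line {lineno}: unrecognized triplet record")
    return out


def validate_ae_triplets(triplets: Iterable[AETriplet], convention: PunctuationConvention = DEFAULT_CONVENTION) -> int:
    """Number of triplets whose shorthand fails to validate against its phrase."""
    return sum(0 if validate_shorthand(t.shorthand, t.full, convention) else 1 for t in triplets)


__all__.append("validate_ae_triplets")
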