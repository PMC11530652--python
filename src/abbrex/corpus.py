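"""Dialogue corpus: data model, JSONL I/O, length filtering, and synthesis.

Dialogues are two-speaker, multi-turn conversations.  The JSONL dialect is
one dialogue per line::

    {"schema": "abbrex-dialogue-v1", "dialogue_id": "...",
     "turns": [{"speaker": "A", "text": "..."}, ...]}

The synthetic generator emits six-turn alternating dialogues from a template
grammar (an opener question plus replies with content-word slots).  A
word-reuse probability controls how often a content slot repeats a content
word from an earlier turn of the same dialogue; this is what makes
conversational context informative for prediction.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .abbreviation import DEFAULT_CONVENTION, PunctuationConvention, tokenize_phrase
from .errors import ParseError, ValidationError

__all__ = [
    "SCHEMA",
    "Turn",
    "Dialogue",
    "Context",
    "read_corpus",
    "write_corpus",
    "turn_length",
    "filter_by_length",
    "context_for",
    "GeneratorConfig",
    "generate_synthetic_corpus",
    "CONTENT_WORDS",
]

SCHEMA = "abbrex-dialogue-v1"
SPEAKERS = ("A", "B")


@dataclass(frozen=True)
class Turn:
    """One utterance: a speaker label and a single sentence or phrase."""

    speaker: str
    text: str

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise ValidationError(f"speaker must be one of {SPEAKERS}, got {self.speaker!r}")
        stripped = self.text.strip()
        if not stripped:
            raise ValidationError("turn text must be non-empty")
        if stripped != self.text:
            object.__setattr__(self, "text", stripped)


@dataclass(frozen=True)
class Dialogue:
    dialogue_id: str
    turns: tuple[Turn, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.turns, tuple):
            object.__setattr__(self, "turns", tuple(self.turns))
        if len(self.turns) < 1:
            raise ValidationError("dialogue must have at least one turn")

    def __len__(self) -> int:
        return len(self.turns)


@dataclass(frozen=True)
class Context:
    """The turns preceding a target turn, in order. Possibly empty."""

    prior_turns: tuple[Turn, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.prior_turns, tuple):
            object.__setattr__(self, "prior_turns", tuple(self.prior_turns))

    def __bool__(self) -> bool:
        return bool(self.prior_turns)

    def words(self, convention: PunctuationConvention = DEFAULT_CONVENTION) -> frozenset[str]:
        """Normalized words occurring in the prior turns."""
        out: set[str] = set()
        for turn in self.prior_turns:
            out.update(t.norm for t in tokenize_phrase(turn.text, convention))
        return frozenset(out)


def context_for(dialogue: Dialogue, turn_index: int) -> Context:
    if not 0 <= turn_index < len(dialogue.turns):
        raise ValidationError(f"turn index {turn_index} out of range")
    return Context(dialogue.turns[:turn_index])


# ---------------------------------------------------------------------------
# I/O


def read_corpus(path: str | Path) -> list[Dialogue]:
    """Read a JSONL dialogue corpus.

    Raises :class:`ParseError` naming the offending line on malformed input
    and :class:`ValidationError` on duplicate dialogue ids.  Non-alternating
    speakers produce a warning, not an error, to tolerate real transcripts.
    """
    path = Path(path)
    dialogues: list[Dialogue] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path.name} line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(record, dict):
                raise ParseError(f"{path.name} line {lineno}: expected an object")
            for key in ("dialogue_id", "turns"):
                if key not in record:
                    raise ParseError(f"{path.name} line {lineno}: missing {key!r} key")
            schema = record.get("schema", SCHEMA)
            if schema != SCHEMA:
                warnings.warn(f"{path.name} line {lineno}: unknown schema {schema!r}", stacklevel=2)
            try:
                turns = tuple(Turn(t["speaker"], t["text"]) for t in record["turns"])
                dialogue = Dialogue(str(record["dialogue_id"]), turns)
            except (KeyError, TypeError, ValidationError) as exc:
                raise ParseError(f"{path.name} line {lineno}: bad turn record ({exc})") from exc
            if dialogue.dialogue_id in seen:
                raise ValidationError(f"duplicate dialogue_id {dialogue.dialogue_id!r}")
            seen.add(dialogue.dialogue_id)
            for prev, cur in zip(turns, turns[1:]):
                if prev.speaker == cur.speaker:
                    warnings.warn(
                        f"{path.name} line {lineno}: speakers do not alternate in {dialogue.dialogue_id!r}",
                        stacklevel=2,
                    )
                    break
            dialogues.append(dialogue)
    return dialogues


def write_corpus(dialogues: Iterable[Dialogue], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in dialogues:
            record = {
                "schema": SCHEMA,
                "dialogue_id": d.dialogue_id,
                "turns": [{"speaker": t.speaker, "text": t.text} for t in d.turns],
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# length accounting and filtering


def turn_length(text: str, convention: PunctuationConvention = DEFAULT_CONVENTION) -> int:
    """Sentence length: whitespace words plus mid-sentence punctuation marks.

    ``"ok, sounds good"`` -> 4 (three words plus one comma).
    """
    n_words = sum(1 for tok in text.split() if any(c.isalnum() for c in tok))
    n_punct = sum(1 for c in text if c in convention.mid_sentence)
    return n_words + n_punct


def filter_by_length(
    dialogues: Iterable[Dialogue],
    max_len: int = 10,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> list[tuple[Dialogue, int]]:
    """Turns with ``turn_length <= max_len``, as (dialogue, turn index) pairs.

    Order is preserved; each pair suffices to rebuild the turn's context via
    :func:`context_for`.
    """
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    out: list[tuple[Dialogue, int]] = []
    for d in dialogues:
        for i, turn in enumerate(d.turns):
            if turn_length(turn.text, convention) <= max_len:
                out.append((d, i))
    return out


# ---------------------------------------------------------------------------
# synthetic generation

# Content nouns. Several prefix-sharing families (garden/garage,
# bedroom/bedrock, kitchen/kitten, ...) are included so that near-miss
# candidates that share more than an initial letter occur naturally.
CONTENT_WORDS: tuple[str, ...] = (
    "garden", "garage", "bedroom", "bedrock", "kitchen", "kitten",
    "painting", "painter", "market", "marble", "window", "winter",
    "coffee", "copper", "dinner", "dining", "garbage", "guitar",
    "blanket", "bottle", "camera", "candle", "carpet", "castle",
    "cousin", "cinema", "doctor", "dragon", "flower", "forest",
    "hammer", "harbor", "island", "jacket", "ladder", "lantern",
    "meadow", "mirror", "mountain", "museum", "notebook", "orchard",
    "package", "pillow", "pocket", "puzzle", "rabbit", "river",
    "saddle", "sandwich", "shelter", "shovel", "spider", "stable",
    "station", "summer", "teacher", "temple", "thunder", "ticket",
    "tunnel", "turtle", "valley", "village", "wallet", "weather",
    "bakery", "basket", "bridge", "button", "cabin", "cellar",
    "chapel", "closet", "corner", "cottage", "desert", "engine",
    "fabric", "fiddle", "glacier", "helmet",
)

_OPENERS: tuple[tuple[str, ...], ...] = (
    ("what", "do", "you", "think", "about", "the", "{c}"),
    ("did", "you", "see", "the", "{c}", "yesterday"),
    ("how", "was", "the", "{c}", "this", "morning"),
    ("have", "you", "found", "the", "{c}", "yet"),
    ("where", "did", "you", "put", "the", "{c}"),
    ("is", "the", "{c}", "ok"),
)

_REPLIES: tuple[tuple[str, ...], ...] = (
    ("i", "think", "the", "{c}", "was", "great"),
    ("yes,", "the", "{c}", "looked", "fine", "to", "me"),
    ("no,", "i", "liked", "the", "{c}", "more"),
    ("we", "should", "visit", "the", "{c}", "and", "the", "{c}"),
    ("maybe", "the", "{c}", "near", "the", "{c}", "works"),
    ("i", "put", "the", "{c}", "by", "the", "{c}"),
    ("the", "{c}", "was", "better", "than", "the", "{c}"),
    ("please", "bring", "the", "{c}", "tomorrow"),
    ("i", "really", "want", "a", "new", "{c}"),
    ("the", "{c}", "is", "fine"),
)


def _template_length(template: tuple[str, ...], convention: PunctuationConvention) -> int:
    return len(template) + sum(1 for tok in template for c in tok if c in convention.mid_sentence)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dialogue generator.

    vocab_size
        Number of content nouns drawn from the built-in list.
    max_turn_length
        Upper bound on :func:`turn_length` for every generated turn.
    word_reuse_prob
        Probability that a content slot repeats a content word already used
        in an earlier turn of the same dialogue (the context signal).
    """

    vocab_size: int = 60
    max_turn_length: int = 10
    word_reuse_prob: float = 0.5
    convention: PunctuationConvention = field(default=DEFAULT_CONVENTION, compare=False)

    def __post_init__(self) -> None:
        if self.max_turn_length < 1:
            raise ValidationError("max_turn_length must be >= 1")
        if not 1 <= self.vocab_size <= len(CONTENT_WORDS):
            raise ValidationError(f"vocab_size must be in 1..{len(CONTENT_WORDS)}")
        if not 0.0 <= self.word_reuse_prob <= 1.0:
            raise ValidationError("word_reuse_prob must be in [0, 1]")

    @property
    def content_vocabulary(self) -> tuple[str, ...]:
        return CONTENT_WORDS[: self.vocab_size]

    @property
    def vocabulary(self) -> frozenset[str]:
        """All normalized words the generator can emit."""
        words = set(self.content_vocabulary)
        for template in _OPENERS + _REPLIES:
            for tok in template:
                if tok != "{c}":
                    words.add(tok.rstrip("".join(self.convention.all_punct)))
        return frozenset(words)


def generate_synthetic_corpus(
    n_dialogues: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> list[Dialogue]:
    """Deterministically generate six-turn alternating dialogues.

    A pure function of ``(n_dialogues, seed, config)``.  Every turn satisfies
    ``turn_length(text) <= config.max_turn_length`` and all emitted words are
    drawn from ``config.vocabulary``.
    """
    if n_dialogues < 1:
        raise ValidationError("n_dialogues must be >= 1")
    config = config or GeneratorConfig()
    conv = config.convention
    rng = random.Random(seed)
    openers = [t for t in _OPENERS if _template_length(t, conv) <= config.max_turn_length]
    replies = [t for t in _REPLIES if _template_length(t, conv) <= config.max_turn_length]
    if not openers or not replies:
        raise ValidationError(f"max_turn_length={config.max_turn_length} admits no dialogue template")
    vocab = config.content_vocabulary

    dialogues: list[Dialogue] = []
    for di in range(n_dialogues):
        prior_content: set[str] = set()  # content words of completed turns
        turns: list[Turn] = []
        for ti in range(6):
            template = rng.choice(openers if ti == 0 else replies)
            words: list[str] = []
            turn_content: list[str] = []
            for tok in template:
                if tok != "{c}":
                    words.append(tok)
                    continue
                if prior_content and rng.random() < config.word_reuse_prob:
                    word = rng.choice(sorted(prior_content))
                else:
                    word = rng.choice(vocab)
                turn_content.append(word)
                words.append(word)
            prior_content.update(turn_content)
            text = " ".join(words)
            text = text[0].upper() + text[1:]
            turns.append(Turn(SPEAKERS[ti % 2], text))
        dialogues.append(Dialogue(f"dlg-{di:05d}", tuple(turns)))
    return dialogues
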