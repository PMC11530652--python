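"""Predictor contract and desk-scale backends.

Three prediction tasks feed the simulator:

* ``expand`` -- abbreviation expansion: given dialogue context and an
  abbreviation mixing initials with keywords, return ranked candidate
  phrases, every one consistent with the abbreviation.
* ``fill_mask`` -- given a phrase with one word masked and that word's
  initial letter, return ranked candidate words.
* ``forward_predict`` -- conventional word completion / next-word
  prediction, the baseline text-entry paradigm.

Two backends implement the contract.  :class:`NgramPredictor` runs a
left-to-right constrained beam search over a stupid-backoff n-gram model,
with an additive log-score bonus for words present in the prior turns of the
dialogue (the context conditioning switch).  :class:`OraclePredictor` is a
configurable test instrument that knows the reference phrase: it reveals the
truth at a configured rank once enough characters were typed, and fills the
remaining slots with near-miss or random decoys that are still consistent
with the abbreviation.

All rankings are deterministic: ties break by score, then lexicographically.
Candidate phrases and words are returned in normalized LM space (lowercase,
punctuation-stripped); the simulator re-attaches punctuation and casing on
commit.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence, runtime_checkable

from . import corpus as _corpus
from .abbreviation import Abbreviation, RenderStyle, _segment_consistent, render
from .corpus import Context
from .errors import ValidationError
from .lm import BOS, EOS, NEG_INF, NgramModel

__all__ = [
    "ScoredOption",
    "RankedPhrases",
    "RankedWords",
    "Predictor",
    "expand_constrained",
    "fill_mask_ngram",
    "forward_predict",
    "NgramPredictor",
    "OracleConfig",
    "OraclePredictor",
    "segment_candidates",
]


@dataclass(frozen=True)
class ScoredOption:
    text: str
    score: float
    rank: int


class _RankedList:
    """Ordered options with non-increasing scores and 1-based ranks."""

    def __init__(self, options: Sequence[ScoredOption]):
        for a, b in zip(options, options[1:]):
            if b.score > a.score:
                raise ValidationError("option scores must be non-increasing")
        for i, opt in enumerate(options, start=1):
            if opt.rank != i:
                raise ValidationError("option ranks must be 1-based and consecutive")
        self.options = tuple(options)

    @classmethod
    def from_scored(cls, scored: Iterable[tuple[str, float]], n_options: int):
        """Rank (text, score) pairs: by score descending, then text."""
        ordered = sorted(scored, key=lambda ts: (-ts[1], ts[0]))[:n_options]
        return cls(tuple(ScoredOption(t, s, i) for i, (t, s) in enumerate(ordered, start=1)))

    def __len__(self) -> int:
        return len(self.options)

    def __bool__(self) -> bool:
        return bool(self.options)

    def __iter__(self):
        return iter(self.options)

    def __getitem__(self, i: int) -> ScoredOption:
        return self.options[i]

    @property
    def texts(self) -> tuple[str, ...]:
        return tuple(o.text for o in self.options)


class RankedPhrases(_RankedList):
    """Ranked candidate phrases from abbreviation expansion."""


class RankedWords(_RankedList):
    """Ranked candidate words from fill-mask or forward prediction."""


@runtime_checkable
class Predictor(Protocol):
    def expand(self, context: Context, abbrev: Abbreviation, n_options: int) -> RankedPhrases: ...

    def fill_mask(
        self,
        context: Context,
        words: Sequence[str | None],
        initial: str,
        n_options: int,
        exclude: frozenset[str] = frozenset(),
    ) -> RankedWords: ...


def _find_slot(words: Sequence[str | None]) -> int:
    slots = [i for i, w in enumerate(words) if w is None]
    if len(slots) != 1:
        raise ValidationError(f"expected exactly one masked slot, found {len(slots)}")
    return slots[0]


# ---------------------------------------------------------------------------
# n-gram backend


def segment_candidates(vocab_words: Iterable[str], abbrev: Abbreviation) -> list[list[str]]:
    """Per segment, the vocabulary words consistent with it (sorted)."""
    words = sorted(vocab_words)
    return [[w for w in words if _segment_consistent(seg, w)] for seg in abbrev]


def expand_constrained(
    model: NgramModel,
    context: Context,
    abbrev: Abbreviation,
    n_options: int,
    beam_width: int = 16,
    context_boost: float = 0.0,
) -> RankedPhrases:
    """Constrained beam search over the n-gram model, one step per word.

    At position *i* the candidate set is the vocabulary words consistent with
    segment *i*.  A hypothesis's score is the summed stupid-backoff log10
    scores (including the end-of-sentence transition) plus ``context_boost``
    for every word that occurs in the prior turns.  If any position admits no
    vocabulary word the result is empty, signalling predictor failure.
    """
    if n_options < 1:
        raise ValidationError("n_options must be >= 1")
    per_position = segment_candidates(model.words, abbrev)
    if any(not cands for cands in per_position):
        return RankedPhrases(())
    boost_words = context.words() if context_boost else frozenset()

    beams: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    for cands in per_position:
        grown: list[tuple[float, tuple[str, ...]]] = []
        for score, words in beams:
            history = (BOS,) + words
            for w in cands:
                s = model.score(w, history)
                if w in boost_words:
                    s += context_boost
                grown.append((score + s, words + (w,)))
        grown.sort(key=lambda sw: (-sw[0], sw[1]))
        beams = grown[:beam_width]
    finished = [(score + model.score(EOS, (BOS,) + words), words) for score, words in beams]
    scored = ((" ".join(words), score) for score, words in finished if score > NEG_INF)
    return RankedPhrases.from_scored(scored, n_options)


def fill_mask_ngram(
    model: NgramModel,
    context: Context,
    words: Sequence[str | None],
    initial: str,
    n_options: int,
    exclude: frozenset[str] = frozenset(),
    context_boost: float = 0.0,
) -> RankedWords:
    """Rank vocabulary words for the masked slot, constrained to ``initial``.

    A candidate's score is the LM score given the left history, plus the LM
    score of the right neighbour given a history that includes the candidate
    (skipped when the slot is final), plus the context bonus.
    """
    if n_options < 1:
        raise ValidationError("n_options must be >= 1")
    if not initial or not initial[:1].isalpha():
        raise ValidationError(f"initial must be an alphabetic character, got {initial!r}")
    slot = _find_slot(words)
    initial = initial.lower()
    left = tuple(str(w).lower() for w in words[:slot])
    right = str(words[slot + 1]).lower() if slot + 1 < len(words) else None
    boost_words = context.words() if context_boost else frozenset()

    scored = []
    for w in model.words:
        if not w.startswith(initial) or w in exclude:
            continue
        s = model.score(w, (BOS,) + left)
        if right is not None:
            s += model.score(right, (BOS,) + left + (w,))
        if w in boost_words:
            s += context_boost
        if s > NEG_INF:
            scored.append((w, s))
    return RankedWords.from_scored(scored, n_options)


def forward_predict(
    model: NgramModel,
    context: Context,
    committed_words: Sequence[str],
    current_prefix: str,
    n_options: int,
) -> RankedWords:
    """Word completion / next-word prediction for the baseline keyboard.

    With an empty ``current_prefix`` this is next-word prediction: the top
    vocabulary words by LM score given the committed history.  Otherwise it
    is completion: vocabulary words having the prefix, ranked the same way.
    """
    if n_options < 1:
        raise ValidationError("n_options must be >= 1")
    history = (BOS,) + tuple(w.lower() for w in committed_words)
    prefix = current_prefix.lower()
    scored = []
    for w in model.words:
        if prefix and not w.startswith(prefix):
            continue
        s = model.score(w, history)
        if s > NEG_INF:
            scored.append((w, s))
    return RankedWords.from_scored(scored, n_options)


class NgramPredictor:
    """Predictor backed by an :class:`NgramModel`.

    ``context_boost`` (log10 units) is added to words present in the prior
    turns; set it to 0 to disable context conditioning.  Expansion results
    are cached per (abbreviation, context) at a fixed internal depth so that
    the ranked list for a smaller ``n_options`` is a prefix of the list for a
    larger one.
    """

    _CACHE_DEPTH = 32

    def __init__(self, model: NgramModel, beam_width: int = 16, context_boost: float = 0.5):
        self.model = model
        self.beam_width = beam_width
        self.context_boost = context_boost
        self._expand_cache: dict[tuple, RankedPhrases] = {}

    def begin_turn(self, reference: str) -> None:  # noqa: ARG002 - contract hook
        pass

    def _context_key(self, context: Context) -> tuple:
        return tuple(t.text for t in context.prior_turns) if self.context_boost else ()

    def expand(self, context: Context, abbrev: Abbreviation, n_options: int) -> RankedPhrases:
        key = (render(abbrev, RenderStyle.SPACED), self._context_key(context))
        full = self._expand_cache.get(key)
        if full is None:
            full = expand_constrained(
                self.model, context, abbrev, max(n_options, self._CACHE_DEPTH),
                self.beam_width, self.context_boost,
            )
            self._expand_cache[key] = full
        return RankedPhrases(full.options[:n_options])

    def fill_mask(
        self,
        context: Context,
        words: Sequence[str | None],
        initial: str,
        n_options: int,
        exclude: frozenset[str] = frozenset(),
    ) -> RankedWords:
        return fill_mask_ngram(
            self.model, context, words, initial, n_options, exclude, self.context_boost
        )


# ---------------------------------------------------------------------------
# oracle backend (test instrument)

#: Fallback decoy lexicon: the generator's content nouns plus common words.
DEFAULT_LEXICON: tuple[str, ...] = tuple(
    sorted(
        set(_corpus.CONTENT_WORDS)
        | {
            "about", "after", "baker", "before", "could", "every", "happy",
            "house", "light", "never", "other", "quiet", "round", "small",
            "table", "there", "today", "under", "voice", "water", "young",
            "zebra", "extra", "inner", "jolly", "known", "maybe", "night",
            "ocean", "plain", "x-ray", "usual", "great", "fresh", "dream",
        }
    )
)


@dataclass(frozen=True)
class OracleConfig:
    """Behaviour of the oracle predictor.

    reveal_rank
        1-based rank at which the reference phrase (or masked word) appears
        once the oracle succeeds.
    min_typed_chars
        Typed characters (letters, excluding punctuation) required in the
        abbreviation before the truth is revealed.  ``math.inf`` yields an
        adversarial oracle that never reveals by typing alone.
    decoys
        ``"near_miss"`` substitutes words preferring the longest shared
        prefix with the truth word; ``"random"`` substitutes seeded-random
        consistent words.
    decoy_distance
        Number of word positions substituted in each decoy.
    decoy_positions
        Fixed positions to substitute; ``None`` draws them per turn from a
        seeded generator.
    fm_mode
        FillMask oracle behaviour: ``"always"`` succeeds, ``"never"`` fails,
        ``"context_sensitive"`` succeeds only when every unmasked word of the
        query equals the reference (a predictor that needs correct
        surrounding words).
    """

    reveal_rank: int = 1
    min_typed_chars: float = 0
    decoys: str = "near_miss"
    decoy_distance: int = 1
    decoy_positions: tuple[int, ...] | None = None
    fm_mode: str = "context_sensitive"
    lexicon: tuple[str, ...] = DEFAULT_LEXICON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reveal_rank < 1:
            raise ValidationError("reveal_rank must be >= 1")
        if self.decoys not in ("near_miss", "random"):
            raise ValidationError(f"unknown decoy strategy {self.decoys!r}")
        if self.fm_mode not in ("always", "never", "context_sensitive"):
            raise ValidationError(f"unknown fm_mode {self.fm_mode!r}")
        if self.decoy_distance < 0:
            raise ValidationError("decoy_distance must be >= 0")


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


class OraclePredictor:
    """Predictor that knows the reference phrase of the current turn.

    Call :meth:`begin_turn` with the reference before each simulated turn
    (the simulator does this).  Deterministic for a fixed config seed.
    """

    def __init__(self, config: OracleConfig | None = None):
        self.config = config or OracleConfig()
        self._truth: tuple[str, ...] = ()
        self._positions: tuple[int, ...] = ()

    def begin_turn(self, reference: str) -> None:
        from .lm import normalize_sentence

        self._truth = tuple(normalize_sentence(reference))
        cfg = self.config
        if cfg.decoy_positions is not None:
            self._positions = tuple(p for p in cfg.decoy_positions if p < len(self._truth))
            return
        rng = random.Random(f"{cfg.seed}|pos|{' '.join(self._truth)}")
        eligible = [
            i
            for i, w in enumerate(self._truth)
            if any(x != w and x[:1] == w[:1] for x in cfg.lexicon)
        ]
        rng.shuffle(eligible)
        k = min(cfg.decoy_distance, len(eligible))
        self._positions = tuple(sorted(eligible[:k]))

    # -- expansion ----------------------------------------------------------

    def _alternatives(self, seg, truth_word: str, rng: random.Random) -> list[str]:
        """Lexicon words != truth_word that remain consistent with ``seg``."""
        alts = [w for w in self.config.lexicon if w != truth_word and _segment_consistent(seg, w)]
        if self.config.decoys == "near_miss":
            alts.sort(key=lambda w: (-_common_prefix_len(w, truth_word), w))
        else:
            rng.shuffle(alts)
        return alts

    def expand(self, context: Context, abbrev: Abbreviation, n_options: int) -> RankedPhrases:
        if not self._truth:
            raise ValidationError("OraclePredictor.begin_turn was not called")
        if len(abbrev) != len(self._truth):
            return RankedPhrases(())
        cfg = self.config
        rng = random.Random(f"{cfg.seed}|exp|{render(abbrev, RenderStyle.SPACED)}")
        alts_by_pos = {
            p: self._alternatives(abbrev.segments[p], self._truth[p], rng)
            for p in self._positions
        }
        live = {p: a for p, a in alts_by_pos.items() if a}
        decoys: list[str] = []
        if live:
            depth = max(len(a) for a in live.values())
            for r in range(depth):
                words = list(self._truth)
                for p, alts in live.items():
                    words[p] = alts[min(r, len(alts) - 1)]
                phrase = " ".join(words)
                if phrase not in decoys:
                    decoys.append(phrase)
        reveal = abbrev.typed_chars >= cfg.min_typed_chars or (
            not live and math.isfinite(cfg.min_typed_chars)
        )
        texts = decoys[:]
        if reveal:
            truth_phrase = " ".join(self._truth)
            if truth_phrase in texts:
                texts.remove(truth_phrase)
            texts.insert(min(cfg.reveal_rank - 1, len(texts)), truth_phrase)
        texts = texts[:n_options]
        return RankedPhrases(
            tuple(ScoredOption(t, -float(i), i + 1) for i, t in enumerate(texts))
        )

    # -- fill mask ----------------------------------------------------------

    def fill_mask(
        self,
        context: Context,
        words: Sequence[str | None],
        initial: str,
        n_options: int,
        exclude: frozenset[str] = frozenset(),
    ) -> RankedWords:
        if not self._truth:
            raise ValidationError("OraclePredictor.begin_turn was not called")
        cfg = self.config
        slot = _find_slot(words)
        initial = initial.lower()
        truth_word = self._truth[slot] if slot < len(self._truth) else ""
        if cfg.fm_mode == "always":
            success = True
        elif cfg.fm_mode == "never":
            success = False
        else:
            success = len(words) == len(self._truth) and all(
                str(w).lower() == t for i, (w, t) in enumerate(zip(words, self._truth)) if i != slot
            )
        fillers = [
            w
            for w in cfg.lexicon
            if w.startswith(initial) and w != truth_word and w not in exclude
        ]
        fillers.sort(key=lambda w: (-_common_prefix_len(w, truth_word), w))
        texts = fillers[: n_options + 1]
        if success and truth_word:
            texts.insert(min(cfg.reveal_rank - 1, len(texts)), truth_word)
        texts = texts[:n_options]
        return RankedWords(
            tuple(ScoredOption(t, -float(i), i + 1) for i, t in enumerate(texts))
        )


def oracle_expand(
    config: OracleConfig,
    truth: str,
    context: Context,
    abbrev: Abbreviation,
    n_options: int,
) -> RankedPhrases:
    """One-shot functional form of :class:`OraclePredictor` expansion."""
    predictor = OraclePredictor(config)
    predictor.begin_turn(truth)
    return predictor.expand(context, abbrev, n_options)


__all__.append("oracle_expand")
__all__.append("DEFAULT_LEXICON")
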