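"""Ideal-user interaction simulation and keystroke-saving-rate accounting.

The simulator replays how an error-free user would enter each dialogue turn
through the abbreviated text-entry UI, counting every motor action under a
broadened keystroke definition: keyboard keypresses plus the UI clicks
needed to use prediction (entering spell mode, selecting a word chip,
entering fill-mask mode, selecting word and phrase options).

Every turn starts from the initials-only abbreviation.  If the first
expansion call does not surface the reference phrase, one of three recovery
strategies runs:

* **Strategy 1** iterates keyword abbreviation expansion: spell out more of
  the first incorrect word in the best-matching candidate until the phrase
  is found.  Version V1 types each keyword in full (one expansion call per
  keyword); V2 appends one letter at a time with a call after every
  keystroke.
* **Strategy 2** is Strategy 1 until a single incorrect word remains, at
  which point fill-mask replaces keyword spelling; keyword mode is never
  re-entered afterwards.  A fill-mask failure falls back to typing the word
  in full.
* **Strategy 2A** switches to fill-mask as soon as two or fewer incorrect
  words remain, treating them left to right.

The keystroke-saving rate of a turn is ``1 - total_actions / ref_chars``
where ``ref_chars`` counts the reference phrase's characters including
interior spaces and mid-sentence punctuation and excluding sentence-final
punctuation.  KSR can be negative when assistance costs exceed plain typing.

A forward-prediction baseline models a conventional predictive keyboard:
type left to right, selecting the intended word as soon as it appears among
the top-n completions or next-word predictions.
"""

from __future__ import annotations

import enum
import json
import statistics
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .abbreviation import (
    DEFAULT_CONVENTION,
    AbbrevSegment,
    PunctuationConvention,
    SegmentKind,
    abbreviate_initials,
    tokenize_phrase,
)
from .corpus import Context, Dialogue, context_for, filter_by_length, turn_length
from .errors import ValidationError
from .lm import NgramModel
from .predictors import Predictor, RankedPhrases, forward_predict

__all__ = [
    "Strategy",
    "AEVersion",
    "SolvedBy",
    "SimConfig",
    "ActionLedger",
    "TurnOutcome",
    "StrategyReport",
    "CostParams",
    "best_match",
    "simulate_turn",
    "simulate_baseline_turn",
    "run_simulation",
    "run_baseline_simulation",
    "project_time",
    "reference_char_count",
]


class Strategy(enum.Enum):
    S1 = "1"
    S2 = "2"
    S2A = "2a"


class AEVersion(enum.Enum):
    V1 = "v1"  # keywords typed in full
    V2 = "v2"  # keywords extended one letter at a time


class SolvedBy(enum.Enum):
    INITIALS_ONLY = "initials_only"
    KEYWORD_AE = "keyword_ae"
    FILLMASK = "fillmask"
    FULL_SPELL = "full_spell"


@dataclass(frozen=True)
class SimConfig:
    strategy: Strategy = Strategy.S1
    ae_version: AEVersion = AEVersion.V2
    n_options: int = 5
    use_context: bool = True
    auto_trigger: bool = True
    max_turn_length: int = 10
    seed: int = 0
    # Individually switchable UI actions, to bound their contribution.
    count_spell_mode_enter: bool = True
    count_select_phrase: bool = True
    count_spaces: bool = True  # include interior spaces in the KSR denominator

    def __post_init__(self) -> None:
        if self.n_options < 1:
            raise ValidationError("n_options must be >= 1")
        if self.max_turn_length < 1:
            raise ValidationError("max_turn_length must be >= 1")


_ACTION_FIELDS = (
    "key_char",
    "select_phrase",
    "spell_mode_enter",
    "chip_select",
    "fm_enter",
    "fm_word_select",
    "fm_option_select",
    "expand_trigger",
    "baseline_option_select",
)


@dataclass
class ActionLedger:
    """Counts of motor actions and predictor calls for one turn."""

    key_char: int = 0
    select_phrase: int = 0
    spell_mode_enter: int = 0
    chip_select: int = 0
    fm_enter: int = 0
    fm_word_select: int = 0
    fm_option_select: int = 0
    expand_trigger: int = 0
    baseline_option_select: int = 0
    num_ae_calls: int = 0
    num_fm_calls: int = 0
    options_reviewed: int = 0

    @property
    def total_actions(self) -> int:
        return sum(getattr(self, f) for f in _ACTION_FIELDS)


@dataclass(frozen=True)
class TurnOutcome:
    reference: str
    ledger: ActionLedger
    solved_by: SolvedBy
    ref_char_count: int
    total_actions: int
    ksr: float


@dataclass
class StrategyReport:
    """Aggregate of one simulation run over a filtered corpus."""

    config: SimConfig
    outcomes: list[TurnOutcome]
    strategy_label: str = ""

    @property
    def n_turns(self) -> int:
        return len(self.outcomes)

    @property
    def mean_ksr(self) -> float:
        return statistics.fmean(o.ksr for o in self.outcomes)

    @property
    def single_call_fraction(self) -> float:
        """Turns solved by the first initials-only expansion call."""
        hits = sum(
            1
            for o in self.outcomes
            if o.solved_by is SolvedBy.INITIALS_ONLY and o.ledger.num_ae_calls == 1
        )
        return hits / len(self.outcomes)

    def summary_row(self) -> dict:
        cfg = self.config
        return {
            "strategy": self.strategy_label or cfg.strategy.value,
            "ae_version": cfg.ae_version.value,
            "n_options": cfg.n_options,
            "use_context": cfg.use_context,
            "mean_ksr": round(self.mean_ksr, 6),
            "single_call_fraction": round(self.single_call_fraction, 6),
            "n_turns": self.n_turns,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "summary": self.summary_row(),
            "denominator": "reference characters incl. interior spaces"
            + ("" if self.config.count_spaces else " (spaces excluded)")
            + ", excl. sentence-final punctuation",
            "seed": self.config.seed,
            "turns": [
                {
                    "reference": o.reference,
                    "solved_by": o.solved_by.value,
                    "ref_char_count": o.ref_char_count,
                    "total_actions": o.total_actions,
                    "ksr": o.ksr,
                    "ledger": asdict(o.ledger),
                }
                for o in self.outcomes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


TSV_COLUMNS = ("strategy", "ae_version", "n_options", "use_context", "mean_ksr", "single_call_fraction", "n_turns")


def write_summary_tsv(reports: Iterable[StrategyReport], path: str | Path) -> None:
    lines = ["\t".join(TSV_COLUMNS)]
    for report in reports:
        row = report.summary_row()
        lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# matching helpers


def _normalize_words(phrase: str, convention: PunctuationConvention) -> tuple[str, ...]:
    return tuple(t.norm for t in tokenize_phrase(phrase, convention))


def reference_char_count(
    reference: str,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
    *,
    count_spaces: bool = True,
) -> int:
    """KSR denominator: characters of the reference phrase.

    Interior spaces and mid-sentence punctuation count; sentence-final
    punctuation does not.
    """
    s = reference.strip()
    s = "".join(c for c in s if c not in convention.sentence_final)
    if not count_spaces:
        s = s.replace(" ", "")
    return len(s.strip())


def best_match(
    options: RankedPhrases,
    reference: str | Sequence[str],
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> tuple[int, tuple[int, ...]]:
    """Best-matching candidate and the incorrect reference word positions.

    The winner maximizes position-wise case-insensitive word matches over
    the shorter length; ties prefer a candidate with the reference's word
    count, then the lower rank.  Incorrect positions are reference indices:
    mismatches over the shorter length plus reference positions beyond the
    candidate's length.  A longer candidate matching every reference
    position is treated as having the last reference position incorrect, so
    the caller keeps specifying rather than accepting a wrong phrase.
    """
    if not options:
        raise ValidationError("best_match requires non-empty options")
    ref = _normalize_words(reference, convention) if isinstance(reference, str) else tuple(reference)
    best: tuple[int, int, int] | None = None  # (-matches, length mismatch, rank index)
    best_incorrect: tuple[int, ...] = ()
    best_idx = 0
    for idx, opt in enumerate(options):
        cand = tuple(opt.text.lower().split())
        m = min(len(cand), len(ref))
        mismatches = [i for i in range(m) if cand[i] != ref[i]]
        n_match = m - len(mismatches)
        incorrect = tuple(mismatches) + tuple(range(m, len(ref)))
        if len(cand) > len(ref) and not incorrect:
            incorrect = (len(ref) - 1,)
        key = (-n_match, 0 if len(cand) == len(ref) else 1, idx)
        if best is None or key < best:
            best = key
            best_incorrect = incorrect
            best_idx = idx
    return best_idx, best_incorrect


# ---------------------------------------------------------------------------
# the strategy state machine


class _TurnState:
    """Mutable per-turn bookkeeping shared by the strategy branches."""

    def __init__(self, reference: str, context: Context, predictor: Predictor, config: SimConfig, convention: PunctuationConvention):
        self.config = config
        self.convention = convention
        self.context = context if config.use_context else Context(())
        self.predictor = predictor
        self.tokens = tokenize_phrase(reference, convention)
        if not self.tokens or not any(any(c.isalpha() for c in t.core) for t in self.tokens):
            raise ValidationError(f"reference {reference!r} contains no alphabetic word")
        self.ref_words = tuple(t.norm for t in self.tokens)
        self.abbrev = abbreviate_initials(reference, convention)
        self.ledger = ActionLedger()
        self.fully_spelled = [len(seg.typed) >= len(tok.core) for seg, tok in zip(self.abbrev, self.tokens)]

    # -- actions ------------------------------------------------------------

    def ae_call(self) -> RankedPhrases:
        self.ledger.num_ae_calls += 1
        if not self.config.auto_trigger:
            self.ledger.expand_trigger += 1
        options = self.predictor.expand(self.context, self.abbrev, self.config.n_options)
        self.ledger.options_reviewed += len(options)
        return options

    def select_phrase(self) -> None:
        if self.config.count_select_phrase:
            self.ledger.select_phrase += 1

    def reference_in(self, options: RankedPhrases) -> bool:
        return " ".join(self.ref_words) in options.texts

    def all_spelled(self) -> bool:
        return all(self.fully_spelled)

    def spell_fully(self, pos: int) -> int:
        """Replace segment ``pos`` with the fully typed word; returns keystrokes."""
        tok = self.tokens[pos]
        self.abbrev = self.abbrev.with_segment(
            pos, AbbrevSegment(pos, SegmentKind.KEYWORD_FULL, tok.norm, tok.trailing_punct)
        )
        self.fully_spelled[pos] = True
        return len(tok.core)

    def extend_by_letter(self, pos: int) -> None:
        """Append one reference letter to the keyword at ``pos`` (V2)."""
        tok = self.tokens[pos]
        typed = self.abbrev.segments[pos].typed
        new = tok.norm[: len(typed) + 1]
        kind = SegmentKind.KEYWORD_FULL if len(new) >= len(tok.core) else SegmentKind.KEYWORD_PREFIX
        self.abbrev = self.abbrev.with_segment(
            pos, AbbrevSegment(pos, kind, new, tok.trailing_punct)
        )
        if kind is SegmentKind.KEYWORD_FULL:
            self.fully_spelled[pos] = True


def _fillmask_block(state: _TurnState, options: RankedPhrases, best_idx: int, incorrect: tuple[int, ...]) -> SolvedBy:
    """Fill-mask recovery: fix each incorrect position left to right."""
    ledger = state.ledger
    cand = list(options[best_idx].text.lower().split())
    working = cand[: len(state.ref_words)] + list(state.ref_words[len(cand):])
    ledger.fm_enter += 1
    any_success = False
    for pos in incorrect:
        ledger.fm_word_select += 1
        wrong = working[pos]
        query: list[str | None] = list(working)
        query[pos] = None
        initial = state.ref_words[pos][0]
        ledger.num_fm_calls += 1
        exclude = frozenset({wrong}) if wrong != state.ref_words[pos] else frozenset()
        ranked = state.predictor.fill_mask(
            state.context, query, initial, state.config.n_options, exclude
        )
        ledger.options_reviewed += len(ranked)
        if state.ref_words[pos] in ranked.texts:
            ledger.fm_option_select += 1
            any_success = True
        else:
            ledger.key_char += len(state.tokens[pos].core)
        working[pos] = state.ref_words[pos]
    state.select_phrase()
    return SolvedBy.FILLMASK if any_success else SolvedBy.FULL_SPELL


def simulate_turn(
    reference: str,
    context: Context,
    predictor: Predictor,
    config: SimConfig,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> TurnOutcome:
    """Simulate one ideal-user phrase entry; see the module docstring."""
    if turn_length(reference, convention) > config.max_turn_length:
        raise ValidationError(f"reference exceeds max_turn_length={config.max_turn_length}")
    state = _TurnState(reference, context, predictor, config, convention)
    ledger = state.ledger
    if hasattr(predictor, "begin_turn"):
        predictor.begin_turn(reference)

    def outcome(solved: SolvedBy) -> TurnOutcome:
        ref_chars = reference_char_count(reference, convention, count_spaces=config.count_spaces)
        total = ledger.total_actions
        return TurnOutcome(
            reference=reference,
            ledger=ledger,
            solved_by=solved,
            ref_char_count=ref_chars,
            total_actions=total,
            ksr=1.0 - total / ref_chars,
        )

    # (1) type the initials-only abbreviation, one expansion call
    ledger.key_char += state.abbrev.key_count
    options = state.ae_call()
    if options and state.reference_in(options):
        state.select_phrase()
        return outcome(SolvedBy.INITIALS_ONLY)
    if state.all_spelled():  # single-letter words only
        state.select_phrase()
        return outcome(SolvedBy.FULL_SPELL)

    fm_threshold = {Strategy.S1: 0, Strategy.S2: 1, Strategy.S2A: 2}[config.strategy]
    spell_mode_entered = False
    current_chip: int | None = None
    guard = reference_char_count(reference, convention) + 3 * len(state.ref_words) + 8

    for _ in range(guard):
        if options:
            best_idx, incorrect = best_match(options, state.ref_words, convention)
        else:
            best_idx, incorrect = -1, tuple(i for i, done in enumerate(state.fully_spelled) if not done)
        if not incorrect:
            # candidate equals the reference word-for-word
            state.select_phrase()
            return outcome(SolvedBy.KEYWORD_AE)

        if best_idx >= 0 and 0 < len(incorrect) <= fm_threshold:
            return outcome(_fillmask_block(state, options, best_idx, incorrect))

        targets = [p for p in incorrect if not state.fully_spelled[p]]
        if not targets:
            targets = [p for p, done in enumerate(state.fully_spelled) if not done]
        if not targets:
            state.select_phrase()
            return outcome(SolvedBy.FULL_SPELL)
        pos = targets[0]

        if not spell_mode_entered:
            if config.count_spell_mode_enter:
                ledger.spell_mode_enter += 1
            spell_mode_entered = True

        if config.ae_version is AEVersion.V1:
            ledger.chip_select += 1
            ledger.key_char += state.spell_fully(pos)
        else:
            if current_chip != pos:
                ledger.chip_select += 1
                current_chip = pos
            state.extend_by_letter(pos)
            ledger.key_char += 1

        if state.all_spelled():
            state.select_phrase()
            return outcome(SolvedBy.FULL_SPELL)
        options = state.ae_call()
        if options and state.reference_in(options):
            state.select_phrase()
            return outcome(SolvedBy.KEYWORD_AE)
    raise AssertionError(f"turn did not terminate within {guard} iterations: {reference!r}")


# ---------------------------------------------------------------------------
# forward-prediction baseline


def simulate_baseline_turn(
    reference: str,
    context: Context,
    model: NgramModel,
    n_options: int,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
    *,
    count_spaces: bool = True,
) -> TurnOutcome:
    """Conventional predictive-keyboard entry of ``reference``.

    Before every keystroke the top-n completions (or next-word predictions
    when no letters of the current word are typed yet) are consulted; the
    intended word is selected as soon as it appears, committing the word and
    one following space in a single action.  Spaces and punctuation are
    otherwise typed literally; a word with trailing punctuation is committed
    without the space, which is typed after the punctuation.
    """
    if n_options < 1:
        raise ValidationError("n_options must be >= 1")
    tokens = tokenize_phrase(reference, convention)
    if not tokens:
        raise ValidationError(f"reference {reference!r} contains no word")
    ledger = ActionLedger()
    committed: list[str] = []
    for idx, tok in enumerate(tokens):
        target = tok.norm
        prefix = ""
        selected = False
        while len(prefix) < len(target):
            ranked = forward_predict(model, context, committed, prefix, n_options)
            ledger.options_reviewed += len(ranked)
            if target in ranked.texts:
                ledger.baseline_option_select += 1
                selected = True
                break
            prefix += target[len(prefix)]
            ledger.key_char += 1
        committed.append(target)
        last = idx == len(tokens) - 1
        ledger.key_char += len(tok.trailing_punct)
        if not last and (not selected or tok.trailing_punct):
            ledger.key_char += 1  # the space; a clean selection commits it
    ref_chars = reference_char_count(reference, convention, count_spaces=count_spaces)
    total = ledger.total_actions
    return TurnOutcome(
        reference=reference,
        ledger=ledger,
        solved_by=SolvedBy.FULL_SPELL,
        ref_char_count=ref_chars,
        total_actions=total,
        ksr=1.0 - total / ref_chars,
    )


# ---------------------------------------------------------------------------
# corpus-level runs


def run_simulation(
    corpus: Sequence[Dialogue],
    predictor: Predictor,
    config: SimConfig,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> StrategyReport:
    """Simulate every length-eligible turn of ``corpus``; aggregate."""
    items = filter_by_length(corpus, config.max_turn_length, convention)
    if not items:
        raise ValidationError("no turns remain after length filtering")
    outcomes = []
    for dialogue, ti in items:
        context = context_for(dialogue, ti) if config.use_context else Context(())
        outcomes.append(
            simulate_turn(dialogue.turns[ti].text, context, predictor, config, convention)
        )
    return StrategyReport(config=config, outcomes=outcomes)


def run_baseline_simulation(
    corpus: Sequence[Dialogue],
    model: NgramModel,
    n_options: int = 5,
    max_turn_length: int = 10,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> StrategyReport:
    items = filter_by_length(corpus, max_turn_length, convention)
    if not items:
        raise ValidationError("no turns remain after length filtering")
    outcomes = []
    for dialogue, ti in items:
        context = context_for(dialogue, ti)
        outcomes.append(
            simulate_baseline_turn(dialogue.turns[ti].text, context, model, n_options, convention)
        )
    config = SimConfig(n_options=n_options, max_turn_length=max_turn_length)
    return StrategyReport(config=config, outcomes=outcomes, strategy_label="baseline")


# ---------------------------------------------------------------------------
# time projection (plumbing; no empirical model behind the defaults)


@dataclass(frozen=True)
class CostParams:
    """Unit costs, milliseconds, for projecting a turn's wall time."""

    keystroke_ms: float = 600.0
    option_review_ms: float = 400.0
    call_latency_ms: float = 600.0

    def __post_init__(self) -> None:
        if min(self.keystroke_ms, self.option_review_ms, self.call_latency_ms) < 0:
            raise ValidationError("cost parameters must be >= 0")


def project_time(outcome: TurnOutcome, costs: CostParams) -> tuple[float, dict[str, float]]:
    """Linear projection of a turn's duration with a per-category breakdown.

    Typing covers character keys; UI covers the remaining motor actions;
    review scales with options displayed; latency with predictor calls.
    """
    ledger = outcome.ledger
    ui_actions = ledger.total_actions - ledger.key_char
    breakdown = {
        "typing_ms": costs.keystroke_ms * ledger.key_char,
        "ui_ms": costs.keystroke_ms * ui_actions,
        "review_ms": costs.option_review_ms * ledger.options_reviewed,
        "latency_ms": costs.call_latency_ms * (ledger.num_ae_calls + ledger.num_fm_calls),
    }
    return sum(breakdown.values()), breakdown
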