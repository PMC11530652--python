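"""Stupid-backoff n-gram language model with ARPA interchange.

This is deliberately a small, deterministic scoring instrument: relative
frequencies for observed n-grams, and a fixed multiplicative discount
``alpha`` (default 0.4) applied per backoff step for unseen ones.  Stupid
backoff yields scores, not a normalized distribution over histories; the
unigram level, however, is a proper relative-frequency distribution.

Scores are log10 throughout, matching the ARPA convention.  ARPA files are
read for their log10 probabilities only; backoff-weight fields are ignored
and the uniform ``alpha`` is applied instead.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable, Sequence

from .abbreviation import DEFAULT_CONVENTION, PunctuationConvention, tokenize_phrase
from .errors import ParseError, ValidationError

__all__ = ["BOS", "EOS", "NgramModel", "train_ngram", "normalize_sentence"]

BOS = "<s>"
EOS = "</s>"

NEG_INF = float("-inf")


def normalize_sentence(text: str, convention: PunctuationConvention = DEFAULT_CONVENTION) -> list[str]:
    """Lowercased, punctuation-stripped word sequence used for LM training."""
    return [t.norm for t in tokenize_phrase(text, convention)]


class NgramModel:
    """n-gram scores over a closed vocabulary with stupid backoff.

    Parameters
    ----------
    order
        Maximum n-gram length (>= 1).
    logprob
        Mapping from n-gram tuples (length 1..order) to log10 relative
        frequency.
    alpha
        Backoff discount applied once per shortening step.
    """

    def __init__(self, order: int, logprob: dict[tuple[str, ...], float], alpha: float = 0.4):
        if order < 1:
            raise ValidationError("order must be >= 1")
        if not 0.0 < alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
        self.order = order
        self.alpha = alpha
        self._logprob = dict(logprob)
        self._log_alpha = math.log10(alpha)
        self.vocab: frozenset[str] = frozenset(ng[0] for ng in self._logprob if len(ng) == 1)

    @property
    def words(self) -> tuple[str, ...]:
        """Vocabulary without sentence markers, sorted (the candidate pool)."""
        return tuple(sorted(self.vocab - {BOS, EOS}))

    def score(self, word: str, history: Sequence[str] = ()) -> float:
        """log10 stupid-backoff score of ``word`` given ``history``."""
        h = tuple(history)[-(self.order - 1):] if self.order > 1 else ()
        penalty = 0.0
        while True:
            lp = self._logprob.get(h + (word,))
            if lp is not None:
                return lp + penalty
            if not h:
                return NEG_INF
            h = h[1:]
            penalty += self._log_alpha

    def sequence_score(self, words: Sequence[str], *, eos: bool = True) -> float:
        """Score of a sentence: sum of per-word scores from ``<s>``."""
        history: tuple[str, ...] = (BOS,)
        total = 0.0
        for w in words:
            total += self.score(w, history)
            history += (w,)
        if eos:
            total += self.score(EOS, history)
        return total

    # -- ARPA interchange ---------------------------------------------------

    def to_arpa(self, path: str | Path) -> None:
        by_order: dict[int, list[tuple[tuple[str, ...], float]]] = {}
        for ng, lp in self._logprob.items():
            by_order.setdefault(len(ng), []).append((ng, lp))
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("\\data\\\n")
            for n in range(1, self.order + 1):
                fh.write(f"ngram {n}={len(by_order.get(n, []))}\n")
            for n in range(1, self.order + 1):
                fh.write(f"\n\\{n}-grams:\n")
                for ng, lp in sorted(by_order.get(n, [])):
                    fh.write(f"{lp:.6f}\t{' '.join(ng)}\n")
            fh.write("\n\\end\\\n")

    @classmethod
    def from_arpa(cls, path: str | Path, alpha: float = 0.4) -> "NgramModel":
        logprob: dict[tuple[str, ...], float] = {}
        order = 0
        section = 0
        section_re = re.compile(r"\\(\d+)-grams:")
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line == "\\data\\" or line.startswith("ngram "):
                    continue
                if line == "\\end\\":
                    break
                m = section_re.fullmatch(line)
                if m:
                    section = int(m.group(1))
                    order = max(order, section)
                    continue
                if section == 0:
                    raise ParseError(f"{path} line {lineno}: entry outside an n-gram section")
                fields = line.split("\t") if "\t" in line else line.split()
                try:
                    lp = float(fields[0])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path} line {lineno}: bad log-probability") from exc
                tokens = tuple(" ".join(fields[1:]).split()[:section]) if "\t" in line else tuple(fields[1 : 1 + section])
                if len(tokens) != section:
                    raise ParseError(f"{path} line {lineno}: expected a {section}-gram")
                logprob[tokens] = lp
        if not logprob:
            raise ParseError(f"{path}: no n-gram entries found")
        return cls(order, logprob, alpha)


def train_ngram(
    corpus_text: Iterable[str],
    order: int,
    alpha: float = 0.4,
    convention: PunctuationConvention = DEFAULT_CONVENTION,
) -> NgramModel:
    """Train an :class:`NgramModel` from sentences (one string each).

    The vocabulary is closed: corpus tokens plus the sentence markers.
    Relative frequencies are exact counts, so training is deterministic.
    """
    sequences = []
    for sentence in corpus_text:
        words = normalize_sentence(sentence, convention)
        if words:
            sequences.append([BOS] + words + [EOS])
    if not sequences:
        raise ValidationError("training corpus is empty")

    counts: dict[tuple[str, ...], int] = {}
    total_tokens = 0
    for seq in sequences:
        total_tokens += len(seq)
        for n in range(1, order + 1):
            for i in range(len(seq) - n + 1):
                ng = tuple(seq[i : i + n])
                counts[ng] = counts.get(ng, 0) + 1

    logprob: dict[tuple[str, ...], float] = {}
    for ng, c in counts.items():
        denom = total_tokens if len(ng) == 1 else counts[ng[:-1]]
        logprob[ng] = math.log10(c / denom)
    return NgramModel(order, logprob, alpha)
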