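# Methods

## The abbreviation schemes

A phrase is tokenized into whitespace words; hyphenated tokens are single
words. Each word contributes one *segment* to the abbreviation:

* **INITIAL** — the word's first alphanumeric character, lowercased. A
  contracted word ("you're") contributes only its initial. Words beginning
  with a digit contribute that digit.
* **KEYWORD_FULL** — the word spelled out (lowercased, trailing punctuation
  excluded, apostrophes kept).
* **KEYWORD_PREFIX** — a prefix of the word, two or more characters. The
  prefix is tested against the raw word including apostrophes; no
  apostrophe-skipping is attempted.
* **KEYWORD_CONSONANT** — a prefix of the word's consonant skeleton: the
  word lowercased with every non-initial vowel (`a e i o u`) removed
  (`bedroom → bdrm`).

Mid-sentence punctuation (default `, ; :`) adjacent to a word is retained
in the abbreviation, attached to that word's segment; sentence-final
punctuation (default `. ! ?`) is dropped wherever it appears. Both sets are
configurable via `PunctuationConvention`; whether marks other than the
comma should be retained is genuinely open, so the default keeps the three
common mid-sentence marks.

Two string dialects exist. COMPACT is the display form (initial runs
concatenated, keywords space-delimited: `ishpit bedroom`). SPACED is the
serialization form used for training triplets (`i s h p i t bedroom`).
COMPACT is ambiguous as a free string — `saw` could be one keyword or three
initials — so parsing is defined only for SPACED; `validate_shorthand`
accepts either dialect when a reference phrase is available, resolving the
alignment by backtracking and promoting keyword tokens to whichever kind
(full / prefix / consonant) fits the aligned word.

`matches` is strict about declared segment kinds and, by default, about
trailing punctuation. Predictor outputs live in punctuation-stripped
lowercase space, so predictor invariants use `require_punct=False`; the
simulator re-attaches punctuation and casing when a phrase is committed.

## Synthetic dialogues

The generator emits six-turn, two-speaker, alternating dialogues from a
small template grammar: an opener question plus reply templates with
content-noun slots, all templates at most ten words counting mid-sentence
punctuation (the same length measure used to filter simulation corpora).
Templates rather than a language model keep test corpora auditable. Knobs:

* `vocab_size` (default 60) — content nouns drawn from a built-in list of
  80. The list includes prefix-sharing families (garden/garage,
  bedroom/bedrock, kitchen/kitten) so that realistic near-miss candidates
  sharing more than an initial occur.
* `word_reuse_prob` (default 0.5) — probability that a content slot repeats
  a content word from a *completed* earlier turn of the same dialogue.
  This is the mechanism that makes conversational context informative; at
  1.0 every later content word is a repeat.
* `max_turn_length` (default 10) — hard bound checked on every turn.

What the generator does **not** emulate: topic structure, disfluencies,
typos, out-of-vocabulary words, and the length/complexity distribution of
natural dialogue. Passing tests therefore demonstrate the correctness and
the directional behaviour of the machinery (context helps; savings grow
with options; fill-mask beats spelling at one wrong word), not the KSR
levels achievable on natural conversations, which depend on the predictor's
real-world accuracy.

## Predictors

The n-gram backend is a stupid-backoff model: relative frequencies for
observed n-grams, a fixed discount `alpha = 0.4` per backoff step, log10
scores, closed vocabulary with `<s>`/`</s>` markers. Stupid backoff was
chosen over Katz or Kneser–Ney because the model is a deterministic test
instrument, not a contribution; ARPA files are read for their
log-probabilities only, with the uniform alpha applied in place of stored
backoff weights.

*Expansion* is a left-to-right beam search, one step per word position; the
candidate set at position *i* is the vocabulary words consistent with
segment *i*. Hypothesis score = sum of per-word LM scores, plus the
end-of-sentence transition, plus `context_boost` (default 0.5 log10 units)
for every word present in the prior turns. The boost is the desk-scale
stand-in for context conditioning; setting it to zero reproduces the
no-context condition exactly. Ties break by score then lexicographically,
everywhere, making every ranking reproducible. The beam (default width 16,
12 in the corpus studies) is exact when wider than the consistent phrase
space; the test suite checks equality against exhaustive enumeration on
random vocabularies up to 30 words and 4-word phrases. `NgramPredictor`
computes each ranked list once at depth 32 and slices, so a larger
`n_options` always extends — never reorders — a smaller one.

*Fill-mask* scores candidate words with matching initial by left-history LM
score plus the right neighbour's score given the candidate (skipped for a
final slot) plus the context boost. *Forward prediction* is completion
(prefix-filtered vocabulary ranked by history score) or next-word
prediction when no letters are typed.

The oracle backend fabricates rankings around the known reference: the
truth appears at `reveal_rank` once the abbreviation has `min_typed_chars`
typed letters; the other slots are decoys consistent with the abbreviation,
built by substituting a fixed, seeded set of `decoy_distance` word
positions with lexicon words preferring the longest shared prefix
(`near_miss`) or a seeded shuffle (`random`). When a position's constraint
excludes every alternative, the decoy reverts to the truth word there; if
no live decoy remains, a finite-`min_typed_chars` oracle reveals the truth
(its constraint space has collapsed), while an infinite one returns an
empty list, exercising the simulator's full-spell fallback. The fill-mask
oracle's default `context_sensitive` mode succeeds only when the unmasked
words of the query are all correct — emulating a predictor misled by wrong
surrounding words, which is what makes engaging fill-mask with two wrong
words costlier than with one.

## The simulator

Each turn starts by typing the initials abbreviation (one action per letter
and per retained punctuation mark) and issuing one expansion call. Calls
are free under automatic triggering (the default); manual triggering costs
one `expand_trigger` action per call. If the reference (compared word-wise,
case-insensitively, punctuation aside) is among the top `n_options`, one
phrase-selection action ends the turn.

Otherwise the strategy loop runs. `best_match` picks the candidate with the
most position-wise word matches (ties: reference word count, then rank) and
its incorrect reference positions; candidates of differing length are
aligned over the shorter, with missing reference positions counted
incorrect. Keyword spelling targets the leftmost incorrect position:
version v1 selects the word's chip and types it in full, then calls once;
v2 selects the chip when switching positions and appends one letter at a
time with a call — and a re-evaluation of the best candidate — after every
keystroke. Entering spell mode costs one action, once per turn. Strategy 2
switches to fill-mask when exactly one incorrect word remains; strategy 2A
when two or fewer remain, handling them left to right. The fill-mask block
costs one mode entry, plus per word one chip selection and either one
option selection (success) or typing the word in full (failure; the known
wrong word is passed to the predictor's exclusion set). After fill-mask
begins, keyword mode is never re-entered. When every position is fully
spelled the phrase is committed directly (`FULL_SPELL`). An upper bound of
`ref_chars + 3·words + 8` iterations is asserted, never reached.

The KSR denominator is the reference's characters including interior spaces
and mid-sentence punctuation, excluding sentence-final punctuation — the
standard text-entry convention, and the one that makes the perfect-predictor
ledger exact (7 + 1 actions for a 32-character phrase: KSR 0.75). Spaces
can be excluded and the spell-button and speaker-button actions can each be
switched off to bound their contribution to any comparison.

The baseline models a conventional predictive keyboard: before every
keystroke consult the top-n completions (or next-word predictions at a word
boundary); selecting the intended word costs one action and commits the
word plus one following space (a word with trailing punctuation commits
without the space, which is typed after the punctuation; the final word
commits without a space). Spaces and punctuation are otherwise typed
literally, so a never-predicting model gives KSR exactly 0.

`project_time` is plumbing: a linear combination of ledger counts with unit
costs (keystroke/UI click, per-option review, per-call latency). It fits no
empirical model and its defaults are round numbers for illustration.

## Triplet synthesis

Every turn yields an initials-only `{context, shorthand, full}` triplet
plus one sampled variant per enabled keyword scheme; contexts are the prior
turns each wrapped in curly braces, concatenated (first turns have empty
context). Shorthands use the SPACED dialect. Keyword counts are sampled
uniformly from {1, 2}, positions uniformly without replacement, prefix
lengths uniformly from 2..len−1 and consonant lengths from 2..skeleton
length; the reference mixing proportions are not public, so these defaults
are explicit placeholders in `SynthesisConfig`. Fill-mask triplets replace
one word with its initial plus `_` (surrounding punctuation intact) and
never mask words starting with a digit or punctuation mark; with-context
examples are emitted alongside no-context variants.

## Study sizes and determinism

The bundled studies use 100 six-turn dialogues (600 turns) for simulation
and a disjoint 300-dialogue corpus for LM training, sizes at which a full
strategy-by-options sweep completes in seconds while leaving enough turns
for stable means. All randomness — generation, sampling, decoys — flows
from explicit integer seeds; repeated runs are byte-identical. Degenerate
inputs are defined, not special-cased: empty expansion results trigger
spelling fallbacks, turns with no maskable word are skipped and counted,
and a reference with no alphabetic word is a validation error.

## Known limitations

No typo tolerance, no revision or backspace modelling, no cognitive-load
model, single-sentence turns, Latin scripts only. The n-gram expander is a
structural stand-in for a large-LM predictor: it defines the interaction
costs exactly but underestimates the accuracy gap between abbreviation
expansion and forward prediction on natural text, because on the templated
corpus a trigram is already close to ceiling for both.
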