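"""Interaction simulation: ledgers, strategies, baseline, aggregation."""

import math

import pytest

from abbrex.corpus import Context, GeneratorConfig, generate_synthetic_corpus
from abbrex.errors import ValidationError
from abbrex.lm import train_ngram
from abbrex.predictors import OracleConfig, OraclePredictor, RankedPhrases, ScoredOption
from abbrex.simulator import (
    AEVersion,
    CostParams,
    SimConfig,
    SolvedBy,
    Strategy,
    best_match,
    project_time,
    reference_char_count,
    run_baseline_simulation,
    run_simulation,
    simulate_baseline_turn,
    simulate_turn,
    write_summary_tsv,
)


def ranked(*texts):
    return RankedPhrases(tuple(ScoredOption(t, -float(i), i + 1) for i, t in enumerate(texts)))


class TestBestMatch:
    def test_near_miss_scenario(self):
        opts = ranked("i saw him play in the backyard", "it should have been said by now")
        idx, incorrect = best_match(opts, "i saw him play in the bedroom")
        assert idx == 0 and incorrect == (6,)

    def test_exact_reference_present(self):
        opts = ranked("b c", "a b")
        idx, incorrect = best_match(opts, "a b")
        assert idx == 1 and incorrect == ()

    def test_tie_breaks_by_rank(self):
        opts = ranked("a x c", "a y c")
        idx, _ = best_match(opts, "a b c")
        assert idx == 0

    def test_length_mismatch_counts_missing_as_incorrect(self):
        opts = ranked("a b")
        _, incorrect = best_match(opts, "a b c d")
        assert incorrect == (2, 3)

    def test_empty_options_rejected(self):
        with pytest.raises(ValidationError):
            best_match(RankedPhrases(()), "a b")


class TestHandLedgers:
    """Action-for-action checks against hand-computed ledgers."""

    def test_perfect_oracle_initials_only(self):
        p = OraclePredictor(OracleConfig(reveal_rank=1, min_typed_chars=0))
        cfg = SimConfig(strategy=Strategy.S1, ae_version=AEVersion.V1)
        o = simulate_turn("I saw him playing in the bedroom", Context(()), p, cfg)
        assert o.ref_char_count == 32
        assert o.ledger.key_char == 7 and o.ledger.select_phrase == 1
        assert o.total_actions == 8
        assert o.ksr == pytest.approx(0.75)
        assert o.solved_by is SolvedBy.INITIALS_ONLY
        assert o.ledger.num_ae_calls == 1

    def test_adversarial_full_spell_negative_ksr(self):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=2, decoy_positions=(0, 1)))
        cfg = SimConfig(strategy=Strategy.S1, ae_version=AEVersion.V1)
        o = simulate_turn("hi there", Context(()), p, cfg)
        led = o.ledger
        # 2 abbrev keys + spell mode + 2 chips + 7 word keys + phrase select
        assert (led.key_char, led.spell_mode_enter, led.chip_select, led.select_phrase) == (9, 1, 2, 1)
        assert o.total_actions == 13
        assert o.ksr == pytest.approx(1 - 13 / 8)
        assert o.solved_by is SolvedBy.FULL_SPELL

    def test_near_miss_fillmask(self):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=1, decoy_positions=(6,)))
        cfg = SimConfig(strategy=Strategy.S2, ae_version=AEVersion.V2)
        o = simulate_turn("I saw him play in the bedroom", Context(()), p, cfg)
        led = o.ledger
        assert (led.fm_enter, led.fm_word_select, led.fm_option_select) == (1, 1, 1)
        assert o.total_actions == 11  # 7 + 4
        assert o.solved_by is SolvedBy.FILLMASK
        assert led.num_ae_calls == 1 and led.num_fm_calls == 1

    def test_s2a_two_word_fillmask_with_one_fallback(self):
        # Two wrong words; the first FillMask query still contains the other
        # wrong word, so the context-sensitive oracle fails and the word is
        # typed in full; the second call succeeds.
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=2, decoy_positions=(3, 4)))
        cfg = SimConfig(strategy=Strategy.S2A, ae_version=AEVersion.V2)
        o = simulate_turn("i like the green garden", Context(()), p, cfg)
        led = o.ledger
        assert (led.fm_enter, led.fm_word_select, led.fm_option_select) == (1, 2, 1)
        assert led.key_char == 5 + 5  # abbreviation + typing "green"
        assert o.total_actions == 15
        assert o.solved_by is SolvedBy.FILLMASK

    def test_manual_trigger_costs_one_action_per_call(self):
        p = OraclePredictor(OracleConfig(reveal_rank=1, min_typed_chars=0))
        cfg = SimConfig(strategy=Strategy.S1, ae_version=AEVersion.V1, auto_trigger=False)
        o = simulate_turn("I saw him playing in the bedroom", Context(()), p, cfg)
        assert o.ledger.expand_trigger == 1
        assert o.total_actions == 9
        assert o.ksr == pytest.approx(1 - 9 / 32)


class TestStrategyBehaviour:
    def test_ksr_identity_invariant(self, small_corpus):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=1))
        report = run_simulation(small_corpus, p, SimConfig(strategy=Strategy.S2))
        for o in report.outcomes:
            assert o.ksr == pytest.approx(1 - o.total_actions / o.ref_char_count)
            assert o.total_actions == o.ledger.total_actions

    def test_full_spell_termination_under_adversary(self, small_corpus):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoys="random", decoy_distance=3))
        for strat in (Strategy.S1,):
            for version in (AEVersion.V1, AEVersion.V2):
                report = run_simulation(
                    small_corpus[:5], p, SimConfig(strategy=strat, ae_version=version)
                )
                assert all(o.solved_by is SolvedBy.FULL_SPELL for o in report.outcomes)

    def test_v2_never_types_more_than_v1_under_monotone_oracle(self, small_corpus):
        # An oracle gated only on typed characters is monotone: success on an
        # abbreviation implies success on any more-specified one.
        for d in small_corpus[:6]:
            for turn in d.turns:
                keys = {}
                for version in (AEVersion.V1, AEVersion.V2):
                    p = OraclePredictor(OracleConfig(min_typed_chars=9, decoy_distance=1))
                    o = simulate_turn(turn.text, Context(()), p, SimConfig(strategy=Strategy.S1, ae_version=version))
                    keys[version] = o.ledger.key_char
                assert keys[AEVersion.V2] <= keys[AEVersion.V1]

    def test_s2_beats_s1_v1_on_long_near_miss_word(self):
        # FillMask replaces one wrong 7-letter word: 4 actions vs 2 + 7.
        ref = "i saw him play in the bedroom"
        outcomes = {}
        for strat in (Strategy.S1, Strategy.S2):
            p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=1, decoy_positions=(6,)))
            outcomes[strat] = simulate_turn(ref, Context(()), p, SimConfig(strategy=strat, ae_version=AEVersion.V1))
        assert outcomes[Strategy.S2].total_actions < outcomes[Strategy.S1].total_actions

    def test_s2a_uses_at_least_as_many_fillmask_calls_as_s2(self, small_corpus):
        calls = {}
        for strat in (Strategy.S2, Strategy.S2A):
            p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=2, seed=3))
            report = run_simulation(small_corpus, p, SimConfig(strategy=strat, ae_version=AEVersion.V2))
            calls[strat] = sum(o.ledger.num_fm_calls for o in report.outcomes)
        assert calls[Strategy.S2A] >= calls[Strategy.S2]

    def test_monotone_in_n_options_with_oracle(self):
        ref = "the garden was great"
        prev_actions = None
        for n in range(1, 6):
            p = OraclePredictor(OracleConfig(reveal_rank=3, min_typed_chars=0, decoy_distance=1))
            o = simulate_turn(ref, Context(()), p, SimConfig(strategy=Strategy.S1, n_options=n))
            if prev_actions is not None:
                assert o.total_actions <= prev_actions
            prev_actions = o.total_actions

    def test_reference_without_alphabetic_word_rejected(self):
        p = OraclePredictor(OracleConfig())
        with pytest.raises(ValidationError):
            simulate_turn("911, 411", Context(()), p, SimConfig())


class TestBaseline:
    def test_never_predicting_lm_gives_zero_ksr(self):
        model = train_ngram(["zzz yyy"], 2)
        o = simulate_baseline_turn("hi there, my friend", Context(()), model, 5)
        assert o.total_actions == o.ref_char_count == reference_char_count("hi there, my friend")
        assert o.ksr == 0.0

    def test_memorized_sentence_hand_ledger(self):
        model = train_ngram(["this test works fine"], 3)
        o = simulate_baseline_turn("this test works fine", Context(()), model, 5)
        # every word selected at word start via next-word prediction
        assert o.ledger.baseline_option_select == 4 and o.ledger.key_char == 0
        assert o.ksr == pytest.approx(1 - 4 / 20)
        assert o.ksr > 0.5

    def test_zero_options_rejected(self):
        model = train_ngram(["a b"], 2)
        with pytest.raises(ValidationError):
            simulate_baseline_turn("a b", Context(()), model, 0)


class TestAggregation:
    def test_perfect_oracle_single_call_fraction_one(self, small_corpus):
        p = OraclePredictor(OracleConfig(reveal_rank=1, min_typed_chars=0))
        report = run_simulation(small_corpus, p, SimConfig())
        assert report.single_call_fraction == 1.0
        assert all(o.solved_by is SolvedBy.INITIALS_ONLY for o in report.outcomes)

    def test_adversarial_single_call_fraction_zero(self, small_corpus):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=2))
        report = run_simulation(small_corpus[:5], p, SimConfig(strategy=Strategy.S1))
        assert report.single_call_fraction == 0.0

    def test_mixed_oracle_fraction_half(self, small_corpus):
        class Alternating(OraclePredictor):
            def __init__(self):
                super().__init__(OracleConfig(min_typed_chars=0, decoy_distance=2))
                self._n = 0

            def begin_turn(self, reference):
                gate = 0 if self._n % 2 == 0 else math.inf
                self.config = OracleConfig(min_typed_chars=gate, decoy_distance=2)
                self._n += 1
                super().begin_turn(reference)

        report = run_simulation(small_corpus, Alternating(), SimConfig(strategy=Strategy.S1))
        assert report.single_call_fraction == pytest.approx(0.5)

    def test_report_serialization(self, tmp_path, small_corpus):
        p = OraclePredictor(OracleConfig())
        report = run_simulation(small_corpus[:3], p, SimConfig())
        report.to_json(tmp_path / "r.json")
        write_summary_tsv([report], tmp_path / "s.tsv")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        assert lines[0].startswith("strategy\t") and len(lines) == 2

    def test_baseline_run(self, small_corpus, corpus_lm):
        report = run_baseline_simulation(small_corpus, corpus_lm, 5)
        assert report.n_turns == 6 * len(small_corpus)
        assert -1.0 < report.mean_ksr <= 1.0


class TestProjectTime:
    def test_zero_costs(self, small_corpus):
        p = OraclePredictor(OracleConfig())
        o = run_simulation(small_corpus[:1], p, SimConfig()).outcomes[0]
        total, breakdown = project_time(o, CostParams(0, 0, 0))
        assert total == 0 and all(v == 0 for v in breakdown.values())

    def test_keystroke_only(self, small_corpus):
        p = OraclePredictor(OracleConfig())
        o = run_simulation(small_corpus[:1], p, SimConfig()).outcomes[0]
        total, breakdown = project_time(o, CostParams(10, 0, 0))
        assert breakdown["typing_ms"] == 10 * o.ledger.key_char
        assert total == 10 * o.total_actions  # keys + UI clicks at same cost

    def test_linearity(self, small_corpus):
        p = OraclePredictor(OracleConfig(min_typed_chars=math.inf, decoy_distance=1))
        o = run_simulation(small_corpus[:1], p, SimConfig(strategy=Strategy.S2)).outcomes[0]
        t1, _ = project_time(o, CostParams(3, 5, 7))
        t2, _ = project_time(o, CostParams(6, 10, 14))
        assert t2 == pytest.approx(2 * t1)

    def test_negative_costs_rejected(self):
        with pytest.raises(ValidationError):
            CostParams(-1, 0, 0)
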