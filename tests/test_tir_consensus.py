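"""TIR sign calls, the 2-of-3 consensus rule, and the surrogate window scorer."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from taclass.tir_consensus import (
    ANTITOXIN_HIGHER,
    INSUFFICIENT,
    SD_CONSENSUS,
    TOXIN_HIGHER,
    TirCall,
    builtin_window_score,
    consensus,
    load_scorer_config,
    read_tir_table,
)


def call(sign_up, method="barrick", variant="P1", operon="op"):
    ta, tt = (2.0, 1.0) if sign_up else (1.0, 2.0)
    return TirCall(operon, method, variant, ta, tt)


def calls(*signs, variant="P1"):
    methods = ["rbs_calculator", "utr_designer", "barrick"]
    return [call(s, m, variant) for s, m in zip(signs, methods)]


class TestConsensus:
    @pytest.mark.parametrize(
        "signs,verdict",
        [
            ((True, True, True), ANTITOXIN_HIGHER),
            ((False, True, True), ANTITOXIN_HIGHER),   # MqsAR-style split
            ((False, False, True), TOXIN_HIGHER),      # HicAB-P1-style split
            ((False, False, False), TOXIN_HIGHER),
        ],
    )
    def test_majority(self, signs, verdict):
        assert consensus(calls(*signs)).verdict == verdict

    def test_single_call_insufficient(self):
        assert consensus([call(True)]).verdict == INSUFFICIENT

    def test_empty_insufficient(self):
        assert consensus([]).verdict == INSUFFICIENT

    def test_even_split_insufficient(self):
        assert consensus(calls(True, False)).verdict == INSUFFICIENT

    def test_permutation_invariance(self):
        for perm in itertools.permutations(calls(False, True, True)):
            assert consensus(list(perm)).verdict == ANTITOXIN_HIGHER

    def test_brute_force_majority_over_all_sign_patterns(self):
        for signs in itertools.product([True, False], repeat=3):
            got = consensus(calls(*signs)).verdict
            ups = sum(signs)
            expected = ANTITOXIN_HIGHER if ups >= 2 else TOXIN_HIGHER
            assert got == expected, signs

    def test_flipping_all_signs_flips_verdict(self):
        for signs in itertools.product([True, False], repeat=3):
            v = consensus(calls(*signs)).verdict
            flipped = consensus(calls(*[not s for s in signs])).verdict
            assert {v, flipped} == {ANTITOXIN_HIGHER, TOXIN_HIGHER}

    def test_mixed_operons_rejected(self):
        with pytest.raises(ValueError):
            consensus([call(True, operon="a"), call(True, operon="b",
                                                    method="utr_designer")])

    def test_hicab_variant_flip(self, fixture_consensus):
        """P1 signs (-,-,+) give toxin_higher; P2 signs (+,-,+) flip the
        verdict to antitoxin_higher."""
        assert fixture_consensus["HicAB"]["P1"].verdict == TOXIN_HIGHER
        assert fixture_consensus["HicAB"]["P2"].verdict == ANTITOXIN_HIGHER


class TestTirTable:
    def test_read_and_sign(self, tmp_path):
        path = tmp_path / "tir.tsv"
        path.write_text(
            "operon_id\tmethod\tvariant\ttir_antitoxin\ttir_toxin\n"
            "relBE\tbarrick\tP1\t1200\t300\n"
            "relBE\tutr_designer\tP1\t10\t40\n"
        )
        got = read_tir_table(path)
        assert [c.sign for c in got] == [ANTITOXIN_HIGHER, TOXIN_HIGHER]

    def test_ties_and_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "tir.tsv"
        path.write_text(
            "operon_id\tmethod\tvariant\ttir_antitoxin\ttir_toxin\n"
            "a\tbarrick\tP1\t100\t100\n"
            "b\tbarrick\tP1\tNA\t100\n"
            "c\tbarrick\tP1\t200\t100\n"
        )
        got = read_tir_table(path)
        assert [c.operon_id for c in got] == ["c"]

    def test_tie_forbidden_in_type(self):
        with pytest.raises(ValueError):
            TirCall("op", "barrick", "P1", 5.0, 5.0)


class TestBuiltinScorer:
    def test_sd_consensus_beats_sd_free_window(self):
        """An AGGAGG at favourable spacing outscores a C-run, for any
        positive anti-SD weight."""
        sd_seq = "CC" + SD_CONSENSUS + "CCC" + "C" + "ATGAAA"
        cc_seq = "CCCCCCCCCCCC" + "ATGAAA"
        start = 12
        assert builtin_window_score(sd_seq, start) > builtin_window_score(cc_seq, start)

    def test_deterministic(self):
        seq = "ACGTACGGAGGTACGATGAAA"
        start = seq.index("ATG", 10)
        assert builtin_window_score(seq, start) == builtin_window_score(seq, start)

    def test_window_off_sequence_errors(self):
        with pytest.raises(ValueError):
            builtin_window_score("ATGAAA", 0)

    def test_matches_brute_force_log_linear_oracle(self):
        """Random coefficient configs and windows: the score equals a direct
        evaluation of the stated log-linear formula."""
        rng = np.random.default_rng(9)
        bases = "ACGT"
        for _ in range(100):
            config = {
                "asd_weight": float(rng.uniform(0.1, 3)),
                "optimal_spacing": int(rng.integers(4, 10)),
                "spacing_penalty": float(rng.uniform(0, 1)),
                "base_weights": {b: float(rng.normal(0, 0.3)) for b in bases},
                "position_weights": {
                    int(rng.integers(-11, 1)): {b: float(rng.normal(0, 0.5))
                                                for b in bases}
                },
            }
            seq = "".join(rng.choice(list(bases), size=40))
            start = 20
            window = (-11, 0)
            win = seq[start - 11:start + 1]
            expected = 0.0
            for i, base in enumerate(win):
                offset = window[0] + i
                weights = config["position_weights"].get(offset,
                                                         config["base_weights"])
                expected += weights.get(base, 0.0)
            best = 0.0
            for i in range(len(win) - 6 + 1):
                matches = sum(a == b for a, b in zip(win[i:i + 6], SD_CONSENSUS))
                spacing = -(window[0] + i + 6)
                best = max(best, matches * config["asd_weight"]
                           - abs(spacing - config["optimal_spacing"])
                           * config["spacing_penalty"])
            got = builtin_window_score(seq, start, config=config)
            assert got == pytest.approx(expected + best, abs=1e-12)

    def test_bundled_config_loads_and_validates(self, tmp_path):
        config = load_scorer_config()
        assert config["asd_weight"] > 0
        bad = tmp_path / "bad.yaml"
        bad.write_text("asd_weight: 1.0\n")
        with pytest.raises(ValueError):
            load_scorer_config(bad)


@given(st.integers(0, 7))
def test_consensus_equals_popcount_majority(pattern):
    signs = [(pattern >> i) & 1 == 1 for i in range(3)]
    verdict = consensus(calls(*signs)).verdict
    assert verdict == (ANTITOXIN_HIGHER if sum(signs) >= 2 else TOXIN_HIGHER)
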