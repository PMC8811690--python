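"""Tokenization, stop-word handling, and lexical statistics."""
import logging
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termlex import lexical_metrics as lm
from termlex.errors import UndefinedDensityError
from termlex.types import ConceptRecord

from naive_oracle import naive_profile


def rec(name: str, vocab: str = "V") -> ConceptRecord:
    return ConceptRecord(concept_id=f"id-{hash((name, vocab)) & 0xFFFF:x}-{name[:6]}",
                         name=name, source_vocab=vocab)


class TestTokenize:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("", []),
            ("Radiation therapy of brain", ["radiation", "therapy", "of", "brain"]),
            (
                "Intensity-modulated radiation therapy (IMRT)",
                ["intensity", "modulated", "radiation", "therapy", "imrt"],
            ),
            ("Dose 10 Gy/fraction", ["dose", "10", "gy", "fraction"]),
        ],
    )
    def test_default_pattern(self, name, expected, config):
        assert lm.tokenize(name, config) == expected

    def test_numeric_tokens_can_be_dropped(self):
        cfg = lm.TokenizationConfig(keep_numeric_tokens=False)
        assert lm.tokenize("Dose 10 Gy", cfg) == ["dose", "gy"]

    def test_case_folding_is_configurable(self):
        cfg = lm.TokenizationConfig(lowercase=False)
        assert lm.tokenize("Radiation Therapy", cfg) == ["Radiation", "Therapy"]

    def test_stopword_removal_preserves_order(self, config):
        toks = ["radiation", "therapy", "of", "brain"]
        assert lm.remove_stopwords(toks, config) == ["radiation", "therapy", "brain"]
        assert lm.remove_stopwords([], config) == []
        no_stops = ["proton", "beam"]
        assert lm.remove_stopwords(no_stops, config) == no_stops

    @pytest.mark.parametrize(
        "name,length",
        [("", 0), ("Radiation therapy of brain", 3), ("the of a", 0)],
    )
    def test_concept_length_counts_post_stop_tokens(self, name, length, config):
        assert lm.concept_length(name, config) == length

    def test_stopword_file_source(self, tmp_path):
        stop = tmp_path / "stop.txt"
        stop.write_text("# custom\nbrain\n", encoding="utf-8")
        cfg = lm.TokenizationConfig.from_dict({"stopwords": f"file:{stop}"})
        assert lm.concept_length("Radiation of brain", cfg) == 2  # only 'brain' dropped


class TestLexicalDensity:
    def test_all_unique_gives_one(self):
        assert lm.lexical_density(5, 5) == 1.0

    def test_corpus_scale_ratio_rounds_to_two_decimals(self):
        from termlex._rounding import round_half_up

        assert round_half_up(lm.lexical_density(56219, 1048), 2) == 0.02

    def test_dominant_vocabulary_ratio_rounds_to_zero(self):
        from termlex._rounding import round_half_up

        assert round_half_up(lm.lexical_density(50682, 175), 1) == 0.0

    def test_zero_total_words_is_an_error(self):
        with pytest.raises(UndefinedDensityError):
            lm.lexical_density(0, 0)

    def test_unique_above_total_is_an_error(self):
        with pytest.raises(ValueError):
            lm.lexical_density(3, 4)


class TestVocabProfile:
    def test_single_concept_all_distinct_words(self, config):
        p = lm.vocab_profile([rec("Anatomical chemical classification system level")], config)
        assert (
            p.total_words,
            p.unique_words,
            p.lexical_density,
            p.avg_len,
            p.median_len,
            p.max_len,
            p.min_len,
        ) == (5, 5, 1.0, 5.0, 5.0, 5, 5)

    def test_single_word_concept(self, config):
        p = lm.vocab_profile([rec("Radiotherapy")], config)
        assert (p.total_words, p.unique_words, p.lexical_density) == (1, 1, 1.0)
        assert (p.avg_len, p.median_len, p.max_len, p.min_len) == (1.0, 1.0, 1, 1)

    def test_word_reuse_lowers_density(self, config):
        p = lm.vocab_profile([rec("alpha beta gamma"), rec("alpha beta")], config)
        assert (p.total_words, p.unique_words) == (5, 3)
        assert p.lexical_density == pytest.approx(0.6)
        assert (p.avg_len, p.median_len, p.max_len, p.min_len) == (2.5, 2.5, 3, 2)

    def test_degenerate_vocabulary_flagged_not_silent(self, config, caplog):
        with caplog.at_level(logging.WARNING):
            p = lm.vocab_profile([rec("of the"), rec("and")], config)
        assert p.total_words == 0
        assert p.lexical_density is None
        assert any("degenerate" in r.message for r in caplog.records)

    def test_mixed_vocabularies_rejected(self, config):
        with pytest.raises(ValueError):
            lm.vocab_profile([rec("a", "X"), rec("b", "Y")], config)

    def test_empty_group_rejected(self, config):
        with pytest.raises(ValueError):
            lm.vocab_profile([], config)

    @given(
        word_lists=st.lists(
            st.lists(
                st.sampled_from(["alpha", "beta", "gamma", "delta", "of", "the"]),
                min_size=1,
                max_size=6,
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_profile_invariants_and_density_identity(self, word_lists, config):
        concepts = [rec(" ".join(ws) + f" x{i}" * 0) for i, ws in enumerate(word_lists)]
        # hypothesis may generate identical names; give records distinct ids
        concepts = [
            ConceptRecord(str(i), c.name, "V") for i, c in enumerate(concepts)
        ]
        p = lm.vocab_profile(concepts, config)
        assert 0 <= p.unique_words <= p.total_words
        assert p.min_len <= p.median_len <= p.max_len
        assert p.min_len <= p.avg_len <= p.max_len
        assert p.n_concepts * p.min_len <= p.total_words <= p.n_concepts * p.max_len
        if p.lexical_density is not None:
            assert 0 <= p.lexical_density <= 1
            assert math.isclose(
                p.lexical_density * p.total_words, p.unique_words, abs_tol=1e-12
            )
            assert (p.lexical_density == 1.0) == (p.unique_words == p.total_words)

    def test_adding_a_concept_is_monotone(self, config):
        base = [rec("alpha beta gamma"), rec("beta delta")]
        extended = base + [rec("epsilon")]
        p0 = lm.vocab_profile(
            [ConceptRecord(str(i), c.name, "V") for i, c in enumerate(base)], config
        )
        p1 = lm.vocab_profile(
            [ConceptRecord(str(i), c.name, "V") for i, c in enumerate(extended)], config
        )
        assert p1.total_words >= p0.total_words
        assert p1.unique_words >= p0.unique_words
        assert p1.min_len <= p0.min_len

    def test_profile_matches_bruteforce_oracle(self, config):
        names = [
            "Radiation therapy of the brain",
            "Radiation therapy",
            "Proton beam therapy with breath hold",
            "10 Gy in 5 fractions",
        ]
        concepts = [ConceptRecord(str(i), n, "V") for i, n in enumerate(names)]
        p = lm.vocab_profile(concepts, config)
        expected = naive_profile(names, config.stopwords)
        for key, value in expected.items():
            assert p.metric(key) == pytest.approx(value), key


class TestPropagationAndTotals:
    def test_three_vocab_example(self):
        entries = lm.word_propagation({"X": {"a", "b"}, "Y": {"b", "c"}, "Z": {"b"}})
        assert [(e.word, e.n_vocabularies) for e in entries] == [
            ("b", 3),
            ("a", 1),
            ("c", 1),
        ]
        assert sum(1 for e in entries if e.n_vocabularies == 1) == 2

    def test_single_vocabulary_all_ones(self):
        entries = lm.word_propagation({"X": {"a", "b", "c"}})
        assert all(e.n_vocabularies == 1 for e in entries)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            lm.word_propagation({})

    def test_corpus_totals_by_hand(self, config):
        groups = {
            "X": [ConceptRecord("1", "alpha beta gamma", "X"),
                  ConceptRecord("2", "alpha beta", "X")],
            "Y": [ConceptRecord("3", "alpha beta", "Y"),
                  ConceptRecord("4", "alpha beta", "Y")],
        }
        # X: tokens a b c / a b (total 5, set {a,b,c}); Y: total 4, set {a,b}
        assert lm.corpus_lexical_totals(groups, config) == (9, 3)

    def test_disjoint_vocabularies_sum_uniques(self, config):
        groups = {
            "X": [ConceptRecord("1", "alpha beta", "X")],
            "Y": [ConceptRecord("2", "gamma delta", "Y")],
        }
        total, unique = lm.corpus_lexical_totals(groups, config)
        assert (total, unique) == (4, 4)

    def test_propagation_conserves_corpus_unique_words(self, config):
        groups = {
            "X": [ConceptRecord("1", "alpha beta gamma", "X")],
            "Y": [ConceptRecord("2", "beta delta", "Y")],
            "Z": [ConceptRecord("3", "beta of the gamma", "Z")],
        }
        entries = lm.word_propagation(lm.vocab_token_sets(groups, config))
        _, unique = lm.corpus_lexical_totals(groups, config)
        assert len(entries) == unique
        bounds = [len(s) for s in lm.vocab_token_sets(groups, config).values()]
        assert max(bounds) <= unique <= sum(bounds)
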