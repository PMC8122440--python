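import random

import pytest

import clinspell as cs
from clinspell.errorgen import (
    concordance_candidates,
    genre_candidates,
    homophone_candidates,
    number_candidates,
)
from clinspell.preprocess import Sentence


class TestGenreRules:
    @pytest.mark.parametrize(
        "word,expected",
        [("unido", "unida"), ("traicioneras", "traicioneros")],
    )
    def test_worked_examples(self, word, expected, worked_example_lexicon):
        assert cs.apply_genre(word, worked_example_lexicon) == expected

    def test_no_suffix_match(self):
        assert cs.apply_genre("azul") is None

    @pytest.mark.parametrize("word", ["unido", "traicioneras", "famoso", "urinaria"])
    def test_inverse_rule_recovers_original(self, word):
        for cand in genre_candidates(word):
            assert word in genre_candidates(cand)


class TestNumberRules:
    @pytest.mark.parametrize(
        "word,expected",
        [("aeronave", "aeronaves"), ("virtudes", "virtud")],
    )
    def test_worked_examples(self, word, expected, worked_example_lexicon):
        assert cs.apply_number(word, worked_example_lexicon) == expected

    def test_candidate_rejected_by_lexicon_gate(self, worked_example_lexicon):
        # "según" yields the candidate "segúnes", which is not a real word
        assert "segúnes" in number_candidates("según")
        assert cs.apply_number("según", worked_example_lexicon) is None

    @pytest.mark.parametrize("word", ["aeronave", "dolor", "masas", "pared"])
    def test_inverse_rule_recovers_original(self, word):
        for cand in number_candidates(word):
            assert word in number_candidates(cand)


class TestGenreNumberRules:
    @pytest.mark.parametrize(
        "word,expected",
        [("sinuosos", "sinuosa"), ("abandonado", "abandonadas")],
    )
    def test_worked_examples(self, word, expected, worked_example_lexicon):
        assert cs.apply_genre_number(word, worked_example_lexicon) == expected

    def test_no_match(self):
        assert cs.apply_genre_number("azul") is None

    def test_both_features_change(self):
        # outputs differ from pure genre flips and pure number flips
        for word in ("sinuosos", "abandonado", "unida"):
            for cand in cs.errorgen.genre_number_candidates(word):
                assert cand not in genre_candidates(word)
                assert cand not in number_candidates(word)


class TestHomophoneRules:
    @pytest.mark.parametrize(
        "word,expected",
        [("a", "ha"), ("enebro", "enhebro"), ("uso", "huso")],
    )
    def test_worked_examples(self, word, expected, worked_example_lexicon):
        assert cs.apply_homophone(word, worked_example_lexicon) == expected

    def test_no_target_letters(self):
        assert cs.apply_homophone("dato") is None

    @pytest.mark.parametrize("word", ["a", "enebro", "uso", "tubo", "vello", "halla"])
    def test_inverse_rule_recovers_original(self, word):
        for cand in homophone_candidates(word):
            assert word in homophone_candidates(cand)

    def test_b_v_and_ll_y_swaps(self):
        assert "tuvo" in homophone_candidates("tubo")
        assert "haya" in homophone_candidates("halla")


class TestSuggestionRule:
    def test_picks_first_ranked_suggestion(self, tables):
        lex = cs.Lexicon({"calle": 9, "callé": 3})
        assert cs.apply_suggestion("calle", lex, tables) == "callé"

    def test_distance_three_example(self, tables):
        lex = cs.Lexicon({"agravio": 4, "agrado": 6})
        assert cs.apply_suggestion("agravio", lex, tables) == "agrado"

    def test_reordering_example(self, tables):
        lex = cs.Lexicon({"masa": 8, "amas": 2})
        assert cs.apply_suggestion("masa", lex, tables) == "amas"

    def test_other_group_outputs_excluded(self, tables):
        # "dolores" is reachable by the number rule, so it is not a
        # suggestion error even though it is the nearest neighbour
        lex = cs.Lexicon({"dolor": 9, "dolores": 9})
        assert cs.apply_suggestion("dolor", lex, tables) is None

    def test_exhausted_list(self, tables):
        assert cs.apply_suggestion("xyz", cs.Lexicon(), tables) is None


class TestConcordanceRule:
    def test_person_swap_within_tense(self, tables, worked_example_lexicon):
        cands = concordance_candidates("llevan", tables, worked_example_lexicon)
        assert "llevas" in cands
        # all candidates share the stem and the present indicative row
        assert all(c.startswith("llev") for c in cands)
        assert any(
            cs.apply_concordance("llevan", tables, worked_example_lexicon, random.Random(s)) == "llevas"
            for s in range(100)
        )

    def test_distance_five_swap_reachable(self, tables, worked_example_lexicon):
        cands = concordance_candidates("peleaba", tables, worked_example_lexicon)
        assert "peleábamos" in cands
        assert cs.indel_distance("peleaba", "peleábamos") == 5

    def test_haber_swaps_within_tense(self, tables, worked_example_lexicon):
        cands = concordance_candidates("hemos", tables, worked_example_lexicon)
        assert set(cands) <= {"he", "has", "ha", "habéis", "han"}

    def test_non_verb(self, tables, worked_example_lexicon, rng):
        assert cs.apply_concordance("mesa", tables, worked_example_lexicon, rng) is None

    def test_never_returns_same_surface_form(self, tables, synth_lexicon, synth_corpus):
        for sent in synth_corpus[:200]:
            for tok in sent.tokens:
                for cand in concordance_candidates(tok.lower(), tables, synth_lexicon):
                    assert cand != tok.lower()


class TestGenerateError:
    def _sentence(self, *tokens):
        return Sentence(tokens=tokens)

    def test_error_planted_at_first_eligible_token(self, worked_example_lexicon, synth_groups):
        lex = cs.Lexicon({"unido": 5, "unida": 5, "abandonado": 5, "abandonada": 5})
        groups = cs.build_rule_groups(lex)
        sent = self._sentence("se", "realiza", "unido", "y", "abandonado", ".")
        rec = cs.generate_error(sent, groups[cs.GENRE], lex, skip_list={"se", "y"})
        assert rec is not None
        assert rec.token_index == 2
        assert rec.error_token == "unida"
        assert rec.source.tokens == ("se", "realiza", "unida", "y", "abandonado", ".")
        assert rec.target is sent

    def test_skip_list_only_sentence_yields_none(self, synth_lexicon, synth_groups, skip_list):
        sent = self._sentence("El", "de", "la", ".")
        for group in synth_groups.values():
            assert cs.generate_error(sent, group, synth_lexicon, skip_list) is None

    def test_case_preserved_on_capitalized_token(self):
        lex = cs.Lexicon({"unido": 5, "unida": 5})
        groups = cs.build_rule_groups(lex)
        sent = self._sentence("Unido", "queda", ".")
        rec = cs.generate_error(sent, groups[cs.GENRE], lex)
        assert rec is not None and rec.error_token == "Unida"

    def test_deterministic_under_seed(self, synth_corpus, synth_lexicon, synth_groups, skip_list):
        for group in synth_groups.values():
            a = [
                cs.generate_error(s, group, synth_lexicon, skip_list, random.Random(7))
                for s in synth_corpus[:50]
            ]
            b = [
                cs.generate_error(s, group, synth_lexicon, skip_list, random.Random(7))
                for s in synth_corpus[:50]
            ]
            assert a == b

    def test_emitted_records_satisfy_invariants(
        self, synth_corpus, synth_lexicon, synth_groups, skip_list, rng
    ):
        seen = 0
        for sent in synth_corpus[:300]:
            for group in synth_groups.values():
                rec = cs.generate_error(sent, group, synth_lexicon, skip_list, rng)
                if rec is None:
                    continue
                seen += 1
                diffs = [
                    i for i, (s, t) in enumerate(zip(rec.source.tokens, rec.target.tokens))
                    if s != t
                ]
                assert diffs == [rec.token_index]
                assert rec.error_token != rec.original_token
                assert rec.error_token.lower() in synth_lexicon
                assert rec.distance <= group.distance_cap
                assert rec.distance == cs.indel_distance(
                    rec.original_token.lower(), rec.error_token.lower()
                )
        assert seen > 300  # the fixture corpus must exercise the rules
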