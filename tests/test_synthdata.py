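import random

import pytest

import clinspell as cs
from clinspell.errorgen import (
    genre_candidates,
    genre_number_candidates,
    number_candidates,
)
from clinspell.evaluation import report
from clinspell.preprocess import normalize_sentence
from clinspell.synthdata import MiniLexicon, _four_forms


class TestGenerateCorpus:
    def test_deterministic_under_seed(self):
        assert cs.generate_corpus(40, 5) == cs.generate_corpus(40, 5)
        assert cs.generate_corpus(40, 5) != cs.generate_corpus(40, 6)

    def test_empty(self):
        assert cs.generate_corpus(0, 1) == []

    def test_sentences_are_normalization_fixed_points(self, synth_corpus):
        for sent in synth_corpus[:200]:
            assert normalize_sentence(sent.text).tokens == sent.tokens

    def test_sentence_lengths_in_template_regime(self, synth_corpus):
        for sent in synth_corpus:
            assert 5 <= len(sent) <= 20

    def test_tokens_attested_in_mini_lexicon(self, synth_corpus, synth_lexicon):
        for sent in synth_corpus[:200]:
            for tok in sent.tokens:
                if tok != ".":
                    assert tok.lower() in synth_lexicon


class TestMiniLexiconClosure:
    def test_paradigm_entries_closed_under_rules(self):
        ml = MiniLexicon.load()
        forms = set(ml.all_forms())
        for base in ml.adjectives + ml.person_nouns:
            for form in _four_forms(base):
                for group_cands in (genre_candidates, number_candidates, genre_number_candidates):
                    cands = group_cands(form)
                    assert set(cands) & forms, (form, group_cands.__name__)

    def test_noun_number_closure(self):
        ml = MiniLexicon.load()
        forms = set(ml.all_forms())
        for sg, pl, _ in ml.nouns:
            assert set(number_candidates(sg)) & forms
            assert set(number_candidates(pl)) & forms

    def test_homophone_pairs_attested(self):
        lex = cs.mini_lexicon()
        for word in ("uso", "huso", "hecho", "echo", "tubo", "tuvo", "a", "ha"):
            assert word in lex


@pytest.fixture(scope="module")
def eval_set(synth_corpus, synth_groups, synth_lexicon, skip_list):
    ds = cs.compile_strategy2(
        synth_corpus[:400], synth_groups, synth_lexicon, skip_list, random.Random(21)
    )
    return cs.ParallelDataset(ds.error_records())


class TestReferenceCorrectors:

    def test_oracle_scores_perfectly(self, eval_set):
        rep = report(eval_set, cs.oracle_corrector(eval_set.records))
        assert rep.to_json()["overall"] == {
            "total": len(eval_set), "corrected": len(eval_set), "bad": 0,
            "R": 100.0, "P": 100.0, "F0.5": 100.0,
        }

    def test_identity_corrector_zero_recall(self, eval_set):
        rep = report(eval_set, cs.identity_corrector(eval_set.records))
        j = rep.to_json()["overall"]
        assert j["R"] == 0.0 and j["corrected"] == 0 and j["bad"] == 0

    def test_half_oracle_half_identity(self, eval_set):
        n = len(eval_set) // 2 * 2
        recs = eval_set.records[:n]
        outputs = [
            r.target if i % 2 == 0 else r.source for i, r in enumerate(recs)
        ]
        rep = report(recs, outputs)
        assert rep.to_json()["overall"]["R"] == 50.0

    def test_frequency_corrector_dominant_context(self, synth_groups):
        # toy corpus: "la herida conservada" dominates "la herida conservado"
        lex = cs.Lexicon({"la": 30, "herida": 20, "conservada": 12, "conservado": 2, "cura": 5})
        groups = cs.build_rule_groups(lex)
        corpus = [
            cs.Sentence(tokens=("la", "herida", "conservada", "."))
        ] * 10 + [cs.Sentence(tokens=("el", "brazo", "conservado", "."))]
        rec = cs.DatasetRecord(
            source=cs.Sentence(tokens=("la", "herida", "conservado", ".")),
            target=cs.Sentence(tokens=("la", "herida", "conservada", ".")),
            error_type="genre", token_index=2,
            original_token="conservada", error_token="conservado", distance=2,
        )
        out = cs.frequency_corrector([rec], corpus, groups, lex)
        assert out[0].tokens == rec.target.tokens

    def test_frequency_corrector_conservative_on_ties(self, synth_groups, synth_lexicon):
        # no bigram evidence at all: every candidate ties at zero, keep source
        rec = cs.DatasetRecord(
            source=cs.Sentence(tokens=("herida", "conservado", ".")),
            target=cs.Sentence(tokens=("herida", "conservada", ".")),
            error_type="genre", token_index=1,
            original_token="conservada", error_token="conservado", distance=2,
        )
        out = cs.frequency_corrector([rec], [], synth_groups, synth_lexicon)
        assert out[0].tokens == rec.source.tokens

    def test_frequency_corrector_deterministic(self, eval_set, synth_corpus, synth_groups, synth_lexicon):
        recs = eval_set.records[:80]
        a = cs.frequency_corrector(recs, synth_corpus, synth_groups, synth_lexicon)
        b = cs.frequency_corrector(recs, synth_corpus, synth_groups, synth_lexicon)
        assert a == b


class TestNmtAdapters:
    def test_round_trip(self, synth_corpus, synth_groups, synth_lexicon, skip_list, tmp_path):
        ds = cs.compile_strategy2(
            synth_corpus[:30], synth_groups, synth_lexicon, skip_list, random.Random(2)
        )
        src, tgt = tmp_path / "src.txt", tmp_path / "tgt.txt"
        cs.nmt_adapter_export(ds, src, tgt)
        preds = cs.nmt_adapter_import(tgt, [r.source for r in ds])
        assert preds == [list(r.target.tokens) for r in ds]

    def test_empty_files(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("", encoding="utf-8")
        assert cs.nmt_adapter_import(p, []) == []

    def test_line_count_mismatch(self, tmp_path):
        p = tmp_path / "preds.txt"
        p.write_text("una sola línea\n", encoding="utf-8")
        with pytest.raises(ValueError, match="1 predictions for 2"):
            cs.nmt_adapter_import(p, [cs.Sentence(tokens=("a",))] * 2)
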