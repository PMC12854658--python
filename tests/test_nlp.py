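"""Sentence segmentation, the aggregation priority law, stratified splitting,
and determinism/accuracy of the 3-stage classifier."""

import itertools
import pickle

import pytest
from sklearn.metrics import f1_score

from bleedwatch.nlp import (AnnotatedDocument, DocLabel, SentenceLabel,
                            TrainConfig, aggregate_sentence_labels,
                            load_bundle, predict_document, save_bundle,
                            segment_sentences, split_corpus, tokenize, train)


class TestSegmentation:
    def test_period_segmentation(self):
        text = "Méléna le 3e jour. Pas de récidive."
        spans = segment_sentences(text)
        assert [text[s:e] for s, e in spans] == \
               ["Méléna le 3e jour.", "Pas de récidive."]

    def test_empty_text_zero_sentences(self):
        assert segment_sentences("") == []
        assert segment_sentences("   ") == []

    def test_abbreviation_not_split(self):
        text = "Saignement mineur p. ex. au site. Suite simple."
        spans = segment_sentences(text)
        assert len(spans) == 2
        assert text[spans[0][0]:spans[0][1]].endswith("au site.")

    def test_trailing_sentence_without_punctuation(self):
        spans = segment_sentences("One. Two without end")
        assert len(spans) == 2

    def test_tokenizer_lowercases(self):
        assert tokenize("Hémorragie MASSIVE, choc.") == \
               ["hémorragie", "massive", "choc"]


class TestAggregation:
    def test_priority_examples(self):
        agg = aggregate_sentence_labels
        assert agg([SentenceLabel.active_mb, SentenceLabel.active_crnmb]) \
            == DocLabel.B_mb
        assert agg([SentenceLabel.antecedent, SentenceLabel.irrelevant]) \
            == DocLabel.C_history
        assert agg([SentenceLabel.irrelevant] * 3) == DocLabel.D_none
        assert agg([]) == DocLabel.D_none

    def test_priority_law_on_all_multisets_up_to_4(self):
        """MB > CRNMB > history > none on every sentence-label multiset."""
        labels = list(SentenceLabel)
        for size in range(0, 5):
            for combo in itertools.combinations_with_replacement(labels, size):
                got = aggregate_sentence_labels(combo)
                if SentenceLabel.active_mb in combo:
                    assert got == DocLabel.B_mb
                elif SentenceLabel.active_crnmb in combo:
                    assert got == DocLabel.A_crnmb
                elif SentenceLabel.antecedent in combo:
                    assert got == DocLabel.C_history
                else:
                    assert got == DocLabel.D_none
                # permutation invariance
                for perm in itertools.permutations(combo):
                    assert aggregate_sentence_labels(perm) == got
                    break


class TestSplitCorpus:
    def _docs(self, sizes: dict[str, int]) -> list[AnnotatedDocument]:
        docs, k = [], 0
        for lab, n in sizes.items():
            for _ in range(n):
                docs.append(AnnotatedDocument(doc_id=f"D{k}", text="x.",
                                              doc_label=DocLabel(lab)))
                k += 1
        return docs

    def test_400_at_0p7_gives_280_120(self):
        docs = self._docs({"B_mb": 100, "A_crnmb": 100, "D_none": 200})
        tr, te = split_corpus(docs, 0.7, seed=0)
        assert (len(tr), len(te)) == (280, 120)

    def test_deterministic_under_seed(self):
        docs = self._docs({"B_mb": 5, "D_none": 5})
        a = split_corpus(docs, 0.5, seed=9)
        b = split_corpus(docs, 0.5, seed=9)
        assert [d.doc_id for d in a[0]] == [d.doc_id for d in b[0]]
        assert [d.doc_id for d in a[1]] == [d.doc_id for d in b[1]]

    def test_stratification_within_one_document(self):
        docs = self._docs({"B_mb": 100, "A_crnmb": 100, "D_none": 200})
        tr, _ = split_corpus(docs, 0.7, seed=4)
        from collections import Counter

        counts = Counter(d.doc_label for d in tr)
        assert abs(counts[DocLabel.B_mb] - 70) <= 1
        assert abs(counts[DocLabel.A_crnmb] - 70) <= 1
        assert abs(counts[DocLabel.D_none] - 140) <= 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_corpus(self._docs({"D_none": 4}), 1.5, seed=0)


@pytest.fixture(scope="module")
def trained(template_corpus):
    tr, te = split_corpus(template_corpus, 0.7, seed=5)
    return train(tr, TrainConfig(), seed=5), tr, te


class TestTraining:
    def test_separable_corpus_high_document_macro_f1(self, trained):
        bundle, _, te = trained
        gold = [d.doc_label.value for d in te]
        pred = [predict_document(bundle, d.text)[1].value for d in te]
        assert f1_score(gold, pred, average="macro") >= 0.90

    def test_determinism_same_seed_same_bundle(self, template_corpus, trained):
        bundle, tr, te = trained
        again = train(tr, TrainConfig(), seed=5)
        assert again.tuning_record == bundle.tuning_record
        texts = [d.text for d in te[:20]]
        assert [predict_document(again, t) for t in texts] == \
               [predict_document(bundle, t) for t in texts]

    def test_degenerate_corpus_errors_name_the_stage(self):
        doc = AnnotatedDocument(
            doc_id="D0", text="Stable. Stable again.",
            sentence_labels=[SentenceLabel.irrelevant, SentenceLabel.irrelevant])
        with pytest.raises(ValueError, match="stage1"):
            train([doc] * 10, TrainConfig(), seed=0)

    def test_serialization_roundtrip(self, trained, tmp_path):
        bundle, _, te = trained
        p1 = tmp_path / "m1.bundle"
        save_bundle(bundle, p1)
        loaded = load_bundle(p1)
        p2 = tmp_path / "m2.bundle"
        save_bundle(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert predict_document(loaded, te[0].text) == \
               predict_document(bundle, te[0].text)

    def test_stage2_irrelevant_overrides_stage1(self, trained):
        """A document of only negation/filler sentences stays D_none."""
        bundle, _, _ = trained
        labels, doc = predict_document(
            bundle, "No bleeding observed during the stay. "
                    "Vitals were within normal limits throughout the day.")
        assert doc == DocLabel.D_none
        assert all(l == SentenceLabel.irrelevant for l in labels)
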