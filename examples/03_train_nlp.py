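"""Train and evaluate the 3-stage discharge-summary classifier.

Builds a 400-document template corpus (100 MB / 100 CRNMB / 200 none),
splits it 280/120 stratified by label, tunes logistic-regression and linear
SVM candidates per stage with 5-fold cross-validated macro-F1, and prints
the selected models and the held-out document-level macro-F1.
"""

from sklearn.metrics import f1_score

from bleedwatch import CohortConfig, generate_documents
from bleedwatch.nlp import TrainConfig, predict_document, split_corpus, train

cfg = CohortConfig(n_stays=400, seed=42,
                   doc_label_mix={"B": 100, "A": 100, "D": 200})
docs = generate_documents(cfg)
train_docs, test_docs = split_corpus(docs, 0.7, seed=42)
print(f"corpus: {len(docs)} docs -> train {len(train_docs)} / test {len(test_docs)}")

bundle = train(train_docs, TrainConfig(folds=5), seed=42)
for stage, rec in bundle.tuning_record.items():
    sel = rec["cv"]["selected"]
    print(f"  {stage}: {sel['model']} (C={sel['C']}), "
          f"CV macro-F1={sel.get('f1_macro', float('nan')):.3f}")

gold = [d.doc_label.value for d in test_docs]
pred = [predict_document(bundle, d.text)[1].value for d in test_docs]
print(f"held-out document macro-F1: {f1_score(gold, pred, average='macro'):.3f}")
print("-> the template corpus is separable by construction, so a linear")
print("   model over TF-IDF lemma n-grams classifies it essentially perfectly.")
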