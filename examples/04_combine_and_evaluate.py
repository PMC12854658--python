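"""Fuse the structured and text detectors and validate against truth.

Runs both detectors over one synthetic cohort, combines them by union
(severity disagreements resolve to the more severe label), shows the
per-detector attribution, and reports sensitivity/specificity/PPV/NPV/
accuracy/F1 with Wilson 95% CIs for the MB-vs-rest scenario.
"""

from bleedwatch import CohortConfig, generate_documents, generate_structured
from bleedwatch.combiner import attribution_summary, combine
from bleedwatch.evaluation import binarize, metrics
from bleedwatch.nlp import (DOC_TO_CALL_LABEL, TrainConfig, predict_document,
                            split_corpus, train)
from bleedwatch.sda import classify_cohort

cfg = CohortConfig(n_stays=400, seed=42)
bundles, truth = generate_structured(cfg)
docs = generate_documents(cfg, truth)

sda_calls = {c.stay_id: c.label for c in classify_cohort(bundles)}

train_docs, _ = split_corpus(docs, 0.7, seed=42)
bundle = train(train_docs, TrainConfig(), seed=42)
nlp_calls = {d.stay_id: DOC_TO_CALL_LABEL[predict_document(bundle, d.text)[1]]
             for d in docs}

combined = combine(sda_calls, nlp_calls, "union")
print("MB attribution across detectors (union positives):")
for k, v in attribution_summary(combined, "MB").items():
    print(f"  {k:7s} {v['count']:3d}  {v['pct']}%")

gold = truth.as_label_map()
report = metrics(binarize({c.stay_id: c.label for c in combined}, gold,
                          "mb_vs_rest"), scenario="mb_vs_rest")
print("\nunion vs truth, MB-vs-rest scenario:")
for name, mv in report.values.items():
    if mv.point is None:
        print(f"  {name:12s} undefined ({mv.undefined_reason})")
    elif mv.ci_low is not None:
        print(f"  {name:12s} {mv.point:.2f} (95% CI {mv.ci_low:.2f}-{mv.ci_high:.2f})")
    else:
        print(f"  {name:12s} {mv.point:.2f}")
print("-> on this synthetic cohort both detectors see the same injected")
print("   events, so the union performs essentially perfectly; on real data")
print("   the two sources disagree and the union trades PPV for sensitivity.")
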