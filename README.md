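# bleedwatch

Computable-phenotype detection of antithrombotic-related bleeding in
inpatient electronic health record (EHR) data.

Bleeding is among the most frequent serious adverse drug events in older
inpatients on antithrombotic therapy (vitamin K antagonists, heparins,
platelet aggregation inhibitors, direct thrombin and factor Xa inhibitors,
fondaparinux). Manual chart review finds these events reliably but does not
scale; `bleedwatch` implements the automated alternative: rule-based
detection from structured data, a supervised sentence classifier over
discharge summaries, fusion of the two detectors, and a validation toolkit —
plus a seeded synthetic cohort generator so the whole pipeline is testable
without patient data.

## What it computes

Each inpatient stay receives a label in {MB, CRNMB, none}:

* **MB — major bleeding** (adapted ISTH criteria): ΔHb ≥ 4 g/dL within
  48 h; ΔHb ∈ [2, 4) g/dL with death within 24 h; nadir Hb < 7 g/dL; nadir
  ∈ [7, 9] g/dL with death within 24 h; transfusion of > 5 units of whole
  blood or red cells; prescription of an antihemorrhagic agent
  (idarucizumab, andexanet alfa, prothromplex, octaplex, beriplex); or an
  MB diagnosis code.
* **CRNMB — clinically relevant nonmajor bleeding**: ΔHb ∈ [2, 4) g/dL or
  nadir ∈ [7, 9] g/dL without the associated death, or a CRNMB diagnosis
  code. MB takes precedence whenever both tiers fire.

The diagnosis branch matches ICD-10-GM codes against packaged lists of
12 MB and 41 CRNMB patterns with dot-aware family wildcards (`I61_` covers
`I61` and every `I61.x`).

The text branch segments discharge summaries into sentences and routes each
through a three-stage cascade of linear classifiers (relevant vs irrelevant;
irrelevant / antecedent / active; MB vs CRNMB), then aggregates sentence
labels into a document label with the conservative priority
MB > CRNMB > history of bleeding > no bleeding.

Two detectors can be fused by union or intersection with severity-max
resolution, and any detector is validated against gold labels with
sensitivity, specificity, PPV, NPV, accuracy (each with a Wilson-score 95%
CI) and F1, in the scenarios MB-vs-rest, CRNMB-vs-none (gold MB excluded)
and any-bleeding. Fleiss κ with Landis–Koch bands covers interrater
agreement.

## Worked example

```python
from bleedwatch import CohortConfig, generate_structured
from bleedwatch.sda import classify_cohort, cohort_prevalence

bundles, truth = generate_structured(CohortConfig(n_stays=500, seed=42))
calls = classify_cohort(bundles)
prev = cohort_prevalence(calls)
print(prev.counts, prev.percentages)
```

prints

```
{'none': 385, 'CRNMB': 75, 'MB': 40, 'MB_mortality': 12}
{'none': 77.0, 'CRNMB': 15.0, 'MB': 8.0, 'MB_mortality': 2.4}
```

i.e. of 500 eligible synthetic stays the rule engine labels 8% MB and 15%
CRNMB (matching the generator's configured prevalences exactly, since every
injected event satisfies exactly one rule), and 12 stays are MB followed by
in-hospital death. The scripts in `examples/` walk through each capability:
simulation, structured detection with per-source attribution, NLP training
(280/120 split, 5-fold CV over logistic-regression and linear-SVM
candidates), union/intersection fusion, and the agreement/CI statistics.

There is also a thin CLI:

```bash
bleedwatch simulate --n-stays 500 --seed 42 --out-dir data/
bleedwatch detect-sda --cohort-dir data/ --out calls.jsonl
bleedwatch nlp-train --corpus data/docs.jsonl --seed 42 --out model.bundle
bleedwatch nlp-predict --model model.bundle --in data/docs.jsonl --out nlp.jsonl
bleedwatch combine --a calls.jsonl --b nlp.jsonl --mode union --out both.jsonl
bleedwatch evaluate --calls both.jsonl --gold gold.jsonl --scenario mb --out report.json
bleedwatch run --config pipeline.yaml   # end-to-end with hashed manifest
```

## Input formats

Cohorts are five UTF-8 CSV tables (`stays`, `labs`, `transfusions`,
`prescriptions`, `diagnoses`) with ISO-8601 timestamps; hemoglobin is
canonical in g/dL and g/L is accepted only with an explicit unit
declaration. Corpora are JSONL documents with optional sentence spans and
labels. See `docs/methods.md` for the full model description, parameter
defaults and limitations.
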