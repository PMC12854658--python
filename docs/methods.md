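# Methods

## Problem and scope

`bleedwatch` labels inpatient stays of older patients on antithrombotic
therapy with one of three bleeding phenotypes — major bleeding (MB),
clinically relevant nonmajor bleeding (CRNMB), or none — from two
complementary evidence streams: structured EHR extracts (hemoglobin series,
transfusions, prescriptions, billing diagnoses, death timing) and the
free text of discharge summaries. It also ships the machinery to fuse the
two detectors, to validate them against gold-standard labels, and to
generate synthetic cohorts with known truth. Cohort eligibility is fixed:
age ≥ 65 at admission, at least one antithrombotic prescription (ATC
prefixes B01AA/AB/AC/AE/AF and B01AX05), and a stay of at least 24 h, the
boundary read inclusively.

## Structured-data rules

The severity definitions adapt the ISTH criteria for retrospective use on
routinely collected data. All thresholds are configurable in `SdaConfig`;
the defaults are:

| parameter | default | meaning |
|---|---|---|
| `window_hours` | 48 | span within which a hemoglobin drop counts |
| `mb_drop_gdl` | 4.0 | ΔHb ≥ 4 g/dL is MB outright |
| `crnmb_drop_gdl` | 2.0 | ΔHb ∈ [2, 4) g/dL is the conditional band |
| `nadir_mb_gdl` | 7.0 | nadir < 7 g/dL is MB outright |
| `nadir_band_high_gdl` | 9.0 | nadir ∈ [7, 9] g/dL is the conditional band |
| `death_horizon_hours` | 24 | death window for the conditional bands |
| `transfusion_units_gt` | 5 | strictly more than 5 whole-blood/RBC units |

Band edges were chosen to make the drop and nadir bands exhaustive and
non-overlapping: "4 g/dL or more" fixes the MB drop edge, so the CRNMB band
is [2, 4) with 4.0 governed by the MB rule; the nadir band [7, 9] is
inclusive at both ends with < 7 strictly MB. The death window is anchored
at the qualifying drop's *later* measurement (the event's detection time)
for ΔHb rules and at the nadir timestamp for nadir rules, with the 24-h
bound inclusive; the anchor choice is a design decision — the data cannot
identify bleed onset, and the later measurement is when the event becomes
observable. Plasma transfusions do not count toward the transfusion rule
because the MB definition names blood or red cells. Missing labs or
diagnoses mean "criterion not met", never an error; a single hemoglobin
value can support the nadir rules but not the drop rules.

ΔHb is the maximum decline between an earlier and a strictly later
measurement at most 48 h apart, computed in O(n) with a time-windowed
monotonic deque; ties resolve to the earliest end, then the earliest start.
The unit tests hold this against an O(n²) all-pairs oracle with the same
tie-break contract.

Per-stay output records every criterion that fired, but source attribution
(`sources_fired`) credits only the tier that determined the final label: an
ICD CRNMB hit inside an MB-labelled stay stays in the evidence list without
polluting the MB attribution, so within-severity contribution analyses
partition cleanly.

Reported prevalence percentages round half away from zero to two decimals.
At large published cohort magnitudes this occasionally differs in the last
digit from tables produced by truncation (e.g. 2979/36,039 = 8.2661%
rounds to 8.27); the package rounds consistently and documents the
difference rather than switching rule by rule.

## Diagnosis-code matching

The MB (12 patterns) and CRNMB (41 patterns) ICD-10-GM lists ship as a CSV
data file so they can be audited by diff and overridden per run. A trailing
underscore denotes a code family; matching is dot-aware after
normalization (uppercase, dot inserted after the third character of dotless
4+‑character codes), so `I61_` matches `I61` and `I61.0` but an exact
pattern such as `R31` does not cover `R31.0`. Known irregularities of the
source list — e.g. `K25.4` absent while `K26.4` is present — are reproduced
verbatim, not corrected. The present-on-admission flag is carried through
for reporting but never changes matching.

## Text pipeline

Sentence segmentation is a deterministic rule: split after runs of `.!?`
followed by whitespace unless the preceding token is in a configurable
abbreviation list. Tokenization is a language-neutral `\w+` regex with
lowercasing; the lemmatizer is pluggable (`noop` by default, plus a crude
French suffix stripper), so no model download is required anywhere in the
pipeline. French is the reference language of the application; all
language-specific parts (templates, abbreviations, lemmatizer) are data or
registry entries.

Features are TF-IDF weighted lemma n-grams (1–2) with a document-frequency
floor of 2. Each of the three stages trains both a logistic regression and
a linear SVM over a small C grid {0.1, 1, 10}, selected by stratified
5-fold cross-validated macro-F1 with ties going to the simpler logistic
model; class imbalance is handled with inverse-frequency class weights. A
stage-2 "irrelevant" overrides a stage-1 "relevant" — a sentence must
survive both gates to carry a bleeding label. Document aggregation is a
pure function of the sentence-label multiset with priority
MB > CRNMB > history > none. All randomness is seeded; the serialized
bundle is passed through one pickle round-trip before writing so that
save → load → save is byte-identical. No contextual-embedding stage is
implemented; the feature extractor is an interface behind which an
embedding backend could be added.

The train/test split takes `round(n·fraction)` training documents,
stratified by document label with largest-remainder allocation, so a
400-document corpus at 0.7 splits 280/120 and class proportions are
preserved within one document.

## Combination

Union calls a stay positive if either detector does; intersection requires
both. Severity disagreements resolve to the maximum severity (MB over
CRNMB) — a conservative hierarchy favouring the more severe call. Because
the alternative reading (the text detector reclassifying structured calls)
is also defensible, `nlp_overrides=True` lets detector B's severity win
whenever both are positive. A "history" document label counts as negative
for active-bleeding combination but is preserved in the component record
for temporal-resolution analyses.

## Validation statistics

`binarize` implements three scenarios: any-bleeding, MB-vs-rest, and
CRNMB-vs-none, the last excluding gold-MB stays from the denominator and
counting a call positive only when it is exactly CRNMB. Six metrics derive
from the confusion counts; every proportion gets a Wilson-score 95% CI
(statsmodels implementation behind the package surface, with the degenerate
edges pinned exactly to 0 and 1, where the score interval is algebraically
exact); F1 gets no interval. Metrics with a zero denominator are reported
as `None` with a reason, never silently as 0. Fleiss κ (statsmodels) takes
an items × raters categorical table, requires a fixed rater count per item,
and returns the Landis–Koch band (> 0.80 almost perfect, 0.61–0.80
substantial, 0.41–0.60 moderate, 0.21–0.40 fair, 0.00–0.20 slight, < 0
poor).

## Synthetic cohort generator

The generator is first-class, tested code: it emulates the structured data
model and the discharge-summary corpus, not any particular hospital's
case-mix. Defaults are the study conditions: 8% MB and 15% CRNMB
prevalence, every stay eligible by construction, and each truth-positive
stay carrying exactly one injected qualifying event drawn from a
configurable criterion mix (uniform within each tier by default).
Hemoglobin series have 3–10 measurements at 4–24 h spacing with baseline
N(13, 1) g/dL truncated to [10, 17]; engineered series keep unintended
criteria from firing (e.g. CRNMB drop stays end above 9 g/dL so the nadir
band cannot trigger, nadir-band stays have total spread < 1.9 g/dL so no
drop can trigger). Deaths for the death-linked criteria occur at the
anchor + U(0, 24) h, with a configurable fraction at exactly +24 h to pin
the inclusive boundary. A quarter of negatives (configurable) are built
deliberately at rule boundaries: 1.9 g/dL drops, 9.1 g/dL nadirs,
exactly-5-unit transfusions, and bleeding-adjacent codes absent from the
lists.

Documents are composed from plain-text template sets (a language-neutral
set used in tests and a French-like set), with filler and hard-negative
negation sentences around label-consistent template sentences; emitted
document labels equal the priority aggregation of the emitted sentence
labels by construction, and emitted spans agree with the package's own
segmenter so annotations align at training time.

What passing tests on this corpus do and do not show: the template corpus
is linearly separable by construction, so perfect macro-F1 demonstrates the
pipeline's mechanics (segmentation, staging, aggregation, determinism), not
expected performance on clinical narrative, which carries negation scope,
ambiguity and vocabulary drift that the generator deliberately does not
model. Likewise the generator/detector closure (sensitivity = specificity
= 1.0 against truth) validates rule logic and boundary placement, not
real-world accuracy, where hemoglobin noise, nonhemorrhagic anemia and
coding practice break the one-event-one-rule idealization. The generator
also does not model comorbidity structure, multi-hospital heterogeneity, or
secular drift in prescribing.

## Numerical and degenerate-input choices

Timestamps are ISO-8601 interpreted in a single zone per cohort; durations
are exact hour differences. Hemoglobin in g/L is accepted only with an
explicit declaration and never guessed from magnitude, because silent
misscaling would flip every threshold. Labs outside
[admission − 24 h, discharge + 24 h] are rejected with a warning
(configurable tolerance); deaths after discharge are rejected at load.
Orphan child rows (unknown stay id) are counted and reported, not silently
dropped. Empty text yields zero sentences; an empty corpus or a stage with
fewer than two classes is a training error naming the stage; a singleton
class skips cross-validation and falls back to logistic C = 1 with a note
in the tuning record. Attribution and prevalence percentages round half
away from zero (1 and 2 decimals respectively); full precision is retained
in JSON outputs.

## Problem sizes used in checks

The automated checks run at desk scale, chosen so the full suite completes
in well under a minute of compute per component: a 1000-stay cohort for the
generator-closure check, 1000 random series (n ≤ 200) for the drop-engine
oracle, 500 random paired call sets for the combination laws, 1000 label
permutations for the Fleiss-κ null, and a 400-document corpus (280/120
split) for the text pipeline.

## Known limitations

Transfusions enter as explicit unit counts; mapping from procedure billing
codes to unit counts is out of scope. Bleeds are not attributed to specific
agents (no causality assessment), and present-on-admission timing is
surfaced but not modelled. The rule engine evaluates the death window only
at the maximal drop and at the nadir; a sub-maximal drop closer to death
is not separately tested — at most it could matter when a stay has a
larger drop far from death and a smaller qualifying drop near it, which the
generator never produces and which would require an onset model to resolve
defensibly.
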