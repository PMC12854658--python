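"""Sentence-level bleeding classifier for discharge summaries.

Documents are segmented into sentences and each sentence is routed through a
three-stage cascade of linear text classifiers:

1. binary — bleeding-relevant vs irrelevant;
2. multiclass — irrelevant, antecedent (past) bleeding, active bleeding
   (a stage-2 "irrelevant" overrides a stage-1 "relevant");
3. binary — major (MB) vs clinically relevant nonmajor (CRNMB), applied only
   to sentences flagged active.

Sentence predictions are aggregated into one of four mutually exclusive
document labels with the conservative priority MB > CRNMB > history of
bleeding > no bleeding.

Features are TF-IDF weighted lemma n-grams (1–2 by default) with a
document-frequency floor. Both logistic regression and a linear SVM are
trained per stage; the winner is chosen by 5-fold cross-validated macro-F1,
ties going to the simpler logistic model. Class imbalance is handled with
inverse-frequency class weights. All randomness is seeded; training twice
with the same corpus and seed yields identical tuning records and
predictions.

Language-specific parts (lemmatizer, abbreviation list) are pluggable; the
default configuration uses a language-neutral regex tokenizer with a no-op
lemmatizer, so no model download is needed.
"""

from __future__ import annotations

import enum
import pickle
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

__all__ = [
    "SentenceLabel",
    "DocLabel",
    "DOC_TO_CALL_LABEL",
    "AnnotatedDocument",
    "FeatureSpec",
    "TrainConfig",
    "ClassifierBundle",
    "segment_sentences",
    "segment_and_normalize",
    "tokenize",
    "aggregate_sentence_labels",
    "train",
    "predict_document",
    "split_corpus",
    "save_bundle",
    "load_bundle",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


class SentenceLabel(str, enum.Enum):
    irrelevant = "irrelevant"
    antecedent = "antecedent"
    active_mb = "active_mb"
    active_crnmb = "active_crnmb"


class DocLabel(str, enum.Enum):
    A_crnmb = "A_crnmb"     # presence of CRNMB
    B_mb = "B_mb"           # presence of MB
    C_history = "C_history"  # history of bleeding (before admission)
    D_none = "D_none"       # absence of any bleeding


#: Mapping from document labels to detector call labels.
DOC_TO_CALL_LABEL = {
    DocLabel.B_mb: "MB",
    DocLabel.A_crnmb: "CRNMB",
    DocLabel.C_history: "history",
    DocLabel.D_none: "none",
}


class AnnotatedDocument(BaseModel):
    """A discharge summary with optional gold sentence and document labels."""

    doc_id: str
    stay_id: Optional[str] = None
    text: str
    sentences: list[tuple[int, int]] = Field(default_factory=list)
    sentence_labels: Optional[list[SentenceLabel]] = None
    doc_label: Optional[DocLabel] = None

    @model_validator(mode="after")
    def _check_spans(self) -> "AnnotatedDocument":
        prev_end = 0
        for start, end in self.sentences:
            if not (0 <= start < end <= len(self.text)):
                raise ValueError(f"span ({start}, {end}) outside text bounds")
            if start < prev_end:
                raise ValueError("sentence spans overlap or are unordered")
            prev_end = end
        if self.sentence_labels is not None and self.sentences \
                and len(self.sentence_labels) != len(self.sentences):
            raise ValueError("one label per sentence span required")
        return self

    def sentence_texts(self) -> list[str]:
        return [self.text[s:e] for s, e in self.sentences]


# ---------------------------------------------------------------------------
# segmentation / normalization

#: Token endings after which a period never ends a sentence.
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "p.", "ex.", "cf.", "etc.", "env.", "dr.", "m.", "mme.", "mr.", "st.",
    "vs.", "resp.", "chf.",
)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def tokenize(text: str) -> list[str]:
    """Language-neutral word tokenizer: unicode word characters, lowercased."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def noop_lemmatizer(token: str) -> str:
    return token


def fr_suffix_lemmatizer(token: str) -> str:
    """Crude French suffix stripper (plural/feminine endings); deterministic
    and dependency-free — a stand-in for a full lemmatizer."""
    for suf in ("aux", "ées", "és", "es", "s", "x"):
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            return token[: -len(suf)]
    return token


LEMMATIZERS: dict[str, Callable[[str], str]] = {
    "noop": noop_lemmatizer,
    "fr_suffix": fr_suffix_lemmatizer,
}


def segment_sentences(text: str,
                      abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
                      ) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence segmentation.

    Splits after runs of ``.!?`` followed by whitespace or end of text,
    unless the preceding token (with its period) is a configured
    abbreviation. Returns character spans trimmed of surrounding whitespace;
    empty text yields zero sentences.
    """
    if not text.strip():
        return []
    abbrev = {a.lower() for a in abbreviations}
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        prefix = text[:end]
        last = prefix.rstrip().rsplit(None, 1)[-1].lower()
        if last in abbrev:
            continue
        seg = text[start:end]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((start + lstrip, end - rstrip))
        start = end
    tail = text[start:]
    if tail.strip():
        lstrip = len(tail) - len(tail.lstrip())
        rstrip = len(tail) - len(tail.rstrip())
        spans.append((start + lstrip, len(text) - rstrip))
    return spans


def segment_and_normalize(text: str,
                          abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
                          lemmatizer: str = "noop",
                          ) -> list[tuple[tuple[int, int], list[str]]]:
    """Sentence spans plus per-sentence lowercased, lemmatized token streams."""
    lemma = LEMMATIZERS[lemmatizer]
    out = []
    for span in segment_sentences(text, abbreviations):
        toks = [lemma(t) for t in tokenize(text[span[0]:span[1]])]
        out.append((span, toks))
    return out


# ---------------------------------------------------------------------------
# features and training


@dataclass(frozen=True)
class FeatureSpec:
    """Tokenizer/lemmatizer settings and n-gram vocabulary parameters shared
    by the three stages."""

    ngram_min: int = 1
    ngram_max: int = 2
    min_df: int = 2
    lemmatizer: str = "noop"
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS


class _LemmaAnalyzer:
    """Picklable TF-IDF analyzer producing lemma n-grams."""

    def __init__(self, spec: FeatureSpec):
        self.spec = spec

    def __call__(self, text: str) -> list[str]:
        lemma = LEMMATIZERS[self.spec.lemmatizer]
        toks = [lemma(t) for t in tokenize(text)]
        grams: list[str] = []
        for n in range(self.spec.ngram_min, self.spec.ngram_max + 1):
            grams.extend(" ".join(toks[i:i + n]) for i in range(len(toks) - n + 1))
        return grams


@dataclass
class TrainConfig:
    folds: int = 5
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)


@dataclass
class ClassifierBundle:
    """The three trained stages plus the feature spec and tuning record."""

    stage1: Pipeline  # relevant vs irrelevant
    stage2: Pipeline  # irrelevant / antecedent / active
    stage3: Pipeline  # active_mb vs active_crnmb
    feature_spec: FeatureSpec
    tuning_record: dict
    seed: int


_STAGE1_RELEVANT = {SentenceLabel.antecedent, SentenceLabel.active_mb,
                    SentenceLabel.active_crnmb}
_ACTIVE = {SentenceLabel.active_mb, SentenceLabel.active_crnmb}


def _stage_targets(labels: Sequence[SentenceLabel], stage: int) -> list[str]:
    if stage == 1:
        return ["relevant" if l in _STAGE1_RELEVANT else "irrelevant" for l in labels]
    if stage == 2:
        return ["active" if l in _ACTIVE else l.value for l in labels]
    return [l.value for l in labels]  # stage 3 operates on active labels only


def _make_pipeline(model: str, c: float, spec: FeatureSpec, seed: int) -> Pipeline:
    vec = TfidfVectorizer(analyzer=_LemmaAnalyzer(spec), min_df=spec.min_df)
    if model == "logistic":
        clf = LogisticRegression(C=c, class_weight="balanced", max_iter=2000,
                                 random_state=seed)
    else:
        clf = LinearSVC(C=c, class_weight="balanced", max_iter=5000,
                        random_state=seed)
    return Pipeline([("tfidf", vec), ("clf", clf)])


def _fit_stage(name: str, texts: list[str], y: list[str], cfg: TrainConfig,
               seed: int) -> tuple[Pipeline, dict]:
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(
            f"stage {name}: needs >= 2 classes after relabeling, got {classes}")
    min_count = min(Counter(y).values())
    n_splits = min(cfg.folds, min_count)
    record: dict = {"stage": name, "classes": classes, "n": len(y)}
    # logistic listed first so that, on ties, the simpler model wins
    candidates = [("logistic", c) for c in cfg.c_grid] + \
                 [("svm", c) for c in cfg.c_grid]
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        scores = {}
        for model, c in candidates:
            pipe = _make_pipeline(model, c, cfg.feature_spec, seed)
            scores[(model, c)] = float(np.mean(
                cross_val_score(pipe, texts, y, scoring="f1_macro", cv=cv)))
        best = max(candidates, key=lambda k: scores[k])  # stable: first max wins
        record["cv"] = {"folds": n_splits,
                        "grid": {f"{m}:C={c}": scores[(m, c)] for m, c in candidates},
                        "selected": {"model": best[0], "C": best[1],
                                     "f1_macro": scores[best]}}
    else:
        # a class with a single example cannot be cross-validated
        best = ("logistic", 1.0)
        record["cv"] = {"folds": 0, "selected": {"model": "logistic", "C": 1.0,
                                                 "note": "singleton class; CV skipped"}}
    pipe = _make_pipeline(best[0], best[1], cfg.feature_spec, seed)
    pipe.fit(texts, y)
    return pipe, record


def _labelled_sentences(corpus: Iterable[AnnotatedDocument],
                        spec: FeatureSpec) -> tuple[list[str], list[SentenceLabel]]:
    texts: list[str] = []
    labels: list[SentenceLabel] = []
    for doc in corpus:
        if doc.sentence_labels is None:
            continue
        spans = doc.sentences or segment_sentences(doc.text, spec.abbreviations)
        if len(spans) != len(doc.sentence_labels):
            raise ValueError(
                f"doc {doc.doc_id}: {len(spans)} sentences but "
                f"{len(doc.sentence_labels)} labels")
        for (s, e), lab in zip(spans, doc.sentence_labels):
            texts.append(doc.text[s:e])
            labels.append(SentenceLabel(lab))
    return texts, labels


def train(corpus: Sequence[AnnotatedDocument], config: Optional[TrainConfig] = None,
          seed: int = 0) -> ClassifierBundle:
    """Train the three-stage cascade on sentence-annotated documents.

    Hyperparameters (model family and regularization C per stage) are chosen
    by stratified 5-fold cross-validated macro-F1.
    """
    cfg = config or TrainConfig()
    texts, labels = _labelled_sentences(corpus, cfg.feature_spec)
    if not texts:
        raise ValueError("corpus contains no sentence-labelled documents")

    s1, r1 = _fit_stage("stage1", texts, _stage_targets(labels, 1), cfg, seed)
    s2, r2 = _fit_stage("stage2", texts, _stage_targets(labels, 2), cfg, seed)
    active_idx = [i for i, l in enumerate(labels) if l in _ACTIVE]
    s3, r3 = _fit_stage("stage3", [texts[i] for i in active_idx],
                        _stage_targets([labels[i] for i in active_idx], 3),
                        cfg, seed)
    return ClassifierBundle(stage1=s1, stage2=s2, stage3=s3,
                            feature_spec=cfg.feature_spec,
                            tuning_record={"stage1": r1, "stage2": r2, "stage3": r3},
                            seed=seed)


# ---------------------------------------------------------------------------
# prediction and aggregation


def aggregate_sentence_labels(labels: Iterable[SentenceLabel]) -> DocLabel:
    """Document label from the multiset of sentence labels, with priority
    MB > CRNMB > history of bleeding > no bleeding. Pure and order-invariant."""
    labels = [SentenceLabel(l) for l in labels]
    if SentenceLabel.active_mb in labels:
        return DocLabel.B_mb
    if SentenceLabel.active_crnmb in labels:
        return DocLabel.A_crnmb
    if SentenceLabel.antecedent in labels:
        return DocLabel.C_history
    return DocLabel.D_none


def _predict_sentences(bundle: ClassifierBundle, texts: Sequence[str]
                       ) -> list[SentenceLabel]:
    if not texts:
        return []
    out: list[SentenceLabel] = []
    p1 = bundle.stage1.predict(list(texts))
    rel_idx = [i for i, p in enumerate(p1) if p == "relevant"]
    labels = [SentenceLabel.irrelevant] * len(texts)
    if rel_idx:
        p2 = bundle.stage2.predict([texts[i] for i in rel_idx])
        act_idx = []
        for i, p in zip(rel_idx, p2):
            if p == "antecedent":
                labels[i] = SentenceLabel.antecedent
            elif p == "active":
                act_idx.append(i)
            # stage-2 "irrelevant" overrides stage-1 "relevant"
        if act_idx:
            p3 = bundle.stage3.predict([texts[i] for i in act_idx])
            for i, p in zip(act_idx, p3):
                labels[i] = SentenceLabel(p)
    out.extend(labels)
    return out


def predict_document(bundle: ClassifierBundle, text: str
                     ) -> tuple[list[SentenceLabel], DocLabel]:
    """Classify every sentence of ``text`` and aggregate to a document label."""
    spans = segment_sentences(text, bundle.feature_spec.abbreviations)
    labels = _predict_sentences(bundle, [text[s:e] for s, e in spans])
    return labels, aggregate_sentence_labels(labels)


def predict_corpus(bundle: ClassifierBundle, corpus: Sequence[AnnotatedDocument]
                   ) -> list[DocLabel]:
    return [predict_document(bundle, d.text)[1] for d in corpus]


# ---------------------------------------------------------------------------
# corpus splitting


def split_corpus(corpus: Sequence[AnnotatedDocument], train_fraction: float,
                 seed: int = 0) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Deterministic train/test split, stratified by document label.

    The train size is ``round(n * train_fraction)`` (e.g. 400 docs at 0.7
    give 280/120); per-class allocations use largest remainders so class
    proportions are preserved within one document.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    n_train = int(np.floor(n * train_fraction + 0.5))
    rng = np.random.default_rng(seed)

    strata: dict[str, list[int]] = {}
    for i, doc in enumerate(corpus):
        key = doc.doc_label.value if doc.doc_label is not None else "__unlabelled__"
        strata.setdefault(key, []).append(i)

    quotas: dict[str, int] = {}
    remainders: list[tuple[float, str]] = []
    for key, idx in sorted(strata.items()):
        exact = len(idx) * n_train / n if n else 0.0
        quotas[key] = int(np.floor(exact))
        remainders.append((exact - np.floor(exact), key))
    shortfall = n_train - sum(quotas.values())
    for _, key in sorted(remainders, key=lambda t: (-t[0], t[1]))[:shortfall]:
        quotas[key] += 1

    train_idx: list[int] = []
    for key, idx in sorted(strata.items()):
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[p] for p in perm[:quotas[key]])
    train_set = set(train_idx)
    train_docs = [corpus[i] for i in sorted(train_set)]
    test_docs = [corpus[i] for i in range(n) if i not in train_set]
    return train_docs, test_docs


# ---------------------------------------------------------------------------
# serialization and corpus I/O


def save_bundle(bundle: ClassifierBundle, path: str | Path) -> None:
    """Serialize the bundle (feature spec, stage weights, tuning record, seed)
    to a single pickle archive; round-trips bit-identically.

    The object graph is passed through one pickle round-trip before writing:
    freshly fitted estimators can carry non-canonical internal object
    sharing, and the round-trip drives the byte stream to its fixed point so
    save -> load -> save reproduces the file exactly.
    """
    raw = pickle.dumps(bundle, protocol=4)
    canonical = pickle.dumps(pickle.loads(raw), protocol=4)
    with open(path, "wb") as fh:
        fh.write(canonical)


def load_bundle(path: str | Path) -> ClassifierBundle:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def read_corpus_jsonl(path: str | Path) -> list[AnnotatedDocument]:
    import json

    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            docs.append(AnnotatedDocument(
                doc_id=str(rec["doc_id"]),
                stay_id=rec.get("stay_id"),
                text=rec["text"],
                sentences=[tuple(s) for s in rec.get("sentences", [])],
                sentence_labels=rec.get("sentence_labels"),
                doc_label=rec.get("doc_label"),
            ))
    return docs


def write_corpus_jsonl(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "stay_id": d.stay_id, "text": d.text,
                   "sentences": [list(s) for s in d.sentences]}
            if d.sentence_labels is not None:
                rec["sentence_labels"] = [l.value for l in d.sentence_labels]
            if d.doc_label is not None:
                rec["doc_label"] = d.doc_label.value
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
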