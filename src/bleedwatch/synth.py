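"""Seeded synthetic cohort generator with ground-truth labels.

Emulates the structured data model of an eligible antithrombotic-exposed
inpatient cohort — hemoglobin time series with controllable 48-h drops and
nadirs, in-hospital death timing, transfusion unit counts, antihemorrhagic
and antithrombotic prescriptions, bleeding diagnosis codes — plus template
discharge summaries carrying MB / CRNMB / history / no-bleeding mentions.

Every generated stay passes the eligibility filter (age >= 65, at least one
antithrombotic ATC code, stay >= 24 h). Each truth-positive stay carries
exactly one injected qualifying event drawn from the configured criterion
mix; negatives receive benign series, a configurable fraction of them built
deliberately at the rule boundaries (1.9 g/dL drops, 9.1 g/dL nadirs,
exactly-5-unit transfusions, non-listed diagnosis codes). Identical
configurations and seeds give byte-identical outputs.

Default prevalences target the magnitudes a large mixed inpatient cohort
shows under these rules: MB ~8%, CRNMB ~15%.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .ehr_model import (DiagnosisRecord, LabMeasurement, PrescriptionEvent,
                        Sex, Stay, StayBundle, TransfusionEvent, write_cohort)
from .nlp import (AnnotatedDocument, DocLabel, SentenceLabel,
                  aggregate_sentence_labels, write_corpus_jsonl)
from .sda import Criterion

__all__ = ["CohortConfig", "GroundTruth", "generate_structured",
           "generate_documents", "write_synthetic", "load_templates"]

_EPOCH = datetime(2015, 1, 1, 8, 0)

_MB_CRITERIA = (Criterion.HB_DROP_GE4, Criterion.HB_DROP_2TO4_DEATH24,
                Criterion.HB_MIN_LT7, Criterion.HB_MIN_7TO9_DEATH24,
                Criterion.TRANSFUSION_GT5, Criterion.ANTIHEMORRHAGIC_RX,
                Criterion.ICD_MB)
_CRNMB_CRITERIA = (Criterion.HB_DROP_2TO4_NO_DEATH,
                   Criterion.HB_MIN_7TO9_NO_DEATH, Criterion.ICD_CRNMB)
_NEAR_MISS_TYPES = ("drop_1p9", "nadir_9p1", "transfusion_5u", "nonlist_code")

# antithrombotic exposure given to every stay (ATC, agent)
_ANTITHROMBOTICS = (
    ("B01AA04", "phenprocoumon"),
    ("B01AB05", "enoxaparin"),
    ("B01AC06", "aspirin"),
    ("B01AE07", "dabigatran"),
    ("B01AF01", "rivaroxaban"),
    ("B01AX05", "fondaparinux"),
)
_ANTIHEMORRHAGICS = ("idarucizumab", "andexanet alfa", "prothromplex",
                     "octaplex", "beriplex")
# concrete representatives of the packaged list patterns
_MB_CODES = ("I61.0", "I62.0", "K66.1", "R57.1", "T81.1", "I60.2", "M25.0")
_CRNMB_CODES = ("K92.1", "K92.2", "R04.0", "R31", "K25.0", "R58", "K62.5")
_BENIGN_CODES = ("I10", "E11.9", "J18.9", "N39.0", "I48.0")
_NONLIST_BLEED_ADJACENT = ("K25.4", "I63.9", "K25.1", "D50.0")


class CohortConfig(BaseModel):
    """Generator parameters; defaults are the study conditions."""

    n_stays: int = Field(ge=0, default=1000)
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {"MB": 0.08, "CRNMB": 0.15})
    criterion_mix: Optional[dict[str, float]] = None
    near_miss_fraction: float = Field(ge=0, le=1, default=0.25)
    doc_label_mix: Optional[dict[str, float]] = None
    seed: int = 0
    language_templates: str = "neutral"
    death_at_boundary_fraction: float = Field(ge=0, le=1, default=0.1)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for k, v in self.prevalence.items():
            if k not in ("MB", "CRNMB"):
                raise ValueError(f"unknown prevalence key {k!r}")
            if v < 0:
                raise ValueError("prevalences must be >= 0")
        if sum(self.prevalence.values()) > 1.0 + 1e-9:
            raise ValueError("prevalences must sum to <= 1")
        if self.criterion_mix is not None:
            known = {c.value for c in (*_MB_CRITERIA, *_CRNMB_CRITERIA)}
            for k in self.criterion_mix:
                if k not in known:
                    raise ValueError(f"unknown criterion {k!r} in criterion_mix")
        return self


class GroundTruth(BaseModel):
    """Per-stay generator truth, consistent with the emitted tables by
    construction."""

    stays: dict[str, dict] = Field(default_factory=dict)

    def label(self, stay_id: str) -> str:
        return self.stays[stay_id]["label"]

    def as_label_map(self) -> dict[str, str]:
        return {sid: rec["label"] for sid, rec in self.stays.items()}


def _allocate(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Integer allocation by largest remainder; deterministic."""
    if total == 0 or not weights:
        return {k: 0 for k in weights}
    wsum = sum(weights.values())
    exact = {k: total * w / wsum for k, w in weights.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = total - sum(counts.values())
    order = sorted(weights, key=lambda k: (-(exact[k] - np.floor(exact[k])), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def _benign_series(rng, start_h: float, n_points: int) -> list[tuple[float, float]]:
    """Flat hemoglobin series: baseline N(13,1) truncated, noise < +-0.4."""
    baseline = float(np.clip(rng.normal(13.0, 1.0), 10.2, 17.0))
    offsets = np.cumsum(rng.uniform(4.0, 24.0, size=n_points - 1)) if n_points > 1 else []
    hours = [start_h] + [start_h + float(o) for o in offsets]
    return [(h, baseline + float(rng.uniform(-0.4, 0.4))) for h in hours]


def _ramp_series(rng, start_h: float, top: float, bottom: float,
                 n_points: int, drop_span_h: float) -> list[tuple[float, float]]:
    """Series hovering near ``top`` then stepping down to ``bottom`` across
    two adjacent measurements ``drop_span_h`` apart; later points hover just
    above ``bottom`` so the engineered pair stays the maximal decline."""
    n_pre = max(1, n_points // 2)
    n_post = max(0, n_points - n_pre - 1)
    pts: list[tuple[float, float]] = []
    h = start_h
    for k in range(n_pre):
        # pre-drop values never exceed top (keeps the drop magnitude exact)
        pts.append((h, top - float(rng.uniform(0.0, 0.3))))
        if k < n_pre - 1:
            h += float(rng.uniform(4.0, 12.0))
    pts[-1] = (pts[-1][0], top)  # the drop starts from the engineered peak
    h = pts[-1][0] + drop_span_h
    pts.append((h, bottom))
    for _ in range(n_post):
        h += float(rng.uniform(4.0, 12.0))
        pts.append((h, bottom + float(rng.uniform(0.05, 0.3))))
    return pts


def _low_flat_series(rng, start_h: float, nadir: float, n_points: int
                     ) -> list[tuple[float, float]]:
    """Monotone-ish descent to ``nadir`` as the last point; total spread
    < 1.9 g/dL so no drop criterion can fire."""
    highs = np.sort(rng.uniform(nadir + 0.1, nadir + 1.7, size=n_points - 1))[::-1]
    offsets = np.cumsum(rng.uniform(4.0, 18.0, size=n_points - 1))
    pts = [(start_h, float(highs[0]))]
    for k in range(1, n_points - 1):
        pts.append((start_h + float(offsets[k - 1]), float(highs[k])))
    pts.append((start_h + float(offsets[-1]), nadir))
    return pts


def generate_structured(config: CohortConfig
                        ) -> tuple[list[StayBundle], GroundTruth]:
    """Generate the structured cohort tables and their ground truth.

    Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    n_mb = int(round(n * config.prevalence.get("MB", 0.0)))
    n_crnmb = int(round(n * config.prevalence.get("CRNMB", 0.0)))
    n_neg = n - n_mb - n_crnmb
    if n_neg < 0:
        raise ValueError("prevalences exceed 1 for this n_stays")

    mix = config.criterion_mix or {}
    mb_mix = {c.value: mix.get(c.value, 1.0) for c in _MB_CRITERIA} \
        if not mix else {k: v for k, v in mix.items()
                         if k in {c.value for c in _MB_CRITERIA}}
    crnmb_mix = {c.value: mix.get(c.value, 1.0) for c in _CRNMB_CRITERIA} \
        if not mix else {k: v for k, v in mix.items()
                         if k in {c.value for c in _CRNMB_CRITERIA}}
    if n_mb and not mb_mix:
        raise ValueError("criterion_mix contains no MB criterion")
    if n_crnmb and not crnmb_mix:
        raise ValueError("criterion_mix contains no CRNMB criterion")

    mb_alloc = _allocate(n_mb, mb_mix or {c.value: 1.0 for c in _MB_CRITERIA})
    crnmb_alloc = _allocate(n_crnmb, crnmb_mix or
                            {c.value: 1.0 for c in _CRNMB_CRITERIA})
    n_near = int(round(n_neg * config.near_miss_fraction))

    plans: list[tuple[str, Optional[str]]] = []
    for crit, k in sorted(mb_alloc.items()):
        plans.extend([("MB", crit)] * k)
    for crit, k in sorted(crnmb_alloc.items()):
        plans.extend([("CRNMB", crit)] * k)
    for i in range(n_near):
        plans.append(("none", "near_miss:" + _NEAR_MISS_TYPES[i % 4]))
    plans.extend([("none", None)] * (n_neg - n_near))
    rng.shuffle(plans)

    bundles: list[StayBundle] = []
    truth = GroundTruth()
    for idx, (label, crit) in enumerate(plans):
        sid = f"S{idx:05d}"
        bundles.append(_build_stay(rng, sid, label, crit, config))
        truth.stays[sid] = {"label": label, "injected_criterion": crit,
                            "doc_label": None, "sentence_labels": None}
    return bundles, truth


def _build_stay(rng, sid: str, label: str, crit: Optional[str],
                config: CohortConfig) -> StayBundle:
    admission = _EPOCH + timedelta(days=int(rng.integers(0, 700)),
                                   hours=float(rng.uniform(0, 12)))
    age = int(rng.integers(65, 96))
    sex = Sex.male if rng.random() < 0.5 else Sex.female
    hospital = ("CH1", "CH2", "CH3")[int(rng.integers(0, 3))]
    atc, agent = _ANTITHROMBOTICS[int(rng.integers(0, len(_ANTITHROMBOTICS)))]
    n_points = int(rng.integers(3, 11))
    needs_death = crit in (Criterion.HB_DROP_2TO4_DEATH24.value,
                           Criterion.HB_MIN_7TO9_DEATH24.value)
    # death-linked anchors must land >= 26 h after admission so the stay
    # remains eligible (>= 24 h) even when death truncates it
    start_h = float(rng.uniform(26.0, 36.0)) if needs_death \
        else float(rng.uniform(1.0, 6.0))

    labs_h: list[tuple[float, float]]
    transfusions: list[TransfusionEvent] = []
    prescriptions = [PrescriptionEvent(
        stay_id=sid, atc_code=atc, agent_name=agent,
        ts=admission + timedelta(hours=start_h))]
    diagnoses: list[DiagnosisRecord] = []
    death_h: Optional[float] = None

    def death_delay() -> float:
        if rng.random() < config.death_at_boundary_fraction:
            return 24.0  # pins the inclusive boundary
        return float(rng.uniform(0.0, 24.0))

    if crit == Criterion.HB_DROP_GE4.value:
        top = float(rng.uniform(13.5, 16.5))
        drop = 4.0 + float(rng.uniform(0.0, 3.0))
        labs_h = _ramp_series(rng, start_h, top, top - drop, n_points,
                              drop_span_h=float(rng.uniform(6.0, 44.0)))
    elif crit == Criterion.HB_DROP_2TO4_DEATH24.value:
        top = float(rng.uniform(12.8, 13.5))
        drop = float(rng.uniform(2.2, 3.6))
        labs_h = _ramp_series(rng, start_h, top, top - drop, n_points,
                              drop_span_h=float(rng.uniform(6.0, 44.0)))
        # anchor is the drop's later measurement
        end_h = labs_h[max(1, n_points // 2)][0]
        death_h = end_h + death_delay()
        labs_h = [p for p in labs_h if p[0] <= death_h]
    elif crit == Criterion.HB_DROP_2TO4_NO_DEATH.value:
        top = float(rng.uniform(12.8, 13.5))
        drop = float(rng.uniform(2.2, 3.6))
        labs_h = _ramp_series(rng, start_h, top, top - drop, n_points,
                              drop_span_h=float(rng.uniform(6.0, 44.0)))
    elif crit == Criterion.HB_MIN_LT7.value:
        labs_h = _low_flat_series(rng, start_h, 7.0 - float(rng.uniform(0.05, 2.0)),
                                  n_points)
    elif crit == Criterion.HB_MIN_7TO9_DEATH24.value:
        labs_h = _low_flat_series(rng, start_h, float(rng.uniform(7.1, 8.9)),
                                  n_points)
        death_h = labs_h[-1][0] + death_delay()
    elif crit == Criterion.HB_MIN_7TO9_NO_DEATH.value:
        labs_h = _low_flat_series(rng, start_h, float(rng.uniform(7.1, 8.9)),
                                  n_points)
    elif crit == Criterion.TRANSFUSION_GT5.value:
        labs_h = _benign_series(rng, start_h, n_points)
        product = "red_blood_cells" if rng.random() < 0.8 else "whole_blood"
        transfusions.append(TransfusionEvent(
            stay_id=sid, product=product, units=int(rng.integers(6, 9)),
            ts=admission + timedelta(hours=labs_h[0][0] + 2.0)))
    elif crit == Criterion.ANTIHEMORRHAGIC_RX.value:
        labs_h = _benign_series(rng, start_h, n_points)
        agent_h = _ANTIHEMORRHAGICS[int(rng.integers(0, len(_ANTIHEMORRHAGICS)))]
        prescriptions.append(PrescriptionEvent(
            stay_id=sid, agent_name=agent_h,
            ts=admission + timedelta(hours=labs_h[0][0] + 1.0)))
    elif crit == Criterion.ICD_MB.value:
        labs_h = _benign_series(rng, start_h, n_points)
        diagnoses.append(DiagnosisRecord(
            stay_id=sid,
            icd10gm_code=_MB_CODES[int(rng.integers(0, len(_MB_CODES)))],
            present_on_admission=bool(rng.random() < 0.5)))
    elif crit == Criterion.ICD_CRNMB.value:
        labs_h = _benign_series(rng, start_h, n_points)
        diagnoses.append(DiagnosisRecord(
            stay_id=sid,
            icd10gm_code=_CRNMB_CODES[int(rng.integers(0, len(_CRNMB_CODES)))],
            present_on_admission=bool(rng.random() < 0.5)))
    elif crit == "near_miss:drop_1p9":
        labs_h = _ramp_series(rng, start_h, 12.9, 11.0, n_points,
                              drop_span_h=float(rng.uniform(6.0, 44.0)))
    elif crit == "near_miss:nadir_9p1":
        labs_h = _low_flat_series(rng, start_h, 9.1, n_points)
    elif crit == "near_miss:transfusion_5u":
        labs_h = _benign_series(rng, start_h, n_points)
        transfusions.append(TransfusionEvent(
            stay_id=sid, product="red_blood_cells", units=5,
            ts=admission + timedelta(hours=labs_h[0][0] + 2.0)))
    elif crit == "near_miss:nonlist_code":
        labs_h = _benign_series(rng, start_h, n_points)
        diagnoses.append(DiagnosisRecord(
            stay_id=sid,
            icd10gm_code=_NONLIST_BLEED_ADJACENT[
                int(rng.integers(0, len(_NONLIST_BLEED_ADJACENT)))],
            present_on_admission=False))
    else:  # plain negative
        labs_h = _benign_series(rng, start_h, n_points)
        if rng.random() < 0.3:
            diagnoses.append(DiagnosisRecord(
                stay_id=sid,
                icd10gm_code=_BENIGN_CODES[int(rng.integers(0, len(_BENIGN_CODES)))],
                present_on_admission=bool(rng.random() < 0.5)))

    last_h = max(h for h, _ in labs_h)
    if death_h is not None:
        discharge_h = death_h
    else:
        discharge_h = max(last_h + float(rng.uniform(6.0, 24.0)), 26.0)
    stay = Stay(stay_id=sid, patient_id=f"P{sid[1:]}", admission_ts=admission,
                discharge_ts=admission + timedelta(hours=discharge_h),
                death_ts=(admission + timedelta(hours=death_h)
                          if death_h is not None else None),
                age_years=age, sex=sex, hospital_id=hospital)
    labs = [LabMeasurement(stay_id=sid, value=round(v, 2),
                           ts=admission + timedelta(hours=h))
            for h, v in labs_h]
    return StayBundle(stay=stay, labs=labs, transfusions=transfusions,
                      prescriptions=prescriptions, diagnoses=diagnoses)


# ---------------------------------------------------------------------------
# discharge summaries


def load_templates(name: str = "neutral") -> dict:
    ref = resources.files("bleedwatch.data") / f"templates_{name}.json"
    try:
        with ref.open(encoding="utf-8") as fh:
            tpl = json.load(fh)
    except FileNotFoundError:
        raise ValueError(f"template set {name!r} not found") from None
    for key in ("filler", "negation", "active_mb", "active_crnmb", "antecedent"):
        if not tpl.get(key):
            raise ValueError(f"template set {name!r} lacks label class {key!r}")
    return tpl


_DOC_FROM_STAY = {"MB": DocLabel.B_mb, "CRNMB": DocLabel.A_crnmb,
                  "none": DocLabel.D_none}
_MIX_KEY_TO_DOC = {"A": DocLabel.A_crnmb, "B": DocLabel.B_mb,
                   "C": DocLabel.C_history, "D": DocLabel.D_none}


def _compose(rng, tpl: dict, doc_label: DocLabel
             ) -> tuple[list[str], list[SentenceLabel]]:
    def pick(key: str) -> str:
        options = tpl[key]
        s = options[int(rng.integers(0, len(options)))]
        if rng.random() < 0.5:  # vary surface form without touching the lexicon
            s = s[:-1] + f" on day {int(rng.integers(1, 10))}."
        return s

    sents: list[tuple[str, SentenceLabel]] = []
    for _ in range(int(rng.integers(2, 6))):
        key = "negation" if rng.random() < 0.3 else "filler"
        sents.append((pick(key), SentenceLabel.irrelevant))
    if doc_label is DocLabel.B_mb:
        for _ in range(int(rng.integers(1, 3))):
            sents.append((pick("active_mb"), SentenceLabel.active_mb))
        if rng.random() < 0.4:
            sents.append((pick("active_crnmb"), SentenceLabel.active_crnmb))
        if rng.random() < 0.3:
            sents.append((pick("antecedent"), SentenceLabel.antecedent))
    elif doc_label is DocLabel.A_crnmb:
        for _ in range(int(rng.integers(1, 3))):
            sents.append((pick("active_crnmb"), SentenceLabel.active_crnmb))
        if rng.random() < 0.3:
            sents.append((pick("antecedent"), SentenceLabel.antecedent))
    elif doc_label is DocLabel.C_history:
        for _ in range(int(rng.integers(1, 3))):
            sents.append((pick("antecedent"), SentenceLabel.antecedent))
    rng.shuffle(sents)
    return [s for s, _ in sents], [l for _, l in sents]


def generate_documents(config: CohortConfig,
                       truth: Optional[GroundTruth] = None
                       ) -> list[AnnotatedDocument]:
    """Generate annotated discharge summaries.

    With ``truth`` given, one document per stay whose label mirrors the
    structured truth (MB -> B, CRNMB -> A, none -> D) and the truth record is
    updated in place. Otherwise a standalone corpus is drawn from
    ``config.doc_label_mix`` (counts or fractions over A/B/C/D; default the
    balanced 1/4 B, 1/4 A, 1/2 D annotation-corpus composition). Emitted
    document labels always equal the priority aggregation of the emitted
    sentence labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    tpl = load_templates(config.language_templates)
    docs: list[AnnotatedDocument] = []

    if truth is not None:
        items = [(f"D{sid[1:]}", sid, _DOC_FROM_STAY[rec["label"]])
                 for sid, rec in sorted(truth.stays.items())]
    else:
        mix = config.doc_label_mix or {"B": 0.25, "A": 0.25, "D": 0.5}
        counts = _allocate(config.n_stays, mix)
        items = []
        k = 0
        for key in sorted(counts):
            for _ in range(counts[key]):
                items.append((f"D{k:05d}", None, _MIX_KEY_TO_DOC[key]))
                k += 1
        order = rng.permutation(len(items))
        items = [items[i] for i in order]

    for doc_id, sid, doc_label in items:
        texts, labels = _compose(rng, tpl, doc_label)
        spans: list[tuple[int, int]] = []
        pos = 0
        chunks = []
        for t in texts:
            spans.append((pos, pos + len(t)))
            chunks.append(t)
            pos += len(t) + 1
        text = " ".join(chunks)
        agg = aggregate_sentence_labels(labels)
        assert agg == doc_label, "template composition violated the priority rule"
        doc = AnnotatedDocument(doc_id=doc_id, stay_id=sid, text=text,
                                sentences=spans, sentence_labels=labels,
                                doc_label=doc_label)
        docs.append(doc)
        if truth is not None and sid is not None:
            truth.stays[sid]["doc_label"] = doc_label.value
            truth.stays[sid]["sentence_labels"] = [l.value for l in labels]
    return docs


def write_synthetic(config: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the cohort CSVs, docs.jsonl, truth.jsonl and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles, truth = generate_structured(config)
    docs = generate_documents(config, truth)
    paths = write_cohort(bundles, out)
    docs_path = out / "docs.jsonl"
    write_corpus_jsonl(docs, docs_path)
    truth_path = out / "truth.jsonl"
    with open(truth_path, "w", encoding="utf-8") as fh:
        for sid in sorted(truth.stays):
            fh.write(json.dumps({"stay_id": sid, **truth.stays[sid]}) + "\n")
    cfg_path = out / "config.resolved.json"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        json.dump(config.model_dump(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.update({"docs": docs_path, "truth": truth_path, "config": cfg_path})
    return paths
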