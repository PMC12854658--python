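"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Optional, Sequence

import pytest
from hypothesis import settings as _hyp_settings

from bleedwatch.ehr_model import (DiagnosisRecord, LabMeasurement,
                                  PrescriptionEvent, Sex, Stay, StayBundle,
                                  TransfusionEvent)

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

T0 = datetime(2015, 3, 1, 8, 0)


def hours(h: float) -> timedelta:
    return timedelta(hours=h)


def make_bundle(
    labs: Sequence[tuple[float, float]] = (),
    *,
    stay_id: str = "S1",
    death_h: Optional[float] = None,
    los_h: float = 200.0,
    age: int = 80,
    transfusions: Sequence[tuple[str, int]] = (),
    agents: Sequence[str] = (),
    codes: Sequence[str] = (),
    atc: str = "B01AB05",
) -> StayBundle:
    """Assemble a stay from shorthand: labs as (hour, g/dL), death as hours
    after admission, transfusions as (product, units)."""
    discharge_h = max(los_h, death_h if death_h is not None else 0.0,
                      max((h for h, _ in labs), default=0.0) + 1.0)
    stay = Stay(
        stay_id=stay_id, patient_id="P1", admission_ts=T0,
        discharge_ts=T0 + hours(discharge_h),
        death_ts=T0 + hours(death_h) if death_h is not None else None,
        age_years=age, sex=Sex.female, hospital_id="CH1",
    )
    return StayBundle(
        stay=stay,
        labs=[LabMeasurement(stay_id=stay_id, value=v, ts=T0 + hours(h))
              for h, v in labs],
        transfusions=[TransfusionEvent(stay_id=stay_id, product=p, units=u,
                                       ts=T0 + hours(1.0))
                      for p, u in transfusions],
        prescriptions=[PrescriptionEvent(stay_id=stay_id, atc_code=atc,
                                         agent_name="agent", ts=T0)] +
                      [PrescriptionEvent(stay_id=stay_id, agent_name=a, ts=T0)
                       for a in agents],
        diagnoses=[DiagnosisRecord(stay_id=stay_id, icd10gm_code=c)
                   for c in codes],
    )


def brute_force_max_drop(points: Sequence[tuple[float, float]],
                         window_hours: float = 48.0):
    """O(n^2) all-pairs oracle for the maximal in-window hemoglobin decline.

    Points are (hour, value). Same tie-breaking contract as the engine:
    largest drop, then earliest end, then earliest start.
    """
    best = None  # (drop, end_h, start_h, start_v, end_v)
    for i, (hi, vi) in enumerate(points):
        for hj, vj in points[i + 1:]:
            if hj <= hi or hj - hi > window_hours:
                continue
            drop = vi - vj
            if drop <= 0:
                continue
            key = (-drop, hj, hi)
            if best is None or key < best[0]:
                best = (key, drop, hi, hj, vi, vj)
    if best is None:
        return None
    _, drop, hi, hj, vi, vj = best
    return {"drop": drop, "start_h": hi, "end_h": hj,
            "start_value": vi, "end_value": vj}


def wilson_closed_form(successes: int, trials: int, z: float = 1.959963984540054):
    """Independent closed-form Wilson score interval."""
    p = successes / trials
    denom = 1 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z / denom) * ((p * (1 - p) / trials
                           + z * z / (4 * trials * trials)) ** 0.5)
    return max(0.0, center - half), min(1.0, center + half)


def fleiss_by_hand(matrix: Sequence[Sequence[str]]) -> float:
    """Direct evaluation of the Fleiss formula via mean per-item agreement
    P-bar and chance agreement P-bar-e."""
    cats = sorted({c for row in matrix for c in row})
    n_items = len(matrix)
    n_raters = len(matrix[0])
    counts = [[row.count(c) for c in cats] for row in matrix]
    p_i = [(sum(k * k for k in row) - n_raters) / (n_raters * (n_raters - 1))
           for row in counts]
    p_bar = sum(p_i) / n_items
    totals = [sum(row[j] for row in counts) for j in range(len(cats))]
    grand = n_items * n_raters
    p_e = sum((t / grand) ** 2 for t in totals)
    return (p_bar - p_e) / (1 - p_e)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 200-stay synthetic cohort shared across tests."""
    from bleedwatch.synth import CohortConfig, generate_structured

    cfg = CohortConfig(n_stays=200, seed=11)
    bundles, truth = generate_structured(cfg)
    return cfg, bundles, truth


@pytest.fixture(scope="session")
def template_corpus():
    """A 200-document separable template corpus (50 B / 50 A / 100 D)."""
    from bleedwatch.synth import CohortConfig, generate_documents

    cfg = CohortConfig(n_stays=200, seed=5,
                       doc_label_mix={"B": 50, "A": 50, "D": 100})
    return generate_documents(cfg)
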