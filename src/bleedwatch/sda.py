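"""Structured-data rule engine for bleeding severity classification.

Each inpatient stay is labelled MB (major bleeding), CRNMB (clinically
relevant nonmajor bleeding) or none by Boolean rules over four structured
sources:

* laboratory — hemoglobin drop within a 48-h window and the stay nadir,
* transfusion — cumulative whole-blood/red-cell units (strictly more than 5),
* medication — prescription of a reversal/antihemorrhagic agent,
* icd — diagnosis codes against the packaged MB/CRNMB lists.

MB criteria: drop >= 4 g/dL within 48 h; drop in [2, 4) with death within
24 h of the drop's end; nadir < 7 g/dL; nadir in [7, 9] with death within
24 h of the nadir; transfusion > 5 units; antihemorrhagic prescription; MB
diagnosis code. CRNMB criteria: drop in [2, 4) or nadir in [7, 9] without the
associated death, or a CRNMB diagnosis code. MB takes precedence whenever
both tiers fire. The death window is anchored at the qualifying drop's later
measurement (the event's detection time) or at the nadir timestamp, bound
inclusive at exactly 24 h.
"""

from __future__ import annotations

import enum
import re
from collections import deque
from dataclasses import dataclass, field
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .ehr_model import (HOUR, BloodProduct, LabMeasurement, PrescriptionEvent,
                        StayBundle, TransfusionEvent)
from .icd import CodeList, Severity, classify_codes, default_code_list

__all__ = [
    "Criterion",
    "Source",
    "HbDropEvent",
    "BleedingCall",
    "SdaConfig",
    "max_hb_drop",
    "min_hb",
    "death_within",
    "transfusion_total",
    "antihemorrhagic_hit",
    "classify_stay",
    "classify_cohort",
    "cohort_prevalence",
    "PrevalenceTable",
    "round_half_away",
    "DEFAULT_ANTIHEMORRHAGIC_AGENTS",
]

#: Reversal / antihemorrhagic agents whose prescription is taken as
#: indicative of major bleeding.
DEFAULT_ANTIHEMORRHAGIC_AGENTS: tuple[str, ...] = (
    "idarucizumab",
    "andexanet alfa",
    "prothromplex",
    "octaplex",
    "beriplex",
)


class Criterion(str, enum.Enum):
    # MB tier
    HB_DROP_GE4 = "HB_DROP_GE4"
    HB_DROP_2TO4_DEATH24 = "HB_DROP_2TO4_DEATH24"
    HB_MIN_LT7 = "HB_MIN_LT7"
    HB_MIN_7TO9_DEATH24 = "HB_MIN_7TO9_DEATH24"
    TRANSFUSION_GT5 = "TRANSFUSION_GT5"
    ANTIHEMORRHAGIC_RX = "ANTIHEMORRHAGIC_RX"
    ICD_MB = "ICD_MB"
    # CRNMB tier
    HB_DROP_2TO4_NO_DEATH = "HB_DROP_2TO4_NO_DEATH"
    HB_MIN_7TO9_NO_DEATH = "HB_MIN_7TO9_NO_DEATH"
    ICD_CRNMB = "ICD_CRNMB"


MB_CRITERIA = frozenset({
    Criterion.HB_DROP_GE4, Criterion.HB_DROP_2TO4_DEATH24, Criterion.HB_MIN_LT7,
    Criterion.HB_MIN_7TO9_DEATH24, Criterion.TRANSFUSION_GT5,
    Criterion.ANTIHEMORRHAGIC_RX, Criterion.ICD_MB,
})
CRNMB_CRITERIA = frozenset({
    Criterion.HB_DROP_2TO4_NO_DEATH, Criterion.HB_MIN_7TO9_NO_DEATH,
    Criterion.ICD_CRNMB,
})


class Source(str, enum.Enum):
    laboratory = "laboratory"
    icd = "icd"
    transfusion = "transfusion"
    medication = "medication"


_CRITERION_SOURCE = {
    Criterion.HB_DROP_GE4: Source.laboratory,
    Criterion.HB_DROP_2TO4_DEATH24: Source.laboratory,
    Criterion.HB_MIN_LT7: Source.laboratory,
    Criterion.HB_MIN_7TO9_DEATH24: Source.laboratory,
    Criterion.TRANSFUSION_GT5: Source.transfusion,
    Criterion.ANTIHEMORRHAGIC_RX: Source.medication,
    Criterion.ICD_MB: Source.icd,
    Criterion.HB_DROP_2TO4_NO_DEATH: Source.laboratory,
    Criterion.HB_MIN_7TO9_NO_DEATH: Source.laboratory,
    Criterion.ICD_CRNMB: Source.icd,
}


class HbDropEvent(BaseModel):
    """The maximal hemoglobin decline between two measurements <= window apart."""

    start_ts: datetime
    end_ts: datetime
    start_value: float
    end_value: float
    drop: float = Field(gt=0)
    window_hours: float

    @property
    def span_hours(self) -> float:
        return (self.end_ts - self.start_ts) / HOUR


class BleedingCall(BaseModel):
    """Per-stay label with firing criteria and per-source attribution."""

    stay_id: str
    label: str  # "MB" | "CRNMB" | "none"
    criteria_fired: set[Criterion] = Field(default_factory=set)
    sources_fired: set[Source] = Field(default_factory=set)
    mb_mortality: bool = False
    evidence: list[dict] = Field(default_factory=list)


class SdaConfig(BaseModel):
    """Rule parameters. Defaults are the adapted ISTH cut-offs."""

    window_hours: float = 48.0
    death_horizon_hours: float = 24.0
    mb_drop_gdl: float = 4.0        # drop >= 4 is MB outright
    crnmb_drop_gdl: float = 2.0     # drop in [2, 4) is the conditional band
    nadir_mb_gdl: float = 7.0       # nadir < 7 is MB outright
    nadir_band_high_gdl: float = 9.0  # nadir in [7, 9] is the conditional band
    transfusion_units_gt: int = 5   # strictly more than 5 units
    antihemorrhagic_agents: tuple[str, ...] = DEFAULT_ANTIHEMORRHAGIC_AGENTS


def max_hb_drop(labs: Sequence[LabMeasurement | tuple],
                window_hours: float = 48.0) -> Optional[HbDropEvent]:
    """Largest decline between an earlier and a later measurement at most
    ``window_hours`` apart; ``None`` when no pair declines.

    Ties are broken by earliest end timestamp, then earliest start timestamp.
    Accepts ``LabMeasurement`` objects or ``(ts, value)`` pairs; input must be
    sorted ascending by timestamp. Runs in O(n) with a monotonic deque.
    """
    pts: list[tuple[datetime, float]] = []
    for m in labs:
        if isinstance(m, LabMeasurement):
            pts.append((m.ts, m.value))
        else:
            pts.append((m[0], m[1]))
    for a, b in zip(pts, pts[1:]):
        if b[0] < a[0]:
            raise ValueError("hemoglobin series must be sorted ascending by ts")

    window = window_hours * HOUR
    best: Optional[HbDropEvent] = None
    # decreasing deque of (ts, value); front = earliest maximum in window.
    # Points sharing a timestamp are processed as a group so a pair always
    # has a strictly later end.
    dq: deque[tuple[datetime, float]] = deque()
    i = 0
    n = len(pts)
    while i < n:
        j = i
        while j < n and pts[j][0] == pts[i][0]:
            j += 1
        group = pts[i:j]
        ts_g = group[0][0]
        while dq and dq[0][0] < ts_g - window:
            dq.popleft()
        if dq:
            ts_i, v_i = dq[0]
            for _, v_j in group:
                drop = v_i - v_j
                if drop > 0 and (best is None or drop > best.drop):
                    best = HbDropEvent(start_ts=ts_i, end_ts=ts_g,
                                       start_value=v_i, end_value=v_j,
                                       drop=drop, window_hours=window_hours)
        for ts_j, v_j in group:
            while dq and dq[-1][1] < v_j:  # strict: keep earliest among equals
                dq.pop()
            dq.append((ts_j, v_j))
        i = j
    return best


def min_hb(labs: Sequence[LabMeasurement | tuple]) -> Optional[tuple[float, datetime]]:
    """Stay nadir: minimum value and its (earliest, on ties) timestamp."""
    best: Optional[tuple[float, datetime]] = None
    for m in labs:
        ts, v = (m.ts, m.value) if isinstance(m, LabMeasurement) else (m[0], m[1])
        if best is None or v < best[0]:
            best = (v, ts)
    return best


def death_within(anchor_ts: datetime, death_ts: Optional[datetime],
                 horizon_hours: float = 24.0) -> bool:
    """True iff death occurred within ``horizon_hours`` after the anchor,
    bound inclusive (death at exactly 24 h counts)."""
    if death_ts is None:
        return False
    delta = (death_ts - anchor_ts) / HOUR
    return 0.0 <= delta <= horizon_hours


def transfusion_total(events: Iterable[TransfusionEvent]) -> int:
    """Cumulative transfused units of whole blood or red cells for the stay;
    plasma does not count toward the major-bleeding transfusion rule."""
    return sum(e.units for e in events
               if e.product in (BloodProduct.whole_blood, BloodProduct.red_blood_cells))


def antihemorrhagic_hit(prescriptions: Iterable[PrescriptionEvent],
                        agents: Sequence[str] = DEFAULT_ANTIHEMORRHAGIC_AGENTS) -> bool:
    """True iff any prescription names a listed antihemorrhagic agent.

    Matching is case-insensitive and word-boundary tolerant, so trade
    formulations like "Beriplex P/N 500" match "beriplex".
    """
    pats = [re.compile(r"(?<!\w)" + re.escape(a.lower()) + r"(?!\w)") for a in agents]
    for rx in prescriptions:
        name = rx.agent_name.lower()
        if name and any(p.search(name) for p in pats):
            return True
    return False


def classify_stay(bundle: StayBundle, config: Optional[SdaConfig] = None,
                  code_list: Optional[CodeList] = None) -> BleedingCall:
    """Apply the full rule cascade to one stay.

    Missing labs or diagnoses mean "criterion not met", never an error. A
    single hemoglobin measurement can support the nadir rules but not the
    drop rules.
    """
    cfg = config or SdaConfig()
    cl = code_list or default_code_list()
    stay = bundle.stay
    fired: set[Criterion] = set()
    evidence: list[dict] = []

    drop = max_hb_drop(bundle.labs, cfg.window_hours)
    if drop is not None:
        if drop.drop >= cfg.mb_drop_gdl:
            fired.add(Criterion.HB_DROP_GE4)
        elif drop.drop >= cfg.crnmb_drop_gdl:
            if death_within(drop.end_ts, stay.death_ts, cfg.death_horizon_hours):
                fired.add(Criterion.HB_DROP_2TO4_DEATH24)
            else:
                fired.add(Criterion.HB_DROP_2TO4_NO_DEATH)
        if drop.drop >= cfg.crnmb_drop_gdl:
            evidence.append({"type": "hb_drop", "drop": drop.drop,
                             "start_ts": drop.start_ts.isoformat(),
                             "end_ts": drop.end_ts.isoformat(),
                             "start_value": drop.start_value,
                             "end_value": drop.end_value})

    nadir = min_hb(bundle.labs)
    if nadir is not None:
        value, ts = nadir
        if value < cfg.nadir_mb_gdl:
            fired.add(Criterion.HB_MIN_LT7)
            evidence.append({"type": "hb_nadir", "value": value,
                             "ts": ts.isoformat()})
        elif value <= cfg.nadir_band_high_gdl:
            if death_within(ts, stay.death_ts, cfg.death_horizon_hours):
                fired.add(Criterion.HB_MIN_7TO9_DEATH24)
            else:
                fired.add(Criterion.HB_MIN_7TO9_NO_DEATH)
            evidence.append({"type": "hb_nadir", "value": value,
                             "ts": ts.isoformat()})

    units = transfusion_total(bundle.transfusions)
    if units > cfg.transfusion_units_gt:
        fired.add(Criterion.TRANSFUSION_GT5)
        evidence.append({"type": "transfusion", "units": units})

    if antihemorrhagic_hit(bundle.prescriptions, cfg.antihemorrhagic_agents):
        fired.add(Criterion.ANTIHEMORRHAGIC_RX)
        evidence.append({"type": "antihemorrhagic_rx",
                         "agents": [p.agent_name for p in bundle.prescriptions]})

    flags = classify_codes(bundle.diagnoses, cl)
    if flags.mb_hit:
        fired.add(Criterion.ICD_MB)
    if flags.crnmb_hit:
        fired.add(Criterion.ICD_CRNMB)
    if flags.matched:
        evidence.append({"type": "icd", "matched": flags.matched})

    mb_fired = fired & MB_CRITERIA
    crnmb_fired = fired & CRNMB_CRITERIA
    if mb_fired:
        label = "MB"
        tier = mb_fired
    elif crnmb_fired:
        label = "CRNMB"
        tier = crnmb_fired
    else:
        label = "none"
        tier = set()
    # attribution: only the criteria of the tier that determined the label
    sources = {_CRITERION_SOURCE[c] for c in tier}
    return BleedingCall(
        stay_id=stay.stay_id, label=label, criteria_fired=fired,
        sources_fired=sources,
        mb_mortality=(label == "MB" and stay.death_ts is not None),
        evidence=evidence,
    )


def classify_cohort(bundles: Iterable[StayBundle],
                    config: Optional[SdaConfig] = None,
                    code_list: Optional[CodeList] = None) -> list[BleedingCall]:
    cfg = config or SdaConfig()
    cl = code_list or default_code_list()
    return [classify_stay(b, cfg, cl) for b in bundles]


# ---------------------------------------------------------------------------
# prevalence


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (13.455 -> 13.46), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceTable:
    """Counts and percentages of stays per label, plus fatal-MB stays."""

    none: int
    crnmb: int
    mb: int
    mb_mortality: int
    denominator: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.none + self.crnmb + self.mb != self.denominator:
            raise RuntimeError(
                "internal error: label counts do not partition the denominator")
        if not self.percentages:
            denom = self.denominator
            self.percentages = {
                key: (round_half_away(100.0 * count / denom, 2) if denom else 0.0)
                for key, count in (("none", self.none), ("CRNMB", self.crnmb),
                                   ("MB", self.mb),
                                   ("MB_mortality", self.mb_mortality))
            }

    @property
    def counts(self) -> dict[str, int]:
        return {"none": self.none, "CRNMB": self.crnmb, "MB": self.mb,
                "MB_mortality": self.mb_mortality}


def cohort_prevalence(calls: Sequence[BleedingCall],
                      denominator: Optional[int] = None) -> PrevalenceTable:
    """Tabulate cohort prevalence from per-stay calls.

    Percentages use half-away-from-zero rounding to 2 decimals.
    """
    n_none = sum(1 for c in calls if c.label == "none")
    n_crnmb = sum(1 for c in calls if c.label == "CRNMB")
    n_mb = sum(1 for c in calls if c.label == "MB")
    n_fatal = sum(1 for c in calls if c.mb_mortality)
    denom = denominator if denominator is not None else len(calls)
    return PrevalenceTable(none=n_none, crnmb=n_crnmb, mb=n_mb,
                           mb_mortality=n_fatal, denominator=denom)
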