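"""Domain types and tabular I/O for inpatient EHR extracts.

The unit of analysis is the inpatient stay. A :class:`StayBundle` gathers all
structured events recorded during one stay — hemoglobin laboratory series,
transfusions, prescriptions and billing diagnoses — and is what the rule
engine classifies.

Interchange format: five UTF-8 CSV tables with a mandatory header row
(``stays.csv``, ``labs.csv``, ``transfusions.csv``, ``prescriptions.csv``,
``diagnoses.csv``); empty string means missing. Timestamps are ISO-8601 and
are interpreted in a single zone per cohort; hemoglobin is canonicalized to
g/dL, with g/L accepted only under an explicit per-row or configured unit
declaration (never guessed from magnitude).
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Sex",
    "BloodProduct",
    "Stay",
    "LabMeasurement",
    "TransfusionEvent",
    "PrescriptionEvent",
    "DiagnosisRecord",
    "StayBundle",
    "EligibilityConfig",
    "CohortLoadResult",
    "LoadError",
    "load_cohort",
    "write_cohort",
    "filter_eligible",
    "DEFAULT_ANTITHROMBOTIC_ATC_PREFIXES",
]

HOUR = timedelta(hours=1)

#: ATC prefixes defining the antithrombotic exposure required for cohort
#: eligibility: vitamin K antagonists (B01AA), heparin group (B01AB),
#: platelet aggregation inhibitors (B01AC), direct thrombin inhibitors
#: (B01AE), direct factor Xa inhibitors (B01AF), fondaparinux (B01AX05).
DEFAULT_ANTITHROMBOTIC_ATC_PREFIXES: tuple[str, ...] = (
    "B01AA",
    "B01AB",
    "B01AC",
    "B01AE",
    "B01AF",
    "B01AX05",
)

_ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")


class LoadError(ValueError):
    """Schema or content violation while loading a cohort table."""

    def __init__(self, message: str, *, file: str = "", row: Optional[int] = None,
                 column: str = ""):
        detail = message
        ctx = ", ".join(
            s for s in (
                f"file={file}" if file else "",
                f"row={row}" if row is not None else "",
                f"column={column}" if column else "",
            ) if s
        )
        if ctx:
            detail = f"{message} ({ctx})"
        super().__init__(detail)
        self.file = file
        self.row = row
        self.column = column


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    other = "other"


class BloodProduct(str, enum.Enum):
    whole_blood = "whole_blood"
    red_blood_cells = "red_blood_cells"
    plasma = "plasma"


class Stay(BaseModel):
    """One inpatient stay; houses mortality timing for the death-linked rules."""

    stay_id: str
    patient_id: str
    admission_ts: datetime
    discharge_ts: datetime
    death_ts: Optional[datetime] = None
    age_years: int = Field(ge=0)
    sex: Sex = Sex.other
    hospital_id: str = ""

    @model_validator(mode="after")
    def _check_times(self) -> "Stay":
        if self.discharge_ts < self.admission_ts:
            raise ValueError(f"stay {self.stay_id}: discharge before admission")
        if self.death_ts is not None:
            if not (self.admission_ts <= self.death_ts <= self.discharge_ts):
                raise ValueError(
                    f"stay {self.stay_id}: death_ts outside [admission, discharge]"
                    " — only in-hospital deaths are accepted"
                )
        return self

    @property
    def length_of_stay_hours(self) -> float:
        return (self.discharge_ts - self.admission_ts) / HOUR


class LabMeasurement(BaseModel):
    """A hemoglobin measurement, canonical unit g/dL."""

    stay_id: str
    analyte: str = "hemoglobin"
    value: float = Field(gt=0, le=25)
    ts: datetime

    @field_validator("analyte")
    @classmethod
    def _analyte(cls, v: str) -> str:
        if v != "hemoglobin":
            raise ValueError(f"unsupported analyte {v!r}")
        return v


class TransfusionEvent(BaseModel):
    stay_id: str
    product: BloodProduct
    units: int = Field(ge=1)
    ts: datetime


class PrescriptionEvent(BaseModel):
    stay_id: str
    atc_code: str = ""
    agent_name: str = ""
    ts: Optional[datetime] = None

    @model_validator(mode="after")
    def _check(self) -> "PrescriptionEvent":
        self.agent_name = self.agent_name.strip().lower()
        self.atc_code = self.atc_code.strip().upper()
        if not self.atc_code and not self.agent_name:
            raise ValueError("prescription needs atc_code or agent_name")
        if self.atc_code and not _ATC_RE.match(self.atc_code):
            raise ValueError(f"invalid ATC code {self.atc_code!r}")
        return self


class DiagnosisRecord(BaseModel):
    stay_id: str
    icd10gm_code: str
    present_on_admission: Optional[bool] = None

    @field_validator("icd10gm_code")
    @classmethod
    def _code(cls, v: str) -> str:
        from .icd import normalize_code  # late import: avoid cycle

        return normalize_code(v)


class StayBundle(BaseModel):
    """All structured events for one stay — the unit of classification."""

    stay: Stay
    labs: list[LabMeasurement] = Field(default_factory=list)
    transfusions: list[TransfusionEvent] = Field(default_factory=list)
    prescriptions: list[PrescriptionEvent] = Field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "StayBundle":
        sid = self.stay.stay_id
        for group in (self.labs, self.transfusions, self.prescriptions, self.diagnoses):
            for rec in group:
                if rec.stay_id != sid:
                    raise ValueError(f"record stay_id {rec.stay_id!r} != bundle {sid!r}")
        self.labs = sorted(self.labs, key=lambda m: m.ts)
        return self

    @property
    def stay_id(self) -> str:
        return self.stay.stay_id


class EligibilityConfig(BaseModel):
    """Cohort eligibility: age >= 65, >= 1 antithrombotic, stay >= 24 h.

    The 24-h boundary is inclusive: a stay of exactly 24 h qualifies.
    """

    min_age_years: int = 65
    min_stay_hours: float = 24.0
    antithrombotic_atc_prefixes: tuple[str, ...] = DEFAULT_ANTITHROMBOTIC_ATC_PREFIXES


class CohortLoadResult(BaseModel):
    """Bundles plus the load report (orphan child rows are reported, not dropped
    silently)."""

    bundles: list[StayBundle]
    orphans: dict[str, int] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)

    def __iter__(self):
        return iter(self.bundles)

    def __len__(self) -> int:
        return len(self.bundles)


# ---------------------------------------------------------------------------
# loading


def _parse_ts(raw, *, file: str, row: int, column: str, timezone: Optional[str]):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        ts = pd.Timestamp(str(raw))
    except Exception as exc:
        raise LoadError(f"unparseable ISO-8601 timestamp {raw!r}: {exc}",
                        file=file, row=row, column=column) from None
    if ts.tzinfo is not None:
        ts = ts.tz_convert(timezone) if timezone else ts.tz_convert("UTC")
        ts = ts.tz_localize(None)
    return ts.to_pydatetime()


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise LoadError("table file not found", file=str(path))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"missing columns {missing}", file=str(path))
    return df


def _canonical_hb(value: float, unit: str, *, file: str, row: int) -> float:
    u = unit.strip().lower().replace(" ", "")
    if u in ("g/dl", "g/dl."):
        return value
    if u == "g/l":
        return value / 10.0
    raise LoadError(
        f"ambiguous or missing hemoglobin unit declaration {unit!r} "
        "(expected 'g/dL' or 'g/L'; units are never guessed from magnitude)",
        file=file, row=row, column="unit",
    )


def load_cohort(
    cohort_dir: str | Path | Mapping[str, str | Path],
    *,
    default_lab_unit: Optional[str] = None,
    timezone: Optional[str] = None,
    lab_tolerance_hours: float = 24.0,
) -> CohortLoadResult:
    """Read the five cohort tables and assemble one :class:`StayBundle` per stay.

    Parameters
    ----------
    cohort_dir:
        Directory containing ``stays.csv`` etc., or a mapping from table name
        (``stays``, ``labs``, ``transfusions``, ``prescriptions``,
        ``diagnoses``) to file path. Only ``stays`` is mandatory.
    default_lab_unit:
        Unit assumed for lab rows whose ``unit`` cell is empty. Without it an
        empty unit cell is a configuration error.
    timezone:
        IANA zone used to interpret timezone-aware timestamps; naive
        timestamps are taken as already being in the cohort zone.
    lab_tolerance_hours:
        Labs outside ``[admission - tol, discharge + tol]`` are rejected with
        a warning (pre-admission labs would corrupt the 48-h drop rule).
    """
    if isinstance(cohort_dir, Mapping):
        paths = {k: Path(v) for k, v in cohort_dir.items()}
    else:
        d = Path(cohort_dir)
        paths = {name: d / f"{name}.csv" for name in
                 ("stays", "labs", "transfusions", "prescriptions", "diagnoses")}

    stays_df = _read_table(paths["stays"], ["stay_id", "patient_id", "admission_ts",
                                            "discharge_ts", "age_years", "sex"])
    stays: dict[str, Stay] = {}
    order: list[str] = []
    sfile = str(paths["stays"])
    for i, rec in enumerate(stays_df.to_dict("records")):
        sid = str(rec["stay_id"]).strip()
        if not sid:
            raise LoadError("empty stay_id", file=sfile, row=i, column="stay_id")
        if sid in stays:
            raise LoadError(f"duplicate stay_id {sid!r}", file=sfile, row=i,
                            column="stay_id")
        try:
            stay = Stay(
                stay_id=sid,
                patient_id=str(rec["patient_id"]),
                admission_ts=_parse_ts(rec["admission_ts"], file=sfile, row=i,
                                       column="admission_ts", timezone=timezone),
                discharge_ts=_parse_ts(rec["discharge_ts"], file=sfile, row=i,
                                       column="discharge_ts", timezone=timezone),
                death_ts=_parse_ts(rec.get("death_ts", ""), file=sfile, row=i,
                                   column="death_ts", timezone=timezone),
                age_years=int(rec["age_years"]),
                sex=Sex(rec["sex"]) if rec["sex"] else Sex.other,
                hospital_id=str(rec.get("hospital_id", "")),
            )
        except LoadError:
            raise
        except (ValueError, TypeError) as exc:
            raise LoadError(str(exc), file=sfile, row=i) from None
        stays[sid] = stay
        order.append(sid)

    labs: dict[str, list[LabMeasurement]] = {sid: [] for sid in stays}
    transfusions: dict[str, list[TransfusionEvent]] = {sid: [] for sid in stays}
    prescriptions: dict[str, list[PrescriptionEvent]] = {sid: [] for sid in stays}
    diagnoses: dict[str, list[DiagnosisRecord]] = {sid: [] for sid in stays}
    orphans: dict[str, int] = {}
    warn_msgs: list[str] = []
    tol = timedelta(hours=lab_tolerance_hours)

    if "labs" in paths and Path(paths["labs"]).exists():
        fname = str(paths["labs"])
        df = _read_table(paths["labs"], ["stay_id", "analyte", "value", "ts"])
        for i, rec in enumerate(df.to_dict("records")):
            sid = str(rec["stay_id"]).strip()
            if sid not in stays:
                orphans["labs"] = orphans.get("labs", 0) + 1
                continue
            unit = str(rec.get("unit", "")).strip() or (default_lab_unit or "")
            try:
                value = float(rec["value"])
            except ValueError:
                raise LoadError(f"non-numeric lab value {rec['value']!r}",
                                file=fname, row=i, column="value") from None
            value = _canonical_hb(value, unit, file=fname, row=i)
            ts = _parse_ts(rec["ts"], file=fname, row=i, column="ts", timezone=timezone)
            stay = stays[sid]
            if not (stay.admission_ts - tol <= ts <= stay.discharge_ts + tol):
                msg = (f"lab at {ts.isoformat()} outside stay bounds of {sid} "
                       f"(tolerance {lab_tolerance_hours} h); rejected")
                warn_msgs.append(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            try:
                labs[sid].append(LabMeasurement(stay_id=sid, analyte=rec["analyte"],
                                                value=value, ts=ts))
            except ValueError as exc:
                raise LoadError(str(exc), file=fname, row=i) from None

    if "transfusions" in paths and Path(paths["transfusions"]).exists():
        fname = str(paths["transfusions"])
        df = _read_table(paths["transfusions"], ["stay_id", "product", "units", "ts"])
        for i, rec in enumerate(df.to_dict("records")):
            sid = str(rec["stay_id"]).strip()
            if sid not in stays:
                orphans["transfusions"] = orphans.get("transfusions", 0) + 1
                continue
            try:
                transfusions[sid].append(TransfusionEvent(
                    stay_id=sid,
                    product=BloodProduct(rec["product"]),
                    units=int(rec["units"]),
                    ts=_parse_ts(rec["ts"], file=fname, row=i, column="ts",
                                 timezone=timezone),
                ))
            except ValueError as exc:
                raise LoadError(str(exc), file=fname, row=i) from None

    if "prescriptions" in paths and Path(paths["prescriptions"]).exists():
        fname = str(paths["prescriptions"])
        df = _read_table(paths["prescriptions"], ["stay_id", "atc_code", "agent_name"])
        for i, rec in enumerate(df.to_dict("records")):
            sid = str(rec["stay_id"]).strip()
            if sid not in stays:
                orphans["prescriptions"] = orphans.get("prescriptions", 0) + 1
                continue
            try:
                prescriptions[sid].append(PrescriptionEvent(
                    stay_id=sid,
                    atc_code=str(rec["atc_code"]),
                    agent_name=str(rec["agent_name"]),
                    ts=_parse_ts(rec.get("ts", ""), file=fname, row=i, column="ts",
                                 timezone=timezone),
                ))
            except ValueError as exc:
                raise LoadError(str(exc), file=fname, row=i) from None

    if "diagnoses" in paths and Path(paths["diagnoses"]).exists():
        fname = str(paths["diagnoses"])
        df = _read_table(paths["diagnoses"], ["stay_id", "icd10gm_code"])
        for i, rec in enumerate(df.to_dict("records")):
            sid = str(rec["stay_id"]).strip()
            if sid not in stays:
                orphans["diagnoses"] = orphans.get("diagnoses", 0) + 1
                continue
            poa_raw = str(rec.get("present_on_admission", "")).strip().lower()
            poa = None if poa_raw == "" else poa_raw in ("1", "true", "yes")
            try:
                diagnoses[sid].append(DiagnosisRecord(
                    stay_id=sid, icd10gm_code=rec["icd10gm_code"],
                    present_on_admission=poa))
            except ValueError as exc:
                raise LoadError(str(exc), file=fname, row=i) from None

    bundles = [StayBundle(stay=stays[sid], labs=labs[sid],
                          transfusions=transfusions[sid],
                          prescriptions=prescriptions[sid],
                          diagnoses=diagnoses[sid]) for sid in order]
    return CohortLoadResult(bundles=bundles, orphans=orphans, warnings=warn_msgs)


def write_cohort(bundles: Iterable[StayBundle], out_dir: str | Path) -> dict[str, Path]:
    """Write bundles back to the five-table CSV interchange format (g/dL)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = list(bundles)

    def iso(ts: Optional[datetime]) -> str:
        return ts.isoformat() if ts is not None else ""

    stays_rows = [{
        "stay_id": b.stay.stay_id, "patient_id": b.stay.patient_id,
        "admission_ts": iso(b.stay.admission_ts),
        "discharge_ts": iso(b.stay.discharge_ts),
        "death_ts": iso(b.stay.death_ts),
        "age_years": b.stay.age_years, "sex": b.stay.sex.value,
        "hospital_id": b.stay.hospital_id,
    } for b in bundles]
    labs_rows = [{"stay_id": m.stay_id, "analyte": m.analyte,
                  "value": repr(m.value), "unit": "g/dL", "ts": iso(m.ts)}
                 for b in bundles for m in b.labs]
    tf_rows = [{"stay_id": t.stay_id, "product": t.product.value,
                "units": t.units, "ts": iso(t.ts)}
               for b in bundles for t in b.transfusions]
    rx_rows = [{"stay_id": p.stay_id, "atc_code": p.atc_code,
                "agent_name": p.agent_name, "ts": iso(p.ts)}
               for b in bundles for p in b.prescriptions]
    dx_rows = [{"stay_id": d.stay_id, "icd10gm_code": d.icd10gm_code,
                "present_on_admission":
                    "" if d.present_on_admission is None
                    else str(d.present_on_admission).lower()}
               for b in bundles for d in b.diagnoses]

    written: dict[str, Path] = {}
    for name, rows, cols in (
        ("stays", stays_rows, ["stay_id", "patient_id", "admission_ts",
                               "discharge_ts", "death_ts", "age_years", "sex",
                               "hospital_id"]),
        ("labs", labs_rows, ["stay_id", "analyte", "value", "unit", "ts"]),
        ("transfusions", tf_rows, ["stay_id", "product", "units", "ts"]),
        ("prescriptions", rx_rows, ["stay_id", "atc_code", "agent_name", "ts"]),
        ("diagnoses", dx_rows, ["stay_id", "icd10gm_code", "present_on_admission"]),
    ):
        path = out / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        written[name] = path
    return written


def is_antithrombotic(rx: PrescriptionEvent,
                      prefixes: Sequence[str] = DEFAULT_ANTITHROMBOTIC_ATC_PREFIXES) -> bool:
    return bool(rx.atc_code) and any(rx.atc_code.startswith(p) for p in prefixes)


def filter_eligible(bundles: Iterable[StayBundle],
                    config: EligibilityConfig | None = None) -> list[StayBundle]:
    """Keep stays of patients >= 65 y with >= 1 antithrombotic and >= 24 h stay.

    The filter is total, idempotent and order-preserving.
    """
    cfg = config or EligibilityConfig()
    kept = []
    for b in bundles:
        if b.stay.age_years < cfg.min_age_years:
            continue
        if b.stay.length_of_stay_hours < cfg.min_stay_hours:
            continue
        if not any(is_antithrombotic(p, cfg.antithrombotic_atc_prefixes)
                   for p in b.prescriptions):
            continue
        kept.append(b)
    return kept
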