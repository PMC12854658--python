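"""ICD-10-GM bleeding code lists and wildcard-aware matching.

The packaged list (``data/icd10gm_bleeding_codes.csv``) carries 12 major
bleeding (MB) patterns and 41 clinically relevant nonmajor bleeding (CRNMB)
patterns, one row per pattern so the list can be audited by diff. A trailing
underscore marks a code family: ``I61_`` matches the bare stem ``I61`` and
every dotted subdivision ``I61.x``; ``M25.0_`` matches ``M25.0`` and its
subdivisions ``M25.0x``. Matching is dot-aware and operates on normalized
codes only.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Severity",
    "CodePattern",
    "CodeList",
    "normalize_code",
    "match",
    "classify_codes",
    "default_code_list",
    "IcdFlags",
]

_CODE_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,3})?$")


class Severity(str, enum.Enum):
    MB = "MB"
    CRNMB = "CRNMB"


def normalize_code(raw: str) -> str:
    """Canonicalize an ICD-10 code: uppercase, strip, insert the dot.

    ``"i61.0" -> "I61.0"``; dotless forms of 4+ characters get a dot after
    position 3 (``"K250" -> "K25.0"``). Raises ``ValueError`` on syntactically
    invalid codes (e.g. a missing chapter letter).
    """
    code = str(raw).strip().upper()
    if not code:
        raise ValueError("empty ICD-10 code")
    if "." not in code and len(code) >= 4:
        code = code[:3] + "." + code[3:]
    if not _CODE_RE.match(code):
        raise ValueError(f"syntactically invalid ICD-10 code {raw!r}")
    return code


@dataclass(frozen=True)
class CodePattern:
    """One Table-style list entry: an exact code or a ``_`` family wildcard."""

    pattern: str
    severity: Severity
    label: str = ""

    @property
    def is_wildcard(self) -> bool:
        return self.pattern.endswith("_")

    @property
    def stem(self) -> str:
        return self.pattern[:-1] if self.is_wildcard else self.pattern

    def matches(self, code: str) -> bool:
        """True for an exact hit, or — for wildcards — the bare stem and any
        dotted subdivision of it."""
        stem = self.stem
        if not self.is_wildcard:
            return code == stem
        if code == stem:
            return True
        if "." in stem:  # e.g. M25.0_ -> M25.0, M25.01 ...
            return code.startswith(stem)
        return code.startswith(stem + ".")


class CodeList:
    """A severity-tagged collection of :class:`CodePattern`."""

    def __init__(self, patterns: Iterable[CodePattern]):
        self.patterns = list(patterns)
        for sev in Severity:
            pats = [p.pattern for p in self.patterns if p.severity == sev]
            if len(pats) != len(set(pats)):
                raise ValueError(f"duplicate patterns in {sev.value} list")

    def for_severity(self, severity: Severity) -> list[CodePattern]:
        return [p for p in self.patterns if p.severity == severity]

    def match(self, code: str, severity: Severity | str) -> bool:
        severity = Severity(severity)
        return any(p.matches(code) for p in self.for_severity(severity))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodeList":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def _from_rows(cls, rows) -> "CodeList":
        pats = []
        for row in rows:
            pats.append(CodePattern(pattern=row["pattern"].strip(),
                                    severity=Severity(row["severity"].strip()),
                                    label=row.get("label", "").strip()))
        return cls(pats)


_default: Optional[CodeList] = None


def default_code_list() -> CodeList:
    """The packaged MB/CRNMB list (12 + 41 patterns)."""
    global _default
    if _default is None:
        ref = resources.files("bleedwatch.data") / "icd10gm_bleeding_codes.csv"
        with ref.open(newline="", encoding="utf-8") as fh:
            _default = CodeList._from_rows(csv.DictReader(fh))
    return _default


def match(code: str, severity: Severity | str,
          code_list: Optional[CodeList] = None) -> bool:
    """True iff the normalized ``code`` hits the severity's pattern list."""
    cl = code_list or default_code_list()
    return cl.match(code, severity)


@dataclass
class IcdFlags:
    mb_hit: bool
    crnmb_hit: bool
    matched: list[tuple[str, str]]  # (code, pattern)


def classify_codes(diagnoses: Sequence, code_list: Optional[CodeList] = None) -> IcdFlags:
    """Flag a stay's diagnosis set against the MB and CRNMB lists.

    ``diagnoses`` may be :class:`~bleedwatch.ehr_model.DiagnosisRecord` objects
    or plain code strings (normalized on the fly). Matched (code, pattern)
    pairs are returned for evidence reporting.
    """
    cl = code_list or default_code_list()
    mb = crnmb = False
    matched: list[tuple[str, str]] = []
    for d in diagnoses:
        code = d if isinstance(d, str) else d.icd10gm_code
        code = normalize_code(code)
        for pat in cl.patterns:
            if pat.matches(code):
                matched.append((code, pat.pattern))
                if pat.severity is Severity.MB:
                    mb = True
                else:
                    crnmb = True
    return IcdFlags(mb_hit=mb, crnmb_hit=crnmb, matched=matched)
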