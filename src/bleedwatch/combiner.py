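"""Fusion of two per-stay bleeding detectors under union / intersection.

Union: a stay is positive if either detector calls bleeding; intersection:
only if both do. When the two detectors disagree on severity, the combined
label defaults to the maximum severity (MB over CRNMB) — a conservative
hierarchy favouring the more severe call. The alternative reading, where the
text detector's severity overrides the structured one whenever both are
positive, is available via ``nlp_overrides=True``.

A "history" label (bleeding prior to admission) counts as negative for
active-bleeding combination but is preserved in the component record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .sda import round_half_away

__all__ = ["CombinedCall", "combine", "attribution_summary", "as_label_map"]

_SEVERITY_RANK = {"none": 0, "history": 0, "CRNMB": 1, "MB": 2}
_VALID = set(_SEVERITY_RANK)


@dataclass
class CombinedCall:
    stay_id: str
    label: str                  # "MB" | "CRNMB" | "none"
    mode: str                   # "union" | "intersection"
    components: dict[str, str]  # detector -> its raw label
    provenance: str             # "a_only" | "b_only" | "both" | "neither"


def as_label_map(calls) -> dict[str, str]:
    """Normalize a call collection to ``{stay_id: label}``.

    Accepts a mapping, or a sequence of objects with ``stay_id`` and
    ``label`` attributes (e.g. :class:`~bleedwatch.sda.BleedingCall`).
    """
    if isinstance(calls, Mapping):
        out = dict(calls)
    else:
        out = {c.stay_id: c.label for c in calls}
    for sid, lab in out.items():
        if lab not in _VALID:
            raise ValueError(f"stay {sid}: unknown label {lab!r}")
    return out


def _positive(label: str) -> bool:
    return _SEVERITY_RANK[label] > 0


def combine(calls_a, calls_b, mode: str, *, nlp_overrides: bool = False,
            ) -> list[CombinedCall]:
    """Combine two detectors' calls keyed by identical stay-id sets.

    ``calls_a`` is conventionally the structured detector, ``calls_b`` the
    text detector (the one whose severity wins under ``nlp_overrides``).
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    a = as_label_map(calls_a)
    b = as_label_map(calls_b)
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise ValueError(
            f"stay_id sets differ: only in a={only_a[:10]}, only in b={only_b[:10]}")

    out = []
    for sid in a:
        la, lb = a[sid], b[sid]
        pa, pb = _positive(la), _positive(lb)
        if pa and pb:
            prov = "both"
        elif pa:
            prov = "a_only"
        elif pb:
            prov = "b_only"
        else:
            prov = "neither"

        if mode == "union":
            positive = pa or pb
        else:
            positive = pa and pb
        if not positive:
            label = "none"
        elif nlp_overrides and pa and pb:
            label = lb
        else:
            label = max((la, lb), key=lambda l: _SEVERITY_RANK[l])
        out.append(CombinedCall(stay_id=sid, label=label, mode=mode,
                                components={"a": la, "b": lb}, provenance=prov))
    return out


def attribution_summary(combined: Sequence[CombinedCall], severity: str
                        ) -> dict[str, dict[str, float | int]]:
    """Contribution of each detector to positives of one severity tier.

    A component contributes to a stay if its own label equals ``severity``;
    the denominator is the number of union-positive stays at that severity.
    Shares are percentages rounded to one decimal, half away from zero.
    Returns an empty dict when there are no positives (no division by zero).
    """
    positives = [c for c in combined if c.label == severity]
    if not positives:
        return {}
    n = len(positives)
    a_only = b_only = both = 0
    for c in positives:
        ca = c.components["a"] == severity
        cb = c.components["b"] == severity
        if ca and cb:
            both += 1
        elif ca:
            a_only += 1
        elif cb:
            b_only += 1
        else:  # combined label reached this severity via one side only
            both += 0
    return {
        "a_only": {"count": a_only, "pct": round_half_away(100.0 * a_only / n, 1)},
        "b_only": {"count": b_only, "pct": round_half_away(100.0 * b_only / n, 1)},
        "both": {"count": both, "pct": round_half_away(100.0 * both / n, 1)},
        "total": {"count": n, "pct": 100.0},
    }
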