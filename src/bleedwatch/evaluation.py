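"""Diagnostic-accuracy validation against gold-standard labels.

Two binary scenarios mirror chart-review validation practice:

* ``mb_vs_rest`` — major bleeding vs everything else (CRNMB or none);
* ``crnmb_vs_none`` — CRNMB vs no bleeding, with gold-MB stays excluded
  from the denominator;
* ``all_bleeding`` — any bleeding (MB or CRNMB) vs none.

Six metrics (sensitivity, specificity, PPV, NPV, accuracy, F1) are computed
from the confusion counts; every proportion carries a Wilson-score 95% CI
(F1 gets no interval). Interrater reliability uses Fleiss kappa with the
Landis–Koch interpretation bands. Metrics with a zero denominator are
reported as undefined (``None`` with a reason), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.proportion import proportion_confint

from .combiner import as_label_map
from .sda import BleedingCall

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "MetricsReport",
    "binarize",
    "metrics",
    "wilson_ci",
    "fleiss_kappa",
    "landis_koch_band",
    "source_contribution",
    "SCENARIOS",
]

SCENARIOS = ("all_bleeding", "mb_vs_rest", "crnmb_vs_none")

# negative-class mapping: "history" denotes pre-admission bleeding and is
# negative in both active-bleeding scenarios
_NEGATIVE_EQUIV = {"history": "none"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize(calls, gold, scenario: str) -> ConfusionCounts:
    """Confusion counts of detector ``calls`` against ``gold`` labels.

    Both arguments may be mappings ``{stay_id: label}`` or sequences of call
    objects; the stay-id sets must agree. In ``crnmb_vs_none`` stays whose
    gold label is MB are excluded from the denominator and a call is positive
    only when it is exactly CRNMB.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    c = {k: _NEGATIVE_EQUIV.get(v, v) for k, v in as_label_map(calls).items()}
    g = {k: _NEGATIVE_EQUIV.get(v, v) for k, v in as_label_map(gold).items()}
    if set(c) != set(g):
        raise ValueError("calls and gold must share the same stay_ids")

    if scenario == "all_bleeding":
        pos = lambda l: l in ("MB", "CRNMB")
        keep = lambda gl: True
    elif scenario == "mb_vs_rest":
        pos = lambda l: l == "MB"
        keep = lambda gl: True
    else:  # crnmb_vs_none
        pos = lambda l: l == "CRNMB"
        keep = lambda gl: gl != "MB"

    tp = fp = tn = fn = 0
    for sid, gl in g.items():
        if not keep(gl):
            continue
        call_pos, gold_pos = pos(c[sid]), pos(gl)
        if call_pos and gold_pos:
            tp += 1
        elif call_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def wilson_ci(successes: int, trials: int, level: float = 0.95
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    Exact at the edges: (0, n) has lower bound exactly 0 and (n, n) upper
    bound exactly 1.
    """
    if trials < 1:
        raise ValueError("wilson_ci requires trials >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials, alpha=1 - level,
                                   method="wilson")
    # the score interval is algebraically exact at the degenerate edges
    if successes == 0:
        low = 0.0
    if successes == trials:
        high = 1.0
    return (float(min(max(low, 0.0), 1.0)), float(min(max(high, 0.0), 1.0)))


@dataclass
class MetricValue:
    point: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    undefined_reason: Optional[str] = None


@dataclass
class MetricsReport:
    scenario: Optional[str]
    counts: ConfusionCounts
    values: dict[str, MetricValue] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        out = {}
        for name, mv in self.values.items():
            out[name] = None if mv.point is None else round(mv.point, ndigits)
        return out

    def to_dict(self) -> dict:
        d: dict = {"scenario": self.scenario,
                   "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                              "tn": self.counts.tn, "fn": self.counts.fn}}
        for name, mv in self.values.items():
            d[name] = {"point": mv.point, "ci_low": mv.ci_low,
                       "ci_high": mv.ci_high}
            if mv.undefined_reason:
                d[name]["undefined_reason"] = mv.undefined_reason
        return d


def metrics(counts: ConfusionCounts, scenario: Optional[str] = None,
            level: float = 0.95) -> MetricsReport:
    """Six accuracy metrics with Wilson CIs on every proportion (no CI on F1)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    values: dict[str, MetricValue] = {}

    def prop(name: str, num: int, den: int, why: str) -> Optional[float]:
        if den == 0:
            values[name] = MetricValue(point=None, undefined_reason=why)
            return None
        p = num / den
        lo, hi = wilson_ci(num, den, level)
        values[name] = MetricValue(point=p, ci_low=lo, ci_high=hi)
        return p

    sens = prop("sensitivity", tp, tp + fn, "no gold-positive stays")
    prop("specificity", tn, tn + fp, "no gold-negative stays")
    ppv = prop("ppv", tp, tp + fp, "no positive calls")
    prop("npv", tn, tn + fn, "no negative calls")
    prop("accuracy", tp + tn, counts.n, "no evaluated stays")

    if sens is None or ppv is None or (sens + ppv) == 0:
        values["f1"] = MetricValue(point=None,
                                   undefined_reason="precision or recall undefined")
    else:
        values["f1"] = MetricValue(point=2 * ppv * sens / (ppv + sens))
    return MetricsReport(scenario=scenario, counts=counts, values=values)


# ---------------------------------------------------------------------------
# interrater agreement

_LANDIS_KOCH = (
    (0.80, "almost perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (0.00, "slight"),
)


def landis_koch_band(kappa: float) -> str:
    """Verbal agreement band: >0.80 almost perfect, 0.61-0.80 substantial,
    0.41-0.60 moderate, 0.21-0.40 fair, 0.00-0.20 slight, <0.00 poor."""
    if kappa < 0.0:
        return "poor"
    for cut, name in _LANDIS_KOCH:
        if kappa > cut:
            return name
    return "slight"


def fleiss_kappa(matrix) -> tuple[float, str]:
    """Fleiss kappa over an items x raters table of categorical ratings.

    Classic Fleiss requires the same number of raters per item; a row with a
    missing rating is a usage error. Returns the kappa and its Landis–Koch
    band.
    """
    arr = np.asarray(matrix, dtype=object)
    if arr.ndim != 2:
        raise ValueError("rating matrix must be items x raters (2-D)")
    n_items, n_raters = arr.shape
    if n_items < 2 or n_raters < 2:
        raise ValueError("need >= 2 items and >= 2 raters")
    for i in range(n_items):
        for j in range(n_raters):
            v = arr[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(
                    f"item {i} lacks a rating from rater {j}: classic Fleiss "
                    "kappa requires a fixed rater count per item")
    table, _ = aggregate_raters(arr)
    kappa = float(_sm_fleiss_kappa(table, method="fleiss"))
    return kappa, landis_koch_band(kappa)


# ---------------------------------------------------------------------------
# source contribution / overlap


def source_contribution(calls: Sequence[BleedingCall], severity: str) -> dict:
    """Per-source detection counts and the overlap histogram for one tier.

    A source's share is its count over the number of positive stays at that
    severity; shares may sum past 100% because sources overlap. The histogram
    counts stays detected by exactly m sources; its total equals the number
    of positive stays. Empty when there are no positives.
    """
    positives = [c for c in calls if c.label == severity]
    if not positives:
        return {}
    n = len(positives)
    per_source: dict[str, int] = {}
    histogram = {1: 0, 2: 0, 3: 0, 4: 0}
    for c in positives:
        srcs = {s.value for s in c.sources_fired}
        for s in srcs:
            per_source[s] = per_source.get(s, 0) + 1
        histogram[len(srcs)] += 1
    from .sda import round_half_away

    return {
        "n_positive": n,
        "per_source": {s: {"count": k,
                           "pct": round_half_away(100.0 * k / n, 2)}
                       for s, k in sorted(per_source.items())},
        "overlap_histogram": histogram,
    }
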