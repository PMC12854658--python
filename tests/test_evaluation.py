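"""Binarization scenarios, metrics with Wilson CIs, Fleiss kappa, and
source-contribution accounting."""

import numpy as np
import pytest

from bleedwatch.evaluation import (ConfusionCounts, binarize, fleiss_kappa,
                                   landis_koch_band, metrics,
                                   source_contribution, wilson_ci)
from bleedwatch.sda import BleedingCall, Source

from conftest import fleiss_by_hand, wilson_closed_form


class TestBinarize:
    GOLD = {"a": "MB", "b": "CRNMB", "c": "none"}

    def test_identical_calls_mb_vs_rest(self):
        c = binarize(self.GOLD, self.GOLD, "mb_vs_rest")
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 0, 0)

    def test_crnmb_scenario_excludes_gold_mb(self):
        c = binarize(self.GOLD, self.GOLD, "crnmb_vs_none")
        assert c.n == 2 and c.tp == 1 and c.tn == 1

    def test_all_none_calls_are_false_negatives(self):
        gold = {f"s{i}": "MB" for i in range(5)}
        calls = {f"s{i}": "none" for i in range(5)}
        c = binarize(calls, gold, "mb_vs_rest")
        assert c.fn == 5 and c.tp == c.fp == c.tn == 0

    def test_history_counts_as_negative(self):
        c = binarize({"a": "history"}, {"a": "none"}, "all_bleeding")
        assert c.tn == 1

    def test_conservation_per_scenario(self):
        gold = {"a": "MB", "b": "MB", "c": "CRNMB", "d": "none", "e": "none"}
        calls = {"a": "MB", "b": "none", "c": "MB", "d": "CRNMB", "e": "none"}
        for scenario, evaluated in (("all_bleeding", 5), ("mb_vs_rest", 5),
                                    ("crnmb_vs_none", 3)):
            assert binarize(calls, gold, scenario).n == evaluated

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            binarize(self.GOLD, self.GOLD, "roc")


class TestMetrics:
    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                     "f1"):
            assert rep.values[name].point == 1.0

    def test_f1_harmonic_mean(self):
        """Counts giving precision 0.51 and recall 0.84 yield F1 ~ 0.635."""
        rep = metrics(ConfusionCounts(tp=232, fp=223, tn=255, fn=44))
        sens = rep.values["sensitivity"].point
        ppv = rep.values["ppv"].point
        assert sens == pytest.approx(232 / 276)
        assert ppv == pytest.approx(232 / 455)
        f1_oracle = 2 * ppv * sens / (ppv + sens)
        assert rep.values["f1"].point == pytest.approx(f1_oracle)
        assert rep.values["f1"].point == pytest.approx(0.6347, abs=5e-4)
        assert rep.values["f1"].ci_low is None  # no CI on F1

    def test_undefined_metric_is_none_with_reason(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert rep.values["ppv"].point is None
        assert rep.values["ppv"].undefined_reason
        assert rep.values["sensitivity"].point == 0.0

    def test_accuracy_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 40, 4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            n = tp + fp + tn + fn
            sens = rep.values["sensitivity"].point
            spec = rep.values["specificity"].point
            assert rep.values["accuracy"].point == pytest.approx(
                (sens * (tp + fn) + spec * (tn + fp)) / n)


class TestWilson:
    def test_degenerate_edges_exact(self):
        assert wilson_ci(0, 10)[0] == 0.0
        assert wilson_ci(10, 10)[1] == 1.0

    def test_published_style_interval(self):
        """232/276 = 0.84 with a Wilson 95% CI printing as 0.79-0.88."""
        lo, hi = wilson_ci(232, 276)
        assert lo == pytest.approx(0.79276, abs=1e-5)
        assert hi == pytest.approx(0.87905, abs=1e-5)
        assert (round(lo, 2), round(hi, 2)) == (0.79, 0.88)

    def test_matches_closed_form_to_1e12(self):
        for successes, trials in [(0, 10), (10, 10), (232, 276), (1, 2),
                                  (7, 1000), (499, 1000), (144, 754)]:
            lo, hi = wilson_ci(successes, trials)
            olo, ohi = wilson_closed_form(successes, trials)
            assert lo == pytest.approx(olo, abs=1e-12)
            assert hi == pytest.approx(ohi, abs=1e-12)

    def test_ci_contains_point_and_shrinks_with_trials(self):
        for k, n in [(3, 10), (30, 100), (300, 1000)]:
            lo, hi = wilson_ci(k, n)
            assert lo <= k / n <= hi
        widths = [wilson_ci(3 * m, 10 * m)[1] - wilson_ci(3 * m, 10 * m)[0]
                  for m in (1, 10, 100)]
        assert widths[0] > widths[1] > widths[2]

    def test_zero_trials_is_error(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestFleissKappa:
    def test_perfect_agreement(self):
        mat = [["yes"] * 3 for _ in range(6)]
        mat[0] = ["no"] * 3  # avoid a single-category degenerate table
        k, band = fleiss_kappa(mat)
        assert k == pytest.approx(1.0)
        assert band == "almost perfect"

    def test_hand_computed_four_item_example(self):
        """3 raters, 2 categories, 4 items: P-bar = 2/3, P-bar-e = 1/2,
        kappa = 1/3."""
        mat = [["a", "a", "a"],
               ["b", "b", "b"],
               ["a", "a", "b"],
               ["a", "b", "b"]]
        k, band = fleiss_kappa(mat)
        assert k == pytest.approx(1 / 3)
        assert k == pytest.approx(fleiss_by_hand(mat))
        assert band == "fair"

    def test_permuted_labels_give_near_zero_kappa(self):
        """Independently shuffling each rater's column destroys agreement."""
        rng = np.random.default_rng(8)
        base = [["pos"] * 4 if i < 20 else ["neg"] * 4 for i in range(40)]
        kappas = []
        for _ in range(1000):
            mat = np.array(base, dtype=object)
            for j in range(mat.shape[1]):
                mat[:, j] = mat[rng.permutation(40), j]
            kappas.append(fleiss_kappa(mat)[0])
        assert abs(float(np.mean(kappas))) < 0.1

    def test_band_cut_points(self):
        assert landis_koch_band(0.65) == "substantial"
        assert landis_koch_band(0.81) == "almost perfect"
        assert landis_koch_band(0.15) == "slight"
        assert landis_koch_band(-0.2) == "poor"

    def test_missing_rating_is_usage_error(self):
        with pytest.raises(ValueError, match="fixed rater count"):
            fleiss_kappa([["a", "b"], ["a", None]])
        with pytest.raises(ValueError):
            fleiss_kappa([["a", "b"]])  # a single item


class TestSourceContribution:
    def _call(self, sid, label, sources):
        return BleedingCall(stay_id=sid, label=label,
                            sources_fired={Source(s) for s in sources})

    def test_counting_example(self):
        calls = [self._call("1", "MB", ["laboratory"]),
                 self._call("2", "MB", ["laboratory", "icd"]),
                 self._call("3", "MB", ["icd"]),
                 self._call("4", "none", [])]
        out = source_contribution(calls, "MB")
        assert out["per_source"]["laboratory"]["count"] == 2
        assert out["per_source"]["icd"]["count"] == 2
        assert out["overlap_histogram"] == {1: 2, 2: 1, 3: 0, 4: 0}

    def test_empty(self):
        assert source_contribution([], "MB") == {}

    def test_histogram_conserves_positives(self, small_cohort):
        from bleedwatch.sda import classify_cohort

        _, bundles, _ = small_cohort
        calls = classify_cohort(bundles)
        for sev in ("MB", "CRNMB"):
            out = source_contribution(calls, sev)
            if out:
                assert sum(out["overlap_histogram"].values()) == out["n_positive"]
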