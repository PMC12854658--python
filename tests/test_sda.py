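"""Rule-engine unit tests: drop/nadir primitives, boundary suite, precedence,
prevalence arithmetic, and the all-pairs oracle property."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bleedwatch.sda import (BleedingCall, Criterion, classify_stay,
                            cohort_prevalence, death_within, max_hb_drop,
                            min_hb, round_half_away, transfusion_total,
                            antihemorrhagic_hit, PrevalenceTable)

from conftest import T0, brute_force_max_drop, hours, make_bundle


def _pts(pairs):
    return [(T0 + hours(h), v) for h, v in pairs]


class TestMaxHbDrop:
    def test_single_pair(self):
        ev = max_hb_drop(_pts([(0, 14.0), (24, 9.5)]))
        assert ev.drop == pytest.approx(4.5)

    def test_window_exclusion(self):
        assert max_hb_drop(_pts([(0, 12.0), (60, 7.5)])) is None

    def test_drop_after_recovery_peak(self):
        ev = max_hb_drop(_pts([(0, 10.0), (24, 12.0), (48, 9.0)]))
        assert ev.drop == pytest.approx(3.0)
        assert ev.start_ts == T0 + hours(24) and ev.end_ts == T0 + hours(48)

    def test_unsorted_input_is_usage_error(self):
        with pytest.raises(ValueError, match="sorted"):
            max_hb_drop(_pts([(24, 12.0), (0, 10.0)]))

    def test_monotone_rise_yields_none(self):
        assert max_hb_drop(_pts([(0, 9.0), (10, 10.0), (20, 11.0)])) is None

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 200), st.floats(1, 20)),
                    min_size=0, max_size=40))
    def test_equals_all_pairs_brute_force(self, raw):
        """The O(n) engine agrees with the O(n^2) oracle, including ties."""
        raw = sorted([(round(h, 2), round(v, 2)) for h, v in raw])
        ev = max_hb_drop(_pts(raw))
        oracle = brute_force_max_drop(raw)
        if oracle is None:
            assert ev is None
        else:
            assert ev is not None
            assert ev.drop == pytest.approx(oracle["drop"])
            assert ev.end_ts == T0 + hours(oracle["end_h"])
            assert ev.start_ts == T0 + hours(oracle["start_h"])


class TestMinHb:
    def test_simple_and_empty(self):
        assert min_hb(_pts([(0, 9.1), (12, 6.8)])) == (6.8, T0 + hours(12))
        assert min_hb([]) is None

    def test_tie_takes_earliest_timestamp(self):
        assert min_hb(_pts([(0, 8.0), (10, 8.0)])) == (8.0, T0)


class TestDeathWithin:
    @pytest.mark.parametrize("death_h,expected", [
        (12, True), (25, False), (24, True), (-1, False), (0, True),
    ])
    def test_horizon_inclusive(self, death_h, expected):
        assert death_within(T0, T0 + hours(death_h)) is expected

    def test_no_death(self):
        assert death_within(T0, None) is False


class TestTransfusionAndAgents:
    def test_cumulative_units_and_plasma_exclusion(self):
        b = make_bundle(transfusions=[("red_blood_cells", 3),
                                      ("red_blood_cells", 3)])
        assert transfusion_total(b.transfusions) == 6
        plasma = make_bundle(transfusions=[("plasma", 8)])
        assert transfusion_total(plasma.transfusions) == 0

    def test_antihemorrhagic_word_boundary_match(self):
        assert antihemorrhagic_hit(
            make_bundle(agents=["Idarucizumab"]).prescriptions)
        assert antihemorrhagic_hit(
            make_bundle(agents=["Beriplex P/N 500"]).prescriptions)
        assert not antihemorrhagic_hit(
            make_bundle(agents=["enoxaparin"]).prescriptions)


class TestClassifyStay:
    @pytest.mark.parametrize("kwargs,label,criterion", [
        # nadir below 7 is MB outright
        (dict(labs=[(0, 8.0), (12, 6.8)]), "MB", Criterion.HB_MIN_LT7),
        # 2-4 drop without death is CRNMB (end value kept above the 7-9 band)
        (dict(labs=[(0, 13.0), (24, 10.0)]), "CRNMB",
         Criterion.HB_DROP_2TO4_NO_DEATH),
        # same drop with death 12 h after the drop's end is MB
        (dict(labs=[(0, 13.0), (24, 10.0)], death_h=36), "MB",
         Criterion.HB_DROP_2TO4_DEATH24),
        # nadir in band with death at the nadir + 24 h exactly (inclusive)
        (dict(labs=[(0, 10.5), (24, 8.5)], death_h=48), "MB",
         Criterion.HB_MIN_7TO9_DEATH24),
        # CRNMB diagnosis alone
        (dict(codes=["K92.2"]), "CRNMB", Criterion.ICD_CRNMB),
        # MB diagnosis alone
        (dict(codes=["I61.0"]), "MB", Criterion.ICD_MB),
        # transfusions: 6 units fire, strictly more than 5
        (dict(transfusions=[("red_blood_cells", 6)]), "MB",
         Criterion.TRANSFUSION_GT5),
        (dict(transfusions=[("red_blood_cells", 5)]), "none", None),
        (dict(agents=["octaplex"]), "MB", Criterion.ANTIHEMORRHAGIC_RX),
        (dict(), "none", None),
    ])
    def test_rule_cascade(self, kwargs, label, criterion):
        call = classify_stay(make_bundle(**kwargs))
        assert call.label == label
        if criterion is not None:
            assert criterion in call.criteria_fired
        else:
            assert not call.criteria_fired

    @pytest.mark.parametrize("drop,label", [
        (1.99, "none"), (2.00, "CRNMB"), (3.99, "CRNMB"), (4.00, "MB"),
    ])
    def test_drop_boundaries(self, drop, label):
        call = classify_stay(make_bundle([(0, 14.0), (24, 14.0 - drop)]))
        assert call.label == label, f"drop {drop}"

    @pytest.mark.parametrize("nadir,label", [
        (6.99, "MB"), (7.00, "CRNMB"), (9.00, "CRNMB"), (9.01, "none"),
    ])
    def test_nadir_boundaries(self, nadir, label):
        # flat series: no drop can interfere
        call = classify_stay(make_bundle([(0, nadir + 0.5), (12, nadir)]))
        assert call.label == label, f"nadir {nadir}"

    def test_mb_precedence_over_crnmb(self):
        """An MB diagnosis dominates a co-occurring CRNMB-band drop."""
        call = classify_stay(make_bundle([(0, 13.0), (24, 10.5)],
                                         codes=["I61.0"]))
        assert call.label == "MB"
        assert Criterion.HB_DROP_2TO4_NO_DEATH in call.criteria_fired
        # attribution only credits the winning tier
        assert {s.value for s in call.sources_fired} == {"icd"}

    def test_mb_mortality_flag(self):
        fatal = classify_stay(make_bundle([(0, 8.0), (12, 6.5)], death_h=100))
        assert fatal.label == "MB" and fatal.mb_mortality
        survivor = classify_stay(make_bundle([(0, 8.0), (12, 6.5)]))
        assert survivor.label == "MB" and not survivor.mb_mortality
        # death in a CRNMB stay does not set the flag
        crnmb = classify_stay(make_bundle([(0, 13.0), (24, 10.5)], death_h=190))
        assert crnmb.label == "CRNMB" and not crnmb.mb_mortality

    def test_single_measurement_supports_nadir_but_not_drop(self):
        call = classify_stay(make_bundle([(0, 6.5)]))
        assert call.criteria_fired == {Criterion.HB_MIN_LT7}

    def test_adding_mb_event_never_lowers_severity(self, small_cohort):
        """Monotonicity: appending an MB diagnosis forces MB everywhere."""
        _, bundles, _ = small_cohort
        from bleedwatch.ehr_model import DiagnosisRecord

        for b in bundles[:40]:
            before = classify_stay(b)
            augmented = b.model_copy(deep=True)
            augmented.diagnoses.append(
                DiagnosisRecord(stay_id=b.stay_id, icd10gm_code="I61.0"))
            after = classify_stay(augmented)
            assert after.label == "MB"
            assert before.criteria_fired <= after.criteria_fired


class TestPrevalence:
    def test_published_style_counts(self):
        """36,039-stay arithmetic: 5419 CRNMB stays are 15.04%."""
        t = PrevalenceTable(none=27641, crnmb=5419, mb=2979,
                            mb_mortality=350, denominator=36039)
        assert t.percentages["CRNMB"] == 15.04
        assert t.percentages["none"] == 76.70
        # exact value 8.2661% rounds (half away from zero) to 8.27
        assert t.percentages["MB"] == 8.27

    def test_small_and_empty(self):
        calls = [BleedingCall(stay_id="a", label="none"),
                 BleedingCall(stay_id="b", label="CRNMB"),
                 BleedingCall(stay_id="c", label="MB"),
                 BleedingCall(stay_id="d", label="MB")]
        t = cohort_prevalence(calls)
        assert t.percentages["MB"] == 50.00
        zero = cohort_prevalence([], denominator=0)
        assert all(v == 0.0 for v in zero.percentages.values())

    def test_inconsistent_counts_internal_error(self):
        with pytest.raises(RuntimeError, match="partition"):
            PrevalenceTable(none=1, crnmb=1, mb=1, mb_mortality=0,
                            denominator=4)


def test_round_half_away():
    assert round_half_away(8.265, 2) == 8.27
    assert round_half_away(-8.265, 2) == -8.27
    assert round_half_away(15.0365 * 100 / 100, 2) == 15.04
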